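"""Segmental-duplication detection and duplicate-region profiling.

Duplicated fragments are accepted when both fragments carry at least three
genes and at least half of the genes in each fragment have a homolog in the
other (homologs at e <= 1e-20 and per-sequence coverage > 80% on both
sides).  Anchors are chained in gene-order coordinates, colinear or fully
reversed, with a configurable gap tolerance; neighbouring region pairs
interrupted by less than 5 kb on both sides are merged with length-weighted
identity averaging.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, replace

import edlib
import numpy as np
import pandas as pd

from .core_io import Assembly, GeneModel, SegmentRecord

logger = logging.getLogger("ploidyscope")


def natural_key(text: str):
    """scaffold_2 sorts before scaffold_10."""
    return tuple(int(p) if p.isdigit() else p for p in re.split(r"(\d+)", text))


@dataclass
class Region:
    scaffold_id: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class DuplicatedRegionPair:
    region_a: Region
    region_b: Region
    anchor_pairs: list[tuple[str, str]]
    n_genes_a: int
    n_genes_b: int
    homolog_fraction_a: float
    homolog_fraction_b: float
    nt_identity: float = float("nan")
    identity_source: str = "anchor_alignment"

    @property
    def length(self) -> float:
        """Mean of the two region lengths."""
        return (self.region_a.length + self.region_b.length) / 2


@dataclass
class DuplicationSummary:
    duplicated_fraction_of_assembly: float
    genes_in_duplicated_regions: int
    genes_in_single_copy_regions: int
    unpaired_length: int
    mean_nt_identity: float
    content_fractions: dict[str, float]


@dataclass
class AllelicReport:
    allelic_model_ids: list[str]
    allelic_fraction: float
    scaffold_coverage: dict[str, float]


# ---------------------------------------------------------------------------
# Homolog pairs for the fragment rule
# ---------------------------------------------------------------------------

def segdup_homolog_pairs(hits, max_evalue: float = 1e-20, min_coverage: float = 80.0
                         ) -> set[tuple[str, str]]:
    """Unordered gene pairs with e <= 1e-20 and both coverages strictly > 80%."""
    pairs = set()
    for h in hits:
        if h.evalue <= max_evalue and h.query_coverage > min_coverage and h.target_coverage > min_coverage:
            pairs.add((min(h.query_id, h.target_id), max(h.query_id, h.target_id)))
    return pairs


# ---------------------------------------------------------------------------
# Fragment detection by anchor chaining
# ---------------------------------------------------------------------------

def _gene_order(genes) -> dict[str, list[GeneModel]]:
    by_scaffold: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_scaffold.setdefault(g.scaffold_id, []).append(g)
    for lst in by_scaffold.values():
        lst.sort(key=lambda g: (g.start, g.end, g.gene_id))
    return by_scaffold


def _compatible(a1, a2, max_gap: int) -> int | None:
    """Direction (+1/-1) if consecutive anchors chain, else None."""
    da = a2[0] - a1[0]
    db = a2[1] - a1[1]
    if da <= 0 or db == 0:
        return None
    if da - 1 > max_gap or abs(db) - 1 > max_gap:
        return None
    return 1 if db > 0 else -1


def detect_duplicated_fragments(genes, gene_pairs, min_genes: int = 3,
                                min_frac: float = 0.5,
                                max_anchor_gap_genes: int = 5) -> list[DuplicatedRegionPair]:
    """Chain homolog anchors into duplicated fragment pairs.

    Within each ordered scaffold pair, anchors (one gene on each scaffold)
    are chained when consecutive anchors are colinear (or consistently
    reversed) with at most ``max_anchor_gap_genes`` intervening genes on each
    side.  All chainable anchor intervals are scored against the gene-count
    and homolog-fraction rules and maximal accepted windows are returned.
    """
    by_scaffold = _gene_order(genes)
    order = {g.gene_id: (g.scaffold_id, i)
             for sid, lst in by_scaffold.items() for i, g in enumerate(lst)}
    partners: dict[str, set[str]] = {}
    for a, b in gene_pairs:
        partners.setdefault(a, set()).add(b)
        partners.setdefault(b, set()).add(a)

    # group anchors per ordered scaffold pair; gene on the smaller scaffold first
    anchors_by_pair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for a, b in gene_pairs:
        if a not in order or b not in order:
            continue
        (sa, ia), (sb, ib) = order[a], order[b]
        if sa == sb:
            if ia > ib:
                a, b, ia, ib = b, a, ib, ia
            key = (sa, sb)
        elif natural_key(sa) > natural_key(sb):
            a, b, sa, sb, ia, ib = b, a, sb, sa, ib, ia
            key = (sa, sb)
        else:
            key = (sa, sb)
        anchors_by_pair.setdefault(key, []).append((ia, ib, a, b))

    results: list[DuplicatedRegionPair] = []
    for (sa, sb), anchors in sorted(anchors_by_pair.items()):
        # one partner per gene per scaffold pair keeps chains well-defined
        anchors.sort()
        seen_a, seen_b, filtered = set(), set(), []
        for ia, ib, a, b in anchors:
            if a in seen_a or b in seen_b:
                continue
            seen_a.add(a)
            seen_b.add(b)
            filtered.append((ia, ib, a, b))
        genes_a, genes_b = by_scaffold[sa], by_scaffold[sb]
        valid_windows = []
        k = len(filtered)
        for i in range(k):
            direction = 0
            for j in range(i, k):
                if j > i:
                    d = _compatible(filtered[j - 1], filtered[j], max_anchor_gap_genes)
                    if d is None or (direction and d != direction):
                        break
                    direction = d
                window = _score_window(filtered[i : j + 1], genes_a, genes_b,
                                       sa, sb, partners, min_genes, min_frac)
                if window is not None:
                    valid_windows.append(window)
        results.extend(_maximal(valid_windows))
    logger.info("detected %d duplicated fragment pairs", len(results))
    return results


def _score_window(chain, genes_a, genes_b, sa, sb, partners, min_genes, min_frac):
    ia0, ia1 = chain[0][0], chain[-1][0]
    ibs = [c[1] for c in chain]
    ib0, ib1 = min(ibs), max(ibs)
    span_a = genes_a[ia0 : ia1 + 1]
    span_b = genes_b[ib0 : ib1 + 1]
    if len(span_a) < min_genes or len(span_b) < min_genes:
        return None
    ids_a = {g.gene_id for g in span_a}
    ids_b = {g.gene_id for g in span_b}
    hom_a = sum(1 for g in span_a if partners.get(g.gene_id, set()) & ids_b)
    hom_b = sum(1 for g in span_b if partners.get(g.gene_id, set()) & ids_a)
    frac_a = hom_a / len(span_a)
    frac_b = hom_b / len(span_b)
    if frac_a < min_frac or frac_b < min_frac:
        return None
    return DuplicatedRegionPair(
        region_a=Region(sa, span_a[0].start, span_a[-1].end),
        region_b=Region(sb, span_b[0].start, span_b[-1].end),
        anchor_pairs=[(c[2], c[3]) for c in chain],
        n_genes_a=len(span_a),
        n_genes_b=len(span_b),
        homolog_fraction_a=frac_a,
        homolog_fraction_b=frac_b,
    )


def _contains(p: DuplicatedRegionPair, q: DuplicatedRegionPair) -> bool:
    """p's windows contain q's windows (same scaffold pair)."""
    return (p.region_a.scaffold_id == q.region_a.scaffold_id
            and p.region_b.scaffold_id == q.region_b.scaffold_id
            and p.region_a.start <= q.region_a.start and p.region_a.end >= q.region_a.end
            and p.region_b.start <= q.region_b.start and p.region_b.end >= q.region_b.end)


def _maximal(windows):
    out = []
    for w in windows:
        if any(_contains(v, w) and not _contains(w, v) for v in windows):
            continue
        if any(_same_span(v, w) for v in out):
            continue
        out.append(w)
    return out


def _same_span(p, q):
    return _contains(p, q) and _contains(q, p)


# ---------------------------------------------------------------------------
# Merging neighbours
# ---------------------------------------------------------------------------

def merge_adjacent_pairs(pairs, max_gap: int = 5000) -> list[DuplicatedRegionPair]:
    """Merge neighbouring pairs separated by < max_gap on BOTH sides.

    Merged identity is the length-weighted mean of the parts (gaps excluded
    from the weighting); region spans extend across the gap.
    """
    by_key: dict[tuple[str, str], list[DuplicatedRegionPair]] = {}
    for p in pairs:
        by_key.setdefault((p.region_a.scaffold_id, p.region_b.scaffold_id), []).append(p)
    merged_all: list[DuplicatedRegionPair] = []
    for key, group in sorted(by_key.items()):
        group = sorted(group, key=lambda p: (p.region_a.start, p.region_b.start))
        current: list[DuplicatedRegionPair] = []
        for p in group:
            if current and _gap(current[-1].region_a, p.region_a) < max_gap \
                    and _gap(current[-1].region_b, p.region_b) < max_gap:
                current.append(p)
            else:
                if current:
                    merged_all.append(_merge_group(current))
                current = [p]
        if current:
            merged_all.append(_merge_group(current))
    return merged_all


def _gap(r1: Region, r2: Region) -> int:
    return max(r2.start, r1.start) - min(r1.end, r2.end)


def _merge_group(group) -> DuplicatedRegionPair:
    if len(group) == 1:
        return group[0]
    weights = np.array([p.length for p in group], dtype=float)
    idents = np.array([p.nt_identity for p in group], dtype=float)
    nt = float(np.average(idents, weights=weights)) if np.all(np.isfinite(idents)) else float("nan")
    anchors = [a for p in group for a in p.anchor_pairs]
    na = sum(p.n_genes_a for p in group)
    nb = sum(p.n_genes_b for p in group)
    ha = sum(p.homolog_fraction_a * p.n_genes_a for p in group) / na
    hb = sum(p.homolog_fraction_b * p.n_genes_b for p in group) / nb
    sources = {p.identity_source for p in group}
    return DuplicatedRegionPair(
        identity_source=sources.pop() if len(sources) == 1 else "mixed",
        region_a=Region(group[0].region_a.scaffold_id,
                        min(p.region_a.start for p in group), max(p.region_a.end for p in group)),
        region_b=Region(group[0].region_b.scaffold_id,
                        min(p.region_b.start for p in group), max(p.region_b.end for p in group)),
        anchor_pairs=anchors,
        n_genes_a=na,
        n_genes_b=nb,
        homolog_fraction_a=ha,
        homolog_fraction_b=hb,
        nt_identity=nt,
    )


# ---------------------------------------------------------------------------
# Nucleotide identity
# ---------------------------------------------------------------------------

def _global_nt_identity(a: str, b: str) -> float:
    res = edlib.align(a, b, task="distance")
    return 100.0 * (1 - res["editDistance"] / max(len(a), len(b)))


def region_nt_identity(pair: DuplicatedRegionPair, genes_by_id: dict[str, GeneModel]) -> float:
    """Length-weighted identity over globally aligned anchor gene territories.

    Anchor CDS pairs (strand-resolved) are aligned; intergenic sequence is
    excluded from the weighting.
    """
    if not pair.anchor_pairs:
        raise ValueError("region pair has no anchors")
    idents, weights = [], []
    for ga, gb in pair.anchor_pairs:
        a = genes_by_id[ga].cds
        b = genes_by_id[gb].cds
        idents.append(_global_nt_identity(a, b))
        weights.append((len(a) + len(b)) / 2)
    return float(np.average(idents, weights=weights))


def annotate_identities(pairs, genes, segment_table=None) -> list[DuplicatedRegionPair]:
    """Fill nt_identity for each pair, preferring an ingested segment table."""
    genes_by_id = {g.gene_id: g for g in genes}
    out = []
    for p in pairs:
        seg_ident = _segment_identity(p, segment_table) if segment_table else None
        if seg_ident is not None:
            out.append(replace(p, nt_identity=seg_ident, identity_source="segment_table"))
        else:
            out.append(replace(p, nt_identity=region_nt_identity(p, genes_by_id)))
    return out


def _segment_identity(pair, segments) -> float | None:
    weights, idents = [], []
    for s in segments:
        if {s.ref_scaffold, s.qry_scaffold} != {pair.region_a.scaffold_id, pair.region_b.scaffold_id}:
            continue
        ref_region = pair.region_a if s.ref_scaffold == pair.region_a.scaffold_id else pair.region_b
        overlap = min(s.ref_end, ref_region.end) - max(s.ref_start, ref_region.start)
        if overlap > 0:
            weights.append(overlap)
            idents.append(s.pct_identity)
    if not weights:
        return None
    return float(np.average(idents, weights=weights))


# ---------------------------------------------------------------------------
# Summary statistics
# ---------------------------------------------------------------------------

def _union_length(intervals) -> int:
    total = 0
    for _, ivs in _group_intervals(intervals).items():
        ivs.sort()
        cur_s, cur_e = None, None
        for s, e in ivs:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += cur_e - cur_s
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            total += cur_e - cur_s
    return total


def _group_intervals(intervals):
    grouped: dict[str, list] = {}
    for sid, s, e in intervals:
        grouped.setdefault(sid, []).append((s, e))
    return grouped


DEFAULT_IDENTITY_INTERVALS = {"gt95": (95.0, 100.0), "88.5-92.5": (88.5, 92.5)}


def duplication_summary(pairs, genes, assembly: Assembly,
                        identity_intervals: dict[str, tuple[float, float]] | None = None
                        ) -> DuplicationSummary:
    """Assembly-level duplication profile from finalized region pairs."""
    identity_intervals = identity_intervals or DEFAULT_IDENTITY_INTERVALS
    intervals = []
    for p in pairs:
        intervals.append((p.region_a.scaffold_id, p.region_a.start, p.region_a.end))
        intervals.append((p.region_b.scaffold_id, p.region_b.start, p.region_b.end))
    union = _union_length(intervals)
    total = assembly.total_length
    grouped = _group_intervals(intervals)

    def in_region(g: GeneModel) -> bool:
        return any(s <= g.midpoint < e for s, e in grouped.get(g.scaffold_id, []))

    n_dup = sum(1 for g in genes if in_region(g))
    content_total = sum(p.region_a.length + p.region_b.length for p in pairs)
    mean_ident = float("nan")
    finite = [p for p in pairs if np.isfinite(p.nt_identity)]
    if finite:
        mean_ident = float(np.average([p.nt_identity for p in finite],
                                      weights=[p.region_a.length + p.region_b.length for p in finite]))
    fractions = {}
    for name, (lo, hi) in identity_intervals.items():
        if content_total == 0:
            fractions[name] = 0.0
            continue
        mass = sum(p.region_a.length + p.region_b.length for p in finite if lo < p.nt_identity <= hi)
        fractions[name] = mass / content_total
    return DuplicationSummary(
        duplicated_fraction_of_assembly=union / total if total else 0.0,
        genes_in_duplicated_regions=n_dup,
        genes_in_single_copy_regions=len(genes) - n_dup,
        unpaired_length=total - union,
        mean_nt_identity=mean_ident,
        content_fractions=fractions,
    )


# ---------------------------------------------------------------------------
# Copy labels
# ---------------------------------------------------------------------------

def assign_copy_labels(pairs, genes) -> list[GeneModel]:
    """Label genes copy1/copy2/triplicate/unpaired by alphanumeric position.

    Within each region pair, genes on the naturally smaller (scaffold_id,
    start) region are copy1 and their counterparts copy2; genes in three or
    more pairings become triplicate; genes outside any region are unpaired.
    """
    label_votes: dict[str, set[str]] = {}
    pairing_count: dict[str, int] = {}
    for p in pairs:
        key_a = (natural_key(p.region_a.scaffold_id), p.region_a.start)
        key_b = (natural_key(p.region_b.scaffold_id), p.region_b.start)
        first_a = key_a <= key_b
        for ga, gb in p.anchor_pairs:
            la, lb = ("copy1", "copy2") if first_a else ("copy2", "copy1")
            label_votes.setdefault(ga, set()).add(la)
            label_votes.setdefault(gb, set()).add(lb)
            pairing_count[ga] = pairing_count.get(ga, 0) + 1
            pairing_count[gb] = pairing_count.get(gb, 0) + 1
    out = []
    for g in sorted(genes, key=lambda g: (natural_key(g.scaffold_id), g.start)):
        votes = label_votes.get(g.gene_id, set())
        if pairing_count.get(g.gene_id, 0) >= 2 or len(votes) > 1:
            label = "triplicate"
        elif votes:
            label = votes.pop()
        else:
            # includes genes inside a duplicated region without an anchored partner
            label = "unpaired"
        out.append(replace(g, copy_label=label))
    return out


# ---------------------------------------------------------------------------
# Allelic-model detection and whole-genome identity
# ---------------------------------------------------------------------------

def allelic_content(segments, assembly: Assembly, gene_models,
                    min_identity: float = 95.0, min_cov: float = 0.5) -> AllelicReport:
    """Models on smaller scaffolds covered >50% by >95%-identity segments.

    For each scaffold, only segments mapping it to a STRICTLY larger scaffold
    at identity > min_identity count; if their union covers more than
    min_cov of the scaffold, every gene model overlapping them is allelic.
    """
    sizes = {sid: len(seq) for sid, seq in assembly.scaffolds}
    per_scaffold: dict[str, list[tuple[int, int]]] = {}
    for s in segments:
        if s.pct_identity <= min_identity:
            continue
        for this, other, start, end in (
            (s.ref_scaffold, s.qry_scaffold, s.ref_start, s.ref_end),
            (s.qry_scaffold, s.ref_scaffold, s.qry_start, s.qry_end),
        ):
            if this in sizes and other in sizes and sizes[other] > sizes[this]:
                per_scaffold.setdefault(this, []).append((start, end))
    coverage = {}
    allelic_ids = []
    for sid, ivs in per_scaffold.items():
        cov = _union_length([(sid, s, e) for s, e in ivs]) / sizes[sid]
        coverage[sid] = cov
        if cov > min_cov:
            for g in gene_models:
                if g.scaffold_id == sid and any(g.start < e and g.end > s for s, e in ivs):
                    allelic_ids.append(g.gene_id)
    n_models = len(gene_models)
    return AllelicReport(
        allelic_model_ids=sorted(set(allelic_ids)),
        allelic_fraction=len(set(allelic_ids)) / n_models if n_models else 0.0,
        scaffold_coverage=coverage,
    )


def regions_to_segments(pairs) -> list[SegmentRecord]:
    """Express finalized duplicated region pairs as coords-style segments."""
    segs = []
    for p in pairs:
        segs.append(SegmentRecord(
            ref_scaffold=p.region_a.scaffold_id, qry_scaffold=p.region_b.scaffold_id,
            ref_start=p.region_a.start, ref_end=p.region_a.end,
            qry_start=p.region_b.start, qry_end=p.region_b.end,
            pct_identity=p.nt_identity if np.isfinite(p.nt_identity) else 0.0,
        ))
    return segs


def whole_genome_identity(segments, min_len: int = 2000) -> float:
    """Length-weighted mean identity over retained segments.

    Repetitive same-position multi-mappings (identical reference intervals)
    are collapsed to their best-identity representative.
    """
    retained = [s for s in segments if s.length >= min_len]
    best: dict[tuple, SegmentRecord] = {}
    for s in retained:
        key = (s.ref_scaffold, s.ref_start, s.ref_end)
        if key not in best or s.pct_identity > best[key].pct_identity:
            best[key] = s
    segs = list(best.values())
    if not segs:
        raise ValueError(
            "no syntenic segments of sufficient length; supply a coords-style "
            "table or lower min_len"
        )
    return float(np.average([s.pct_identity for s in segs], weights=[s.length for s in segs]))


def pairs_to_frame(pairs) -> pd.DataFrame:
    return pd.DataFrame(
        [(p.region_a.scaffold_id, p.region_a.start, p.region_a.end,
          p.region_b.scaffold_id, p.region_b.start, p.region_b.end,
          len(p.anchor_pairs), p.nt_identity, p.length) for p in pairs],
        columns=["scaffold_a", "start_a", "end_a", "scaffold_b", "start_b", "end_b",
                 "n_anchor_pairs", "nt_identity", "length"],
    )
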