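"""All-vs-all protein similarity, reciprocal best hits and identity profiles.

The search is a Smith-Waterman local alignment (BLOSUM62, gap open 11 /
extend 1) with Karlin-Altschul e-values computed against the total residue
count of the protein set.  A shared-5-mer prefilter skips pairs with no exact
word in common, the same heuristic trade-off seeded-search tools make;
sensitivity at the divergences this pipeline profiles (<= ~30% amino-acid
divergence) is unaffected.  Externally computed tabular results with the
same column semantics can be ingested instead.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices

logger = logging.getLogger("ploidyscope")

# gapped Karlin-Altschul parameters for BLOSUM62 with 11/1 affine gaps
_KA_LAMBDA = 0.267
_KA_K = 0.041


@dataclass
class HomologyHit:
    query_id: str
    target_id: str
    bitscore: float
    evalue: float
    pct_identity: float
    query_coverage: float
    target_coverage: float


@dataclass
class BBHPair:
    """Mutual best hit; gene_a < gene_b lexicographically."""

    gene_a: str
    gene_b: str
    aa_identity: float


@dataclass
class IdentityHistogram:
    bin_edges: np.ndarray  # 0..100
    fractions: np.ndarray
    n_pairs: int

    @property
    def top_bin_fraction(self) -> float:
        return float(self.fractions[-1])


def _make_aligner() -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.mode = "local"
    return aligner


def _kmer_set(seq: str, k: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _alignment_stats(alignment):
    """(identities, columns, query_span, target_span) of a pairwise alignment."""
    a, b = alignment[0], alignment[1]
    ident = sum(1 for x, y in zip(a, b) if x == y and x != "-")
    (qs, qe) = alignment.aligned[0][0][0], alignment.aligned[0][-1][1]
    (ts, te) = alignment.aligned[1][0][0], alignment.aligned[1][-1][1]
    return ident, len(a), qe - qs, te - ts


def bitscore(raw_score: float) -> float:
    return (_KA_LAMBDA * raw_score - math.log(_KA_K)) / math.log(2)


def evalue(raw_score: float, query_len: int, db_residues: int) -> float:
    return query_len * db_residues * 2.0 ** (-bitscore(raw_score))


def all_vs_all_search(proteins: dict[str, str], min_evalue: float = 1e-5,
                      kmer_size: int = 5) -> list[HomologyHit]:
    """Self-comparison of a protein set; at most one hit per ordered pair.

    Sequences must be plain amino-acid strings keyed by gene id.  Proteins
    are compared in both directions (hits are reported per query) but each
    unordered pair is aligned once.  A cheap score-only pass discards pairs
    that cannot reach the e-value cutoff before the full traceback.
    """
    if len(proteins) < 2:
        raise ValueError("need at least two proteins")
    clean = {}
    for gid, seq in proteins.items():
        seq = seq.replace("*", "")
        if seq:
            clean[gid] = seq
    db_residues = sum(len(s) for s in clean.values())
    aligner = _make_aligner()

    index: dict[str, list[str]] = defaultdict(list)
    for gid, seq in clean.items():
        for kmer in _kmer_set(seq, kmer_size):
            index[kmer].append(gid)
    shared: dict[tuple[str, str], int] = defaultdict(int)
    for members in index.values():
        if len(members) < 2:
            continue
        for i, a in enumerate(members):
            for b in members[i + 1 :]:
                if a != b:
                    shared[(min(a, b), max(a, b))] += 1
    candidates = sorted(shared)

    hits: list[HomologyHit] = []
    for a, b in candidates:
        sa, sb = clean[a], clean[b]
        raw = aligner.score(sa, sb)
        # the larger sequence bounds the query length in either direction
        if evalue(raw, max(len(sa), len(sb)), db_residues) > min_evalue:
            continue
        aln = aligner.align(sa, sb)[0]
        ident, cols, qspan, tspan = _alignment_stats(aln)
        pid = 100.0 * ident / cols
        for q, t, ql, tl, qsp, tsp in ((a, b, len(sa), len(sb), qspan, tspan),
                                       (b, a, len(sb), len(sa), tspan, qspan)):
            e = evalue(raw, ql, db_residues)
            if e <= min_evalue:
                hits.append(HomologyHit(
                    query_id=q, target_id=t, bitscore=bitscore(raw), evalue=e,
                    pct_identity=pid,
                    query_coverage=100.0 * qsp / ql,
                    target_coverage=100.0 * tsp / tl,
                ))
    logger.info("all-vs-all: %d proteins, %d candidate pairs, %d hits at e<=%g",
                len(clean), len(candidates), len(hits), min_evalue)
    return hits


def hits_to_frame(hits) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.query_id, h.target_id, h.pct_identity, h.query_coverage,
          h.target_coverage, h.bitscore, h.evalue) for h in hits],
        columns=["query", "target", "pident", "qcov", "tcov", "bitscore", "evalue"],
    )


def read_external_hits(path) -> list[HomologyHit]:
    """Ingest a 12-column tabular search result (outfmt-6 style)."""
    cols = ["query", "target", "pident", "length", "mismatch", "gapopen",
            "qstart", "qend", "tstart", "tend", "evalue", "bitscore"]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    raise_if = df[["pident", "evalue", "bitscore"]].isna().any().any()
    if raise_if:
        raise ValueError(f"malformed hit table {path}")
    hits = []
    for row in df.itertuples():
        if row.query == row.target:
            continue
        hits.append(HomologyHit(
            query_id=row.query, target_id=row.target, bitscore=row.bitscore,
            evalue=row.evalue, pct_identity=row.pident,
            query_coverage=100.0 * abs(row.qend - row.qstart + 1) / max(row.qend, row.qstart),
            target_coverage=100.0 * abs(row.tend - row.tstart + 1) / max(row.tend, row.tstart),
        ))
    return hits


def bidirectional_best_hits(hits, min_evalue: float = 1e-5) -> list[BBHPair]:
    """Mutual best hits ranked by (bitscore desc, identity desc, target asc)."""
    best: dict[str, HomologyHit] = {}
    for h in hits:
        if h.query_id == h.target_id or h.evalue > min_evalue:
            continue
        cur = best.get(h.query_id)
        if cur is None or (
            (-h.bitscore, -h.pct_identity, h.target_id)
            < (-cur.bitscore, -cur.pct_identity, cur.target_id)
        ):
            best[h.query_id] = h
        elif cur is not None and h.bitscore == cur.bitscore and h.pct_identity == cur.pct_identity \
                and h.target_id != cur.target_id:
            logger.warning("tied best hits for %s; keeping %s", h.query_id, cur.target_id)
    pairs = []
    for q, h in best.items():
        t = h.target_id
        if q < t and t in best and best[t].target_id == q:
            pairs.append(BBHPair(gene_a=q, gene_b=t, aa_identity=h.pct_identity))
    pairs.sort(key=lambda p: (p.gene_a, p.gene_b))
    return pairs


def bbh_identity_histogram(pairs, bin_width: float = 0.25) -> IdentityHistogram:
    """Per-bin fractions of BBH amino-acid identities, bins (x, x + width]."""
    n_bins = round(100 / bin_width)
    if abs(n_bins * bin_width - 100) > 1e-9:
        raise ValueError("bin_width must divide 100")
    edges = np.linspace(0, 100, n_bins + 1)
    counts = np.zeros(n_bins)
    for p in pairs:
        # left-open right-closed: identity of exactly 100 lands in the top bin
        idx = int(np.ceil(p.aa_identity / bin_width)) - 1
        idx = min(max(idx, 0), n_bins - 1)
        counts[idx] += 1
    n = len(pairs)
    if n == 0:
        logger.warning("identity histogram over zero BBH pairs")
        return IdentityHistogram(bin_edges=edges, fractions=counts, n_pairs=0)
    return IdentityHistogram(bin_edges=edges, fractions=counts / n, n_pairs=n)
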