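"""Pairwise dN/dS over duplicated gene pairs and distribution comparisons.

Two counting estimators are provided:

* ``dnds_ng86`` - Nei-Gojobori (1986): equal-weight pathway counting and
  Jukes-Cantor correction of the synonymous and nonsynonymous proportions.
* ``dnds_yn00`` - a Yang-Nielsen (2000) style estimator: kappa is estimated
  from fourfold-degenerate and nondegenerate sites via Kimura's two-parameter
  model, sites and pathways are weighted by kappa and F3x4 codon frequencies,
  and the synonymous/nonsynonymous distances receive a
  transition/transversion-corrected (K80) correction.

Pairs with no synonymous difference carry status ``dS_zero`` and are excluded
from omega distributions; corrected dS above 3 is flagged ``saturated``.
When no nonsynonymous difference is observed, omega is 0 regardless of the
size of dS, so such pairs stay usable.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
from Bio.Align import PairwiseAligner, substitution_matrices
from sklearn.mixture import GaussianMixture

from .simulate import STOP_CODONS, _AA, _TRANSITION

logger = logging.getLogger("ploidyscope")

_NTS = "ACGT"
MIN_CODONS = 30
SATURATION_DS = 3.0


class AlignmentTooShortError(ValueError):
    pass


@dataclass
class CodonAlignment:
    gene_a: str
    gene_b: str
    codons_a: list[str]
    codons_b: list[str]
    stops_removed: int = 0

    @property
    def n_codons(self) -> int:
        return len(self.codons_a)


@dataclass
class DnDsEstimate:
    gene_a: str
    gene_b: str
    dN: float
    dS: float
    omega: float | None
    method: str
    status: str  # ok | dS_zero | saturated | too_short
    kappa_hat: float | None = None
    n_codons: int = 0


@dataclass
class QQComparison:
    quantile_probs: np.ndarray
    quantiles_x: np.ndarray
    quantiles_y: np.ndarray
    r_squared: float
    slope: float
    intercept: float


# ---------------------------------------------------------------------------
# Codon alignment
# ---------------------------------------------------------------------------

_ALIGNER = None


def _protein_aligner() -> PairwiseAligner:
    global _ALIGNER
    if _ALIGNER is None:
        _ALIGNER = PairwiseAligner()
        _ALIGNER.substitution_matrix = substitution_matrices.load("BLOSUM62")
        _ALIGNER.open_gap_score = -11.0
        _ALIGNER.extend_gap_score = -1.0
        _ALIGNER.mode = "global"
    return _ALIGNER


def codon_align(cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b",
                min_codons: int = MIN_CODONS) -> CodonAlignment:
    """Global protein alignment back-translated onto codons.

    Columns containing a gap or a stop codon in either sequence are removed.
    Raises :class:`AlignmentTooShortError` when fewer than ``min_codons``
    columns survive, and ValueError for untranslatable input.
    """
    prots, codon_lists = [], []
    for name, cds in ((gene_a, cds_a), (gene_b, cds_b)):
        if len(cds) < 3:
            raise ValueError(f"{name}: CDS too short to translate")
        usable = cds[: len(cds) - len(cds) % 3]
        codons = [usable[i : i + 3] for i in range(0, len(usable), 3)]
        prot = "".join(_AA.get(c, "X") for c in codons)
        if not prot.replace("*", ""):
            raise ValueError(f"{name}: untranslatable CDS")
        prots.append(prot)
        codon_lists.append(codons)
    # align proteins with stops masked as X so a premature stop does not
    # shred the alignment; stop columns are dropped afterwards
    aln = _protein_aligner().align(prots[0].replace("*", "X"), prots[1].replace("*", "X"))[0]
    sa, sb = aln[0], aln[1]
    ia = ib = 0
    cols_a, cols_b = [], []
    stops_removed = 0
    for x, y in zip(sa, sb):
        ca = codon_lists[0][ia] if x != "-" else None
        cb = codon_lists[1][ib] if y != "-" else None
        if x != "-":
            ia += 1
        if y != "-":
            ib += 1
        if ca is None or cb is None:
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            stops_removed += 1
            continue
        if "N" in ca or "N" in cb:
            continue
        cols_a.append(ca)
        cols_b.append(cb)
    if len(cols_a) < min_codons:
        raise AlignmentTooShortError(
            f"{gene_a}/{gene_b}: {len(cols_a)} codons after gap/stop removal (< {min_codons})"
        )
    return CodonAlignment(gene_a=gene_a, gene_b=gene_b, codons_a=cols_a,
                          codons_b=cols_b, stops_removed=stops_removed)


# ---------------------------------------------------------------------------
# NG86
# ---------------------------------------------------------------------------

def _is_transition(a: str, b: str) -> bool:
    return _TRANSITION[a] == b


def _ng86_codon_sites(codon: str) -> float:
    """Synonymous site count of one codon (stop targets excluded)."""
    syn = 0.0
    for pos in range(3):
        alts = [codon[:pos] + nt + codon[pos + 1 :] for nt in _NTS if nt != codon[pos]]
        alts = [c for c in alts if c not in STOP_CODONS]
        if not alts:
            continue
        syn += sum(1 for c in alts if _AA[c] == _AA[codon]) / len(alts)
    return syn


_NG86_SITES = {c: _ng86_codon_sites(c) for c in _AA if c not in STOP_CODONS}


def _pathways(ca: str, cb: str):
    """Minimal substitution paths between two codons, avoiding stops."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    paths = []
    for order in itertools.permutations(diff):
        cur = ca
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            steps.append((cur, nxt, pos))
            cur = nxt
        if ok:
            paths.append(steps)
    return paths


def _count_differences(codons_a, codons_b, path_weight=None):
    """Accumulate per-class substitution counts over all codon columns.

    Returns (syn_ts, syn_tv, nonsyn_ts, nonsyn_tv).  ``path_weight`` maps a
    path (list of steps) to an unnormalized weight; default equal weighting.
    """
    totals = np.zeros(4)
    for ca, cb in zip(codons_a, codons_b):
        if ca == cb:
            continue
        paths = _pathways(ca, cb)
        if not paths:  # all paths blocked by stops: fall back to direct count
            continue
        weights = np.array([path_weight(p) if path_weight else 1.0 for p in paths], dtype=float)
        if weights.sum() <= 0:
            weights = np.ones(len(paths))
        weights /= weights.sum()
        for w, path in zip(weights, paths):
            for cur, nxt, pos in path:
                syn = _AA[cur] == _AA[nxt]
                ts = _is_transition(cur[pos], nxt[pos])
                idx = (0 if syn else 2) + (0 if ts else 1)
                totals[idx] += w
    return totals


def _jc_correct(p: float) -> float:
    if p == 0:
        return 0.0
    if p >= 0.75:
        return math.inf
    return -0.75 * math.log(1 - 4 * p / 3)


def _finalize(gene_a, gene_b, dN, dS, sd, nd, method, kappa_hat, n_codons) -> DnDsEstimate:
    if sd == 0 and dS == 0:
        # no synonymous change observed: omega undefined (or infinite)
        return DnDsEstimate(gene_a, gene_b, dN, 0.0, None, method, "dS_zero",
                            kappa_hat, n_codons)
    if nd == 0:
        # zero numerator: omega is 0 whatever the synonymous distance
        return DnDsEstimate(gene_a, gene_b, 0.0, dS, 0.0, method, "ok",
                            kappa_hat, n_codons)
    if not math.isfinite(dS) or dS > SATURATION_DS or not math.isfinite(dN):
        return DnDsEstimate(gene_a, gene_b, dN, dS, None, method, "saturated",
                            kappa_hat, n_codons)
    return DnDsEstimate(gene_a, gene_b, dN, dS, dN / dS, method, "ok",
                        kappa_hat, n_codons)


def dnds_ng86(alignment: CodonAlignment) -> DnDsEstimate:
    """Nei-Gojobori 1986 pathway counting with Jukes-Cantor correction."""
    s_sites = 0.5 * (sum(_NG86_SITES[c] for c in alignment.codons_a)
                     + sum(_NG86_SITES[c] for c in alignment.codons_b))
    n_sites = 3 * alignment.n_codons - s_sites
    syn_ts, syn_tv, non_ts, non_tv = _count_differences(alignment.codons_a, alignment.codons_b)
    sd, nd = syn_ts + syn_tv, non_ts + non_tv
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    dS = _jc_correct(ps)
    dN = _jc_correct(pn)
    return _finalize(alignment.gene_a, alignment.gene_b, dN, dS, sd, nd,
                     "NG86", None, alignment.n_codons)


# ---------------------------------------------------------------------------
# YN00-style estimator
# ---------------------------------------------------------------------------

def _position_degeneracy(codon: str, pos: int) -> int:
    """Number of the 3 alternative nucleotides that are synonymous."""
    syn = 0
    for nt in _NTS:
        if nt == codon[pos]:
            continue
        alt = codon[:pos] + nt + codon[pos + 1 :]
        if alt not in STOP_CODONS and _AA[alt] == _AA[codon]:
            syn += 1
    return syn


# per-codon lookup tables, computed once
_DEGENERACY = {c: tuple(_position_degeneracy(c, p) for p in range(3))
               for c in _AA if c not in STOP_CODONS}
_ALTS = {
    c: tuple(
        (pos, _TRANSITION[c[pos]] == nt, c[:pos] + nt + c[pos + 1 :],
         _AA[c[:pos] + nt + c[pos + 1 :]] == _AA[c])
        for pos in range(3)
        for nt in _NTS
        if nt != c[pos] and c[:pos] + nt + c[pos + 1 :] not in STOP_CODONS
    )
    for c in _AA
    if c not in STOP_CODONS
}


def _k80(P: float, Q: float) -> tuple[float, float, float]:
    """(distance, ts part, tv part) under Kimura 1980; inf when saturated."""
    w1 = 1 - 2 * P - Q
    w2 = 1 - 2 * Q
    if w1 <= 0 or w2 <= 0:
        return math.inf, math.inf, math.inf
    a = -0.5 * math.log(w1) + 0.25 * math.log(w2)
    b = -0.25 * math.log(w2)
    return a + 2 * b, a, b


def estimate_kappa(codons_a, codons_b) -> float:
    """Kappa from fourfold-degenerate and nondegenerate sites (K80)."""
    L = Counter()
    ts = Counter()
    tv = Counter()
    for ca, cb in zip(codons_a, codons_b):
        if ca not in _DEGENERACY or cb not in _DEGENERACY:
            continue
        for pos in range(3):
            da, db = _DEGENERACY[ca][pos], _DEGENERACY[cb][pos]
            if da == 3 and db == 3:
                cls = 4
            elif da == 0 and db == 0:
                cls = 0
            else:
                continue
            L[cls] += 1
            if ca[pos] != cb[pos]:
                if _is_transition(ca[pos], cb[pos]):
                    ts[cls] += 1
                else:
                    tv[cls] += 1
    total = L[0] + L[4]
    if total == 0:
        return 1.0
    P = (ts[0] + ts[4]) / total
    Q = (tv[0] + tv[4]) / total
    _, a, b = _k80(P, Q)
    if not math.isfinite(a) or not math.isfinite(b) or b <= 0 or a <= 0:
        return 1.0
    return max(a / b, 0.1)


def _f3x4(codons_a, codons_b) -> dict[str, float]:
    """F3x4 codon frequencies from both sequences."""
    pos_counts = [Counter() for _ in range(3)]
    for codons in (codons_a, codons_b):
        for c in codons:
            for pos in range(3):
                pos_counts[pos][c[pos]] += 1
    pos_freq = []
    for pc in pos_counts:
        tot = sum(pc.values()) or 1
        pos_freq.append({nt: pc[nt] / tot for nt in _NTS})
    freqs = {}
    z = 0.0
    for c in _AA:
        if c in STOP_CODONS:
            continue
        f = pos_freq[0][c[0]] * pos_freq[1][c[1]] * pos_freq[2][c[2]]
        freqs[c] = f
        z += f
    return {c: f / z for c, f in freqs.items()}


def _weighted_sites(codons, kappa, freqs) -> float:
    """Synonymous site total under kappa- and frequency-weighted mutation."""
    syn_total = 0.0
    for codon, count in Counter(codons).items():
        if codon not in _ALTS:
            continue
        syn_w = tot_w = 0.0
        for _pos, is_ts, alt, is_syn in _ALTS[codon]:
            w = (kappa if is_ts else 1.0) * freqs.get(alt, 0.0)
            tot_w += w
            if is_syn:
                syn_w += w
        if tot_w > 0:
            syn_total += count * 3 * syn_w / tot_w
    return syn_total


def dnds_yn00(alignment: CodonAlignment) -> DnDsEstimate:
    """YN00-style estimator with kappa and codon-frequency weighting."""
    ca, cb = alignment.codons_a, alignment.codons_b
    kappa = estimate_kappa(ca, cb)
    freqs = _f3x4(ca, cb)

    s_sites = 0.5 * (_weighted_sites(ca, kappa, freqs) + _weighted_sites(cb, kappa, freqs))
    n_sites = 3 * alignment.n_codons - s_sites

    def path_weight(path) -> float:
        w = 1.0
        for cur, nxt, pos in path:
            w *= (kappa if _is_transition(cur[pos], nxt[pos]) else 1.0) * freqs.get(nxt, 1e-9)
        return w

    syn_ts, syn_tv, non_ts, non_tv = _count_differences(ca, cb, path_weight)
    sd, nd = syn_ts + syn_tv, non_ts + non_tv
    if s_sites <= 0 or n_sites <= 0:
        return DnDsEstimate(alignment.gene_a, alignment.gene_b, 0.0, 0.0, None,
                            "YN00", "dS_zero", kappa, alignment.n_codons)
    dS, _, _ = _k80(syn_ts / s_sites, syn_tv / s_sites)
    dN, _, _ = _k80(non_ts / n_sites, non_tv / n_sites)
    return _finalize(alignment.gene_a, alignment.gene_b, dN, dS, sd, nd,
                     "YN00", kappa, alignment.n_codons)


def estimate_pair(cds_a: str, cds_b: str, gene_a: str = "a", gene_b: str = "b",
                  method: str = "YN00", min_codons: int = MIN_CODONS) -> DnDsEstimate:
    """Align two CDS and estimate dN/dS; short alignments become too_short."""
    try:
        aln = codon_align(cds_a, cds_b, gene_a, gene_b, min_codons=min_codons)
    except AlignmentTooShortError:
        return DnDsEstimate(gene_a, gene_b, float("nan"), float("nan"), None,
                            method, "too_short")
    est = dnds_yn00(aln) if method == "YN00" else dnds_ng86(aln)
    return est


# ---------------------------------------------------------------------------
# Pair selection, distributions, QQ and parent separation
# ---------------------------------------------------------------------------

def single_copy_duplicate_pairs(labeled_genes, hits, anchor_pairs,
                                max_evalue: float = 1e-20,
                                min_coverage: float = 80.0) -> list[tuple[str, str]]:
    """(copy1, copy2) pairs with no further strong homolog on either side."""
    from .duplication import segdup_homolog_pairs

    labels = {g.gene_id: g.copy_label for g in labeled_genes}
    strong = segdup_homolog_pairs(hits, max_evalue=max_evalue, min_coverage=min_coverage)
    strong_partners: dict[str, set[str]] = {}
    for a, b in strong:
        strong_partners.setdefault(a, set()).add(b)
        strong_partners.setdefault(b, set()).add(a)
    out = []
    for a, b in sorted(set(anchor_pairs)):
        if labels.get(a) not in ("copy1", "copy2") or labels.get(b) not in ("copy1", "copy2"):
            continue
        if labels.get(a) == labels.get(b):
            continue
        if strong_partners.get(a, set()) - {b} or strong_partners.get(b, set()) - {a}:
            continue
        if labels.get(a) == "copy2":
            a, b = b, a
        out.append((a, b))
    return out


def omega_distribution(estimates) -> tuple[np.ndarray, dict[str, int]]:
    """Omega values of status-ok estimates plus excluded-category counts."""
    counts = Counter(e.status for e in estimates)
    omegas = np.array([e.omega for e in estimates if e.status == "ok"], dtype=float)
    if omegas.size == 0:
        raise ValueError(f"no usable omega estimates; statuses: {dict(counts)}")
    return omegas, dict(counts)


def qq_compare(omega_x, omega_y, k: int = 100) -> QQComparison:
    """Quantile-quantile comparison of two omega samples.

    Quantiles at probabilities (i - 0.5)/k (type-7 interpolation), a
    least-squares line through the quantile pairs, and the squared Pearson
    correlation of the quantile pairs.
    """
    x = np.asarray(omega_x, dtype=float)
    y = np.asarray(omega_y, dtype=float)
    if x.size < 20 or y.size < 20:
        raise ValueError("need at least 20 values per sample")
    probs = (np.arange(1, k + 1) - 0.5) / k
    qx = np.quantile(x, probs)
    qy = np.quantile(y, probs)
    if np.allclose(qx, qx[0]) or np.allclose(qy, qy[0]):
        # a constant sample carries no shape information; the identity check
        # still distinguishes "same constant" from anything else
        slope, intercept = 1.0, float(qy[0] - qx[0])
        r2 = 1.0 if np.allclose(qy, qx + intercept) else 0.0
    else:
        slope, intercept = np.polyfit(qx, qy, 1)
        r2 = float(np.corrcoef(qx, qy)[0, 1] ** 2)
    return QQComparison(quantile_probs=probs, quantiles_x=qx, quantiles_y=qy,
                        r_squared=r2, slope=float(slope), intercept=float(intercept))


@dataclass
class SeparationVerdict:
    verdict: str  # separation | no_separation
    statistic: float  # BIC(1 component) - BIC(2 components)
    n_triplets: int
    deltas: np.ndarray


def parent_separation_by_ds(triplets, method: str = "YN00",
                            min_triplets: int = 30, seed: int = 0) -> SeparationVerdict:
    """Synonymous-divergence parent-separation test.

    ``triplets`` are (cds_copy1, cds_copy2, cds_outgroup) tuples ordered by
    copy label.  Per triplet Delta = dS(copy1, outgroup) - dS(copy2,
    outgroup); a hybrid with distinguishable parents shows a bimodal Delta.
    Verdict 'separation' requires a two-component Gaussian mixture preferred
    by BIC over one component AND component means more than two pooled
    standard deviations apart.
    """
    deltas = []
    for c1, c2, out in triplets:
        e1 = estimate_pair(c1, out, method=method)
        e2 = estimate_pair(c2, out, method=method)
        if math.isfinite(e1.dS) and math.isfinite(e2.dS) \
                and e1.status != "too_short" and e2.status != "too_short":
            deltas.append(e1.dS - e2.dS)
    if len(deltas) < min_triplets:
        raise ValueError(f"only {len(deltas)} usable triplets (< {min_triplets})")
    x = np.array(deltas).reshape(-1, 1)
    if np.allclose(x, x[0]):
        return SeparationVerdict("no_separation", 0.0, len(deltas), x.ravel())
    gm1 = GaussianMixture(1, random_state=seed).fit(x)
    gm2 = GaussianMixture(2, random_state=seed, n_init=3).fit(x)
    stat = gm1.bic(x) - gm2.bic(x)
    means = gm2.means_.ravel()
    pooled_sd = float(np.sqrt(np.average(gm2.covariances_.ravel(), weights=gm2.weights_)))
    separated = stat > 0 and abs(means[0] - means[1]) > 2 * pooled_sd
    return SeparationVerdict("separation" if separated else "no_separation",
                             float(stat), len(deltas), x.ravel())
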