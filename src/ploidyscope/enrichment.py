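"""Gene-family abundance comparisons between genome groups.

Counts are deduplicated before testing: for each duplicated gene only the
copy1 representative is kept (and a single representative per triplicate),
so a genome that doubled its gene complement stays comparable to relatives
without a duplication.  Families are tested with a two-sided Fisher's exact
test on family-vs-all-other-family pooled counts, Benjamini-Hochberg
corrected, and flagged as expanded/contracted when the focal count lies more
than two sample standard deviations from a comparison-set mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger("ploidyscope")


@dataclass
class EnrichmentResult:
    family: str
    p_value: float
    q_value: float
    direction: str  # enriched | depleted
    test_counts: tuple[tuple[int, int], tuple[int, int]]


@dataclass
class SDFlag:
    family: str
    focal_count: int
    comparison_mean: float
    comparison_sd: float
    flag: str  # expanded | contracted | none


def dedupe_counts(gene_models, family_annotation: dict[str, str]) -> pd.Series:
    """Per-family gene counts with secondary duplicate copies removed.

    copy2 genes are dropped; triplicate genes keep a single natural-order
    representative per family group; copy1, unpaired and (with a warning)
    unassigned genes are retained.
    """
    from .duplication import natural_key

    kept = []
    n_unlabeled = 0
    triplicate_seen: set[tuple] = set()
    for g in sorted(gene_models, key=lambda g: (natural_key(g.scaffold_id), g.start)):
        fam = family_annotation.get(g.gene_id)
        if fam is None:
            continue
        if g.copy_label == "copy2":
            continue
        if g.copy_label == "triplicate":
            key = (fam, _triplicate_group(g.gene_id))
            if key in triplicate_seen:
                continue
            triplicate_seen.add(key)
        if g.copy_label == "unassigned":
            n_unlabeled += 1
        kept.append(fam)
    if n_unlabeled:
        logger.warning("%d genes without copy labels counted as-is", n_unlabeled)
    return pd.Series(kept, dtype="object").value_counts().sort_index()


def _triplicate_group(gene_id: str) -> str:
    # triplicate copies share a common stem before the copy suffix when they
    # come from the simulator; otherwise each gene is its own group
    return gene_id.rsplit("_", 1)[0] if "_" in gene_id else gene_id


def fisher_two_sided(table) -> float:
    """Two-sided Fisher exact p for a 2x2 table.

    Sums hypergeometric point probabilities not exceeding the observed one
    (the conventional two-sided definition), vectorized over the support.
    """
    (a, b), (c, d) = table
    for v in (a, b, c, d):
        if v < 0 or v != int(v):
            raise ValueError(f"table entries must be nonnegative integers: {table}")
    n = a + b + c + d
    if n == 0:
        return 1.0
    support = np.arange(max(0, a - d), min(a + b, a + c) + 1)
    # hypergeometric pmf over the support via log-gamma (row margin a+b,
    # column margin a+c fixed)
    r1, c1 = a + b, a + c
    logpmf = (
        gammaln(r1 + 1) - gammaln(support + 1) - gammaln(r1 - support + 1)
        + gammaln(n - r1 + 1) - gammaln(c1 - support + 1) - gammaln(n - r1 - c1 + support + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    pmf = np.exp(logpmf)
    p_obs = pmf[int(a - support[0])]
    return float(min(pmf[pmf <= p_obs * (1 + 1e-7)].sum(), 1.0))


def fisher_family_test(matrix: pd.DataFrame, group_labels: dict[str, str],
                       group_a: str, group_b: str, alpha: float = 0.05
                       ) -> list[EnrichmentResult]:
    """Per-family Fisher tests between pooled genome groups with BH FDR.

    ``matrix`` is genomes x families (nonnegative integers).  For family F
    the 2x2 table is [[F in group_a, other families in group_a],
    [F in group_b, other families in group_b]].
    """
    genomes_a = [g for g in matrix.index if group_labels.get(g) == group_a]
    genomes_b = [g for g in matrix.index if group_labels.get(g) == group_b]
    if not genomes_a or not genomes_b:
        raise ValueError("both groups must contain at least one genome")
    sum_a = matrix.loc[genomes_a].sum(axis=0)
    sum_b = matrix.loc[genomes_b].sum(axis=0)
    tot_a, tot_b = int(sum_a.sum()), int(sum_b.sum())
    if tot_a == 0 or tot_b == 0:
        raise ValueError("zero total counts in a group")
    results = []
    pvals = []
    for fam in matrix.columns:
        fa, fb = int(sum_a[fam]), int(sum_b[fam])
        table = ((fa, tot_a - fa), (fb, tot_b - fb))
        p = fisher_two_sided(table)
        pvals.append(p)
        direction = "enriched" if fa / tot_a >= fb / tot_b else "depleted"
        results.append(EnrichmentResult(family=fam, p_value=p, q_value=np.nan,
                                        direction=direction, test_counts=table))
    qvals = multipletests(pvals, method="fdr_bh")[1]
    for r, q in zip(results, qvals):
        r.q_value = float(max(q, r.p_value))
    return results


def sd_outlier_flags(matrix: pd.DataFrame, focal_genome: str, comparison_set,
                     k: float = 2.0) -> list[SDFlag]:
    """Flag families > k sample SDs above/below the comparison-set mean."""
    comparison_set = list(comparison_set)
    if len(comparison_set) < 2:
        raise ValueError("comparison set must contain at least 2 genomes")
    flags = []
    comp = matrix.loc[comparison_set]
    for fam in matrix.columns:
        focal = int(matrix.loc[focal_genome, fam])
        mean = float(comp[fam].mean())
        sd = float(comp[fam].std(ddof=1))
        flags.append(SDFlag(family=fam, focal_count=focal, comparison_mean=mean,
                            comparison_sd=sd, flag=sd_flag(focal, mean, sd, k)))
    return flags


def sd_flag(focal: float, mean: float, sd: float, k: float = 2.0) -> str:
    """The two-standard-deviation expansion/contraction rule (strict)."""
    if focal > mean + k * sd:
        return "expanded"
    if focal < mean - k * sd:
        return "contracted"
    return "none"


def enrichment_frame(results) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.family, r.p_value, r.q_value, r.direction,
          r.test_counts[0][0], r.test_counts[0][1], r.test_counts[1][0], r.test_counts[1][1])
         for r in results],
        columns=["family", "p_value", "q_value", "direction", "a_family", "a_other",
                 "b_family", "b_other"],
    )


def flags_frame(flags) -> pd.DataFrame:
    return pd.DataFrame(
        [(f.family, f.focal_count, f.comparison_mean, f.comparison_sd, f.flag) for f in flags],
        columns=["family", "focal_count", "comparison_mean", "comparison_sd", "flag"],
    )
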