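"""Rule-based duplication-mode call from aggregated ploidy evidence.

The cascade mirrors the argument structure used to separate assembly ploidy
classes: near-identical duplicates (or a high allelic fraction) indicate an
unphased diploid/dikaryotic assembly; relaxed selection (omega ~ 1) or heavy
copy loss indicates autopolyploidy; diverged duplicates under genome-wide
purifying selection whose omega distribution matches an interspecies
baseline indicate allopolyploidization (hybrid origin).
"""

from __future__ import annotations

import logging
import math
from dataclasses import asdict, dataclass

import numpy as np

logger = logging.getLogger("ploidyscope")

LABELS = ("no_wgd", "unphased_diploid_or_dikaryon", "autopolyploid", "allopolyploid", "ambiguous")


@dataclass
class PloidyEvidence:
    duplicated_fraction: float
    content_fraction_gt95: float
    mean_nt_identity: float
    bbh_topbin_fraction: float
    allelic_fraction: float
    omega_median: float
    omega_near1_fraction: float
    retention: float
    qq_r2_vs_baseline: float | None = None

    def __post_init__(self) -> None:
        for name in ("duplicated_fraction", "content_fraction_gt95", "bbh_topbin_fraction",
                     "allelic_fraction", "omega_near1_fraction", "retention"):
            v = getattr(self, name)
            if not (math.isnan(v) or 0 <= v <= 1):
                raise ValueError(f"{name} out of [0,1]: {v}")


@dataclass
class Thresholds:
    t_dup: float = 0.2  # below: no whole-genome duplication
    t_near_identical: float = 0.85  # content >95% identity: diploid/dikaryon
    t_allelic: float = 0.2
    t_omega_relaxed: float = 0.3  # fraction of omega in [0.9, 1.1]
    t_retention: float = 0.7
    t_purifying_median: float = 0.5
    t_qq_r2: float = 0.9


@dataclass
class DuplicationCall:
    label: str
    triggered_rules: list[str]
    thresholds_used: Thresholds
    evidence: PloidyEvidence


def classify_duplication(evidence: PloidyEvidence,
                         thresholds: Thresholds | None = None) -> DuplicationCall:
    """Pure rule cascade from evidence to a duplication-mode label."""
    t = thresholds or Thresholds()
    e = evidence
    fired: list[str] = []

    def call(label):
        return DuplicationCall(label=label, triggered_rules=fired, thresholds_used=t, evidence=e)

    if e.duplicated_fraction < t.t_dup:
        fired.append(f"duplicated_fraction {e.duplicated_fraction:.4f} < {t.t_dup}")
        return call("no_wgd")
    fired.append(f"duplicated_fraction {e.duplicated_fraction:.4f} >= {t.t_dup}")

    if e.content_fraction_gt95 >= t.t_near_identical or e.allelic_fraction >= t.t_allelic:
        fired.append(
            f"content_fraction_gt95 {e.content_fraction_gt95:.4f} >= {t.t_near_identical} "
            f"or allelic_fraction {e.allelic_fraction:.5f} >= {t.t_allelic}"
        )
        return call("unphased_diploid_or_dikaryon")
    fired.append(f"content_fraction_gt95 {e.content_fraction_gt95:.4f} < {t.t_near_identical} "
                 f"and allelic_fraction {e.allelic_fraction:.5f} < {t.t_allelic}")

    if e.omega_near1_fraction >= t.t_omega_relaxed or e.retention < t.t_retention:
        fired.append(
            f"omega_near1_fraction {e.omega_near1_fraction:.3f} >= {t.t_omega_relaxed} "
            f"or retention {e.retention:.3f} < {t.t_retention}"
        )
        return call("autopolyploid")
    fired.append(f"omega_near1_fraction {e.omega_near1_fraction:.3f} < {t.t_omega_relaxed} "
                 f"and retention {e.retention:.3f} >= {t.t_retention}")

    qq_ok = e.qq_r2_vs_baseline is None or e.qq_r2_vs_baseline >= t.t_qq_r2
    if e.omega_median <= t.t_purifying_median and qq_ok:
        fired.append(f"omega_median {e.omega_median:.3f} <= {t.t_purifying_median} "
                     f"and qq_r2 {e.qq_r2_vs_baseline} >= {t.t_qq_r2} (or absent)")
        return call("allopolyploid")
    fired.append("purifying-selection / baseline-match rule not satisfied")
    return call("ambiguous")


def evidence_from_pipeline(summary, histogram, allelic_report, omega_sample,
                           labeled_genes, bbh_pairs, region_pairs=None,
                           qq: float | None = None) -> PloidyEvidence:
    """Aggregate upstream outputs into a PloidyEvidence record.

    Retention is the fraction of duplicate-implicated genes (members of a
    reciprocal-best-hit pair, plus unpaired genes whose midpoint lies inside
    a detected duplicated region) whose reciprocal pair has intact open
    reading frames on both sides.  Unpaired genes inside duplicated regions
    are counted in the denominator because their missing reciprocal partner
    is itself evidence of copy loss.  It estimates the survival of duplicated
    content against pseudogenization and gene loss.
    """
    for name, obj in (("duplication summary", summary), ("identity histogram", histogram),
                      ("allelic report", allelic_report), ("gene models", labeled_genes)):
        if obj is None:
            raise ValueError(f"missing required component: {name}")
    omega_sample = np.asarray(omega_sample, dtype=float)

    intact = {g.gene_id: "*" not in _internal(g) for g in labeled_genes}
    paired_genes: set[str] = set()
    intact_pair_genes = 0
    for p in bbh_pairs:
        paired_genes.update((p.gene_a, p.gene_b))
        if intact.get(p.gene_a) and intact.get(p.gene_b):
            intact_pair_genes += 2
    intervals: dict[str, list[tuple[int, int]]] = {}
    for rp in region_pairs or ():
        for region in (rp.region_a, rp.region_b):
            intervals.setdefault(region.scaffold_id, []).append((region.start, region.end))

    def _in_region(gene) -> bool:
        mid = (gene.start + gene.end) // 2
        return any(s <= mid < e for s, e in intervals.get(gene.scaffold_id, ()))

    in_region_unpaired = sum(
        1 for g in labeled_genes
        if g.gene_id not in paired_genes and _in_region(g)
    )
    denom = len(paired_genes) + in_region_unpaired
    retention = intact_pair_genes / denom if denom else 1.0

    if summary.duplicated_fraction_of_assembly == 0 or omega_sample.size == 0:
        omega_median = float("nan")
        near1 = 0.0
    else:
        omega_median = float(np.median(omega_sample))
        near1 = float(np.mean((omega_sample >= 0.9) & (omega_sample <= 1.1)))
    return PloidyEvidence(
        duplicated_fraction=summary.duplicated_fraction_of_assembly,
        content_fraction_gt95=summary.content_fractions.get("gt95", 0.0),
        mean_nt_identity=summary.mean_nt_identity,
        bbh_topbin_fraction=histogram.top_bin_fraction,
        allelic_fraction=allelic_report.allelic_fraction,
        omega_median=omega_median,
        omega_near1_fraction=near1,
        retention=min(retention, 1.0),
        qq_r2_vs_baseline=qq,
    )


def _internal(gene) -> str:
    """Protein with the terminal stop ignored (internal stops only)."""
    prot = gene.protein
    # protein is already truncated at the first stop by translate_cds; detect
    # internal stops by comparing to the full CDS length instead
    full = len(gene.cds) // 3
    expected = full - 1 if gene.cds[-3:].upper() in ("TAA", "TAG", "TGA") else full
    return prot + ("*" if len(prot) < expected else "")


def call_to_text(call: DuplicationCall) -> str:
    lines = [f"duplication-mode call: {call.label}", "", "evidence:"]
    for k, v in asdict(call.evidence).items():
        lines.append(f"  {k}: {v}")
    lines.append("")
    lines.append("rules fired:")
    for r in call.triggered_rules:
        lines.append(f"  - {r}")
    return "\n".join(lines)
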