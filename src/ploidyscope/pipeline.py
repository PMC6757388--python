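"""End-to-end orchestration: genome in, duplication-mode call out."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from . import classify, duplication, homology, selection
from .classify import DuplicationCall, PloidyEvidence, Thresholds
from .core_io import Assembly, GeneModel

logger = logging.getLogger("ploidyscope")


@dataclass
class PipelineResult:
    hits: list
    bbh_pairs: list
    histogram: homology.IdentityHistogram
    region_pairs: list
    summary: duplication.DuplicationSummary
    allelic: duplication.AllelicReport
    labeled_genes: list[GeneModel]
    single_copy_pairs: list[tuple[str, str]]
    estimates: list[selection.DnDsEstimate]
    omega_sample: np.ndarray
    omega_status_counts: dict
    evidence: PloidyEvidence
    call: DuplicationCall
    qq: selection.QQComparison | None = None


def run_pipeline(assembly: Assembly, genes: list[GeneModel],
                 baseline_omegas=None,
                 segment_table=None,
                 thresholds: Thresholds | None = None,
                 dnds_method: str = "YN00") -> PipelineResult:
    """Run search -> duplication profiling -> dN/dS -> classification.

    ``baseline_omegas`` is an optional interspecies omega sample used for the
    QQ comparison; ``segment_table`` optionally supplies externally computed
    syntenic segments (preferred over internal anchor-based identity).
    """
    proteins = {g.gene_id: g.protein for g in genes if g.protein}
    hits = homology.all_vs_all_search(proteins)
    bbh = homology.bidirectional_best_hits(hits)
    hist = homology.bbh_identity_histogram(bbh)

    strong_pairs = duplication.segdup_homolog_pairs(hits)
    fragments = duplication.detect_duplicated_fragments(genes, strong_pairs)
    fragments = duplication.annotate_identities(fragments, genes, segment_table)
    fragments = duplication.merge_adjacent_pairs(fragments)
    summary = duplication.duplication_summary(fragments, genes, assembly)
    labeled = duplication.assign_copy_labels(fragments, genes)

    segments = segment_table or duplication.regions_to_segments(fragments)
    allelic = duplication.allelic_content(segments, assembly, genes)

    anchor_pairs = [a for p in fragments for a in p.anchor_pairs]
    sc_pairs = selection.single_copy_duplicate_pairs(labeled, hits, anchor_pairs)
    cds = {g.gene_id: g.cds for g in genes}
    estimates = [
        selection.estimate_pair(cds[a], cds[b], a, b, method=dnds_method)
        for a, b in sc_pairs
    ]
    try:
        omega_sample, status_counts = selection.omega_distribution(estimates)
    except ValueError:
        omega_sample = np.array([])
        status_counts = {}

    qq = None
    qq_r2 = None
    if baseline_omegas is not None and omega_sample.size >= 20 and len(baseline_omegas) >= 20:
        qq = selection.qq_compare(omega_sample, baseline_omegas)
        qq_r2 = qq.r_squared

    evidence = classify.evidence_from_pipeline(summary, hist, allelic, omega_sample,
                                               labeled, bbh, region_pairs=fragments,
                                               qq=qq_r2)
    call = classify.classify_duplication(evidence, thresholds)
    logger.info("pipeline call: %s", call.label)
    return PipelineResult(
        hits=hits, bbh_pairs=bbh, histogram=hist, region_pairs=fragments,
        summary=summary, allelic=allelic, labeled_genes=labeled,
        single_copy_pairs=sc_pairs, estimates=estimates, omega_sample=omega_sample,
        omega_status_counts=status_counts, evidence=evidence, call=call, qq=qq,
    )


def baseline_omega_sample(baseline, method: str = "YN00") -> np.ndarray:
    """Omega estimates for a simulated interspecies baseline pair."""
    ests = [
        selection.estimate_pair(baseline.cds_a[g], baseline.cds_b[g], g, g, method=method)
        for g in baseline.gene_ids
    ]
    omegas, _ = selection.omega_distribution(ests)
    return omegas


def run_scenario(config, thresholds: Thresholds | None = None) -> tuple:
    """Simulate one genome under ``config`` and run the full pipeline."""
    from .simulate import build_genome

    sim = build_genome(config)
    baseline = baseline_omega_sample(sim.baselines[0]) if sim.baselines else None
    result = run_pipeline(sim.assembly, sim.genes, baseline_omegas=baseline,
                          thresholds=thresholds)
    return sim, result
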