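"""simulate: determinism, closed-form oracles and scenario structure."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.stats import chisquare, kstest

from ploidyscope.core_io import translate_cds
from ploidyscope.simulate import (
    SENSE_CODONS,
    ScenarioConfig,
    build_genome,
    default_config,
    evolve_cds,
    pseudogenize,
    sample_ancestral_genes,
)


# ---------------------------------------------------------------------------
# Config validation
# ---------------------------------------------------------------------------

def test_config_validation():
    with pytest.raises(ValueError, match="scenario"):
        ScenarioConfig(scenario="tetraploid")
    with pytest.raises(ValueError, match="haploid"):
        ScenarioConfig(scenario="haploid", p_gene_loss=0.1)
    with pytest.raises(ValueError, match="diploid"):
        ScenarioConfig(scenario="diploid", p_pseudogenize=0.1)
    with pytest.raises(ValueError, match=r"\[0,1\]"):
        ScenarioConfig(scenario="autopolyploid", p_gene_loss=1.5)
    with pytest.raises(ValueError, match="divergence"):
        ScenarioConfig(scenario="diploid", divergence_d=-0.1)
    with pytest.raises(ValueError, match="n_genes"):
        ScenarioConfig(scenario="haploid", n_genes=2, n_scaffolds=4)
    with pytest.raises(ValueError, match="outgroup_mode"):
        ScenarioConfig(scenario="allopolyploid", outgroup_mode="weird")


# ---------------------------------------------------------------------------
# Ancestral gene sampling
# ---------------------------------------------------------------------------

def test_ancestral_genes_deterministic():
    a = sample_ancestral_genes(10, (60, 80), seed=3)
    b = sample_ancestral_genes(10, (60, 80), seed=3)
    assert a == b
    assert sample_ancestral_genes(10, (60, 80), seed=4) != a


def test_ancestral_genes_structure():
    for cds in sample_ancestral_genes(20, (60, 90), seed=0):
        assert cds.startswith("ATG")
        assert len(cds) % 3 == 0
        prot = translate_cds(cds)
        assert len(prot) == len(cds) // 3  # no internal stops


def test_ancestral_genes_nonpositive_n():
    with pytest.raises(ValueError):
        sample_ancestral_genes(0, (60, 80), seed=0)


def test_ancestral_codon_uniformity():
    genes = sample_ancestral_genes(60, (200, 220), seed=12)
    codons = [g[i : i + 3] for g in genes for i in range(3, len(g), 3)]
    counts = {c: 0 for c in SENSE_CODONS}
    for c in codons:
        counts[c] += 1
    stat, p = chisquare(list(counts.values()))
    assert p > 0.001


# ---------------------------------------------------------------------------
# Codon evolution
# ---------------------------------------------------------------------------

def test_evolve_identity_at_zero_divergence():
    cds = sample_ancestral_genes(1, (100, 100), seed=1)[0]
    assert evolve_cds(cds, 0.0, 1.0, 2.0, seed=1) == cds


def test_evolve_omega_zero_preserves_protein():
    cds = sample_ancestral_genes(1, (200, 200), seed=2)[0]
    out = evolve_cds(cds, 0.1, 0.0, 2.0, seed=5)
    assert translate_cds(out) == translate_cds(cds)
    assert out != cds  # synonymous changes still occur


def test_evolve_deterministic():
    cds = sample_ancestral_genes(1, (100, 100), seed=1)[0]
    assert evolve_cds(cds, 0.05, 0.5, 2.0, seed=9) == evolve_cds(cds, 0.05, 0.5, 2.0, seed=9)


def test_evolve_jukes_cantor_oracle():
    """At omega=1, kappa=1 the p-distance follows the JC expectation."""
    d = 0.05
    n_sites = 0
    diffs = 0
    rng = np.random.default_rng(77)
    for cds in sample_ancestral_genes(12, (280, 280), seed=42):
        out = evolve_cds(cds, d, 1.0, 1.0, seed=rng)
        n_sites += len(cds)
        diffs += sum(x != y for x, y in zip(cds, out))
    expected_p = 0.75 * (1 - np.exp(-4 * d / 3))
    observed_p = diffs / n_sites
    se = np.sqrt(expected_p * (1 - expected_p) / n_sites)
    assert abs(observed_p - expected_p) < 3 * se


def test_evolve_never_introduces_stops():
    cds = sample_ancestral_genes(1, (150, 150), seed=3)[0]
    out = evolve_cds(cds, 0.3, 1.0, 2.0, seed=11)
    assert len(translate_cds(out)) == len(out) // 3


# ---------------------------------------------------------------------------
# Pseudogenization
# ---------------------------------------------------------------------------

def test_pseudogenize_truncates_translation():
    cds = sample_ancestral_genes(1, (100, 100), seed=4)[0]
    out = pseudogenize(cds, seed=1)
    assert len(translate_cds(out)) < len(translate_cds(cds))
    assert pseudogenize(cds, seed=1) == out  # deterministic


def test_pseudogenize_frameshift():
    cds = sample_ancestral_genes(1, (100, 100), seed=4)[0]
    out = pseudogenize(cds, seed=1, mode="frameshift")
    assert len(out) == len(cds) - 1


def test_pseudogenize_short_cds_rejected():
    with pytest.raises(ValueError):
        pseudogenize("ATGAAA", seed=0)
    with pytest.raises(ValueError, match="mode"):
        pseudogenize("ATG" * 20, seed=0, mode="bogus")


def test_pseudogenize_position_uniform():
    """Premature-stop positions are uniform over the allowed codon span."""
    n_codons = 300
    cds = sample_ancestral_genes(1, (n_codons, n_codons), seed=5)[0]
    lo, hi = 30, 270  # middle 80% of a 300-codon gene
    rng = np.random.default_rng(123)
    jitter = np.random.default_rng(321)
    positions = []
    for _ in range(1000):
        out = pseudogenize(cds, seed=rng)
        stop_codon = next(i for i in range(0, len(out), 3)
                          if out[i : i + 3] in ("TAA", "TAG", "TGA"))
        positions.append(stop_codon // 3)
    assert min(positions) >= lo and max(positions) < hi
    # continuity-corrected KS: integer + U[0,1) is uniform on [lo, hi)
    x = (np.array(positions) + jitter.random(len(positions)) - lo) / (hi - lo)
    assert kstest(x, "uniform").pvalue > 0.001


# ---------------------------------------------------------------------------
# Genome building
# ---------------------------------------------------------------------------

def test_build_genome_deterministic():
    cfg = default_config("allopolyploid", seed=6, n_genes=20, n_scaffolds=2)
    a, b = build_genome(cfg), build_genome(cfg)
    assert a.assembly.scaffolds == b.assembly.scaffolds
    assert [(g.gene_id, g.start, g.cds) for g in a.genes] == \
        [(g.gene_id, g.start, g.cds) for g in b.genes]
    assert a.truth.equals(b.truth)


def test_haploid_truth_unpartnered():
    sim = build_genome(default_config("haploid", seed=1, n_genes=12, n_scaffolds=2))
    assert (sim.truth.partner_id == "").all()
    assert len(sim.genes) == 12


def test_truth_partner_symmetry(small_allo_sim):
    truth = small_allo_sim.truth.set_index("gene_id")
    for gid, row in truth.iterrows():
        if row.partner_id and not gid.endswith("_3"):
            assert truth.loc[row.partner_id, "partner_id"] == gid


def test_lost_genes_absent_from_annotation():
    sim = build_genome(default_config("autopolyploid", seed=2, n_genes=30, n_scaffolds=2))
    annotated = {g.gene_id for g in sim.genes}
    lost = set(sim.truth[sim.truth.lost].gene_id)
    assert lost and not (lost & annotated)
    kept = set(sim.truth[~sim.truth.lost].gene_id)
    assert kept <= annotated | {""}


def test_pseudogenized_genes_have_internal_stop():
    sim = build_genome(default_config("autopolyploid", seed=2, n_genes=30, n_scaffolds=2))
    by_id = {g.gene_id: g for g in sim.genes}
    pseudo = sim.truth[sim.truth.pseudogenized].gene_id
    assert len(pseudo) > 0
    for gid in pseudo:
        g = by_id[gid]
        assert len(g.protein) < len(g.cds) // 3 - 1


def test_allopolyploid_realized_identity_band():
    sim = build_genome(default_config("allopolyploid", seed=3, n_genes=200,
                                      n_scaffolds=4, outgroup_divergences=()))
    assert 90.5 <= sim.realized_mean_identity <= 93.0


def test_diploid_partner_protein_identity(small_diploid_sim):
    """Near-identical haplotypes: almost all partner proteins > 99% identical."""
    sim = small_diploid_sim
    cds = sim.cds_by_gene
    idents = []
    for row in sim.truth.itertuples():
        if row.gene_id.endswith("_1") and row.partner_id:
            a = translate_cds(cds[row.gene_id])
            b = translate_cds(cds[row.partner_id])
            same = sum(x == y for x, y in zip(a, b))
            idents.append(100 * same / max(len(a), len(b)))
    assert np.mean(np.array(idents) > 99.0) >= 0.95


def test_divergence_monotone_in_d():
    idents = []
    for d in (0.01, 0.05, 0.1, 0.2, 0.3):
        sim = build_genome(default_config("allopolyploid", seed=8, n_genes=30,
                                          n_scaffolds=2, divergence_d=d,
                                          outgroup_divergences=()))
        idents.append(sim.realized_mean_identity)
    assert idents == sorted(idents, reverse=True)


def test_baseline_shares_omega_distribution(small_allo_sim):
    sim = build_genome(default_config("allopolyploid", seed=9, n_genes=20,
                                      n_scaffolds=2))
    assert len(sim.baselines) == 1
    b = sim.baselines[0]
    assert set(b.cds_a) == set(b.cds_b) == set(b.gene_ids)
    assert all(w >= 0 for w in b.omegas.values())
    assert 0.12 in sim.outgroups and len(sim.outgroups[0.12]) == 20


def test_triplicates_emitted():
    sim = build_genome(default_config("allopolyploid", seed=10, n_genes=20,
                                      n_scaffolds=2, triplicate_fraction=0.5,
                                      outgroup_divergences=()))
    trip = [g for g in sim.genes if g.gene_id.endswith("_3")]
    assert trip
    assert all(g.scaffold_id == "scaffold_5" for g in trip)
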