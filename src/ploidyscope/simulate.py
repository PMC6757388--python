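"""Synthetic genomes under haploid, diploid, auto- and allopolyploid scenarios.

Sequences evolve by a rejection-style codon substitution process: nucleotide
changes are proposed with a transition/transversion bias kappa and
nonsynonymous proposals are accepted with probability omega.  The divergence
parameter d is the expected number of accepted substitutions per nucleotide
site, realized as a Poisson(d * L) count of accepted events, so at omega = 1
and kappa = 1 the realized p-distance follows the Jukes-Cantor expectation
0.75 * (1 - exp(-4 d / 3)).

Scenario fingerprints emulated:

* haploid - single-copy gene content, no duplicated regions;
* diploid/dikaryon - every gene present as two near-identical haplotypes
  (divergence ~0.1-0.5%), both emitted into the assembly;
* autopolyploid - duplicates at the configured divergence with a neutral
  (omega ~ 1) fraction, pseudogenization and gene loss;
* allopolyploid - homeologs at the configured divergence, per-gene omega
  drawn from a purifying-selection distribution that is SHARED with the
  interspecies baseline pairs (the property the QQ comparison exploits).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core_io import Assembly, GeneModel, reverse_complement, translate_cds

SCENARIOS = ("haploid", "diploid", "autopolyploid", "allopolyploid")

_NTS = "ACGT"
_NT_INDEX = {c: i for i, c in enumerate(_NTS)}
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
STOP_CODONS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = tuple(
    a + b + c for a in _NTS for b in _NTS for c in _NTS if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class ScenarioConfig:
    """Knobs for one synthetic genome; defaults via :func:`default_config`."""

    scenario: str
    n_genes: int = 100
    n_scaffolds: int = 4
    cds_len_range: tuple[int, int] = (150, 450)  # codons
    intergenic_mean: int = 400  # bp, geometric
    divergence_d: float = 0.085  # expected substitutions / nt site between copies
    kappa: float = 2.0
    omega_dist: tuple = ("gamma", 2.0, 0.15)  # or ("point", w)
    omega_near1_fraction: float = 0.0  # fraction of duplicate pairs evolving at omega ~ 1
    p_pseudogenize: float = 0.0
    p_gene_loss: float = 0.0
    p_inversion: float = 0.2
    block_size: int = 10  # genes per syntenic block on duplicate scaffolds
    triplicate_fraction: float = 0.0
    outgroup_divergences: tuple[float, ...] = ()
    outgroup_mode: str = "equidistant"  # or "parent_a"
    minus_strand_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        for name in ("p_pseudogenize", "p_gene_loss", "p_inversion", "triplicate_fraction",
                     "omega_near1_fraction", "minus_strand_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.divergence_d < 0:
            raise ValueError("divergence_d must be >= 0")
        if self.n_genes < self.n_scaffolds:
            raise ValueError("n_genes must be >= n_scaffolds")
        if self.scenario == "haploid" and (self.p_pseudogenize or self.p_gene_loss):
            raise ValueError("haploid scenario cannot lose or pseudogenize duplicates")
        if self.scenario == "diploid" and (self.p_pseudogenize or self.p_gene_loss):
            raise ValueError("diploid haplotypes are emitted intact")
        if self.outgroup_mode not in ("equidistant", "parent_a"):
            raise ValueError(f"unknown outgroup_mode {self.outgroup_mode!r}")


def default_config(scenario: str, seed: int = 0, **overrides) -> ScenarioConfig:
    """Study-condition defaults per scenario."""
    base = dict(seed=seed)
    if scenario == "haploid":
        base.update(divergence_d=0.0)
    elif scenario == "diploid":
        # unphased haplotypes: ~0.15% divergence under purifying selection
        base.update(divergence_d=0.0015, omega_dist=("point", 0.15))
    elif scenario == "autopolyploid":
        base.update(
            divergence_d=0.085,
            omega_dist=("gamma", 2.0, 0.15),
            omega_near1_fraction=0.5,
            p_pseudogenize=0.40,
            p_gene_loss=0.20,
        )
    elif scenario == "allopolyploid":
        base.update(
            divergence_d=0.085,
            omega_dist=("gamma", 2.0, 0.15),
            outgroup_divergences=(0.12,),
        )
    else:
        raise ValueError(f"unknown scenario {scenario!r}")
    base.update(overrides)
    return ScenarioConfig(scenario=scenario, **base)


@dataclass
class BaselinePair:
    """Two species evolved from the shared ancestor at total divergence d."""

    divergence_d: float
    gene_ids: list[str]
    cds_a: dict[str, str]
    cds_b: dict[str, str]
    omegas: dict[str, float]


@dataclass
class SimResult:
    config: ScenarioConfig
    assembly: Assembly
    genes: list[GeneModel]
    truth: pd.DataFrame
    ancestral_cds: dict[str, str]
    cds_by_gene: dict[str, str]  # includes lost genes
    baselines: list[BaselinePair] = field(default_factory=list)
    outgroups: dict[float, dict[str, str]] = field(default_factory=dict)

    @property
    def realized_mean_identity(self) -> float:
        """Mean percent nucleotide identity over non-lost duplicate CDS pairs."""
        idents = []
        seen = set()
        for row in self.truth.itertuples():
            if not row.partner_id or row.lost or row.gene_id in seen:
                continue
            partner = self.truth.set_index("gene_id")["lost"].get(row.partner_id)
            if partner is None or partner:
                continue
            a = self.cds_by_gene[row.gene_id]
            b = self.cds_by_gene[row.partner_id]
            if len(a) == len(b):
                mism = sum(x != y for x, y in zip(a, b))
                idents.append(100.0 * (1 - mism / len(a)))
            seen.update((row.gene_id, row.partner_id))
        return float(np.mean(idents)) if idents else float("nan")


# ---------------------------------------------------------------------------
# Sequence-level operations
# ---------------------------------------------------------------------------

def sample_ancestral_genes(n: int, cds_len_range: tuple[int, int], seed) -> list[str]:
    """Sample n CDS of uniform sense codons (ATG start, no internal stops)."""
    if n <= 0:
        raise ValueError("n must be positive")
    lo, hi = cds_len_range
    if lo < 60:
        raise ValueError("minimum CDS length is 60 codons")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for _ in range(n):
        n_codons = int(rng.integers(lo, hi + 1))
        body = rng.choice(len(SENSE_CODONS), size=n_codons - 1)
        out.append("ATG" + "".join(SENSE_CODONS[i] for i in body))
    return out


def _propose_target(base: str, kappa: float, rng: np.random.Generator) -> str:
    """Kappa-biased mutant nucleotide."""
    if rng.random() < kappa / (kappa + 2):
        return _TRANSITION[base]
    tvs = [b for b in _NTS if b != base and b != _TRANSITION[base]]
    return tvs[int(rng.integers(2))]


def evolve_cds(cds: str, d: float, omega: float, kappa: float, seed,
               allow_stop: bool = False) -> str:
    """Evolve a CDS to expected divergence d substitutions per nt site."""
    if d < 0:
        raise ValueError("d must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if d == 0:
        return cds
    seq = list(cds)
    n_sites = len(seq)
    n_events = rng.poisson(d * n_sites)
    accepted = 0
    guard = 0
    while accepted < n_events:
        guard += 1
        if guard > 1000 * (n_events + 10):
            raise RuntimeError("substitution process failed to accept proposals")
        pos = int(rng.integers(n_sites))
        new = _propose_target(seq[pos], kappa, rng)
        codon_start = 3 * (pos // 3)
        old_codon = "".join(seq[codon_start : codon_start + 3])
        new_codon = old_codon[: pos % 3] + new + old_codon[pos % 3 + 1 :]
        if new_codon in STOP_CODONS and not allow_stop:
            continue
        if old_codon in STOP_CODONS:  # terminal stop left untouched
            continue
        syn = _AA[old_codon] == _AA.get(new_codon)
        if not syn and rng.random() >= omega:
            continue
        seq[pos] = new
        accepted += 1
    return "".join(seq)


def mutate_neutral(seq: str, d: float, kappa: float, rng: np.random.Generator) -> str:
    """Neutral nucleotide evolution for intergenic sequence."""
    if d == 0 or not seq:
        return seq
    out = list(seq)
    for _ in range(rng.poisson(d * len(out))):
        pos = int(rng.integers(len(out)))
        if out[pos] not in _NT_INDEX:
            continue
        out[pos] = _propose_target(out[pos], kappa, rng)
    return "".join(out)


def pseudogenize(cds: str, seed, mode: str = "stop") -> str:
    """Introduce a premature stop (or 1-bp frameshift) in the middle 80%."""
    if len(cds) < 9:
        raise ValueError("CDS too short to pseudogenize")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_codons = len(cds) // 3
    lo = max(1, int(np.floor(0.1 * n_codons)))
    hi = min(n_codons - 1, int(np.ceil(0.9 * n_codons)))
    idx = int(rng.integers(lo, hi))
    if mode == "stop":
        stop = ("TAA", "TAG", "TGA")[int(rng.integers(3))]
        return cds[: 3 * idx] + stop + cds[3 * idx + 3 :]
    if mode == "frameshift":
        pos = 3 * idx + int(rng.integers(3))
        return cds[:pos] + cds[pos + 1 :]
    raise ValueError(f"unknown mode {mode!r}")


from Bio.Data.CodonTable import standard_dna_table as _TABLE  # noqa: E402

_AA = dict(_TABLE.forward_table)
for _stop in STOP_CODONS:
    _AA[_stop] = "*"


def _draw_omega(dist: tuple, rng: np.random.Generator) -> float:
    if dist[0] == "point":
        return float(dist[1])
    if dist[0] == "gamma":
        shape, mean = dist[1], dist[2]
        return float(rng.gamma(shape, mean / shape))
    raise ValueError(f"unknown omega distribution {dist!r}")


# ---------------------------------------------------------------------------
# Genome assembly from evolved gene sets
# ---------------------------------------------------------------------------

def _random_spacer(mean: int, rng: np.random.Generator) -> str:
    n = int(rng.geometric(1 / mean)) if mean > 0 else 0
    return "".join(_NTS[i] for i in rng.choice(4, size=max(n, 20)))


def _lay_out_scaffold(entries, intergenic_mean, rng):
    """Place (gene_id, cds, strand) entries on one scaffold sequence."""
    parts = []
    pos = 0
    placed = []
    for gene_id, cds, strand in entries:
        spacer = _random_spacer(intergenic_mean, rng)
        parts.append(spacer)
        pos += len(spacer)
        seq = cds if strand == "+" else reverse_complement(cds)
        placed.append((gene_id, pos, pos + len(seq), strand, cds))
        parts.append(seq)
        pos += len(seq)
    parts.append(_random_spacer(intergenic_mean, rng))
    return "".join(parts), placed


def build_genome(config: ScenarioConfig) -> SimResult:
    """Generate an assembly, annotation, truth table and baseline species."""
    rng = np.random.default_rng(config.seed)
    duplicated = config.scenario != "haploid"

    ancestors = sample_ancestral_genes(config.n_genes, config.cds_len_range, rng)
    anc_ids = [f"anc{i:04d}" for i in range(config.n_genes)]
    ancestral_cds = dict(zip(anc_ids, ancestors))

    # per-gene evolutionary regime
    omegas, fates = {}, {}
    for aid in anc_ids:
        if duplicated and rng.random() < config.omega_near1_fraction:
            omegas[aid] = 1.0
        else:
            omegas[aid] = _draw_omega(config.omega_dist, rng)
        fate = "intact"
        if duplicated:
            u = rng.random()
            if u < config.p_gene_loss:
                fate = "lost"
            elif u < config.p_gene_loss + config.p_pseudogenize:
                fate = "pseudogenized"
        fates[aid] = fate

    half = config.divergence_d / 2
    copy1_cds, copy2_cds = {}, {}
    for aid in anc_ids:
        copy1_cds[aid] = evolve_cds(ancestors[aid_index(aid)], half, omegas[aid], config.kappa, rng)
        if duplicated:
            c2 = evolve_cds(ancestors[aid_index(aid)], half, omegas[aid], config.kappa, rng)
            if fates[aid] == "pseudogenized":
                c2 = pseudogenize(c2, rng)
            copy2_cds[aid] = c2

    # triplicates: a third copy of a configured fraction of intact pairs
    triplicate_ids = []
    if duplicated and config.triplicate_fraction > 0:
        for aid in anc_ids:
            if fates[aid] == "intact" and rng.random() < config.triplicate_fraction:
                triplicate_ids.append(aid)
    copy3_cds = {
        aid: evolve_cds(ancestral_cds[aid], half, omegas[aid], config.kappa, rng)
        for aid in triplicate_ids
    }

    # scaffold layout: copy1 scaffolds, then copy2 scaffolds block-by-block
    per_scaffold = np.array_split(np.arange(config.n_genes), config.n_scaffolds)
    scaffolds: list[tuple[str, str]] = []
    models: list[GeneModel] = []
    strands = {aid: ("-" if rng.random() < config.minus_strand_fraction else "+") for aid in anc_ids}

    def add_scaffold(name, entries):
        seq, placed = _lay_out_scaffold(entries, config.intergenic_mean, rng)
        scaffolds.append((name, seq))
        for gene_id, s, e, strand, cds in placed:
            models.append(GeneModel(gene_id=gene_id, scaffold_id=name, start=s, end=e,
                                    strand=strand, cds=cds, protein=translate_cds(cds)))

    for k, idxs in enumerate(per_scaffold, start=1):
        entries = [(f"g{i:04d}_1", copy1_cds[anc_ids[i]], strands[anc_ids[i]]) for i in idxs]
        add_scaffold(f"scaffold_{k}", entries)

    if duplicated:
        for k, idxs in enumerate(per_scaffold, start=1):
            entries = []
            blocks = [idxs[j : j + config.block_size] for j in range(0, len(idxs), config.block_size)]
            for block in blocks:
                block_entries = [
                    (f"g{i:04d}_2", copy2_cds[anc_ids[i]], strands[anc_ids[i]])
                    for i in block
                    if fates[anc_ids[i]] != "lost"
                ]
                if block_entries and rng.random() < config.p_inversion:
                    block_entries = [
                        (gid, cds, "-" if strand == "+" else "+")
                        for gid, cds, strand in reversed(block_entries)
                    ]
                entries.extend(block_entries)
            add_scaffold(f"scaffold_{config.n_scaffolds + k}", entries)
        if triplicate_ids:
            entries = [(f"g{aid_index(aid):04d}_3", copy3_cds[aid], "+") for aid in triplicate_ids]
            add_scaffold(f"scaffold_{2 * config.n_scaffolds + 1}", entries)

    # truth table
    rows = []
    cds_by_gene = {}
    for i, aid in enumerate(anc_ids):
        g1, g2, g3 = f"g{i:04d}_1", f"g{i:04d}_2", f"g{i:04d}_3"
        cds_by_gene[g1] = copy1_cds[aid]
        rows.append(dict(gene_id=g1, partner_id=g2 if duplicated else "",
                         true_omega=omegas[aid], pseudogenized=False, lost=False))
        if duplicated:
            cds_by_gene[g2] = copy2_cds[aid]
            rows.append(dict(gene_id=g2, partner_id=g1, true_omega=omegas[aid],
                             pseudogenized=fates[aid] == "pseudogenized",
                             lost=fates[aid] == "lost"))
            if aid in copy3_cds:
                cds_by_gene[g3] = copy3_cds[aid]
                rows.append(dict(gene_id=g3, partner_id=g1, true_omega=omegas[aid],
                                 pseudogenized=False, lost=False))
    truth = pd.DataFrame(rows)

    # interspecies baselines sharing the omega distribution
    baselines = []
    outgroups: dict[float, dict[str, str]] = {}
    for d_out in config.outgroup_divergences:
        ids, ca, cb, om = [], {}, {}, {}
        for i, aid in enumerate(anc_ids):
            w = _draw_omega(config.omega_dist, rng)
            gid = f"b{i:04d}"
            ids.append(gid)
            ca[gid] = evolve_cds(ancestral_cds[aid], d_out / 2, w, config.kappa, rng)
            cb[gid] = evolve_cds(ancestral_cds[aid], d_out / 2, w, config.kappa, rng)
            om[gid] = w
        baselines.append(BaselinePair(divergence_d=d_out, gene_ids=ids, cds_a=ca, cds_b=cb, omegas=om))
        out = {}
        for i, aid in enumerate(anc_ids):
            w = _draw_omega(config.omega_dist, rng)
            src = copy1_cds[aid] if config.outgroup_mode == "parent_a" else ancestral_cds[aid]
            out[f"g{i:04d}_1"] = evolve_cds(src, d_out, w, config.kappa, rng)
        outgroups[d_out] = out

    return SimResult(
        config=config,
        assembly=Assembly(scaffolds),
        genes=models,
        truth=truth,
        ancestral_cds=ancestral_cds,
        cds_by_gene=cds_by_gene,
        baselines=baselines,
        outgroups=outgroups,
    )


def aid_index(aid: str) -> int:
    return int(aid[3:])
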