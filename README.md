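# ploidyscope

Detect whole-genome duplication in fungal assemblies and decide *what kind*
of duplication it is: an unphased diploid/dikaryon assembly, a recent
autopolyploid, or a hybrid-derived allopolyploid.

Long-read fungal assemblies sometimes come out roughly twice the expected
size, with most of the genome present in two copies. Three very different
biological histories produce that picture, and they are distinguishable from
the sequence alone:

* **unphased diploid / dikaryon** — the two haplotypes of one strain were
  assembled separately. Copies are nearly identical (>95% nucleotide
  identity) and large scaffolds align inside larger ones as allelic variants.
* **autopolyploid** — genome doubling within one lineage. Copies start
  identical, so surviving pairs look young, but redundancy relaxes selection:
  many pairs evolve with dN/dS near 1, and pseudogenization and gene loss
  erode duplicate retention.
* **allopolyploid (hybrid)** — two diverged parental genomes merged. Copies
  show a characteristic intermediate identity band (~92%), duplicate pairs
  evolve under ordinary purifying selection (their divergence predates the
  merger), retention stays high, and the homeolog dN/dS distribution matches
  an interspecies ortholog baseline.

`ploidyscope` implements the full evidence chain: protein all-vs-all search
and bidirectional best hits, segmental-duplication detection by anchor
chaining, nucleotide identity profiling, NG86 and YN00-style pairwise dN/dS,
quantile-quantile comparison against ortholog baselines, allelic-content
scanning, a transparent rule-based classifier, and gene-family enrichment
statistics. A built-in codon-level genome simulator generates assemblies
under each scenario so every stage is testable offline against known truth.

## Quick start

Simulate an allopolyploid genome and classify it:

```bash
ploidyscope simulate allopolyploid --seed 1 --outdir demo
ploidyscope classify --assembly demo/assembly.fasta --gff demo/genes.gff3 \
    --out demo/call.json
```

Output:

```
duplication-mode call: allopolyploid

evidence:
  duplicated_fraction: 0.9817455186155631
  content_fraction_gt95: 0.0
  mean_nt_identity: 92.44080888172223
  bbh_topbin_fraction: 0.0
  allelic_fraction: 0.0
  omega_median: 0.14329298351180236
  omega_near1_fraction: 0.0
  retention: 1.0
  qq_r2_vs_baseline: None

rules fired:
  - duplicated_fraction 0.9817 >= 0.2
  - content_fraction_gt95 0.0000 < 0.85 and allelic_fraction 0.00000 < 0.2
  - omega_near1_fraction 0.000 < 0.3 and retention 1.000 >= 0.7
  - omega_median 0.143 <= 0.5 and qq_r2 None >= 0.9 (or absent)
```

The JSON report additionally records every evidence value, the thresholds
used, and the exact rules that fired, so a call is always auditable.

### Other subcommands

| command | purpose |
|---|---|
| `ploidyscope stats` | assembly statistics (N50/L50, lengths) |
| `ploidyscope search` | protein all-vs-all search + bidirectional best hits |
| `ploidyscope dupscan` | duplicated-region detection and identity summary |
| `ploidyscope dnds` | pairwise dN/dS (NG86 or YN00) for listed gene pairs |
| `ploidyscope classify` | end-to-end evidence aggregation and ploidy call |
| `ploidyscope enrich` | gene-family Fisher/FDR enrichment + 2-SD flags |
| `ploidyscope simulate` | generate a scenario genome with truth tables |

Precomputed whole-genome aligner output can be supplied to `dupscan` and
`classify` via `--segments` (a 9-column coordinate table); otherwise
identities are computed from anchor-gene alignments.

## Python API

```python
from ploidyscope.pipeline import run_scenario
from ploidyscope.simulate import default_config

sim, result = run_scenario(default_config("autopolyploid", seed=7))
print(result.call.label)              # "autopolyploid"
print(result.evidence.retention)      # duplicate retention, 0.412 here
print(result.call.triggered_rules)    # the audit trail of fired rules
```

`run_pipeline(assembly, genes, ...)` accepts any `Assembly` + GFF3-derived
gene models, simulated or real.

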