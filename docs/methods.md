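# Methods

This document describes the statistical methods, the simulator model, the
numerical choices behind `ploidyscope`, and the limits of what the package
claims to do.

## 1. Problem statement

Given an assembly and its gene models, decide among five duplication modes:

* `no_wgd` — little of the assembly is present in duplicated regions;
* `unphased_diploid_or_dikaryon` — duplicated content is near-identical
  haplotype redundancy;
* `autopolyploid` — whole-genome doubling within one lineage;
* `allopolyploid` — merger of two diverged parental genomes;
* `ambiguous` — the evidence pattern fits none of the above cleanly.

The discriminating signals, in the order the pipeline computes them, are
duplicated fraction, copy-to-copy nucleotide identity, BBH amino-acid
identity distribution, allelic (contained-scaffold) content, the dN/dS
distribution of duplicate pairs, duplicate retention, and the match between
duplicate-pair dN/dS and an interspecies ortholog baseline.

## 2. Homology search and bidirectional best hits

Proteins are compared all-vs-all with Smith–Waterman local alignment
(Biopython `PairwiseAligner`, BLOSUM62, gap open 11 / extend 1). To keep an
O(n²) search tractable, pairs are pre-filtered by shared 5-mers and scored
before traceback; only pairs passing an e-value screen are realigned for
coordinates and identity. E-values use Karlin–Altschul statistics with
ungapped BLOSUM62 constants (λ = 0.267, K = 0.041), bitscore
S' = (λS − ln K)/ln 2, E = mn·2^(−S'). These are approximations adequate for
ranking and thresholding, not a BLAST re-implementation.

Bidirectional best hits (BBH) take each protein's best partner by
(bitscore desc, percent identity desc, target id asc) and keep mutual pairs.
BBH amino-acid identities are binned into 0.25-point, left-open right-closed
bins; a large mass in the top bin (>99.75%) is the haplotype-redundancy
signature.

## 3. Duplicated-fragment detection

Gene pairs that pass e ≤ 1e-20 and alignment coverage strictly >80% of both
proteins become anchors. Within each ordered scaffold pair, anchors are
chained when consecutive anchors advance by at most 5 gene positions on both
scaffolds and keep a consistent orientation (colinear or reversed). A
chain's gene windows (every gene between the first and last anchor on each
side) form a candidate fragment. A fragment is reported when both windows
contain ≥3 genes and ≥50% of the genes in each window have a homolog in the
opposite window. Only maximal fragments are kept: any window pair strictly
contained in another reported pair is dropped. Acceptance criterion 1 checks
this implementation against exhaustive enumeration of all index windows.

Fragments whose regions lie within 5 kb on both scaffolds are merged, with
nucleotide identity combined as a length-weighted average.

## 4. Nucleotide identity

Copy-to-copy identity is computed per anchor pair by global alignment of the
two CDS sequences (edlib Needleman–Wunsch), as
100·(1 − distance / alignment length), then length-weighted over anchors to
give a region identity. When a precomputed whole-genome segment table is
supplied, segment identities override anchor-based values
(`identity_source` records which route produced each number; merged regions
with mixed provenance are marked `mixed`). Content fractions report the
duplicated-assembly fraction whose region identity falls in fixed intervals,
notably >95% (haplotype band) and 88.5–92.5% (hybrid band).

## 5. Pairwise dN/dS

Codon alignments are built by aligning the translated proteins and projecting
the alignment back onto codons; gap and stop columns are removed and
alignments shorter than 30 codons are rejected.

**NG86.** Synonymous/nonsynonymous site counts per codon come from the
standard one-third rule over all single-nucleotide mutations (stops
excluded); differences between codons are counted over all shortest
mutational pathways, averaging the synonymous/nonsynonymous split across
pathways (pathways through stops are excluded). Proportions are corrected
with Jukes–Cantor, d = −3/4·ln(1 − 4p/3).

**YN00-style.** κ is estimated from 4-fold degenerate and 0-fold sites via
the K80 transition/transversion relation; codon frequencies use F3×4. Site
counts and pathway weights are κ- and frequency-weighted, and distances are
K80-corrected. This follows the structure of the Yang–Nielsen (2000) method
without its iterative ML refinement; acceptance criterion 2 bounds its
disagreement with NG86 at κ=1 to 15% relative.

Estimates are labelled `ok`, `dS_zero` (no synonymous divergence — common
for very young duplicates), `saturated` (dS > 3), or `too_short`. Only `ok`
estimates enter the ω distribution.

## 6. Baseline comparison and parent separation

The ω distribution of single-copy duplicate pairs is compared with an
ortholog baseline by quantile–quantile agreement: quantiles at probabilities
(i − 0.5)/k (type-7 interpolation), Pearson R² between the two quantile
vectors. Under allopolyploidy the homeolog pairs are ordinary orthologs of
the two parents, so their ω distribution should track an interspecies
baseline (R² ≥ 0.9); under autopolyploidy relaxed selection inflates the
upper quantiles and the match degrades.

A complementary parent-separation test takes (copy1, copy2, outgroup)
triplets and asks whether dS(copy1, outgroup) − dS(copy2, outgroup) is
consistently offset or bimodal, via a 2-component Gaussian mixture (BIC
against a 1-component fit plus a pooled-SD separation requirement). This
detects an outgroup that is closer to one parental subgenome.

## 7. Allelic content

Scaffold pairs whose smaller member aligns to the larger at >95% identity
over >50% of its length are counted as allelic (haplotype) redundancy; the
allelic fraction is the affected fraction of the assembly. In practice this
uses the duplicated-region segments; a high allelic fraction supports the
unphased-diploid call.

## 8. Classification

Evidence is aggregated into a fixed, auditable rule cascade
(`classify_duplication`), with all thresholds in one `Thresholds` object:

1. duplicated fraction < 0.2 → `no_wgd`;
2. content >95% identity ≥ 0.85 or BBH top-bin ≥ 0.85 or allelic fraction
   ≥ 0.2 → `unphased_diploid_or_dikaryon`;
3. ω≈1 fraction ≥ 0.3 or retention < 0.7 → `autopolyploid`;
4. median ω ≤ 0.5 and (QQ R² ≥ 0.9 or unavailable) → `allopolyploid`;
5. otherwise `ambiguous`.

Retention is the fraction of genes in BBH pairs with both copies intact
(no internal stops / truncation), over those genes plus unpaired genes whose
midpoints lie inside detected duplicated regions — an unpaired gene inside a
duplicated region is evidence that its partner was lost. Every call records
the exact comparisons that fired.

## 9. Simulator

The simulator generates codon sequences and assemblies under the four
scenarios with known truth:

* **Ancestral genes** are uniform random sense-codon sequences starting with
  ATG (uniform codon usage; no codon-bias model).
* **Evolution** applies Poisson(d·L_nt) candidate events with κ-biased
  (transition:transversion) proposals; a nonsynonymous candidate is accepted
  with probability ω, synonymous candidates always. At ω=1, κ=1 this reduces
  to Jukes–Cantor, and the identity oracle 0.75·(1 − e^(−4d/3)) is tested
  directly. Stops are never introduced by accepted events.
* **Scenarios.** *Haploid*: one copy per gene. *Diploid*: two near-identical
  haplotypes (d = 0.0015, purifying ω). *Autopolyploid*: doubling followed
  by divergence with an ω distribution putting half its mass near 1, plus
  pseudogenization (premature stops or frameshifts, p = 0.40) and gene loss
  (p = 0.20). *Allopolyploid*: two parents diverged to d = 0.085 total
  (≈92% nucleotide identity) under gamma-distributed purifying ω, merged
  without loss. Scenario parameter values are fixed study conditions chosen
  from the biology each scenario represents, and the same ω distributions
  drive the matched ortholog baselines and optional outgroups.
* Genes are laid out in blocks (10 genes) with occasional inversions on
  paired scaffolds, separated by random intergenic spacers, giving the
  anchor-chaining logic realistic colinear and reversed structure. A small
  fraction of segmental triplicates exercises the copy-labelling logic.

## 10. Numerical and implementation choices

* Fisher's exact test (two-sided, minimum-likelihood definition) is computed
  from log-gamma hypergeometric pmfs with a 1+1e-7 relative tie tolerance,
  matching `scipy.stats.fisher_exact` to ~1e-13 while being ~3× faster per
  table; acceptance criterion 8 verifies it against exhaustive enumeration
  over every 2×2 table with margins ≤ 40.
* Benjamini–Hochberg q-values use `statsmodels.multipletests`.
* The ±2 SD family-expansion rule uses strict inequalities: a focal count
  exactly at mean ± 2·SD is not flagged.
* Family counts are deduplicated before enrichment: one representative per
  duplicate pair/triplicate (copy1), so a fully duplicated genome does not
  spuriously double every family.
* All randomness flows through `numpy.random.default_rng` seeds; every
  simulation and analysis is reproducible from its seed.

## 11. Scope and limitations

* The homology search is a compact Smith–Waterman pipeline suitable for the
  simulator's genome sizes (hundreds of genes); for real genomes, external
  search results can be imported (`read_external_hits`) and whole-genome
  aligner segments ingested via the segment table.
* The YN00-style estimator omits the iterative refinement of the full
  Yang–Nielsen method; its agreement with NG86 is therefore checked, not
  assumed.
* The simulator has uniform codon usage, no indel evolution within CDS, no
  transposable elements, and block-level rather than nucleotide-level
  rearrangement.
* Classifier thresholds are fixed, interpretable constants, not fitted
  parameters; they are validated end-to-end by scenario-recovery tests
  rather than optimized against them.
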