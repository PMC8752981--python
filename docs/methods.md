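# Methods

## Overview

`featsig` implements a feature-driven framework for somatic mutation signature
analysis. The pipeline has five stages:

1. **Spectrum construction** — somatic single-nucleotide variants are
   classified into 96 trinucleotide channels; indels contribute to the tumor
   mutation burden (TMB) but occupy no channel.
2. **Refitting** — each spectrum is decomposed against a catalog of known
   signatures by nonnegative least squares to obtain per-sample exposures.
3. **Feature-driven signature discovery** — genomes are stratified on a
   per-sample feature and the positive/negative parts of the differential mean
   frequencies become de novo signatures.
4. **Metagene projection** — a positive/negative signature pair forms a
   96 × 2 basis whose Moore–Penrose pseudoinverse, applied to per-genome
   normalized frequencies, yields two levels per genome.
5. **Correlative layer** — Pearson rankings against feature tables with
   Benjamini–Hochberg correction, median-split four-class stratification, and
   Welch two-sample t-tests.

A seeded synthetic-cohort generator provides ground truth for every stage.

## Spectrum model

Substitutions are collapsed to the pyrimidine strand: a purine reference
allele (A/G) has the mutation and both flanks reverse-complemented before
lookup. Channel order is canonical: blocks C>A, C>G, C>T, T>A, T>C, T>G, each
holding the 16 flanking contexts sorted lexicographically by (5′ base,
3′ base), so channel 0 is A[C>A]A and channel 95 is T[T>G]T.

Conventions and degenerate-input handling:

- Coordinates are 1-based inclusive (MAF convention); the context is the
  reference base at pos − 1 and pos + 1.
- TMB = accepted SNVs + accepted indels (+ other non-SNV substitutions, which
  are logged and never classified). Multi-allelic/MNV decomposition is not
  attempted.
- Duplicate records (same sample, contig, position, alt) are dropped with a
  warning; ref-allele mismatches against the reference, unknown contigs,
  contig-edge positions and non-ACGT context bases are skipped per record.
- Samples with fewer than 50 SNVs are flagged ineligible for signature
  analysis but retained for burden-level analyses. No hypermutator capping is
  applied.

## Refitting

For frequencies f and catalog P (K × 96, rows sum to 1), weights solve
min‖f − Pᵀs‖₂ with s ≥ 0 (`scipy.optimize.nnls`). Weights below the cutoff
(default 0.06, the conventional refitting cutoff) are zeroed and the reduced
problem is re-solved, then re-thresholded once. This single-pass
threshold-and-refit is deterministic and convex, deliberately simpler than
iterative forward-selection refitters. Weights are not forced to sum to one —
the residual (L2 reconstruction error) absorbs unexplained mass — but a
`renormalize` flag rescales them for comparability. In the rare case where
the unconstrained NNLS weight sum exceeds 1, a sum ≤ 1 constrained refinement
(SLSQP, warm-started) restores the exposure-simplex invariant.

## Feature-driven signatures

Stratification modes:

- **percentile** (default 95th/5th): high = values ≥ the hi quantile
  (nearest-rank from above), low = values ≤ the lo quantile (nearest-rank from
  below); ties at a threshold are all included.
- **median**: "hi" is strictly above the median, ties go low (deterministic).
- **binary**: 1 = high (e.g. mutated), 0 = low (wild-type).

Groups below 3 samples are an error, below 10 a warning: the variance of a
96-bin mean frequency is unusable on tiny groups.

The differential is the difference of group means of per-sample normalized
frequencies (not pooled counts), so a single hypermutant cannot dominate a
group; a `pooled` option implements the count-pooled alternative. The
positive part, renormalized to sum to one, is the feature-representing
signature; the negative part represents the complementary state. `invert`
computes low − high for features whose low state is causal (repair-gene
loss). Positive and negative parts have disjoint support by construction, and
swapping groups swaps them exactly.

## Metagene projection

With M = [pos, neg] (96 × 2), per-sample levels are pinv(M) · f on per-genome
frequencies f (each summing to 1; no cross-genome z-scoring — per-genome
normalization is the natural reading of projecting onto "normalized mutation
frequencies", and the cross-genome alternative is deliberately not
implemented). The unconstrained solution can produce negative levels; these
are reported as-is with a logged count, since clamping would bias concordance
statistics, and a `nonneg` flag provides the NNLS-constrained variant, which
agrees with the pseudoinverse whenever the unconstrained solution is already
nonnegative. A collinear pair (rank < 2 at tolerance 1e-8) is rejected.

Concordance is the Pearson correlation of each level with a reference score;
when the pair was derived from that score, the expected pattern is r_pos > 0,
r_neg < 0.

## Similarity and clustering

Cosine similarity on the 96-vectors; agglomerative clustering on 1 − cosine
with average (default) or complete linkage. Signatures are sorted
lexicographically by name before linkage, making merge heights and leaf order
invariant to input permutation. Euclidean-distance clustering is a plausible
alternative convention; cosine is the standard in the signature literature
and is used throughout. Nearest-neighbor ties break lexicographically. The
merge tree can be serialized as Newick (merge heights as node heights).

## Correlative layer

Log transforms use log2(x + 1). Pearson r with two-sided p per feature,
Benjamini–Hochberg q-values appended; zero-variance features yield NaN rows
rather than errors, a zero-variance response is an error. The four-class
stratification median-splits two features ("hi" strictly above the median).
Class contrasts use the Welch (unequal-variance) t-test — the safer default
when class sizes differ, as they do for median splits of coupled features. A
permutation helper returns the p-value distribution under response
relabeling for calibration checks.

## Synthetic cohorts

Per sample i and catalog of K signatures:

- baseline exposures w⁰ᵢ ~ Dirichlet(α);
- each causal signature j has latent activity aᵢⱼ ~ LogNormal(0, σ); its
  cohort-standardized log, zᵢⱼ, is the **true score**;
- the causal exposure share is a bounded saturating link
  sᵢⱼ = 0.75 · Φ(zᵢⱼ / 1.5), total shares capped at 0.9;
- final exposures wᵢ = (1 − Σⱼ sᵢⱼ) w⁰ᵢ + Σⱼ sᵢⱼ eⱼ; channel counts are
  multinomial(nᵢ, wᵢᵀP);
- an observed feature with coupling c is c·z + √(1 − c²)·ε with ε ~ N(0, 1),
  so the realized feature–score correlation is c in expectation (a supplied
  `noise_sd` overrides the calibrated noise; |c| = 1 with positive noise is
  rejected as infeasible). Binary features threshold the same noisy latent at
  a 10% prevalence. "Methylation"-style features are noisy negative
  transforms of their expression feature.

Working on the log scale keeps the score → exposure → projection chain
near-linear, which is the structure percentile stratification and
pseudoinverse projection assume, and matches the field's log-scale treatment
of expression values. Mutation counts default to LogNormal(median 500, σ = 1)
clipped to [50, 10 000]; scenario presets fix 2 000 mutations per sample and
n = 300 with coupling 0.8 — sizes at which every stage of the pipeline is
identifiable on one CPU in seconds.

`make_catalog` draws sparse-Dirichlet profiles with pairwise cosine < 0.8
enforced by rejection. The preset catalog is instead fixed and stylized
(synthetic, not a published catalog): six profiles echoing clock-like CpG
deamination, APOBEC C>T and C>G at TpC (with the characteristic 3′ ranking —
TCG weakest), MMRd-like GpC transitions plus T>C mass, proofreading-polymerase
failure (T[C>A]T, T[T>G]T), and a broad HRD-like profile spanning the
transversion blocks with a within-block context gradient. The gradient
descends toward T-flanked contexts so the broad profile's largest channels do
not coincide with the POLE/APOBEC peak channels — collisions there would make
the positive differential unidentifiable whenever baseline fluctuations of a
peaked process leak into a tail group. Baseline Dirichlet concentrations make
the clock-like process ~73% of background mass with total concentration 8
(background clock share sd ≈ 0.15): mutagenesis by APOBEC, MMRd,
proofreading failure and HR deficiency is episodic, so those processes get
small baseline weight, while the total concentration keeps tail-percentile
group means estimable at cohort sizes of a few hundred.

The MAF writer tiles one contig per pyrimidine-centered trinucleotide so that
every third position carries the wanted context; re-ingestion through the
spectrum builder reproduces the count matrix exactly, and output is
byte-stable for fixed input.

## What the generator does and does not emulate

It reproduces: mixture-of-signatures spectra with multinomial sampling noise,
heavy-tailed mutation burdens, features coupled to process activity at a
controlled correlation, anti-coupled methylation-style features, binary
genotype drivers, and an episodic-process exposure structure. It does not
reproduce: genomic position effects (replication timing, chromatin),
signature profiles of any published catalog, inter-signature exposure
correlations, tumor-type structure, purity/ploidy confounding, or measurement
error in the mutation calls themselves. Passing tests therefore demonstrate
correctness of the algorithms under the assumed statistical structure, not
performance on real cohorts — on real data, effect sizes are far smaller
(score–signature concordance around 0.5 rather than 0.9) and confounders
matter.

## Numerical choices

- Frequencies must sum to 1 within 1e-12 after normalization; all-zero
  spectra raise.
- Catalog rows must sum to 1 within 1e-6 (a `renormalize` flag fixes sloppy
  input).
- Grid-search oracle for refitting (tests only): exhaustive simplex grid,
  step 0.01, sum ≤ 1.
- Collinearity tolerance for projection pairs: 1e-8 on the rank computation.
- Ties: stratification thresholds include ties; median "hi" is strict;
  nearest-neighbor and clustering ties break lexicographically by name.

## Known limitations

- The refitting cutoff-and-refit is applied once, not iterated to a fixed
  point; with the 6% default this matches the convex optimum in all tested
  regimes but is not guaranteed to for adversarial catalogs.
- Differential signatures are biased toward zero at channels where the two
  group backgrounds differ; the bias is negligible when the causal process's
  support is distinct from the background's (see the catalog-design note
  above) but grows with overlap.
- The projection treats exactly one pos/neg pair; joint projection of more
  than two signatures is out of scope.
- VCF input assumes one sample per file (site-only VCFs take the file stem as
  sample id).
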