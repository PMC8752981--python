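# featsig

Feature-driven somatic mutation signature analysis for cancer genomics.

Somatic mutations accumulate in tumor genomes with sequence footprints —
mutation signatures — characteristic of the mutagenic or repair process that
produced them (APOBEC deaminase activity, mismatch-repair deficiency,
proofreading-polymerase failure, homologous-recombination deficiency, ...).
`featsig` implements a supervised, feature-driven approach to signature
analysis: instead of (or alongside) unsupervised factorization, it derives
signatures directly from a phenotypic or genotypic feature of interest and
then uses those signatures to read the feature back out of mutation profiles.

## What it computes

- **96-channel spectra and TMB** from MAF/VCF mutation tables plus a reference
  FASTA: each SNV is collapsed to the pyrimidine strand and classified by
  substitution type and 5′/3′ flanking bases (channel 0 = A[C>A]A, channel
  95 = T[T>G]T); indels count toward tumor mutation burden only. Samples with
  < 50 SNVs are flagged ineligible for signature analysis.
- **Signature refitting**: nonnegative least squares of each normalized
  spectrum f against a catalog P — min‖f − Pᵀs‖₂, s ≥ 0 — with a 6%
  threshold-and-refit cutoff, giving per-sample exposures (proportions and
  mutation counts).
- **Feature-driven signatures**: stratify genomes on a feature (expression
  percentiles 95th/5th, median split, or mutated vs wild-type), take the
  differential Δ = mean high-group frequencies − mean low-group frequencies,
  and split it into the positive part (the feature-representing signature)
  and negative part (the complementary state).
- **Metagene projection**: per-genome levels of a pos/neg signature pair via
  the Moore–Penrose pseudoinverse, s = pinv([pos, neg]) · f, plus Pearson
  concordance of the levels with the originating score.
- **Similarity & clustering**: cosine similarity and average-linkage
  hierarchical clustering of derived vs known signatures, with Newick export.
- **Correlative layer**: ranked Pearson correlations (log2(x+1) transforms,
  BH q-values), median-split four-class stratification of two features, and
  Welch t-tests between classes.
- **Synthetic cohorts**: a seeded generator producing spectra from signature
  mixtures with latent process activities and coupled feature variables, so
  the whole pipeline is testable with ground truth (scenario presets:
  `apobec`, `mlh1`, `pole`, `hrd`, `hypoxia`).

See `docs/methods.md` for the model details and design choices.

## Worked example

Derive an APOBEC-representing signature from expression tails and identify it
against the catalog (`examples/03_feature_signature.py`):

```python
import featsig as fs
from featsig import presets

cfg = presets.scenario_config("apobec", seed=3)   # n=300, 2000 mutations/sample
spectra, features, _ = fs.simulate_cohort(cfg)

pair = fs.derive_signature(spectra, features["APOBEC3A_expr"],
                           mode="percentile", hi_q=0.95, lo_q=0.05)
name, sim = fs.nearest_known(pair.pos, cfg.catalog)
```

Output:

```
groups: 15 high vs 15 low
nearest catalog signature to the positive differential: APOBEC-TpC-CtoT (cosine 0.989)

strongest channels of the derived signature:
channel
T[C>T]T    0.421
T[C>T]A    0.327
T[C>T]C    0.245
T[T>G]T    0.002
T[C>A]T    0.001
```

The 15 genomes in each expression tail differ mainly in their T[C>T]N
channels; the positive differential therefore reconstructs the generating
APOBEC-like profile almost exactly (cosine 0.989), exactly the behaviour the
feature-driven approach relies on. Projecting the derived pos/neg pair back
onto all 300 genomes (`examples/04_projection.py`) gives per-genome levels
that correlate with the true underlying score at r ≈ 0.95, with the
background-representing negative signature anti-correlated (r ≈ −0.83).

The other examples cover spectrum construction from MAF+FASTA (`01`),
exposure refitting (`02`), similarity clustering of a hypoxia-derived
signature with the APOBEC profiles (`05`), and the correlation/four-class
layer (`06`). Each runs in seconds.

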