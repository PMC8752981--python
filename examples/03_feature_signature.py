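"""Derive a feature-driven mutation signature from expression percentiles.

High vs low deaminase expression tails (95th/5th percentile) define two genome
groups; the positive part of their mean-frequency differential is the derived
signature, compared against the catalog by cosine similarity.
"""

import featsig as fs
from featsig import presets

cfg = presets.scenario_config("apobec", seed=3)   # n=300, 2000 mutations/sample
spectra, features, _ = fs.simulate_cohort(cfg)

pair = fs.derive_signature(spectra, features["APOBEC3A_expr"],
                           feature_name="APOBEC3A_expr",
                           mode="percentile", hi_q=0.95, lo_q=0.05)
print(f"groups: {pair.n_high} high vs {pair.n_low} low")

name, sim = fs.nearest_known(pair.pos, cfg.catalog)
print(f"nearest catalog signature to the positive differential: {name} "
      f"(cosine {sim:.3f})")

top = pair.to_frame()["pos"].nlargest(5)
print("\nstrongest channels of the derived signature:")
print(top.round(3))

# the derived signature should match the generating APOBEC-like profile with
# cosine ~0.99, its mass concentrated on the T[C>T]N channels.
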