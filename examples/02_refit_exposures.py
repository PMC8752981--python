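"""Refit spectra against a known-signature catalog to get per-sample exposures."""

import featsig as fs
from featsig import presets

cfg = presets.scenario_config("apobec", n_samples=8, mutations_per_sample=2000, seed=2)
spectra, _, truth = fs.simulate_cohort(cfg)
catalog = cfg.catalog

exposures = fs.exposure_matrix(spectra, catalog, min_mutations=50, min_weight=0.06)
print(exposures.round(3))
print("\ntrue simulated exposure of the APOBEC-like process:")
print(truth.exposures[presets.APOBEC_CT].round(3))

# each row gives the nonnegative fraction of a genome's mutations attributed to
# each catalog signature (weights < 6% are zeroed and the fit repeated); the
# residual column is the L2 reconstruction error of the normalized spectrum.
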