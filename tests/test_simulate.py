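"""Synthetic cohort generator: determinism, conservation, coupling calibration."""

import hashlib

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import featsig as fs
from featsig import presets
from featsig.errors import ConfigError
from featsig.simulate import spectra_to_maf
from featsig.spectrum import InMemoryReference, build_spectra


def test_make_catalog_seeded_and_row_stochastic():
    a = fs.make_catalog(k=5, seed=42)
    b = fs.make_catalog(k=5, seed=42)
    pd.testing.assert_frame_equal(a.profiles, b.profiles)
    assert np.allclose(a.profiles.sum(axis=1), 1.0)
    sim = fs.similarity_matrix(a).to_numpy()
    np.fill_diagonal(sim, 0.0)
    assert sim.max() < 0.8


def test_make_catalog_invalid_args():
    with pytest.raises(ConfigError):
        fs.make_catalog(k=1)
    with pytest.raises(ConfigError):
        fs.make_catalog(k=3, sparsity=0.0)


def test_simulate_cohort_conservation_and_determinism():
    cfg = presets.scenario_config("apobec", n_samples=50,
                                  mutations_per_sample=500, seed=3)
    spectra, feats, truth = fs.simulate_cohort(cfg)
    assert (spectra.counts.sum(axis=1).to_numpy() == truth.n_mut.to_numpy()).all()
    W = truth.exposures.to_numpy()
    assert (W >= 0).all()
    assert np.allclose(W.sum(axis=1), 1.0)

    spectra2, feats2, _ = fs.simulate_cohort(cfg)
    pd.testing.assert_frame_equal(spectra.counts, spectra2.counts)
    pd.testing.assert_frame_equal(feats, feats2)


def test_realized_coupling_tracks_request():
    """Feature-activity Pearson r lands within +-0.1 of the asked coupling."""
    for coupling in (0.8, -0.5):
        cfg = presets.scenario_config("apobec", n_samples=400,
                                      mutations_per_sample=200,
                                      coupling=abs(coupling), seed=9)
        cfg.causal_map[0].coupling = coupling
        _, feats, truth = fs.simulate_cohort(cfg)
        r = stats.pearsonr(feats["APOBEC3A_expr"],
                           truth.scores["score_" + presets.APOBEC_CT]).statistic
        assert abs(r - coupling) <= 0.1


def test_perfect_coupling_without_noise_recovers_profile():
    """coupling=1, noise-free, deep spectra: the causal profile comes back."""
    cfg = presets.scenario_config("apobec", n_samples=100,
                                  mutations_per_sample=10_000,
                                  coupling=1.0, seed=5)
    spectra, feats, _ = fs.simulate_cohort(cfg)
    pair = fs.derive_signature(spectra, feats["APOBEC3A_expr"])
    true = presets.reference_catalog().profiles.loc[presets.APOBEC_CT].to_numpy()
    assert fs.cosine_similarity(pair.pos, true) > 0.98


def test_zero_coupling_yields_no_signature():
    """Uncoupled features give tail groups whose differential is near noise."""
    true = presets.reference_catalog().profiles.loc[presets.APOBEC_CT].to_numpy()
    sims = []
    for seed in range(5):
        cfg = presets.scenario_config("apobec", n_samples=200,
                                      mutations_per_sample=1000,
                                      coupling=0.0, seed=seed)
        spectra, feats, _ = fs.simulate_cohort(cfg)
        pair = fs.derive_signature(spectra, feats["APOBEC3A_expr"])
        sims.append(fs.cosine_similarity(pair.pos, true))
    assert max(sims) < 0.6


def test_infeasible_coupling_rejected(catalog):
    with pytest.raises(ConfigError):
        fs.CausalLink("f", "x", coupling=1.0, noise_sd=0.5)
    with pytest.raises(ConfigError):
        fs.CausalLink("f", "x", coupling=1.5)


def test_anti_feature_is_negatively_correlated():
    cfg = presets.scenario_config("mlh1", n_samples=200, seed=4)
    _, feats, _ = fs.simulate_cohort(cfg)
    r = stats.pearsonr(feats["MLH1_expr"], feats["MLH1_meth"]).statistic
    assert r < -0.9


def test_binary_scenario_rate():
    cfg = presets.scenario_config("pole", n_samples=300, seed=6)
    _, feats, _ = fs.simulate_cohort(cfg)
    assert set(np.unique(feats["POLE_mut"])) == {0.0, 1.0}
    assert 0.05 <= feats["POLE_mut"].mean() <= 0.15


def test_maf_roundtrip_identity():
    cfg = presets.scenario_config("apobec", n_samples=30,
                                  mutations_per_sample=300, seed=8)
    spectra, _, _ = fs.simulate_cohort(cfg)
    maf, contigs = spectra_to_maf(spectra)
    back = build_spectra(maf, InMemoryReference(contigs),
                         sample_ids=spectra.sample_ids)
    pd.testing.assert_frame_equal(back.counts, spectra.counts)


def test_maf_file_byte_stable(tmp_path):
    cfg = presets.scenario_config("apobec", n_samples=3,
                                  mutations_per_sample=100, seed=2)
    spectra, _, _ = fs.simulate_cohort(cfg)
    digests = []
    for name in ("a.maf", "b.maf"):
        path = tmp_path / name
        fs.write_maf(spectra, path)
        digests.append(hashlib.sha256(path.read_bytes()).hexdigest())
    assert digests[0] == digests[1]


def test_empty_cohort_gives_header_only_maf(tmp_path, make_spectrum_set):
    empty = fs.SpectrumSet(
        counts=pd.DataFrame(columns=fs.CHANNELS, dtype=np.int64),
        meta=pd.DataFrame(columns=["n_snv", "tmb", "eligible"]),
    )
    path = tmp_path / "empty.maf"
    fs.write_maf(empty, path)
    lines = path.read_text().strip().splitlines()
    assert len(lines) == 1 and lines[0].startswith("Tumor_Sample_Barcode")


def test_mutation_count_spec_bounds():
    spec = fs.MutationCountSpec(kind="lognormal", median=500, sigma=1.0)
    draws = spec.draw(1000, np.random.default_rng(0))
    assert draws.min() >= 50 and draws.max() <= 10_000
    with pytest.raises(ConfigError):
        fs.MutationCountSpec(kind="lognormal", lo=0).draw(5, np.random.default_rng(0))
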