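"""Stratification and differential signature derivation."""

import numpy as np
import pandas as pd
import pytest

import featsig as fs
from featsig import presets
from featsig.errors import DegenerateStratificationError, EmptySignatureError


def test_percentile_stratification_nearest_rank():
    values = pd.Series(np.arange(1, 101, dtype=float),
                       index=[f"s{i}" for i in range(1, 101)])
    high, low = fs.stratify_samples(values, mode="percentile")
    assert sorted(high) == [f"s{i}" for i in (100, 96, 97, 98, 99)] or \
        set(high) == {f"s{i}" for i in range(96, 101)}
    assert set(low) == {f"s{i}" for i in range(1, 6)}


def test_binary_stratification_group_sizes():
    flags = pd.Series([1, 1, 1, 0, 0, 0, 0, 0, 0, 0],
                      index=[f"s{i}" for i in range(10)], dtype=float)
    high, low = fs.stratify_samples(flags, mode="binary")
    assert len(high) == 3 and len(low) == 7


def test_median_stratification_ties_go_low():
    values = pd.Series([1.0, 2.0, 3.0, 3.0, 5.0, 6.0, 7.0], index=list("abcdefg"))
    high, low = fs.stratify_samples(values, mode="median")  # median = 3, ties low
    assert set(high) == {"e", "f", "g"} and set(low) == {"a", "b", "c", "d"}


def test_constant_feature_errors():
    values = pd.Series(np.ones(50), index=[f"s{i}" for i in range(50)])
    with pytest.raises(DegenerateStratificationError):
        fs.stratify_samples(values, mode="percentile")


def test_tiny_group_errors():
    values = pd.Series([1.0, 2.0, 3.0, 4.0])
    with pytest.raises(DegenerateStratificationError):
        fs.stratify_samples(values, mode="percentile")


def test_disjoint_support_algebra(make_spectrum_set, disjoint_profiles):
    """High group exactly signature A, low exactly B, disjoint: pos=A, neg=B."""
    a, b = disjoint_profiles
    spectra = make_spectrum_set({
        "h1": (a * 2000).astype(int), "h2": (a * 2000).astype(int),
        "h3": (a * 2000).astype(int),
        "l1": (b * 2000).astype(int), "l2": (b * 2000).astype(int),
        "l3": (b * 2000).astype(int),
    })
    pair = fs.differential_signature(spectra, ["h1", "h2", "h3"], ["l1", "l2", "l3"])
    assert np.allclose(pair.pos, a)
    assert np.allclose(pair.neg, b)
    assert pair.n_high == 3 and pair.n_low == 3


def test_identical_groups_error(make_spectrum_set, disjoint_profiles):
    a, _ = disjoint_profiles
    spectra = make_spectrum_set({f"s{i}": (a * 1000).astype(int) for i in range(6)})
    with pytest.raises(EmptySignatureError):
        fs.differential_signature(spectra, ["s0", "s1", "s2"], ["s3", "s4", "s5"])


def test_antisymmetry_and_disjoint_support(apobec_cohort):
    """Swapping groups swaps pos and neg; pos and neg never share channels."""
    spectra, feats, _ = apobec_cohort
    high, low = fs.stratify_samples(feats["APOBEC3A_expr"], hi_q=0.8, lo_q=0.2)
    pair = fs.differential_signature(spectra, high, low)
    swapped = fs.differential_signature(spectra, low, high)
    assert np.allclose(pair.pos, swapped.neg)
    assert np.allclose(pair.neg, swapped.pos)
    assert np.allclose(pair.raw, -swapped.raw)
    assert float(pair.pos @ pair.neg) == 0.0


def test_invert_equals_swapped_groups(apobec_cohort):
    spectra, feats, _ = apobec_cohort
    high, low = fs.stratify_samples(feats["APOBEC3A_expr"], hi_q=0.8, lo_q=0.2)
    inv = fs.differential_signature(spectra, high, low, invert=True)
    swapped = fs.differential_signature(spectra, low, high)
    assert np.allclose(inv.raw, swapped.raw)


def test_pooled_mode_weights_by_counts(make_spectrum_set, disjoint_profiles):
    """Pooled counts let a hypermutant dominate; the mean of frequencies does not."""
    a, b = disjoint_profiles
    c = np.zeros(96)
    c[[20, 21]] = 0.5
    spectra = make_spectrum_set({
        "hyper": (a * 100000).astype(int),
        "quiet": (c * 100).astype(int),
        "l1": (b * 1000).astype(int), "l2": (b * 1000).astype(int),
        "l3": (b * 1000).astype(int),
    })
    mean_pair = fs.differential_signature(spectra, ["hyper", "quiet"], ["l1", "l2", "l3"])
    pooled_pair = fs.differential_signature(spectra, ["hyper", "quiet"],
                                            ["l1", "l2", "l3"], pooled=True)
    # in mean mode the quiet sample's channels carry half the high-group mass
    assert mean_pair.pos[20] > 0.2
    assert pooled_pair.pos[20] < 0.01


def test_feature_driven_recovery_quick(apobec_cohort):
    """An expression-coupled process is recovered from the tails of its feature."""
    spectra, feats, _ = apobec_cohort
    pair = fs.derive_signature(spectra, feats["APOBEC3A_expr"],
                               feature_name="APOBEC3A_expr")
    cat = presets.reference_catalog()
    name, sim = fs.nearest_known(pair.pos, cat)
    assert name == presets.APOBEC_CT
    assert sim >= 0.9


def test_derive_signature_drops_missing_and_ineligible(apobec_cohort):
    spectra, feats, _ = apobec_cohort
    vals = feats["APOBEC3A_expr"].copy()
    vals.iloc[:5] = np.nan
    pair = fs.derive_signature(spectra, vals, hi_q=0.9, lo_q=0.1)
    assert pair.n_high + pair.n_low <= len(vals.dropna())


def test_signature_pair_tsv_roundtrip(tmp_path, apobec_cohort):
    spectra, feats, _ = apobec_cohort
    pair = fs.derive_signature(spectra, feats["APOBEC3A_expr"])
    path = tmp_path / "pair.tsv"
    pair.to_tsv(path)
    back = fs.SignaturePair.from_tsv(path, "APOBEC3A_expr")
    assert np.allclose(back.pos, pair.pos)
    assert np.allclose(back.raw, pair.raw)
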