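"""Correlative layer: feature-burden/signature correlations and class contrasts.

Three pieces: (i) ranked Pearson correlations of a per-sample response (burden
or a signature level) against every column of a feature table, with
Benjamini-Hochberg q-values; (ii) a median-split four-class stratification on
two features (e.g. expression of a mutagen gene and of a repair gene); (iii)
Welch two-sample t-tests of a level between chosen classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import (DegenerateStratificationError, InsufficientDataError,
                     UndefinedCorrelationError)

FOUR_CLASSES = ["a_hi_b_hi", "a_hi_b_lo", "a_lo_b_hi", "a_lo_b_lo"]


def log2p1(x):
    """log2(x + 1), the transform used for expression-like values and burden."""
    return np.log2(np.asarray(x, dtype=float) + 1.0)


def correlate_features(
    response: pd.Series,
    features: pd.DataFrame,
    log_response: bool = False,
    log_features: bool = False,
    min_n: int = 3,
) -> pd.DataFrame:
    """Pearson correlation of a response against every feature column.

    Returns one row per feature (r, two-sided p, n, BH q), sorted by r.
    Zero-variance features yield NaN rows; a zero-variance response is an
    error.
    """
    resp = response.dropna().astype(float)
    if log_response:
        resp = pd.Series(log2p1(resp), index=resp.index)
    if resp.std() == 0 or len(resp) < min_n:
        raise UndefinedCorrelationError("response has zero variance or too few values")

    rows = []
    for name in features.columns:
        feat = features[name].dropna().astype(float)
        if log_features:
            feat = pd.Series(log2p1(feat), index=feat.index)
        joint = pd.concat([resp.rename("y"), feat.rename("x")], axis=1).dropna()
        if len(joint) < min_n or joint["x"].std() == 0 or joint["y"].std() == 0:
            rows.append((name, np.nan, np.nan, len(joint)))
            continue
        res = stats.pearsonr(joint["x"], joint["y"])
        rows.append((name, float(res.statistic), float(res.pvalue), len(joint)))
    out = pd.DataFrame(rows, columns=["feature", "r", "p", "n"]).set_index("feature")

    q = pd.Series(np.nan, index=out.index)
    ok = out["p"].notna()
    if ok.any():
        q[ok] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["q"] = q
    return out.sort_values("r")


def four_class_stratify(feat_a: pd.Series, feat_b: pd.Series) -> pd.Series:
    """Median-split both features and label each sample with its quadrant.

    "hi" means strictly above the median of non-missing values; samples
    missing either feature are dropped.
    """
    joint = pd.concat([feat_a.rename("a"), feat_b.rename("b")], axis=1).dropna()
    labels = {}
    for col in ("a", "b"):
        v = joint[col].astype(float)
        if v.std() == 0:
            raise DegenerateStratificationError(f"feature {col} is constant")
        labels[col] = np.where(v > v.median(), "hi", "lo")
    out = pd.Series([f"a_{la}_b_{lb}" for la, lb in zip(labels["a"], labels["b"])],
                    index=joint.index, name="class")
    return out


@dataclass
class LevelComparison:
    """Welch t-test of a level between two classes."""

    t: float
    p: float
    means: tuple[float, float]
    ns: tuple[int, int]


def compare_levels(
    levels: pd.Series,
    classes: pd.Series,
    pair: tuple[str, str],
) -> LevelComparison:
    """Welch (unequal-variance) two-sample t-test of ``levels`` between classes."""
    joint = pd.concat([levels.rename("level"), classes.rename("cls")], axis=1).dropna()
    groups = []
    for cls in pair:
        g = joint.loc[joint["cls"] == cls, "level"].to_numpy(dtype=float)
        if len(g) < 2:
            raise InsufficientDataError(f"class {cls!r} has {len(g)} samples (< 2)")
        groups.append(g)
    res = stats.ttest_ind(groups[0], groups[1], equal_var=False)
    return LevelComparison(t=float(res.statistic), p=float(res.pvalue),
                           means=(float(groups[0].mean()), float(groups[1].mean())),
                           ns=(len(groups[0]), len(groups[1])))


def permuted_pvalues(
    response: pd.Series,
    feature: pd.Series,
    n_perm: int = 1000,
    seed: int = 0,
) -> np.ndarray:
    """Two-sided Pearson p-values under random relabelings of the response.

    Useful as a calibration check: under the null the returned p-values should
    be approximately uniform on (0, 1).
    """
    joint = pd.concat([response.rename("y"), feature.rename("x")], axis=1).dropna()
    y = joint["y"].to_numpy(dtype=float)
    x = joint["x"].to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    out = np.empty(n_perm)
    for i in range(n_perm):
        out[i] = stats.pearsonr(x, rng.permutation(y)).pvalue
    return out
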