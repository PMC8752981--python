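"""Feature-driven signature discovery by differential trinucleotide frequencies.

A cohort is stratified on a per-sample feature — extreme expression percentiles,
a median split, or a binary genotype (e.g. mutated vs wild-type) — and the
difference between the mean per-sample channel frequencies of the high and low
groups is split into its positive and negative parts.  Each part, renormalized
to sum to one, is a candidate mutation signature: the positive part carries the
channels enriched in feature-high genomes, the negative part those enriched in
feature-low genomes.  For features whose *low* state drives mutagenesis (loss
of a repair gene such as MLH1), ``invert=True`` swaps the groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import channels as ch
from .errors import (DegenerateStratificationError, EmptySignatureError,
                     InsufficientDataError)
from .spectrum import SpectrumSet

logger = logging.getLogger(__name__)

HI_Q_DEFAULT = 0.95
LO_Q_DEFAULT = 0.05
MIN_GROUP_WARN = 10
MIN_GROUP_ERROR = 3


@dataclass
class SignaturePair:
    """Positive/negative differential signatures derived from one feature.

    ``raw`` is the signed 96-vector mean(high) - mean(low); ``pos`` and ``neg``
    are its clipped, renormalized parts and have disjoint support.
    """

    feature_name: str
    pos: np.ndarray
    neg: np.ndarray
    raw: np.ndarray
    n_high: int
    n_low: int

    def swapped(self) -> "SignaturePair":
        return SignaturePair(self.feature_name, self.neg.copy(), self.pos.copy(),
                             -self.raw, self.n_low, self.n_high)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"pos": self.pos, "neg": self.neg, "raw": self.raw},
                            index=pd.Index(ch.CHANNELS, name="channel"))

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path, feature_name: str = "") -> "SignaturePair":
        df = pd.read_csv(path, sep="\t", index_col=0).loc[ch.CHANNELS]
        return cls(feature_name or str(path), df["pos"].to_numpy(),
                   df["neg"].to_numpy(), df["raw"].to_numpy(), 0, 0)


def stratify_samples(
    values: pd.Series,
    mode: str = "percentile",
    hi_q: float = HI_Q_DEFAULT,
    lo_q: float = LO_Q_DEFAULT,
) -> tuple[list[str], list[str]]:
    """Split samples into (high, low) groups on one feature.

    percentile mode keeps the tails: high = value >= the hi_q quantile
    (nearest-rank from above), low = value <= the lo_q quantile (nearest-rank
    from below); ties at either threshold are all included.  median mode splits
    the whole cohort at the median with ties going low.  binary mode treats 1
    as high (e.g. mutated) and 0 as low (wild-type).
    """
    vals = values.dropna()
    if len(vals) < 2:
        raise DegenerateStratificationError("need at least 2 non-missing values")
    v = vals.to_numpy(dtype=float)

    if mode == "percentile":
        hi_thr = np.quantile(v, hi_q, method="higher")
        lo_thr = np.quantile(v, lo_q, method="lower")
        high = vals.index[v >= hi_thr]
        low = vals.index[v <= lo_thr]
    elif mode == "median":
        med = np.median(v)
        high = vals.index[v > med]
        low = vals.index[v <= med]
    elif mode == "binary":
        if not set(np.unique(v)) <= {0.0, 1.0}:
            raise DegenerateStratificationError("binary mode requires values in {0,1}")
        high = vals.index[v == 1.0]
        low = vals.index[v == 0.0]
    else:
        raise ValueError(f"unknown stratification mode {mode!r}")

    high, low = list(high), list(low)
    overlap = set(high) & set(low)
    if overlap:
        # percentile ties can straddle both thresholds on near-constant features
        raise DegenerateStratificationError(
            f"{len(overlap)} samples fall in both groups (feature nearly constant)")
    if not high or not low:
        raise DegenerateStratificationError("one stratification group is empty")
    for name, grp in (("high", high), ("low", low)):
        if len(grp) < MIN_GROUP_ERROR:
            raise DegenerateStratificationError(
                f"{name} group has {len(grp)} samples (< {MIN_GROUP_ERROR})")
        if len(grp) < MIN_GROUP_WARN:
            logger.warning("%s group has only %d samples", name, len(grp))
    return high, low


def differential_signature(
    spectra: SpectrumSet,
    high_ids: list[str],
    low_ids: list[str],
    feature_name: str = "feature",
    invert: bool = False,
    pooled: bool = False,
) -> SignaturePair:
    """Positive/negative differential signatures between two sample groups.

    By default the differential is the difference of group means of per-sample
    normalized frequencies, so hypermutant samples do not dominate their group;
    ``pooled=True`` instead pools raw counts within each group before
    normalizing.  ``invert=True`` computes low - high (for features whose low
    state is causal).
    """
    if set(high_ids) & set(low_ids):
        raise DegenerateStratificationError("high and low groups overlap")
    if invert:
        high_ids, low_ids = low_ids, high_ids

    def group_mean(ids: list[str]) -> np.ndarray:
        sub = spectra.counts.loc[ids]
        totals = sub.sum(axis=1)
        if (totals == 0).any():
            raise InsufficientDataError("group contains samples with zero SNVs")
        if pooled:
            pool = sub.sum(axis=0).to_numpy(dtype=float)
            return pool / pool.sum()
        return sub.div(totals, axis=0).mean(axis=0).to_numpy(dtype=float)

    raw = group_mean(high_ids) - group_mean(low_ids)
    pos_part = np.clip(raw, 0.0, None)
    neg_part = np.clip(-raw, 0.0, None)
    if pos_part.sum() == 0 and neg_part.sum() == 0:
        raise EmptySignatureError("group mean spectra are identical")
    pos = pos_part / pos_part.sum() if pos_part.sum() > 0 else pos_part
    neg = neg_part / neg_part.sum() if neg_part.sum() > 0 else neg_part
    return SignaturePair(feature_name, pos, neg, raw, len(high_ids), len(low_ids))


def derive_signature(
    spectra: SpectrumSet,
    values: pd.Series,
    feature_name: str = "feature",
    mode: str = "percentile",
    hi_q: float = HI_Q_DEFAULT,
    lo_q: float = LO_Q_DEFAULT,
    invert: bool = False,
    pooled: bool = False,
    eligible_only: bool = True,
) -> SignaturePair:
    """Stratify on a feature and compute its differential signature pair.

    Samples missing the feature, absent from the spectrum table, or (by
    default) failing the mutation-count gate are dropped before stratifying.
    """
    keep = values.dropna().index.intersection(spectra.counts.index)
    if eligible_only:
        keep = keep[spectra.meta.loc[keep, "eligible"]]
    high, low = stratify_samples(values.loc[keep], mode=mode, hi_q=hi_q, lo_q=lo_q)
    return differential_signature(spectra, high, low, feature_name=feature_name,
                                  invert=invert, pooled=pooled)
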