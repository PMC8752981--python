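"""Metagene projection of signature pairs onto per-sample spectra.

Given a positive/negative signature pair derived from one feature or score,
per-sample levels of the two signatures are estimated by applying the
Moore-Penrose generalized pseudoinverse of the 96 x 2 basis [pos, neg] to each
sample's normalized channel frequencies.  When the originating score is
available, concordance is the Pearson correlation of the projected levels with
that score: the positive level should correlate positively, the negative level
negatively, when the pair truly encodes the score.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import (SingularPairError, UndefinedCorrelationError)
from .feature_sig import SignaturePair
from .spectrum import SpectrumSet

logger = logging.getLogger(__name__)

_COLLINEAR_TOL = 1e-8


def project_levels(
    spectra: SpectrumSet,
    pair: SignaturePair,
    nonneg: bool = False,
) -> pd.DataFrame:
    """Per-sample (pos_level, neg_level) by pseudoinverse projection.

    Default is the unconstrained least-squares solution pinv([pos, neg]) @ f,
    which may produce negative levels (reported as-is, with a logged count);
    ``nonneg=True`` solves the per-sample nonnegative least squares instead.
    Samples with zero SNVs are dropped.
    """
    M = np.column_stack([pair.pos, pair.neg])
    if np.linalg.matrix_rank(M, tol=_COLLINEAR_TOL) < 2:
        raise SingularPairError("pos and neg signatures are linearly dependent")
    F = spectra.frequencies()
    X = F.to_numpy(dtype=float)
    if nonneg:
        levels = np.vstack([optimize.nnls(M, x)[0] for x in X])
    else:
        levels = (np.linalg.pinv(M) @ X.T).T
        n_negative = int((levels < 0).sum())
        if n_negative:
            logger.warning("%d of %d projected levels are negative",
                           n_negative, levels.size)
    return pd.DataFrame(levels, index=F.index, columns=["pos_level", "neg_level"])


def score_concordance(
    result: pd.DataFrame,
    scores: pd.Series,
) -> tuple[float, float]:
    """Pearson r of (pos_level, neg_level) against a reference score."""
    joint = result.join(scores.rename("score"), how="inner").dropna()
    if len(joint) < 3:
        raise UndefinedCorrelationError("need >= 3 overlapping scored samples")
    out = []
    for col in ("pos_level", "neg_level"):
        if joint[col].std() == 0 or joint["score"].std() == 0:
            raise UndefinedCorrelationError(f"zero variance in {col} or score")
        out.append(float(stats.pearsonr(joint[col], joint["score"]).statistic))
    return out[0], out[1]
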