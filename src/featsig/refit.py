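"""Signature refitting: per-sample exposures of known signatures.

Each eligible spectrum is decomposed against a catalog by nonnegative least
squares on its normalized frequencies,

    min_{s >= 0} || f - P^T s ||_2,

where P is the K x 96 catalog and f the 96-vector of channel frequencies.
Signatures whose fitted weight falls below a cutoff (default 6%, mirroring the
conventional refitting cutoff) are zeroed and the reduced problem re-solved.
Samples carrying fewer than ``min_mutations`` SNVs are flagged excluded rather
than fitted — their weights are reported as missing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import channels as ch
from .catalog import SignatureCatalog
from .errors import DimensionError
from .spectrum import Spectrum96, SpectrumSet, normalize_spectrum

MIN_MUTATIONS_DEFAULT = 50
MIN_WEIGHT_DEFAULT = 0.06


@dataclass
class Exposure:
    """Fitted signature contributions for one sample.

    ``weights`` are nonnegative proportions of the spectrum (sum <= 1, the
    residual absorbs unexplained mass); ``counts`` = weights * n_snv.  When the
    sample fails the mutation-count gate, ``excluded`` is True and both vectors
    are NaN.
    """

    sample_id: str
    weights: pd.Series
    counts: pd.Series
    residual: float
    excluded: bool = False


def _solve_nnls(A: np.ndarray, f: np.ndarray) -> np.ndarray:
    w, _ = optimize.nnls(A, f)
    if w.sum() > 1.0:
        # keep the exposure simplex constraint sum(w) <= 1; refine from the
        # unconstrained optimum
        res = optimize.minimize(
            lambda x: 0.5 * np.sum((A @ x - f) ** 2),
            x0=w / w.sum(),
            jac=lambda x: A.T @ (A @ x - f),
            bounds=[(0.0, None)] * A.shape[1],
            constraints=[{"type": "ineq", "fun": lambda x: 1.0 - x.sum(),
                          "jac": lambda x: -np.ones_like(x)}],
            method="SLSQP",
            options={"maxiter": 200, "ftol": 1e-12},
        )
        w = np.clip(res.x, 0.0, None)
    return w


def refit_exposures(
    spectrum: Spectrum96,
    catalog: SignatureCatalog,
    min_mutations: int = MIN_MUTATIONS_DEFAULT,
    min_weight: float = MIN_WEIGHT_DEFAULT,
    renormalize: bool = False,
) -> Exposure:
    """Fit one spectrum against the catalog; threshold-and-refit small weights."""
    if spectrum.counts.shape != (ch.N_CHANNELS,):
        raise DimensionError("spectrum must have 96 channels")
    names = catalog.names
    if spectrum.n_snv < min_mutations:
        nan = pd.Series(np.nan, index=names)
        return Exposure(spectrum.sample_id, nan, nan.copy(), np.nan, excluded=True)

    A = catalog.matrix().T  # 96 x K
    f = normalize_spectrum(spectrum.counts)
    w = _solve_nnls(A, f)

    active = w >= min_weight
    w_full = np.zeros(catalog.k)
    if active.any():
        if active.all():
            w_full = w
        else:
            w_red = _solve_nnls(A[:, active], f)
            # re-threshold once on the reduced fit for stability
            w_red[w_red < min_weight] = 0.0
            w_full[active] = w_red
    residual = float(np.linalg.norm(f - A @ w_full))
    if renormalize and w_full.sum() > 0:
        w_full = w_full / w_full.sum()
    weights = pd.Series(w_full, index=names)
    return Exposure(spectrum.sample_id, weights, weights * spectrum.n_snv,
                    residual, excluded=False)


def exposure_matrix(
    spectra: SpectrumSet,
    catalog: SignatureCatalog,
    min_mutations: int = MIN_MUTATIONS_DEFAULT,
    min_weight: float = MIN_WEIGHT_DEFAULT,
    renormalize: bool = False,
) -> pd.DataFrame:
    """Per-sample exposure weights for a cohort.

    Returns a samples x (K + 1) DataFrame: one column per signature plus a
    ``residual`` column.  Excluded samples (below the mutation gate) carry NaN.
    """
    rows = {}
    for sp in spectra.spectra():
        exp = refit_exposures(sp, catalog, min_mutations, min_weight, renormalize)
        rows[sp.sample_id] = pd.concat([exp.weights,
                                        pd.Series({"residual": exp.residual})])
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "sample_id"
    return out.loc[spectra.sample_ids, catalog.names + ["residual"]]
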