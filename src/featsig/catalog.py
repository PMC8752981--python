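"""Signature catalogs: named K x 96 row-stochastic profile matrices."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import channels as ch
from .errors import DimensionError

_ROW_SUM_TOL = 1e-6


@dataclass
class SignatureCatalog:
    """A set of known (or derived) mutation signatures.

    ``profiles`` is a DataFrame indexed by signature name with the 96 canonical
    channel labels as columns; every row sums to one.
    """

    profiles: pd.DataFrame

    def __post_init__(self):
        if list(self.profiles.columns) != ch.CHANNELS:
            raise DimensionError("catalog columns must be the 96 canonical channel labels")
        if len(self.profiles) < 1:
            raise DimensionError("catalog must contain at least one signature")
        if self.profiles.index.duplicated().any():
            raise DimensionError("signature names must be unique")
        if (self.profiles.to_numpy() < 0).any():
            raise DimensionError("signature profiles must be nonnegative")
        sums = self.profiles.sum(axis=1)
        if not np.allclose(sums, 1.0, atol=_ROW_SUM_TOL):
            raise DimensionError("every signature profile must sum to 1")

    @property
    def names(self) -> list[str]:
        return list(self.profiles.index)

    @property
    def k(self) -> int:
        return len(self.profiles)

    def matrix(self) -> np.ndarray:
        """K x 96 numpy view."""
        return self.profiles.to_numpy(dtype=float)

    def subset(self, names: list[str]) -> "SignatureCatalog":
        return SignatureCatalog(self.profiles.loc[names])

    @classmethod
    def from_matrix(cls, profiles: np.ndarray, names: list[str],
                    renormalize: bool = False) -> "SignatureCatalog":
        arr = np.asarray(profiles, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != ch.N_CHANNELS:
            raise DimensionError(f"expected K x 96 matrix, got {arr.shape}")
        if renormalize:
            arr = arr / arr.sum(axis=1, keepdims=True)
        return cls(pd.DataFrame(arr, index=pd.Index(names, name="signature"),
                                columns=ch.CHANNELS))

    @classmethod
    def from_cosmic_tsv(cls, path: str | Path) -> "SignatureCatalog":
        """Read the COSMIC v2 ("Sanger ver.2") 30-signature TSV layout.

        96 rows; columns ``Substitution Type``, ``Trinucleotide``,
        ``Somatic Mutation Type`` (e.g. ``A[C>A]A``) followed by one column per
        signature.  Rows are reordered into canonical channel order.
        """
        df = pd.read_csv(path, sep="\t")
        if "Somatic Mutation Type" not in df.columns:
            raise DimensionError("not a COSMIC v2 signature table")
        df = df.set_index("Somatic Mutation Type")
        sig_cols = [c for c in df.columns
                    if c not in ("Substitution Type", "Trinucleotide")
                    and pd.api.types.is_numeric_dtype(df[c])]
        try:
            block = df.loc[ch.CHANNELS, sig_cols]
        except KeyError as exc:
            raise DimensionError("COSMIC table does not cover all 96 channels") from exc
        return cls.from_matrix(block.to_numpy().T, sig_cols, renormalize=True)

    @classmethod
    def from_tsv(cls, path: str | Path, renormalize: bool = False) -> "SignatureCatalog":
        """Read a plain signature x 96 TSV (channel labels as header)."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        missing = [c for c in ch.CHANNELS if c not in df.columns]
        if missing:
            raise DimensionError(f"signature TSV lacks {len(missing)} channel columns")
        return cls.from_matrix(df[ch.CHANNELS].to_numpy(), list(df.index),
                               renormalize=renormalize)

    def to_tsv(self, path: str | Path) -> None:
        self.profiles.to_csv(path, sep="\t", index_label="signature")
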