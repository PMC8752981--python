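"""Per-sample 96-channel mutation spectra and tumor mutation burden.

The entry point is :func:`build_spectra`, which takes somatic mutation records
(one row per call, MAF-style 1-based coordinates) plus a reference-sequence
lookup, classifies every SNV into its trinucleotide channel, and returns one
:class:`Spectrum96` per sample.  Indels (and any non-SNV substitution) count
toward the tumor mutation burden but occupy no channel.  Samples with fewer
than ``min_snv`` SNVs are flagged ineligible for signature analysis but kept
for burden-level analyses.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import channels as ch
from .errors import EmptyInputError, InvalidMutationError, UndefinedNormalizationError

logger = logging.getLogger(__name__)

#: default SNV-count gate for signature analysis
MIN_SNV_DEFAULT = 50

_SNV_CLASSES = {"SNV", "SNP"}
_INDEL_CLASSES = {"INS", "DEL"}
RECORD_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "variant_class"]


@dataclass(frozen=True)
class MutationRecord:
    """One somatic call: sample, 1-based position, ref/alt alleles, class."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    variant_class: str = "SNV"

    def __post_init__(self):
        if self.pos < 1:
            raise InvalidMutationError(f"position {self.pos} < 1")
        if self.ref == self.alt:
            raise InvalidMutationError("ref and alt alleles are identical")
        if self.variant_class == "SNV" and not (
            len(self.ref) == 1 and len(self.alt) == 1
            and self.ref in ch.BASES and self.alt in ch.BASES
        ):
            raise InvalidMutationError(
                f"SNV must be a single ACGT>ACGT change, got {self.ref}>{self.alt}"
            )


@dataclass
class Spectrum96:
    """Counts over the 96 canonical channels for one sample.

    ``tmb`` is the tumor mutation burden: accepted SNVs plus accepted indels
    (and other non-SNV substitutions), following the convention that burden is
    the sum of all somatic calls.
    """

    sample_id: str
    counts: np.ndarray
    n_snv: int
    tmb: int
    eligible: bool = True

    def frequencies(self) -> np.ndarray:
        return normalize_spectrum(self.counts)


@dataclass
class SpectrumSet:
    """A cohort of spectra with aligned count and metadata tables."""

    counts: pd.DataFrame  # samples x 96, columns = channel labels
    meta: pd.DataFrame    # samples x [n_snv, tmb, eligible]

    def __post_init__(self):
        if list(self.counts.columns) != ch.CHANNELS:
            raise InvalidMutationError("count matrix columns must be the 96 canonical labels")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    def frequencies(self) -> pd.DataFrame:
        """Row-normalized per-sample frequencies (rows with zero SNVs dropped)."""
        totals = self.counts.sum(axis=1)
        nz = totals > 0
        return self.counts.loc[nz].div(totals[nz], axis=0)

    def spectra(self) -> list[Spectrum96]:
        out = []
        for sid in self.counts.index:
            m = self.meta.loc[sid]
            out.append(Spectrum96(sid, self.counts.loc[sid].to_numpy(),
                                  int(m["n_snv"]), int(m["tmb"]), bool(m["eligible"])))
        return out

    def __len__(self) -> int:
        return len(self.counts)


class InMemoryReference:
    """Reference lookup backed by plain contig strings (1-based positions)."""

    def __init__(self, contigs: Mapping[str, str]):
        self._contigs = {name: seq.upper() for name, seq in contigs.items()}
        self._arrays = {name: ch.encode_bases(np.frombuffer(seq.encode(), dtype="S1"))
                        for name, seq in self._contigs.items()}

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._contigs

    def length(self, chrom: str) -> int:
        return len(self._contigs[chrom])

    def base_codes(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Base codes at 1-based positions; out-of-range -> -1."""
        arr = self._arrays[chrom]
        out = np.full(len(pos), -1, dtype=np.int8)
        ok = (pos >= 1) & (pos <= len(arr))
        out[ok] = arr[pos[ok] - 1]
        return out


class FastaReference(InMemoryReference):
    """Reference lookup from an (indexed) FASTA file via pyfaidx."""

    def __init__(self, path: str):
        import pyfaidx

        fa = pyfaidx.Fasta(str(path), as_raw=True, sequence_always_upper=True)
        super().__init__({name: str(fa[name][:]) for name in fa.keys()})


def records_to_frame(mutations: Iterable[MutationRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(mutations, pd.DataFrame):
        missing = set(RECORD_COLUMNS) - set(mutations.columns)
        if missing:
            raise InvalidMutationError(f"mutation table lacks columns {sorted(missing)}")
        return mutations[RECORD_COLUMNS].copy()
    rows = [(m.sample_id, m.chrom, m.pos, m.ref, m.alt, m.variant_class) for m in mutations]
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def build_spectra(
    mutations: Iterable[MutationRecord] | pd.DataFrame,
    reference: InMemoryReference,
    min_snv: int = MIN_SNV_DEFAULT,
    sample_ids: Sequence[str] | None = None,
) -> SpectrumSet:
    """Classify SNVs into channels and assemble the cohort spectrum table.

    Records are deduplicated on (sample, chrom, pos, alt); records whose ref
    allele mismatches the reference, fall on an unknown contig, sit at a contig
    edge, or have a non-ACGT flanking base are skipped with a warning.  Raises
    :class:`EmptyInputError` if nothing survives.
    """
    df = records_to_frame(mutations)
    if len(df) == 0:
        raise EmptyInputError("no mutation records supplied")

    before = len(df)
    df = df.drop_duplicates(subset=["sample_id", "chrom", "pos", "alt"])
    if len(df) < before:
        logger.warning("dropped %d duplicate records", before - len(df))

    known = df["chrom"].map(lambda c: c in reference)
    if not known.all():
        logger.warning("skipped %d records on contigs absent from the reference",
                       int((~known).sum()))
        df = df[known]
    if len(df) == 0:
        raise EmptyInputError("all records were rejected")

    is_snv = (df["variant_class"].isin(_SNV_CLASSES)
              & (df["ref"].str.len() == 1) & (df["alt"].str.len() == 1)
              & df["ref"].isin(list(ch.BASES)) & df["alt"].isin(list(ch.BASES)))

    snv = df[is_snv]
    channel = np.full(len(snv), -1, dtype=np.int64)
    mismatched = 0
    for chrom, grp in snv.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy(dtype=np.int64)
        ref_code = ch.encode_bases(grp["ref"].to_numpy())
        alt_code = ch.encode_bases(grp["alt"].to_numpy())
        genome_ref = reference.base_codes(chrom, pos)
        five = reference.base_codes(chrom, pos - 1)
        three = reference.base_codes(chrom, pos + 1)
        ok_ref = genome_ref == ref_code
        mismatched += int((~ok_ref & (genome_ref >= 0)).sum())
        idx = ch.classify_codes(ref_code, alt_code, five, three)
        idx[~ok_ref] = -1
        loc = snv.index.get_indexer(grp.index)
        channel[loc] = idx
    if mismatched:
        logger.warning("skipped %d SNVs whose ref allele mismatches the reference",
                       mismatched)
    n_context_skipped = int((channel < 0).sum()) - mismatched
    if n_context_skipped > 0:
        logger.warning("skipped %d SNVs with unusable context (edge or ambiguous base)",
                       n_context_skipped)

    accepted = channel >= 0
    if sample_ids is None:
        order = list(pd.unique(df["sample_id"]))
    else:
        order = list(sample_ids)

    counts = pd.DataFrame(0, index=pd.Index(order, name="sample_id"),
                          columns=ch.CHANNELS, dtype=np.int64)
    acc = pd.DataFrame({"sample_id": snv["sample_id"].to_numpy()[accepted],
                        "channel": channel[accepted]})
    if len(acc):
        tab = acc.groupby(["sample_id", "channel"]).size()
        for (sid, chan), n in tab.items():
            if sid in counts.index:
                counts.iat[counts.index.get_loc(sid), int(chan)] = int(n)

    non_snv = df[~is_snv]
    other_counts = non_snv.groupby("sample_id").size()
    n_snv = counts.sum(axis=1)
    if int(n_snv.sum()) == 0 and other_counts.sum() == 0:
        raise EmptyInputError("all records were rejected")
    tmb = n_snv.add(other_counts.reindex(counts.index).fillna(0).astype(int), fill_value=0)
    meta = pd.DataFrame({
        "n_snv": n_snv.astype(int),
        "tmb": tmb.astype(int),
        "eligible": n_snv >= min_snv,
    })
    return SpectrumSet(counts=counts, meta=meta)


def normalize_spectrum(counts: np.ndarray | Sequence[float]) -> np.ndarray:
    """Normalize channel counts to frequencies summing to one."""
    arr = np.asarray(counts, dtype=float)
    if arr.shape != (ch.N_CHANNELS,):
        raise InvalidMutationError(f"expected 96 channels, got shape {arr.shape}")
    total = arr.sum()
    if total <= 0:
        raise UndefinedNormalizationError("cannot normalize an all-zero spectrum")
    return arr / total
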