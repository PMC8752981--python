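"""Readers and writers for the tabular formats used throughout the package.

MAF tables follow the TCGA dialect (tab-separated, 1-based inclusive
coordinates, columns ``Tumor_Sample_Barcode``, ``Chromosome``,
``Start_Position``, ``Reference_Allele``, ``Tumor_Seq_Allele2``,
``Variant_Type``).  Spectrum matrices are written as sample x 96 TSV with the
canonical channel labels as header.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import channels as ch
from .errors import DimensionError
from .spectrum import RECORD_COLUMNS, SpectrumSet

MAF_COLUMNS = {
    "Tumor_Sample_Barcode": "sample_id",
    "Chromosome": "chrom",
    "Start_Position": "pos",
    "Reference_Allele": "ref",
    "Tumor_Seq_Allele2": "alt",
    "Variant_Type": "variant_class",
}

_VARIANT_TYPE_MAP = {"SNP": "SNV", "SNV": "SNV", "INS": "INS", "DEL": "DEL"}


def read_maf(path: str | Path) -> pd.DataFrame:
    """Read a MAF file into the internal mutation-record table."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"Chromosome": str},
                     low_memory=False)
    missing = set(MAF_COLUMNS) - set(df.columns)
    if missing:
        raise DimensionError(f"MAF lacks required columns {sorted(missing)}")
    out = df[list(MAF_COLUMNS)].rename(columns=MAF_COLUMNS)
    out["variant_class"] = out["variant_class"].map(_VARIANT_TYPE_MAP).fillna("other")
    out["pos"] = out["pos"].astype(np.int64)
    return out[RECORD_COLUMNS]


def write_maf(records: pd.DataFrame, path: str | Path) -> None:
    """Write the internal mutation-record table as a minimal MAF."""
    inv = {v: k for k, v in MAF_COLUMNS.items()}
    out = records[RECORD_COLUMNS].rename(columns=inv)
    out["End_Position"] = out["Start_Position"] + out["Reference_Allele"].str.len() - 1
    out["Variant_Type"] = out["Variant_Type"].replace({"SNV": "SNP"})
    cols = ["Tumor_Sample_Barcode", "Chromosome", "Start_Position", "End_Position",
            "Reference_Allele", "Tumor_Seq_Allele2", "Variant_Type"]
    out[cols].to_csv(path, sep="\t", index=False)


def read_vcf(path: str | Path, sample_id: str | None = None) -> pd.DataFrame:
    """Read a (single-sample) VCF into the internal mutation-record table.

    ``sample_id`` defaults to the first genotype column, or the file stem for
    site-only VCFs.  Multi-allelic records contribute one row per alternate.
    """
    import pysam

    vcf = pysam.VariantFile(str(path))
    if sample_id is None:
        samples = list(vcf.header.samples)
        sample_id = samples[0] if samples else Path(path).stem
    rows = []
    for rec in vcf:
        for alt in rec.alts or ():
            ref = rec.ref
            if len(ref) == 1 and len(alt) == 1 and ref in ch.BASES and alt in ch.BASES:
                vc = "SNV"
            elif len(alt) > len(ref):
                vc = "INS"
            elif len(alt) < len(ref):
                vc = "DEL"
            else:
                vc = "other"
            rows.append((sample_id, rec.chrom, rec.pos, ref, alt, vc))
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def write_spectra_tsv(spectra: SpectrumSet, path: str | Path) -> None:
    """Write counts plus n_snv/tmb/eligible metadata columns as one TSV."""
    out = pd.concat([spectra.meta, spectra.counts], axis=1)
    out.to_csv(path, sep="\t", index_label="sample_id")


def read_spectra_tsv(path: str | Path, min_snv: int = 50) -> SpectrumSet:
    """Read a spectrum TSV written by :func:`write_spectra_tsv` (or a bare
    sample x 96 count matrix, in which case metadata are recomputed)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    missing = [c for c in ch.CHANNELS if c not in df.columns]
    if missing:
        raise DimensionError(f"spectrum TSV lacks {len(missing)} channel columns")
    counts = df[ch.CHANNELS].astype(np.int64)
    if {"n_snv", "tmb", "eligible"} <= set(df.columns):
        meta = df[["n_snv", "tmb", "eligible"]].astype({"n_snv": int, "tmb": int,
                                                        "eligible": bool})
    else:
        n_snv = counts.sum(axis=1)
        meta = pd.DataFrame({"n_snv": n_snv, "tmb": n_snv, "eligible": n_snv >= min_snv})
    return SpectrumSet(counts=counts, meta=meta)


def write_fasta(contigs: dict[str, str], path: str | Path, width: int = 70) -> None:
    """Write contig strings as an uncompressed FASTA file."""
    with open(path, "w") as fh:
        for name in sorted(contigs):
            fh.write(f">{name}\n")
            seq = contigs[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
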