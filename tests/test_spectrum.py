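"""Channel classification, spectrum construction and normalization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import featsig as fs
from featsig import channels as ch
from featsig.errors import (EmptyInputError, InvalidMutationError,
                            UndefinedNormalizationError)
from featsig.spectrum import InMemoryReference, build_spectra

BASES = st.sampled_from("ACGT")


@pytest.mark.parametrize("ref,alt,five,three,expected", [
    ("C", "A", "A", "A", 0),     # first channel A[C>A]A
    ("G", "T", "T", "T", 0),     # reverse complement of A[C>A]A
    ("T", "G", "T", "T", 95),    # last channel T[T>G]T
    ("A", "C", "A", "A", 95),    # reverse complement of T[T>G]T
    ("C", "T", "A", "G", 32 + 2),  # A[C>T]G
])
def test_classify_substitution_canonical_order(ref, alt, five, three, expected):
    assert fs.classify_substitution(ref, alt, five, three) == expected


def test_classify_substitution_rejects_bad_input():
    with pytest.raises(InvalidMutationError):
        fs.classify_substitution("C", "C", "A", "A")
    with pytest.raises(InvalidMutationError):
        fs.classify_substitution("N", "A", "A", "A")


def test_channel_labels_match_contexts():
    for idx, label in enumerate(ch.CHANNELS):
        five, ref, alt, three = ch.channel_context(idx)
        assert label == f"{five}[{ref}>{alt}]{three}"
        assert fs.classify_substitution(ref, alt, five, three) == idx


@settings(deadline=None, derandomize=True)
@given(ref=BASES, alt=BASES, five=BASES, three=BASES)
def test_classify_substitution_strand_symmetry(ref, alt, five, three):
    """Both strands of one mutation map to the same channel."""
    if ref == alt:
        return
    c = ch.COMPLEMENT
    fwd = fs.classify_substitution(ref, alt, five, three)
    rev = fs.classify_substitution(c[ref], c[alt], c[three], c[five])
    assert fwd == rev


def test_vectorized_classification_matches_scalar():
    rng = np.random.default_rng(0)
    codes = rng.integers(0, 4, size=(500, 4))
    keep = codes[:, 0] != codes[:, 1]
    codes = codes[keep]
    vec = ch.classify_codes(codes[:, 0], codes[:, 1], codes[:, 2], codes[:, 3])
    for row, v in zip(codes, vec):
        r, a, f, t = (ch.BASES[i] for i in row)
        assert fs.classify_substitution(r, a, f, t) == v


def _ref():
    # positions:        123456789
    return InMemoryReference({"chr1": "AACGTTACGA"})


def test_build_spectra_counts_and_tmb():
    """3 C>T SNVs at an ACG context plus one deletion: one channel = 3, tmb = 4."""
    recs = [fs.MutationRecord("s1", "chr1", 3, "C", "T"),
            fs.MutationRecord("s1", "chr1", 8, "C", "T"),
            fs.MutationRecord("s1", "chr1", 3, "C", "G"),
            fs.MutationRecord("s1", "chr1", 5, "TT", "T", "DEL")]
    out = build_spectra(recs, _ref(), min_snv=2)
    chan_ct = fs.classify_substitution("C", "T", "A", "G")
    chan_cg = fs.classify_substitution("C", "G", "A", "G")
    row = out.counts.loc["s1"]
    assert row.iloc[chan_ct] == 2
    assert row.iloc[chan_cg] == 1
    assert row.sum() == 3
    meta = out.meta.loc["s1"]
    assert meta["n_snv"] == 3 and meta["tmb"] == 4 and bool(meta["eligible"])


def test_build_spectra_skips_mismatch_and_unknown_contig(caplog):
    recs = [fs.MutationRecord("s1", "chr1", 3, "C", "T"),
            fs.MutationRecord("s1", "chr1", 3, "A", "T"),   # ref mismatch
            fs.MutationRecord("s1", "chrX", 3, "C", "T")]   # unknown contig
    out = build_spectra(recs, _ref(), min_snv=1)
    assert out.counts.loc["s1"].sum() == 1


def test_build_spectra_deduplicates_records():
    recs = [fs.MutationRecord("s1", "chr1", 3, "C", "T")] * 3
    out = build_spectra(recs, _ref(), min_snv=1)
    assert out.counts.loc["s1"].sum() == 1


def test_build_spectra_empty_after_filtering():
    recs = [fs.MutationRecord("s1", "chrZ", 3, "C", "T")]
    with pytest.raises(EmptyInputError):
        build_spectra(recs, _ref())


def test_build_spectra_permutation_invariance():
    rng = np.random.default_rng(1)
    recs = [fs.MutationRecord(f"s{i%3}", "chr1", int(p), "C", "T")
            for i, p in enumerate([3, 8, 3, 8, 3])]
    recs += [fs.MutationRecord("s0", "chr1", 5, "T", "A")]
    a = build_spectra(recs, _ref(), min_snv=1)
    perm = [recs[i] for i in rng.permutation(len(recs))]
    b = build_spectra(perm, _ref(), min_snv=1)
    pd.testing.assert_frame_equal(a.counts.sort_index(), b.counts.sort_index())


def test_build_spectra_strand_symmetry():
    """Reverse-complementing every record and the genome leaves spectra unchanged."""
    seq = "AACGTTACGA"
    comp = str.maketrans("ACGT", "TGCA")
    rc = seq.translate(comp)[::-1]
    L = len(seq)
    recs = [fs.MutationRecord("s1", "chr1", 3, "C", "T"),
            fs.MutationRecord("s1", "chr1", 8, "C", "A"),
            fs.MutationRecord("s1", "chr1", 5, "T", "G")]
    flipped = [fs.MutationRecord(r.sample_id, r.chrom, L - r.pos + 1,
                                 r.ref.translate(comp), r.alt.translate(comp))
               for r in recs]
    a = build_spectra(recs, InMemoryReference({"chr1": seq}), min_snv=1)
    b = build_spectra(flipped, InMemoryReference({"chr1": rc}), min_snv=1)
    pd.testing.assert_frame_equal(a.counts, b.counts)


def test_normalize_spectrum():
    counts = np.zeros(96)
    counts[5] = 10
    freq = fs.normalize_spectrum(counts)
    assert freq[5] == 1.0 and freq.sum() == 1.0

    uniform = fs.normalize_spectrum(np.ones(96))
    assert np.allclose(uniform, 1 / 96)

    rng = np.random.default_rng(2)
    counts = rng.integers(0, 50, 96)
    freq = fs.normalize_spectrum(counts)
    assert abs(freq.sum() - 1) < 1e-12
    assert np.allclose(freq, counts / counts.sum())

    with pytest.raises(UndefinedNormalizationError):
        fs.normalize_spectrum(np.zeros(96))
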