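"""Canonical 96-channel trinucleotide substitution encoding.

Single-base substitutions are collapsed to the pyrimidine strand and indexed in
the canonical catalog order: six substitution blocks C>A, C>G, C>T, T>A, T>C,
T>G, and within each block the 16 flanking contexts sorted lexicographically by
(5' base, 3' base) over A, C, G, T.  Channel 0 is therefore A[C>A]A and channel
95 is T[T>G]T.
"""

from __future__ import annotations

import numpy as np

from .errors import InvalidMutationError

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: the six pyrimidine-reference substitution types, in block order
SUBSTITUTIONS = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]

#: canonical channel labels, "A[C>A]A" ... "T[T>G]T"
CHANNELS: list[str] = [
    f"{five}[{ref}>{alt}]{three}"
    for ref, alt in SUBSTITUTIONS
    for five in BASES
    for three in BASES
]

N_CHANNELS = 96

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_SUB_INDEX = {sub: i for i, sub in enumerate(SUBSTITUTIONS)}

# numeric lookup tables for the vectorized path: byte value -> base code (or -1)
_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _BASE_CODE[ord(_b)] = _i
    _BASE_CODE[ord(_b.lower())] = _i

_COMP_CODE = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G on codes


def classify_substitution(ref: str, alt: str, five_prime: str, three_prime: str) -> int:
    """Return the 0-95 channel index of one single-base substitution.

    Purine-reference mutations (A or G) are reverse-complemented, flanks
    included, before lookup so that both strands map to the same channel.
    """
    for b in (ref, alt, five_prime, three_prime):
        if b not in _BASE_INDEX:
            raise InvalidMutationError(f"non-ACGT base {b!r}")
    if ref == alt:
        raise InvalidMutationError("ref and alt alleles are identical")
    if ref in "AG":
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five_prime, three_prime = COMPLEMENT[three_prime], COMPLEMENT[five_prime]
    sub = _SUB_INDEX[(ref, alt)]
    return sub * 16 + _BASE_INDEX[five_prime] * 4 + _BASE_INDEX[three_prime]


def encode_bases(seq: np.ndarray) -> np.ndarray:
    """Map an array of single-character base strings to codes 0-3 (-1 if not ACGT)."""
    as_bytes = seq.astype("S1").view(np.uint8)
    return _BASE_CODE[as_bytes]


def classify_codes(
    ref: np.ndarray, alt: np.ndarray, five: np.ndarray, three: np.ndarray
) -> np.ndarray:
    """Vectorized channel lookup on base codes (0=A,1=C,2=G,3=T).

    Entries with any code outside 0-3 or with ref == alt yield -1.
    """
    valid = (ref >= 0) & (alt >= 0) & (five >= 0) & (three >= 0) & (ref != alt)
    r = np.where(valid, ref, 1)
    a = np.where(valid, alt, 0)
    f = np.where(valid, five, 0)
    t = np.where(valid, three, 0)
    purine = (r == 0) | (r == 2)  # A or G: flip to pyrimidine strand
    r2 = np.where(purine, _COMP_CODE[r], r)
    a2 = np.where(purine, _COMP_CODE[a], a)
    f2 = np.where(purine, _COMP_CODE[t], f)
    t2 = np.where(purine, _COMP_CODE[f], t)
    # r2 is 1 (C) or 3 (T); substitution block index within {C,T} x remaining alts
    sub = np.where(r2 == 1, 0, 3)
    # alt order for C: A,G,T -> 0,1,2 ; for T: A,C,G -> 0,1,2
    alt_rank = np.where(r2 == 1, np.where(a2 == 0, 0, np.where(a2 == 2, 1, 2)),
                        np.where(a2 == 0, 0, np.where(a2 == 1, 1, 2)))
    channel = (sub + alt_rank) * 16 + f2 * 4 + t2
    return np.where(valid, channel, -1)


def channel_context(channel: int) -> tuple[str, str, str, str]:
    """Return (five_prime, ref, alt, three_prime) for a channel index."""
    sub = channel // 16
    rest = channel % 16
    ref, alt = SUBSTITUTIONS[sub]
    return BASES[rest // 4], ref, alt, BASES[rest % 4]
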