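"""Low-level DNA sequence helpers shared across the package.

Sequences are plain uppercase strings over {A,C,G,T}; hot paths convert to
numpy ``uint8`` code arrays (A=0, C=1, G=2, T=3).
"""

from __future__ import annotations

import numpy as np

ALPHABET = "ACGT"

_COMP = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")

# char -> 2-bit code lookup; unknown characters map to 4 (never matches a k-mer)
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate(ALPHABET):
    _CODE[ord(_c)] = _i
    _CODE[ord(_c.lower())] = _i

_DECODE = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.translate(_COMP)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 array (A=0,C=1,G=2,T=3, other=4)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Inverse of :func:`encode` for arrays containing only codes 0..3."""
    return _DECODE[codes].tobytes().decode()


def random_dna(length: int, rng: np.random.Generator, gc: float = 0.5) -> str:
    """Random DNA with the requested expected GC fraction."""
    if length < 0:
        raise ValueError("length must be non-negative")
    p_gc = gc / 2.0
    p_at = (1.0 - gc) / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at]).astype(np.uint8)
    return decode(codes)


def gc_fraction(seq: str) -> float:
    if not seq:
        return 0.0
    codes = encode(seq)
    return float(np.count_nonzero((codes == 1) | (codes == 2)) / len(codes))


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-mer of a code array into an int64.

    Positions whose window contains a non-ACGT character are returned as -1.
    Result has length ``len(codes) - k + 1`` (empty if shorter than k).
    """
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    c = codes.astype(np.int64)
    for i in range(k):
        w = c[i : i + n]
        out = (out << 2) | (w & 3)
        bad |= w > 3
    out[bad] = -1
    return out
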