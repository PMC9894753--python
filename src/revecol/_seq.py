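"""Low-level sequence utilities: 2-bit-style encoding, mutation planting, k-mer codes.

All genome-scale code in this package works on ``numpy`` ``uint8`` arrays with
A,C,G,T encoded as 0..3 (gap/unknown = 4). Strings are converted at the API
boundary only.
"""
from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)
_LUT = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _LUT[b] = i
    _LUT[ord(chr(b).lower())] = i

GAP = np.uint8(4)


def encode(seq) -> np.ndarray:
    """Encode a DNA string (or bytes) as a uint8 array with A,C,G,T -> 0..3."""
    if isinstance(seq, np.ndarray):
        return seq.astype(np.uint8, copy=False)
    if isinstance(seq, str):
        seq = seq.encode()
    return _LUT[np.frombuffer(seq, dtype=np.uint8)]


def decode(arr: np.ndarray) -> str:
    """Decode a 0..3 (4=N) array back to an upper-case DNA string."""
    return BASES[np.asarray(arr, dtype=np.uint8)].tobytes().decode()


def revcomp(arr: np.ndarray) -> np.ndarray:
    """Reverse complement of an encoded array (N maps to N)."""
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    return comp[arr][::-1]


def random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def plant_substitutions(
    seq: np.ndarray,
    n_subs: int,
    rng: np.random.Generator,
    positions: np.ndarray | None = None,
) -> np.ndarray:
    """Return a copy of ``seq`` with exactly ``n_subs`` substitutions.

    Sites are drawn uniformly without replacement; every chosen site is changed
    to one of the three other bases uniformly, so the raw p-distance between
    input and output is exactly ``n_subs / len(seq)``.
    """
    out = seq.copy()
    if n_subs == 0:
        return out
    if positions is None:
        positions = rng.choice(len(seq), size=n_subs, replace=False)
    # offset 1..3 added mod 4 always yields a different base
    offsets = rng.integers(1, 4, size=len(positions), dtype=np.uint8)
    out[positions] = (out[positions] + offsets) % 4
    return out


def p_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Raw proportion of differing sites over non-gap columns."""
    valid = (a != GAP) & (b != GAP)
    n = int(valid.sum())
    if n == 0:
        return float("nan")
    return float(((a != b) & valid).sum() / n)


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all overlapping k-mers (int64). k-mers containing
    non-ACGT characters get code -1."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    a = arr.astype(np.int64)
    codes = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        col = a[j : j + n]
        codes = codes * 4 + np.where(col > 3, 0, col)
        bad |= col > 3
    codes[bad] = -1
    return codes
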