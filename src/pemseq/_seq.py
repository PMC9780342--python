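"""Small DNA-string helpers shared across modules.

Sequences are plain uppercase ACGT strings throughout; coordinates are
0-based, half-open (BED convention).
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")

BASES = "ACGT"
_BASE_TO_INT = {b: i for i, b in enumerate(BASES)}


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT(N) string."""
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("hamming() requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def encode(seq: str) -> np.ndarray:
    """Encode ACGT string as uint8 array (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.empty(arr.shape, dtype=np.uint8)
    # ASCII: A=65 C=67 G=71 T=84
    out[arr == 65] = 0
    out[arr == 67] = 1
    out[arr == 71] = 2
    out[arr == 84] = 3
    return out


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random ACGT string."""
    return "".join(BASES[i] for i in rng.integers(0, 4, size=length))


def mismatch_profile(window: str, pattern: str) -> np.ndarray:
    """Mismatch count of ``pattern`` against every k-mer start in ``window``.

    Vectorised sliding comparison; returns an int array of length
    ``len(window) - len(pattern) + 1``.
    """
    k = len(pattern)
    if len(window) < k:
        return np.zeros(0, dtype=np.int64)
    w = encode(window)
    p = encode(pattern)
    sw = np.lib.stride_tricks.sliding_window_view(w, k)
    return (sw != p[None, :]).sum(axis=1)
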