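"""Low-level 2-bit sequence encoding and canonical k-mer extraction.

Bases are encoded A=0, C=1, G=2, T=3 so that complementation is ``3 - code``.
A k-mer code is the base-4 integer of its sequence; the canonical form of a
k-mer is the lexicographic minimum of the k-mer and its reverse complement,
which on codes is an elementwise ``min``.
"""

from __future__ import annotations

import numpy as np

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)

BASES = "ACGT"


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to a uint8 array of 2-bit codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    arr = _ENCODE[raw]
    if (arr == 255).any():
        bad = chr(raw[int(np.argmax(arr == 255))])
        raise ValueError(f"non-ACGT character in sequence: {bad!r}")
    return arr


def decode(arr: np.ndarray) -> str:
    """Decode a 2-bit code array back to a DNA string."""
    return _DECODE[arr].tobytes().decode("ascii")


def revcomp(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]


def kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Forward-strand k-mer codes of every window, as int64, 5'→3' order."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > arr.size:
        raise ValueError(f"k={k} exceeds sequence length {arr.size}")
    if k > 31:
        raise ValueError("k must be <= 31 to fit an int64 code")
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows.astype(np.int64) @ powers


def canonical_kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Canonical (strand-folded) k-mer codes of every window of ``arr``."""
    fwd = kmer_codes(arr, k)
    rc = kmer_codes(revcomp(arr), k)[::-1]
    return np.minimum(fwd, rc)


def distinct_canonical_kmers(seq: str, k: int) -> np.ndarray:
    """Sorted distinct canonical k-mer codes of a DNA string."""
    return np.unique(canonical_kmer_codes(encode(seq), k))


def random_dna(rng: np.random.Generator, length: int) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability ``rate``; new base always differs."""
    if rate < 0 or rate > 1:
        raise ValueError("mutation rate must be in [0, 1]")
    out = arr.copy()
    if rate == 0:
        return out
    hit = rng.random(arr.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        shift = rng.integers(1, 4, size=n_hit, dtype=np.uint8)
        out[hit] = (out[hit] + shift) % 4
    return out
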