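"""Shared 2-bit nucleotide codec used by the simulator, mapper and marker classifier.

Bases are encoded A=0, C=1, G=2, T=3; anything else maps to 255 so that
non-ACGT symbols can be detected with a single comparison.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string to uint8 codes (255 marks non-ACGT)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def kmer_ints(codes: np.ndarray, k: int) -> np.ndarray:
    """All overlapping k-mers of a code array as base-4 integers (uint64).

    Requires codes to be pure ACGT; caller screens non-ACGT first.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.uint64)
    windows = np.lib.stride_tricks.sliding_window_view(codes.astype(np.uint64), k)
    return windows @ powers


def canonical_kmer_ints(codes: np.ndarray, k: int) -> np.ndarray:
    """Canonical (strand-independent) k-mer integers: min of k-mer and its
    reverse complement, computed positionally so forward/reverse windows pair up."""
    fwd = kmer_ints(codes, k)
    rev = kmer_ints(revcomp_codes(codes), k)[::-1]
    return np.minimum(fwd, rev)
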