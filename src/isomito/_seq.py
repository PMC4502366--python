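"""Low-level nucleotide helpers shared across the package.

Sequences are plain upper-case ACGT strings throughout; numpy uint8 code
arrays (A=0, C=1, G=2, T=3) are used on hot paths (mapping, k-mer counting).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
DELETION = "-"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# byte value -> 2-bit code; 255 marks non-ACGT
_CODE_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _CODE_LUT[ord(_b)] = _i
    _CODE_LUT[ord(_b.lower())] = _i

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode to uint8 codes; raises ValueError on non-ACGT characters."""
    codes = _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if codes.size and codes.max() > 3:
        bad = int(np.argmax(codes > 3))
        raise ValueError(f"non-ACGT character {seq[bad]!r} at position {bad}")
    return codes


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def rc_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]


def random_seq(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))


def kmer_ints(codes: np.ndarray, k: int) -> np.ndarray:
    """All k-mer 2-bit packings of a 1-D code array (int64; requires k <= 31)."""
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit packing in int64")
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    out = np.zeros(n, dtype=np.int64)
    c = codes.astype(np.int64)
    for j in range(k):
        out = (out << 2) | c[j : j + n]
    return out


def kmer_ints_2d(codes: np.ndarray, k: int) -> np.ndarray:
    """Row-wise k-mer packings for a (n_reads, read_len) code matrix."""
    if k > 31:
        raise ValueError("k must be <= 31 for 2-bit packing in int64")
    n = codes.shape[1] - k + 1
    if n <= 0:
        return np.empty((codes.shape[0], 0), dtype=np.int64)
    out = np.zeros((codes.shape[0], n), dtype=np.int64)
    c = codes.astype(np.int64)
    for j in range(k):
        out = (out << 2) | c[:, j : j + n]
    return out


def rc_kmer_ints(vals: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of packed k-mers, vectorised."""
    out = np.zeros_like(vals)
    v = vals.copy()
    for _ in range(k):
        out = (out << 2) | (3 - (v & 3))
        v >>= 2
    return out


def int_to_kmer(val: int, k: int) -> str:
    chars = []
    for _ in range(k):
        chars.append(BASES[val & 3])
        val >>= 2
    return "".join(reversed(chars))
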