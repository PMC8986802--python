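"""Low-level sequence utilities shared across modules.

DNA is handled either as Python strings (uppercase ACGTN) or as numpy
uint8 code arrays (A=0, C=1, G=2, T=3, N=4).  Bisulfite "reduction"
collapses the alphabet: C->T on the top strand, G->A on the bottom.
"""

from __future__ import annotations

import numpy as np

BASES = "ACGTN"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

_COMP = str.maketrans("ACGTN", "TGCAN")

# complement in code space: A<->T, C<->G, N->N
_COMP_CODE = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
# C->T reduction in code space
_CT_CODE = np.array([0, 3, 2, 3, 4], dtype=np.uint8)
# G->A reduction in code space
_GA_CODE = np.array([0, 1, 0, 3, 4], dtype=np.uint8)

A, C, G, T, N = 0, 1, 2, 3, 4


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string into a uint8 code array."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_BASE_BYTES = np.frombuffer(b"ACGTN", dtype=np.uint8)


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back to a DNA string."""
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP_CODE[codes[..., ::-1]]


def reduce_ct(codes: np.ndarray) -> np.ndarray:
    """Collapse C onto T (top-strand bisulfite space)."""
    return _CT_CODE[codes]


def reduce_ga(codes: np.ndarray) -> np.ndarray:
    """Collapse G onto A (bottom-strand bisulfite space)."""
    return _GA_CODE[codes]


def ct_convert(seq: str) -> str:
    """Fully bisulfite-convert a string (every C -> T)."""
    return seq.replace("C", "T")


def ga_convert(seq: str) -> str:
    """Complement-strand full conversion (every G -> A)."""
    return seq.replace("G", "A")


def find_cpg_positions(seq: str) -> list[int]:
    """0-based offsets i where seq[i:i+2] == 'CG' (brute scan)."""
    out = []
    start = 0
    while True:
        i = seq.find("CG", start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def kmer_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-5 integer of every k-mer window of a 1-D code array.

    Windows containing N (code 4) still produce a value; callers mask
    them via :func:`kmer_valid`.  Base 5 keeps N-containing k-mers from
    colliding with clean ones.
    """
    n = codes.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    pow5 = (5 ** np.arange(k - 1, -1, -1, dtype=np.uint64))
    out = np.zeros(n, dtype=np.uint64)
    c64 = codes.astype(np.uint64)
    for j in range(k):
        out += c64[j:j + n] * pow5[j]
    return out


def kmer_valid(codes: np.ndarray, k: int) -> np.ndarray:
    """Boolean mask of k-mer windows free of N."""
    isn = (codes == N).astype(np.int32)
    cs = np.concatenate([[0], np.cumsum(isn)])
    n = codes.size - k + 1
    return (cs[k:k + n] - cs[:n]) == 0
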