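"""Integer encoding of DNA sequences used throughout the package.

Bases are encoded alphabetically (A=0, C=1, G=2, T=3) so that the
Watson-Crick complement is simply ``3 - code`` and a codon maps to the
index ``16*b1 + 4*b2 + b3`` in [0, 64).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
A, C, G, T = 0, 1, 2, 3

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_DECODE = np.frombuffer(BASES.encode(), dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to an int8 array; ambiguity codes become -1."""
    raw = np.frombuffer(seq.encode(), dtype=np.uint8)
    return _ENCODE[raw]


def decode(codes: np.ndarray) -> str:
    if np.any(codes < 0):
        raise ValueError("cannot decode ambiguous (-1) codes")
    return _DECODE[np.asarray(codes, dtype=np.intp)].tobytes().decode()


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    """Reverse complement in code space (complement of b is 3-b)."""
    return (3 - codes[::-1]).astype(codes.dtype)


def revcomp(seq: str) -> str:
    return decode(revcomp_codes(encode(seq)))


def codon_index(codes: np.ndarray) -> np.ndarray:
    """Map an (n, 3) array of base codes to codon indices in [0, 64)."""
    codes = np.asarray(codes)
    return 16 * codes[..., 0] + 4 * codes[..., 1] + codes[..., 2]


def codon_str(index: int) -> str:
    return BASES[index // 16] + BASES[(index // 4) % 4] + BASES[index % 4]


ALL_CODONS = [codon_str(i) for i in range(64)]
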