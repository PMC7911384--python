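"""Byte-level DNA encoding shared by the mapper, simulator and consensus caller.

Bases are encoded A=0, C=1, G=2, T=3, N=4 in uint8 arrays; code 4 never
matches anything, including itself.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

# complement: A<->T, C<->G, N->N
_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)

COMPLEMENT_STR = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str | bytes) -> np.ndarray:
    """Encode a DNA string into a uint8 code array."""
    if isinstance(seq, str):
        seq = seq.encode("ascii")
    return _CODE[np.frombuffer(seq, dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    """Decode a uint8 code array back into an uppercase DNA string."""
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return _COMP[codes[::-1]]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (case-preserving, N-safe)."""
    return seq.translate(COMPLEMENT_STR)[::-1]
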