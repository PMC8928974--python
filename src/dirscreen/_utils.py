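"""Small sequence helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: complement lookup for ASCII-coded uint8 arrays
_COMP_U8 = np.arange(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANtgcan"):
    _COMP_U8[_a] = _b

BASES = "ACGT"
BASE_U8 = np.frombuffer(b"ACGT", dtype=np.uint8)

#: ASCII byte -> base index 0..3, 255 for anything else
BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate(b"ACGT"):
    BASE_INDEX[_c] = _i
for _i, _c in enumerate(b"acgt"):
    BASE_INDEX[_c] = _i


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMP_TABLE)[::-1]


def seq_to_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def u8_to_seq(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def revcomp_u8(arr: np.ndarray) -> np.ndarray:
    """Reverse complement along the last axis of an ASCII uint8 array."""
    return _COMP_U8[arr][..., ::-1]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def check_dna(seq: str, what: str = "sequence") -> str:
    s = seq.upper()
    if not s or any(c not in "ACGT" for c in s):
        raise ValueError(f"{what} must be a non-empty A/C/G/T string, got {seq!r}")
    return s
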