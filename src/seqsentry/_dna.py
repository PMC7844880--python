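"""Low-level DNA encoding helpers shared across modules.

Bases are packed 2 bits each (A=0, C=1, G=2, T=3); anything else maps to
code 4 and poisons any k-mer key that contains it.
"""

from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i  # lowercase

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "a": "t", "c": "g", "g": "c", "t": "a", "n": "n"}

_COMP_TABLE = bytes.maketrans(b"ACGTNacgtn", b"TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """2-bit codes for a sequence; ambiguous bases become code 4."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def decode(codes: np.ndarray) -> str:
    return "".join("ACGTN"[c] for c in codes)
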