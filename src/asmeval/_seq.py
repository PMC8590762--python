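"""Nucleotide encoding helpers shared across modules.

Sequences are held as Python strings at module boundaries and as uint8
code arrays (A=0, C=1, G=2, T=3, anything else=4) inside numeric kernels.
"""
from __future__ import annotations

import numpy as np

_CODE = np.full(256, 4, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[b + 32] = i  # lowercase

_DECODE = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
         "a": "t", "c": "g", "g": "c", "t": "a", "n": "n"}
_COMP_TABLE = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string into uint8 codes."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _CODE[raw]


def decode(codes: np.ndarray) -> str:
    return _DECODE[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def random_sequence(length: int, rng: np.random.Generator) -> str:
    return decode(rng.integers(0, 4, size=length, dtype=np.uint8))
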