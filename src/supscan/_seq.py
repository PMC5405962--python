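"""Fast DNA <-> integer-code conversion shared by the simulator, aligner
and pileup builder. Codes: A=0, C=1, G=2, T=3 (complement = 3 - code)."""

from __future__ import annotations

import numpy as np

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


def encode(seq: str) -> np.ndarray:
    """DNA string -> uint8 code array. Non-ACGT symbols map to 255."""
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode("ascii")


def revcomp_codes(codes: np.ndarray) -> np.ndarray:
    return (3 - codes)[::-1]
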