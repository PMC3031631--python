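"""Small shared helpers: alphabet handling, reverse complement, encodings."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# uppercase ACGTN pass through, everything else becomes N
_CLEAN = bytes(
    (c if chr(c).upper() in "ACGTN" else ord("N")) for c in range(256)
).upper()

# byte -> small integer code; A,C,G,T = 0..3, anything else = 4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _b, _i in BASE_INDEX.items():
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}."""
    return seq.translate(_COMPLEMENT)[::-1]


def clean_sequence(seq: str) -> str:
    """Uppercase and map any non-ACGTN character to N."""
    return seq.encode("ascii", errors="replace").translate(_CLEAN).decode("ascii")


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes (A=0 C=1 G=2 T=3, other=4)."""
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_DECODE = np.array(list("ACGTN"), dtype="U1")


def decode(codes: np.ndarray) -> str:
    return "".join(_DECODE[codes])
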