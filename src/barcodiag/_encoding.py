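"""Integer encoding of IUPAC nucleotide strings shared across modules.

Codes 0-3 are the unambiguous bases; everything else (gaps, N, partial
ambiguity codes) maps to 4 and is treated as missing wherever a definite
base is required.
"""

from __future__ import annotations

import numpy as np

A, C, G, T, OTHER = 0, 1, 2, 3, 4

IUPAC_CHARS = frozenset("ACGTRYSWKMBDHVN-")
UNAMBIGUOUS = frozenset("ACGT")

_LUT = np.full(256, OTHER, dtype=np.uint8)
for _ch, _code in (("A", A), ("C", C), ("G", G), ("T", T)):
    _LUT[ord(_ch)] = _code
    _LUT[ord(_ch.lower())] = _code


def encode(seq: str) -> np.ndarray:
    """Encode a nucleotide string as a uint8 array (A=0 C=1 G=2 T=3, other=4)."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _LUT[raw]


def encode_many(seqs) -> np.ndarray:
    """Stack equal-length sequences into an (n, L) uint8 matrix."""
    return np.vstack([encode(s) for s in seqs])
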