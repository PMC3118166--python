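"""Symbol encoding shared across the package.

The reference text is stored as a ``uint8`` array.  Code 0 is the terminal
sentinel (lexicographically smallest), code 1 an inter-segment separator,
and codes 2..5 the bases A, C, G, T.  Sentinel and separator sort below
every base, and read patterns only ever contain base codes, so no pattern
can match across a segment boundary.
"""

from __future__ import annotations

import numpy as np

SENTINEL = 0
SEPARATOR = 1
CODE_A, CODE_C, CODE_G, CODE_T = 2, 3, 4, 5
NSYMBOLS = 6  # sentinel, separator, A, C, G, T

#: code used for read symbols outside {A,C,G,T}; never matches the index
UNKNOWN = 255

_BASES = "ACGT"

_ENC = np.full(256, UNKNOWN, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENC[ord(_b)] = CODE_A + _i
    _ENC[ord(_b.lower())] = CODE_A + _i

_DEC = {SENTINEL: "$", SEPARATOR: "#", CODE_A: "A", CODE_C: "C", CODE_G: "G", CODE_T: "T"}

_COMPLEMENT = str.maketrans("ACGTacgtNn", "TGCAtgcaNn")


def encode_seq(seq: str) -> np.ndarray:
    """Encode a nucleotide string; non-ACGT symbols become :data:`UNKNOWN`."""
    raw = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    return _ENC[raw]


def decode_codes(codes: np.ndarray) -> str:
    return "".join(_DEC.get(int(c), "N") for c in codes)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def is_base(code: int) -> bool:
    return CODE_A <= code <= CODE_T
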