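"""RNA alphabet codecs shared by all modules.

Sequences are RNA over ``ACGU``; alignments additionally use ``-`` as the gap
symbol (state index 4). ``T`` is accepted on input and mapped to ``U``; ``.``
is read as a gap. Integer encodings are ``A=0, C=1, G=2, U=3, -=4``.
"""

from __future__ import annotations

import numpy as np

from .errors import InputError

RNA = "ACGU"
GAP = "-"
STATES = RNA + GAP  # training alphabet, q = 5
Q_RNA = 4
Q_GAPPED = 5

_CODE = {c: i for i, c in enumerate(STATES)}
_CODE["T"] = _CODE["U"]
_CODE["."] = _CODE[GAP]

#: canonical Watson-Crick / wobble pairs as ordered nucleotide-index tuples
CANONICAL_PAIRS = tuple(
    (_CODE[a], _CODE[b]) for a, b in ("GC", "CG", "GU", "UG", "AU", "UA")
)


def normalize(seq: str) -> str:
    """Uppercase, map T->U and '.'->'-'. Raises on foreign symbols."""
    s = seq.upper().replace("T", "U").replace(".", GAP)
    bad = set(s) - set(STATES)
    if bad:
        raise InputError(f"invalid symbols {sorted(bad)} in sequence")
    return s


def encode(seq: str, allow_gap: bool = False) -> np.ndarray:
    """Encode a sequence string to an int8 array."""
    s = normalize(seq)
    if not allow_gap and GAP in s:
        raise InputError("gap symbol not allowed here")
    return np.array([_CODE[c] for c in s], dtype=np.int8)


def decode(codes: np.ndarray) -> str:
    """Decode an integer array back to a string."""
    return "".join(STATES[int(c)] for c in codes)


def encode_rows(rows, allow_gap: bool = True) -> np.ndarray:
    """Encode equal-length strings into an (n, L) int8 matrix."""
    if not rows:
        raise InputError("empty sequence collection")
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise InputError("sequences have unequal lengths")
    return np.stack([encode(r, allow_gap=allow_gap) for r in rows])
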