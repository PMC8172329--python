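"""Amino-acid composition (AAC) and dipeptide composition (DPC).

AAC is the 20-vector of residue frequencies normalized by sequence length,
indexed alphabetically A..Y.  DPC is the 400-vector of overlapping
dipeptide frequencies normalized by the N-1 windows, indexed first-letter
major: AA, AC, AD, ..., YY.  Both are probability vectors.
"""

from __future__ import annotations

import numpy as np

from .aaindex import STANDARD_AMINO_ACIDS

AAC_ORDER: tuple[str, ...] = STANDARD_AMINO_ACIDS
DPC_ORDER: tuple[str, ...] = tuple(
    a + b for a in STANDARD_AMINO_ACIDS for b in STANDARD_AMINO_ACIDS
)

_AA_TO_COL = {aa: i for i, aa in enumerate(STANDARD_AMINO_ACIDS)}


def _encode(sequence: str) -> np.ndarray:
    try:
        return np.array([_AA_TO_COL[aa] for aa in sequence])
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in sequence") from None


def aac(sequence: str) -> np.ndarray:
    """Amino-acid composition: count of each residue divided by length N."""
    if len(sequence) == 0:
        raise ValueError("AAC requires a nonempty sequence")
    cols = _encode(sequence)
    return np.bincount(cols, minlength=20) / len(sequence)


def dpc(sequence: str) -> np.ndarray:
    """Dipeptide composition: overlapping pair counts divided by N - 1."""
    if len(sequence) < 2:
        raise ValueError("DPC requires a sequence of length >= 2")
    cols = _encode(sequence)
    flat = cols[:-1] * 20 + cols[1:]
    return np.bincount(flat, minlength=400) / (len(sequence) - 1)
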