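"""Amino-acid alphabet and substitution-matrix helpers.

The 20 canonical residues are indexed 0..19 in the fixed order below; the
ambiguity code ``X`` is index 20.  All numeric kernels (profile scoring,
local alignment) work on these integer encodings.
"""

from __future__ import annotations

import numpy as np
from Bio.Align import substitution_matrices

#: canonical residue order used everywhere in this package
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
#: ambiguity code, always the last index
X_INDEX = 20
ALPHABET = AA_ORDER + "X"

_AA_TO_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

VALID_RESIDUES = frozenset(ALPHABET)


def encode(sequence: str) -> np.ndarray:
    """Encode an uppercase amino-acid string as int8 indices."""
    try:
        return np.fromiter(
            (_AA_TO_INDEX[c] for c in sequence), dtype=np.int8, count=len(sequence)
        )
    except KeyError as exc:  # pragma: no cover - message formatting only
        raise ValueError(f"invalid amino-acid character {exc}") from None


def decode(indices) -> str:
    return "".join(ALPHABET[i] for i in indices)


def _build_blosum62() -> np.ndarray:
    """BLOSUM62 as a dense (21, 21) float array in AA_ORDER + X order."""
    mat = substitution_matrices.load("BLOSUM62")
    out = np.zeros((21, 21), dtype=np.float64)
    for i, a in enumerate(ALPHABET):
        for j, b in enumerate(ALPHABET):
            out[i, j] = mat[a, b]
    return out


#: BLOSUM62 scores on the package alphabet (X row/column included)
BLOSUM62 = _build_blosum62()

#: uniform residue background over the 20 canonical residues
BACKGROUND = np.full(20, 0.05)

def _conditional() -> np.ndarray:
    """P(b | a) implied by BLOSUM62 half-bit scores: p_ab ~ q_a q_b 2^(s/2)."""
    joint = BACKGROUND[None, :] * np.exp2(BLOSUM62[:20, :20] / 2.0)
    return joint / joint.sum(axis=1, keepdims=True)

#: substitution probabilities P(replacement | original) implied by BLOSUM62
BLOSUM62_CONDITIONAL = _conditional()
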