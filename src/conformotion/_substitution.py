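"""BLOSUM62 scoring helpers shared by the alignment and consensus code.

The substitution matrix itself comes from biotite; this module only adds
the gap-score convention used throughout the pipeline: a position where
either symbol is a gap (or the unknown symbol 'X') scores
``min over all BLOSUM62 pairs − 1 = −5``.
"""

from __future__ import annotations

import numpy as np
from biotite.sequence.align import SubstitutionMatrix

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
UNKNOWN = "X"

_MATRIX = SubstitutionMatrix.std_protein_matrix()
_ALPHABET = _MATRIX.get_alphabet1()

# min over the 20x20 amino-acid block, not the extended B/Z/X/* rows
_AA_IDX = [_ALPHABET.encode(a) for a in AMINO_ACIDS]
_AA_BLOCK = np.asarray(_MATRIX.score_matrix())[np.ix_(_AA_IDX, _AA_IDX)]

#: Score assigned when either symbol of a pair is a gap or 'X'.
GAP_SCORE: int = int(_AA_BLOCK.min()) - 1


def is_gap_like(symbol: str) -> bool:
    """True for gap characters and the unknown-residue symbol (any case)."""
    return symbol == GAP or symbol.upper() == UNKNOWN


def blosum62(a: str, b: str) -> int:
    """BLOSUM62 score of two one-letter codes; gap/'X' pairs score ``GAP_SCORE``.

    Lowercase letters (unresolved residues) are scored as their amino acid.
    """
    if is_gap_like(a) or is_gap_like(b):
        return GAP_SCORE
    return int(_MATRIX.get_score(a.upper(), b.upper()))


def self_score(a: str) -> int:
    """Diagonal BLOSUM62 score, used for consensus tie-breaking."""
    return int(_MATRIX.get_score(a.upper(), a.upper()))


def substitution_matrix() -> SubstitutionMatrix:
    return _MATRIX
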