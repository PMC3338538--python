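"""Error-correcting output codes for the three-class problem.

Each class carries a codeword of length three, one entry per binary
comparison (F-B, F-A, B-A; first-named class coded positive).  SVM votes are
compared to the prediction codewords by Hamming distance (any mismatch
counts, including a +/-1 vote against a 0 entry); GP probabilities are
compared to the probability codewords by the sum of absolute differences,
the probability in each column being that of the first-named class.  The
class at the smallest distance wins; exact ties are broken uniformly at
random and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import CATEGORIES, PAIR_LABELS

_PREDICTION_ROWS = {
    "faces": (1, 1, 0),
    "buildings": (-1, 0, 1),
    "animals": (0, -1, -1),
}
_PROBABILITY_ROWS = {
    "faces": (1.0, 1.0, 0.5),
    "buildings": (0.0, 0.5, 1.0),
    "animals": (0.5, 0.0, 0.0),
}


@dataclass(frozen=True)
class CodewordTable:
    scheme: str
    classes: tuple
    comparisons: tuple
    matrix: np.ndarray  # 3 class rows x 3 comparison columns

    def row(self, cls: str) -> np.ndarray:
        return self.matrix[self.classes.index(cls)]


def codeword_table(scheme: str) -> CodewordTable:
    """The codeword table for the named scheme ('prediction' or 'probability')."""
    if scheme == "prediction":
        rows = _PREDICTION_ROWS
    elif scheme == "probability":
        rows = _PROBABILITY_ROWS
    else:
        raise ValueError(f"unknown codeword scheme {scheme!r}")
    matrix = np.array([rows[c] for c in CATEGORIES], dtype=float)
    return CodewordTable(
        scheme=scheme, classes=CATEGORIES, comparisons=PAIR_LABELS, matrix=matrix
    )


def assign_class(votes, table: CodewordTable, rng=None):
    """Assign the class whose codeword is nearest to the vote vector.

    ``votes`` holds the three +1/-1 votes (prediction scheme) or the three
    probabilities of the first-named class (probability scheme), in
    comparison order F-B, F-A, B-A.  Returns (class, distances, tie_flag).
    """
    votes = np.asarray(votes, dtype=float)
    if votes.shape != (3,):
        raise ValueError("votes must have length 3")
    if table.scheme == "prediction":
        distances = np.sum(votes[None, :] != table.matrix, axis=1).astype(float)
    else:
        if np.any(votes < 0) or np.any(votes > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        distances = np.sum(np.abs(votes[None, :] - table.matrix), axis=1)
    best = np.flatnonzero(np.isclose(distances, distances.min()))
    tie = len(best) > 1
    if tie:
        rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
        winner = int(rng.choice(best))
    else:
        winner = int(best[0])
    return table.classes[winner], dict(zip(table.classes, distances)), tie
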