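"""All-against-all cosine distances between interaction signatures.

Each compound gets a ranked similarity list over every other compound,
sorted by ascending cosine distance (ties broken lexicographically by
compound id so results are stable under input permutation). A signature
that is all zeros — e.g. an unscoreable compound — sits at distance 1.0
from everything, keeping it at the bottom of every list rather than
undefined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .model import SignatureMatrix


@dataclass(frozen=True)
class SimilarityEntry:
    compound_id: str
    distance: float
    rank: int


@dataclass
class SimilarityList:
    query_id: str
    entries: list[SimilarityEntry]

    def rank_of(self, compound_id: str) -> int:
        for e in self.entries:
            if e.compound_id == compound_id:
                return e.rank
        raise KeyError(f"compound {compound_id!r} not in similarity list of {self.query_id!r}")


def cosine_distance(x: Sequence[float], y: Sequence[float]) -> float:
    """1 − cos(x, y), defined as 1.0 when either vector is all-zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"vector length mismatch: {x.shape} vs {y.shape}")
    nx = float(np.linalg.norm(x))
    ny = float(np.linalg.norm(y))
    if nx == 0.0 or ny == 0.0:
        return 1.0
    return max(0.0, 1.0 - float(np.dot(x, y)) / (nx * ny))


def distance_matrix(matrix: SignatureMatrix) -> np.ndarray:
    """Pairwise cosine distance matrix with the all-zero-row convention."""
    X = matrix.values
    norms = np.linalg.norm(X, axis=1)
    zero = norms == 0.0
    N = np.divide(X, np.where(zero, 1.0, norms)[:, None])
    N[zero] = 0.0
    D = np.maximum(1.0 - N @ N.T, 0.0)
    D[zero, :] = 1.0
    D[:, zero] = 1.0
    return D


def rank_all(matrix: SignatureMatrix) -> list[SimilarityList]:
    """One ranked similarity list per compound, query excluded from its list."""
    ids = matrix.compound_ids
    D = distance_matrix(matrix)
    lists = []
    for i, query in enumerate(ids):
        order = sorted((j for j in range(len(ids)) if j != i),
                       key=lambda j: (D[i, j], ids[j]))
        entries = [SimilarityEntry(ids[j], float(D[i, j]), r + 1)
                   for r, j in enumerate(order)]
        lists.append(SimilarityList(query, entries))
    return lists


def within_cutoff(slist: SimilarityList, compound_id: str, cutoff: int) -> tuple[bool, int]:
    """Whether ``compound_id`` ranks within ``cutoff`` in the list; returns its rank."""
    if cutoff < 1:
        raise ValidationError(f"cutoff must be >= 1, got {cutoff}")
    rank = slist.rank_of(compound_id)
    return rank <= cutoff, rank
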