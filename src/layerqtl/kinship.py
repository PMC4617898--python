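"""Pedigree additive (numerator) relationship matrix.

Built with the recursive tabular method: processing individuals in an
order where parents precede offspring,

* ``a_ii = 1 + F_i`` with the inbreeding coefficient
  ``F_i = a_{sire(i),dam(i)} / 2`` (0 if either parent is unknown), and
* ``a_ij = (a_{j,sire(i)} + a_{j,dam(i)}) / 2`` for earlier ``j``,
  with an unknown parent contributing 0.

The resulting matrix is the covariance structure (up to the genetic
variance) of breeding values under the additive infinitesimal model and
is what the mixed-model scan uses as its polygenic covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Pedigree

__all__ = ["RelationshipMatrix", "build_A"]


@dataclass
class RelationshipMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")

    def subset(self, ids: list[str]) -> "RelationshipMatrix":
        index = {s: i for i, s in enumerate(self.ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise KeyError(f"ids not in relationship matrix: {missing[:5]}")
        idx = np.array([index[s] for s in ids])
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def inbreeding(self) -> np.ndarray:
        """Per-individual inbreeding coefficients F = a_ii − 1."""
        return np.diag(self.values) - 1.0


def build_A(pedigree: Pedigree, ids: list[str] | None = None) -> RelationshipMatrix:
    """Additive relationship matrix for ``ids`` (default: all individuals).

    When ``ids`` is given, the recursion runs on those individuals plus
    all their pedigree ancestors and the result is sub-selected, so a
    matrix over genotyped sires still reflects any recorded ancestry.
    """
    order = (pedigree.topological_order() if ids is None
             else pedigree.ancestors_of([str(i) for i in ids]))
    index = {ind: i for i, ind in enumerate(order)}
    parents = pedigree.parents()
    n = len(order)
    A = np.zeros((n, n))
    for i, ind in enumerate(order):
        s, d = parents[ind]
        si = index.get(s, -1)
        di = index.get(d, -1)
        if si >= 0 and di >= 0:
            A[i, i] = 1.0 + 0.5 * A[si, di]
        else:
            A[i, i] = 1.0
        row = np.zeros(i)
        if si >= 0:
            row += A[si, :i]
        if di >= 0:
            row += A[di, :i]
        row *= 0.5
        A[i, :i] = row
        A[:i, i] = row
    result = RelationshipMatrix(order, A)
    if ids is not None:
        result = result.subset([str(i) for i in ids])
    return result
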