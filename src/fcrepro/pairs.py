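"""Canonical vectorisation of unordered ROI pairs.

Every edgewise quantity in this package (Fisher-z connectivity, t-vectors,
p-vectors) lives on the P = R(R-1)/2 upper-triangle pairs of an R-region
parcellation, ordered lexicographically by (i, j) with 0 <= i < j < R.
PairIndex is the single source of truth for that order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def pair_count(n_regions: int) -> int:
    """Number of unordered region pairs, R(R-1)/2.

    For the 116-region AAL parcellation this is 6670.
    """
    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    return n_regions * (n_regions - 1) // 2


@dataclass(frozen=True)
class PairIndex:
    """Bijection k <-> (i, j), 0 <= i < j < R, lexicographic in (i, j)."""

    n_regions: int

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least 2 regions")

    @property
    def n_pairs(self) -> int:
        return pair_count(self.n_regions)

    def rows_cols(self) -> tuple[np.ndarray, np.ndarray]:
        """(i, j) arrays of length P in canonical order."""
        return np.triu_indices(self.n_regions, k=1)

    def to_pair(self, k: int) -> tuple[int, int]:
        i, j = self.rows_cols()
        if not 0 <= k < self.n_pairs:
            raise IndexError(f"pair index {k} out of range [0, {self.n_pairs})")
        return int(i[k]), int(j[k])

    def to_flat(self, i: int, j: int) -> int:
        if not 0 <= i < j < self.n_regions:
            raise IndexError(f"invalid pair ({i}, {j}) for R={self.n_regions}")
        # offset of row i plus position of j within the row
        return i * (2 * self.n_regions - i - 1) // 2 + (j - i - 1)

    def condense(self, matrix: np.ndarray) -> np.ndarray:
        """Extract the canonical upper-triangle vector from a symmetric matrix."""
        i, j = self.rows_cols()
        return np.asarray(matrix)[i, j]

    def to_matrix(self, vector: np.ndarray, diagonal: float = 0.0) -> np.ndarray:
        """Inverse of :meth:`condense`; fills a symmetric matrix."""
        vector = np.asarray(vector, dtype=float)
        if vector.shape != (self.n_pairs,):
            raise ValueError(f"expected length-{self.n_pairs} vector")
        out = np.full((self.n_regions, self.n_regions), diagonal, dtype=float)
        i, j = self.rows_cols()
        out[i, j] = vector
        out[j, i] = vector
        return out
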