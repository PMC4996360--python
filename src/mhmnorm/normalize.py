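"""Inter-array normalization of time-series expression matrices.

Two methods are implemented on :class:`~mhmnorm.matrix.ExpressionMatrix`:

``quantile_normalize``
    Classical quantile normalization (QN): every array (column) is forced to
    share an identical value distribution by replacing the rank-``r`` value in
    each column with the mean of the rank-``r`` values across columns.  Ranks
    within a column are preserved, but all between-array level differences are
    erased — after QN every column contains exactly the same multiset of
    numbers.

``mhmn``
    Modified histogram matching normalization.  Instead of averaging across
    arrays, the pooled distribution of *all* ``M * N`` values is partitioned
    into ``M`` consecutive bins of ``N`` values each, and the rank-``i`` values
    across columns are linearly rescaled into the range of bin ``i``.  Every
    column then follows the global histogram, yet the contrast between arrays
    within each rank is preserved — the property that matters when the
    downstream analysis (e.g. fitting a continuous-time ODE network model)
    needs more than rank information.

Both methods use stable sorts throughout, so tied values return to their
exact original positions when the columns are un-sorted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .matrix import ExpressionMatrix

__all__ = [
    "BinPartition",
    "RankSortedMatrix",
    "pool_and_bin",
    "column_sort",
    "scale_row",
    "mhmn",
    "quantile_normalize",
]


@dataclass(frozen=True)
class BinPartition:
    """The ``M`` consecutive bins of the pooled sorted data.

    ``bins[i]`` holds the ``i``-th block of ``N`` sorted values; concatenating
    the rows reproduces the non-decreasing sort of the whole input matrix.
    """

    bins: np.ndarray  # (M, N), each row sorted, rows consecutive

    @property
    def mins(self) -> np.ndarray:
        return self.bins[:, 0]

    @property
    def maxs(self) -> np.ndarray:
        return self.bins[:, -1]

    @property
    def endpoints(self) -> list[tuple[float, float]]:
        return [(float(lo), float(hi)) for lo, hi in zip(self.mins, self.maxs)]


@dataclass(frozen=True)
class RankSortedMatrix:
    """Column-wise sorted matrix plus the permutations that undo the sort.

    ``order[r, j]`` is the original row index of the rank-``r`` value in
    column ``j`` (a stable argsort), so ``sorted_values[r, j] ==
    source[order[r, j], j]``.
    """

    sorted_values: np.ndarray  # (M, N), each column non-decreasing
    order: np.ndarray  # (M, N) int, rank position -> original row index

    def restore(self, values: np.ndarray | None = None) -> np.ndarray:
        """Map rank-ordered ``values`` (default: ``sorted_values``) back to the
        original row order of the source matrix, column by column."""
        if values is None:
            values = self.sorted_values
        values = np.asarray(values, dtype=np.float64)
        if values.shape != self.sorted_values.shape:
            raise ValidationError(
                f"values have shape {values.shape}, expected {self.sorted_values.shape}"
            )
        out = np.empty_like(values)
        np.put_along_axis(out, self.order, values, axis=0)
        return out


def pool_and_bin(x: ExpressionMatrix) -> BinPartition:
    """Sort all ``M * N`` values and split them into ``M`` bins of ``N``.

    The pooled sort is over the whole matrix regardless of position, so the
    bins describe the global histogram of the data; bin ``i`` supplies the
    target value range for the rank-``i`` row in :func:`mhmn`.
    """
    pooled = np.sort(x.values, axis=None, kind="stable")
    return BinPartition(pooled.reshape(x.n_genes, x.n_timepoints))


def column_sort(x: ExpressionMatrix) -> RankSortedMatrix:
    """Stable ascending sort of each column, keeping the inverse permutation."""
    order = np.argsort(x.values, axis=0, kind="stable")
    sorted_values = np.take_along_axis(x.values, order, axis=0)
    return RankSortedMatrix(sorted_values, order)


def scale_row(row_values: np.ndarray, bin_min: float, bin_max: float) -> np.ndarray:
    """Linearly rescale one rank row into the range ``[bin_min, bin_max]``.

    The map is ``f(s) = (bin_max - bin_min) * (s - min(row)) / (max(row) -
    min(row)) + bin_min``; entries equal to the row minimum map exactly to
    ``bin_min`` and entries equal to the row maximum exactly to ``bin_max``.
    A degenerate row (all values equal, where the map is 0/0) is sent to the
    bin midpoint, which reduces to the common constant when the bin itself is
    degenerate.
    """
    row = np.asarray(row_values, dtype=np.float64)
    if bin_min > bin_max:
        raise ValidationError(f"bin_min {bin_min} exceeds bin_max {bin_max}")
    lo = row.min()
    hi = row.max()
    if hi == lo:
        return np.full_like(row, 0.5 * (bin_min + bin_max))
    out = (bin_max - bin_min) * (row - lo) / (hi - lo) + bin_min
    # pin the extremes bit-exactly (the arithmetic above can be off by 1 ulp)
    out[row == lo] = bin_min
    out[row == hi] = bin_max
    return out


def mhmn(x: ExpressionMatrix) -> ExpressionMatrix:
    """Modified histogram matching normalization.

    Pipeline: pool and bin the whole matrix, sort each column, rescale the
    rank-``i`` row of the sorted matrix into the range of bin ``i``, and
    return every value to its original position within its column.  Shape and
    labels are preserved; the global minimum and maximum of the matrix are
    unchanged.
    """
    partition = pool_and_bin(x)
    ranked = column_sort(x)
    scaled = np.empty_like(ranked.sorted_values)
    for i in range(x.n_genes):
        scaled[i] = scale_row(
            ranked.sorted_values[i], partition.bins[i, 0], partition.bins[i, -1]
        )
    return x.with_values(ranked.restore(scaled))


def quantile_normalize(x: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile normalization: rank values are replaced by cross-array means.

    Plain sort / row-mean / un-sort with stable tie handling; no tie-averaging
    adjustment is applied, so on tied inputs this differs from tie-averaged QN
    variants (tied values may receive different normalized values according to
    their original positions).
    """
    ranked = column_sort(x)
    row_means = ranked.sorted_values.mean(axis=1)
    equalized = np.broadcast_to(
        row_means[:, None], ranked.sorted_values.shape
    )
    return x.with_values(ranked.restore(np.ascontiguousarray(equalized)))
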