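"""Log2 transformation and quantile normalization of intensity matrices.

Normalization operates across injections (columns) of a single study;
studies are never co-normalized.
"""

from __future__ import annotations

import numpy as np

from .io_model import IntensityMatrix

__all__ = ["log2_transform", "quantile_normalize"]


class DomainError(ValueError):
    """Input values outside the mathematical domain of an operation."""


def log2_transform(matrix: IntensityMatrix) -> IntensityMatrix:
    """Replace every non-missing linear intensity by its base-2 logarithm.

    Raises :class:`DomainError` naming the offending protein/injection if a
    non-missing value is <= 0.
    """
    values = matrix.values
    bad = (values <= 0) & ~np.isnan(values)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise DomainError(
            f"non-positive intensity {values[i, j]!r} for protein "
            f"{matrix.protein_ids[i]!r}, injection {matrix.injection_ids[j]!r}"
        )
    return IntensityMatrix(
        list(matrix.protein_ids), list(matrix.injection_ids), np.log2(values)
    )


def quantile_normalize(matrix: IntensityMatrix) -> IntensityMatrix:
    """Force all columns to share one empirical distribution.

    Complete-data behaviour is the classic procedure: the rank-r value of
    every column becomes the mean over columns of their rank-r values,
    after which all columns hold the same multiset.  Ties are assigned the
    average of their tied ranks' target values.  Missing entries are
    skipped when ranking and stay missing.
    """
    values = matrix.values
    n_rows, n_cols = values.shape
    if n_cols < 1:
        raise ValueError("need at least one column")

    counts = (~np.isnan(values)).sum(axis=0)
    if (counts == 0).any():
        j = int(np.argmin(counts))
        raise ValueError(f"column {matrix.injection_ids[j]!r} is entirely missing")

    # reference quantile function on the probability grid of a full column,
    # averaged over columns (each column contributes its own interpolated
    # quantiles when it has missing entries)
    grid = (np.arange(n_rows) + 0.5) / n_rows
    reference = np.zeros(n_rows)
    for j in range(n_cols):
        col = np.sort(values[~np.isnan(values[:, j]), j])
        m = col.size
        probs = (np.arange(m) + 0.5) / m
        reference += np.interp(grid, probs, col)
    reference /= n_cols

    out = np.full_like(values, np.nan)
    for j in range(n_cols):
        mask = ~np.isnan(values[:, j])
        col = values[mask, j]
        m = col.size
        # average ranks for ties, so tied cells share one target value
        order = np.argsort(col, kind="mergesort")
        ranks = np.empty(m)
        ranks[order] = np.arange(1, m + 1)
        sorted_col = col[order]
        # replace ranks of tied runs with their mean rank
        start = 0
        for end in range(1, m + 1):
            if end == m or sorted_col[end] != sorted_col[start]:
                mean_rank = 0.5 * (start + 1 + end)
                ranks[order[start:end]] = mean_rank
                start = end
        probs = (ranks - 0.5) / m
        ref_probs = (np.arange(n_rows) + 0.5) / n_rows
        out[mask, j] = np.interp(probs, ref_probs, reference)

    return IntensityMatrix(list(matrix.protein_ids), list(matrix.injection_ids), out)
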