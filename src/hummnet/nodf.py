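"""NODF nestedness (Nestedness metric based on Overlap and Decreasing Fill).

For every ordered pair of rows (u above v in the operative order) the paired
term is 0 when degree(u) <= degree(v) (the *decreasing fill* condition is
strict) and otherwise 100 times the fraction of v's ones that overlap u's.
Column pairs are scored the same way; the total score pools all row and
column pairs.  0 means a compartmentalized matrix, 100 a perfectly nested
one.

Two orderings are supported: ``sorted`` internally re-sorts rows and columns
by descending degree (the conventional NODF), while ``fixed`` scores the
matrix in the order supplied -- e.g. a phylogenetic tip order -- so that
nestedness is measured against an externally meaningful node arrangement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import BipartiteMatrix

__all__ = ["NestednessResult", "nodf"]


@dataclass(frozen=True)
class NestednessResult:
    nodf_total: float
    nodf_rows: float
    nodf_cols: float
    order_mode: str

    def rounded(self, ndigits: int = 3) -> "NestednessResult":
        """Interface-precision copy (3 decimals by convention)."""
        return NestednessResult(
            round(self.nodf_total, ndigits),
            round(self.nodf_rows, ndigits),
            round(self.nodf_cols, ndigits),
            self.order_mode,
        )


def _axis_terms(a: np.ndarray) -> tuple:
    """Sum of pairwise NODF terms along axis 0 and the number of pairs."""
    n = a.shape[0]
    if n < 2:
        return 0.0, 0
    deg = a.sum(axis=1)
    overlap = (a @ a.T).astype(float)  # shared ones between every pair
    with np.errstate(divide="ignore", invalid="ignore"):
        term = 100.0 * overlap / deg[None, :]  # term[u, v]: overlap / degree(v)
    term[~np.isfinite(term)] = 0.0
    term *= deg[:, None] > deg[None, :]  # strict decreasing fill
    upper = np.triu_indices(n, k=1)
    return float(term[upper].sum()), n * (n - 1) // 2


def nodf(matrix: BipartiteMatrix, order_mode: str = "sorted") -> NestednessResult:
    """NODF of ``matrix`` under sorted or externally fixed node order.

    ``sorted`` mode sorts by descending degree internally (the input matrix
    is untouched); ``fixed`` mode uses the current row/column order as-is.
    Raises on a 1x1 matrix, which has no pairs to score.
    """
    if order_mode not in ("sorted", "fixed"):
        raise ValueError(f"unknown order mode {order_mode!r}")
    a = matrix.cells.astype(np.int64)
    if a.shape[0] < 2 and a.shape[1] < 2:
        raise ValueError("NODF is undefined for a single-row, single-column matrix")
    if order_mode == "sorted":
        a = a[np.argsort(-a.sum(axis=1), kind="stable"), :]
        a = a[:, np.argsort(-a.sum(axis=0), kind="stable")]

    row_sum, n_row_pairs = _axis_terms(a)
    col_sum, n_col_pairs = _axis_terms(a.T)
    nodf_rows = row_sum / n_row_pairs if n_row_pairs else 0.0
    nodf_cols = col_sum / n_col_pairs if n_col_pairs else 0.0
    total = (row_sum + col_sum) / (n_row_pairs + n_col_pairs)
    return NestednessResult(total, nodf_rows, nodf_cols, order_mode)
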