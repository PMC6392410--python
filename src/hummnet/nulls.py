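"""Null-matrix generators and ensemble testing for binary network statistics.

Three classical null models, ordered from least to most constrained:

* ER -- the observed 1s are reassigned uniformly among all cells (total fill
  conserved exactly, everything else free);
* CE -- each cell is filled independently with probability equal to the
  arithmetic mean of the focal row's and column's fill probabilities, so the
  expected generalization level of every node is conserved;
* FF (fixed-fixed) -- row and column marginal totals are conserved exactly,
  sampled by curveball trades.

ER and CE can produce empty rows or columns, on which metrics like NODF are
undefined; those draws are rejected and resampled up to a retry cap.

:func:`null_ensemble` evaluates an arbitrary matrix statistic on an ensemble
of null matrices and summarizes it as a standardized effect size
SES = (observed - null mean) / null sd together with an upper-tail empirical
p-value with the add-one small-sample correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .matrix import BipartiteMatrix

__all__ = ["NullEnsemble", "er_null", "ce_null", "ff_null", "null_ensemble"]

logger = logging.getLogger(__name__)

RETRY_CAP = 1000


@dataclass(frozen=True)
class NullEnsemble:
    model: str
    n_reps: int
    observed: float
    values: np.ndarray
    null_mean: float
    null_sd: float
    ses: float
    p_value: float
    degenerate: bool = False


def _no_empty_margins(cells: np.ndarray) -> bool:
    return cells.any(axis=1).all() and cells.any(axis=0).all()


def er_null(matrix: BipartiteMatrix, rng: np.random.Generator) -> BipartiteMatrix:
    """Reassign the observed 1s uniformly at random among all cells."""
    r, c = matrix.shape
    links = matrix.n_links
    for _ in range(RETRY_CAP):
        flat = np.zeros(r * c, dtype=np.int8)
        flat[rng.choice(r * c, size=links, replace=False)] = 1
        cells = flat.reshape(r, c)
        if _no_empty_margins(cells):
            return BipartiteMatrix(list(matrix.rows), list(matrix.cols), cells, "given")
    raise RuntimeError(
        f"ER null: no draw without empty rows/columns in {RETRY_CAP} tries; matrix too sparse"
    )


def ce_null(matrix: BipartiteMatrix, rng: np.random.Generator) -> BipartiteMatrix:
    """Independent Bernoulli cells with p_ij = (row fill + column fill) / 2."""
    r, c = matrix.shape
    p = 0.5 * (matrix.row_degrees()[:, None] / c + matrix.col_degrees()[None, :] / r)
    for attempt in range(RETRY_CAP):
        cells = (rng.random((r, c)) < p).astype(np.int8)
        if _no_empty_margins(cells):
            if attempt:
                logger.debug("CE null: resampled %d time(s) to avoid empty margins", attempt)
            return BipartiteMatrix(list(matrix.rows), list(matrix.cols), cells, "given")
    raise RuntimeError(
        f"CE null: no draw without empty rows/columns in {RETRY_CAP} tries; matrix too sparse"
    )


def ff_null(matrix: BipartiteMatrix, rng: np.random.Generator, n_trades: int | None = None) -> BipartiteMatrix:
    """Margin-preserving null via curveball trades.

    Both row-sum and column-sum vectors are conserved exactly.  The default
    number of trades is five times the number of links, a comfortable burn-in
    for matrices of this size.
    """
    if n_trades is None:
        n_trades = 5 * matrix.n_links
    if n_trades < 1:
        raise ValueError("n_trades must be >= 1")
    rows = [set(np.flatnonzero(row)) for row in matrix.cells]
    n = len(rows)
    if n >= 2:
        picks = rng.integers(0, n, size=(n_trades, 2))
        for i, j in picks:
            if i == j:
                continue
            a, b = rows[i], rows[j]
            a_only = list(a - b)
            b_only = list(b - a)
            total = a_only + b_only
            if not a_only or not b_only:
                continue
            sel = rng.permutation(len(total))[: len(a_only)]
            new_a = {total[s] for s in sel}
            shared = a & b
            rows[i] = shared | new_a
            rows[j] = shared | (set(total) - new_a)
    cells = np.zeros(matrix.shape, dtype=np.int8)
    for i, cols in enumerate(rows):
        cells[i, list(cols)] = 1
    return BipartiteMatrix(list(matrix.rows), list(matrix.cols), cells, "given")


_GENERATORS = {"ER": er_null, "CE": ce_null, "FF": ff_null}


def null_ensemble(
    matrix: BipartiteMatrix,
    statistic,
    model: str,
    n_reps: int,
    rng: np.random.Generator,
    observed: float | None = None,
) -> NullEnsemble:
    """Test a matrix statistic against one of the three null models.

    ``statistic`` is any callable mapping a BipartiteMatrix to a float; null
    matrices keep the observed label order, so fixed-order statistics (e.g.
    phylogenetic-order NODF) are evaluated coherently.  When the null sd is
    zero the SES is reported as 0 with a degenerate-null warning.
    """
    if model not in _GENERATORS:
        raise ValueError(f"unknown null model {model!r}")
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    gen = _GENERATORS[model]
    if observed is None:
        observed = float(statistic(matrix))
    values = np.array([float(statistic(gen(matrix, rng))) for _ in range(n_reps)])
    mean = float(values.mean())
    sd = float(values.std(ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        logger.warning("null ensemble for %s is degenerate (sd = 0); SES reported as 0", model)
        ses = 0.0
    else:
        ses = (observed - mean) / sd
    p = (1 + int((values >= observed).sum())) / (1 + n_reps)
    return NullEnsemble(model, n_reps, observed, values, mean, sd, ses, p, degenerate)
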