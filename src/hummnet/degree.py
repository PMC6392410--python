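"""Cumulative degree distributions and model selection among three decay laws.

The number of links per node in a mutualistic network is typically
heterogeneous: a few generalists concentrate many links while most nodes
hold few.  The shape of the cumulative distribution P(k) = P(degree >= k)
distinguishes an exponential decay exp(-k/gamma) (single-scale), a power law
k**(-gamma) (scale-free), and a truncated power law
k**(-gamma) * exp(-k/k_c).  Each form is fit to the untransformed cumulative
distribution by nonlinear least squares and the fits are compared with the
least-squares AIC, n*ln(RSS/n) + 2p; the lowest AIC wins.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .matrix import BipartiteMatrix

__all__ = [
    "DegreeDistribution",
    "FitResult",
    "degree_sequence",
    "cumulative_distribution",
    "fit_degree_models",
]

logger = logging.getLogger(__name__)

RSS_FLOOR = 1e-12  # AIC floor for numerically perfect fits

MODELS = {
    "exponential": (lambda k, g: np.exp(-k / g), 1),
    "power_law": (lambda k, g: k ** (-g), 1),
    "truncated_power_law": (lambda k, g, kc: k ** (-g) * np.exp(-k / kc), 2),
}


@dataclass(frozen=True)
class DegreeDistribution:
    k_values: np.ndarray  # ascending distinct positive degrees
    cum_prob: np.ndarray  # P(degree >= k)
    n_nodes: int


@dataclass(frozen=True)
class FitResult:
    model: str
    params: dict
    rss: float
    aic: float
    converged: bool = True


def degree_sequence(matrix: BipartiteMatrix, guild: str = "combined") -> np.ndarray:
    """Row sums, column sums, or their concatenation (``combined``)."""
    if guild == "rows":
        return matrix.row_degrees().astype(int)
    if guild == "cols":
        return matrix.col_degrees().astype(int)
    if guild == "combined":
        return np.concatenate([matrix.row_degrees(), matrix.col_degrees()]).astype(int)
    raise ValueError(f"unknown guild {guild!r}")


def cumulative_distribution(degrees) -> DegreeDistribution:
    """P(degree >= k) at each distinct observed degree k."""
    degrees = np.asarray(degrees, dtype=int)
    if degrees.size == 0:
        raise ValueError("empty degree sequence")
    if (degrees <= 0).any():
        raise ValueError("degrees must be positive")
    k = np.unique(degrees)
    cum = np.array([(degrees >= kk).sum() for kk in k], dtype=float) / degrees.size
    return DegreeDistribution(k, cum, int(degrees.size))


def _initial_guesses(k, p):
    # log-log slope for the power-law exponent; rate from the log-linear slope
    logk, logp = np.log(k), np.log(np.clip(p, 1e-12, None))
    slope_ll = np.polyfit(logk, logp, 1)[0]
    gamma0 = max(-slope_ll, 0.1)
    slope_le = np.polyfit(k, logp, 1)[0]
    rate0 = max(-1.0 / slope_le, 1e-3) if slope_le < 0 else float(k.max())
    return gamma0, rate0


def _aic(rss: float, n: int, p: int) -> float:
    return n * np.log(max(rss, RSS_FLOOR) / n) + 2 * p


def fit_degree_models(dist: DegreeDistribution) -> tuple:
    """Fit the three decay models and select the lowest-AIC fit.

    Returns ``(fits, best)`` where ``fits`` maps model name to
    :class:`FitResult` and ``best`` is the winning model name.  A model that
    fails to converge is flagged unfit (infinite AIC) and excluded from
    selection.
    """
    k = dist.k_values.astype(float)
    p = dist.cum_prob
    if len(k) < 3:
        raise ValueError("need at least 3 distinct degrees to fit the 2-parameter model")
    gamma0, rate0 = _initial_guesses(k, p)
    starts = {
        "exponential": ([rate0], ([1e-9], [np.inf])),
        "power_law": ([gamma0], ([-np.inf], [np.inf])),
        "truncated_power_law": ([gamma0, float(k.max())], ([-np.inf, 1e-9], [np.inf, np.inf])),
    }
    names = {"exponential": ["gamma"], "power_law": ["gamma"], "truncated_power_law": ["gamma", "k_c"]}

    fits = {}
    for name, (func, n_par) in MODELS.items():
        p0, bounds = starts[name]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(func, k, p, p0=p0, bounds=bounds, maxfev=20000)
            rss = float(((func(k, *popt) - p) ** 2).sum())
            fits[name] = FitResult(name, dict(zip(names[name], popt)), rss, _aic(rss, len(k), n_par))
        except (RuntimeError, ValueError) as exc:
            logger.warning("model %s failed to converge: %s", name, exc)
            fits[name] = FitResult(name, {}, np.inf, np.inf, converged=False)

    candidates = {n: f for n, f in fits.items() if f.converged}
    if not candidates:
        raise RuntimeError("no degree model converged")
    best = min(candidates, key=lambda n: candidates[n].aic)
    return fits, best
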