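"""Binomial GLMs for niche conservatism: does a clade's center of
diversification predict whether its species occupy multiple biogeographical
regions?

The response is binary per species: 1 ("success") when the species is
present in two or three of the Nearctic / Neotropical / Austral regions, 0
when it occupies at most one.  Predictors are categorical (diversification
center with two levels, or clade with eight levels -- the single-species
Patagona clade is excluded upstream).  Models are fit with either the logit
or probit link; for the logit link exponentiated coefficients are odds
ratios.

Term significance uses the likelihood-ratio (deviance difference)
chi-square; Wald chi-squares on coefficient contrasts drive the post-hoc
pairwise clade comparisons, Bonferroni-adjusted over all pairs tested.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "GLMResult",
    "ContrastTable",
    "make_response",
    "fit_binomial_glm",
    "lr_chi_test",
    "wald_chi_test",
    "pairwise_contrasts",
    "overdispersion_check",
]

SEPARATION_EPS = 1e-8


@dataclass(frozen=True)
class GLMResult:
    link: str
    coefficients: pd.Series
    covariance: pd.DataFrame
    deviance: float
    null_deviance: float
    df_residual: int
    odds_ratios: pd.Series | None
    factors: dict  # predictor name -> (levels, reference)
    pearson_chi2: float
    fittedvalues: np.ndarray = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return len(self.coefficients)


@dataclass(frozen=True)
class ContrastTable:
    pairs: list
    estimates: np.ndarray
    odds_ratios: np.ndarray
    chi: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    m: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "pair": [f"{a} - {b}" for a, b in self.pairs],
            "estimate": self.estimates,
            "odds_ratio": self.odds_ratios,
            "chi": self.chi,
            "p_raw": self.p_raw,
            "p_bonferroni": self.p_adjusted,
        })


def make_response(table) -> np.ndarray:
    """1 per species present in >= 2 biogeographical regions, else 0."""
    return np.array([1 if s.n_regions >= 2 else 0 for s in table], dtype=int)


def _design(predictors: dict, references: dict | None = None) -> tuple:
    """Intercept + treatment-coded dummies, reference level first."""
    references = references or {}
    n = len(next(iter(predictors.values())))
    cols = {"Intercept": np.ones(n)}
    factors = {}
    for name, values in predictors.items():
        values = np.asarray(values)
        levels = sorted(set(values))
        ref = references.get(name, levels[0])
        if ref not in levels:
            raise ValueError(f"reference level {ref!r} not among levels of {name}")
        ordered = [ref] + [l for l in levels if l != ref]
        factors[name] = (ordered, ref)
        for level in ordered[1:]:
            colname = f"{name}[{level}]"
            col = (values == level).astype(float)
            if col.sum() == 0:
                raise ValueError(f"predictor level {level!r} of {name} has zero observations")
            cols[colname] = col
    X = pd.DataFrame(cols)
    if np.linalg.matrix_rank(X.values) < X.shape[1]:
        raise ValueError(f"rank-deficient design; aliased columns among {list(X.columns)}")
    return X, factors


def fit_binomial_glm(y, predictors: dict | None = None, link: str = "logit",
                     references: dict | None = None) -> GLMResult:
    """Fit a binomial GLM of a binary response on categorical predictors.

    ``predictors`` maps names to per-observation level arrays; ``None`` or
    empty fits the intercept-only model.  ``references`` optionally pins the
    reference level per predictor (default: first level alphabetically).
    Coefficients come from iteratively reweighted least squares; complete
    separation is reported as a warning with the offending diagnostic.
    """
    y = np.asarray(y, dtype=float)
    links = {"logit": sm.families.links.Logit(), "probit": sm.families.links.Probit()}
    if link not in links:
        raise ValueError(f"unknown link {link!r}")
    if predictors:
        X, factors = _design(predictors, references)
    else:
        X, factors = pd.DataFrame({"Intercept": np.ones(len(y))}), {}

    model = sm.GLM(y, X, family=sm.families.Binomial(link=links[link]))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = model.fit(tol=1e-8, maxiter=200)

    mu = res.fittedvalues
    if np.any(mu < SEPARATION_EPS) or np.any(mu > 1 - SEPARATION_EPS):
        warnings.warn(
            "fitted probabilities numerically 0 or 1: possible complete separation; "
            f"max |coefficient| = {np.abs(res.params).max():.3g}",
            stacklevel=2,
        )

    coefficients = pd.Series(res.params, index=X.columns)
    return GLMResult(
        link=link,
        coefficients=coefficients,
        covariance=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        deviance=float(res.deviance),
        null_deviance=float(res.null_deviance),
        df_residual=int(res.df_resid),
        odds_ratios=np.exp(coefficients) if link == "logit" else None,
        factors=factors,
        pearson_chi2=float(res.pearson_chi2),
        fittedvalues=np.asarray(mu),
    )


def lr_chi_test(full: GLMResult, reduced: GLMResult) -> tuple:
    """Likelihood-ratio chi-square for nested binomial GLMs.

    Returns (chi, df, p) with chi the deviance drop from reduced to full.
    """
    if not set(reduced.coefficients.index) <= set(full.coefficients.index):
        raise ValueError("models are not nested (reduced terms not a subset of full terms)")
    df = full.n_params - reduced.n_params
    if df == 0:
        return 0.0, 0, 1.0
    chi = reduced.deviance - full.deviance
    p = float(stats.chi2.sf(max(chi, 0.0), df))
    return float(chi), int(df), p


def wald_chi_test(model: GLMResult, term: str) -> tuple:
    """Wald chi-square that all coefficients of a factor are jointly zero."""
    if term not in model.factors:
        raise ValueError(f"unknown factor {term!r}")
    names = [c for c in model.coefficients.index if c.startswith(f"{term}[")]
    beta = model.coefficients[names].values
    cov = model.covariance.loc[names, names].values
    chi = float(beta @ np.linalg.solve(cov, beta))
    df = len(names)
    return chi, df, float(stats.chi2.sf(chi, df))


def pairwise_contrasts(model: GLMResult, factor: str) -> ContrastTable:
    """All pairwise level differences of a factor as Wald chi-square tests.

    The Bonferroni adjustment multiplies each raw p by the number of pairs
    actually tested (28 for 8 levels), capped at 1.
    """
    if factor not in model.factors:
        raise ValueError(f"unknown factor {factor!r}")
    levels, ref = model.factors[factor]
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs >= 2 levels")

    def coefvec(level):
        v = pd.Series(0.0, index=model.coefficients.index)
        if level != ref:
            v[f"{factor}[{level}]"] = 1.0
        return v

    pairs = list(itertools.combinations(levels, 2))
    estimates, chis, ps = [], [], []
    for a, b in pairs:
        contrast = (coefvec(a) - coefvec(b)).values
        est = float(contrast @ model.coefficients.values)
        var = float(contrast @ model.covariance.values @ contrast)
        chi = est * est / var if var > 0 else 0.0
        estimates.append(est)
        chis.append(chi)
        ps.append(float(stats.chi2.sf(chi, 1)))
    m = len(pairs)
    estimates = np.array(estimates)
    chis = np.array(chis)
    ps = np.array(ps)
    return ContrastTable(
        pairs=pairs,
        estimates=estimates,
        odds_ratios=np.exp(np.abs(estimates)) if model.link == "logit" else np.full(m, np.nan),
        chi=chis,
        p_raw=ps,
        p_adjusted=np.minimum(1.0, m * ps),
        m=m,
    )


def overdispersion_check(model: GLMResult, flag_above: float = 1.5) -> tuple:
    """Pearson chi-square over residual df; (ratio, flagged).

    For a strictly binary response the ratio is reported with the usual
    caveat that overdispersion is only weakly identifiable; the flag trips
    above ``flag_above``.
    """
    if model.df_residual == 0:
        raise ValueError("dispersion ratio undefined with zero residual df")
    ratio = model.pearson_chi2 / model.df_residual
    return float(ratio), bool(ratio > flag_above)
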