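"""Negative binomial trend + Fourier-seasonality model with population offset.

The counterfactual engine: a log-linear negative binomial (NB2) regression

    E[y_t] = exp(b0 + b_trend * x_t
                 + sum_{k=1..n} [b1k sin(2 pi k x_t / 12) + b2k cos(2 pi k x_t / 12)])
             * population_t

is fitted by maximum likelihood to the pre-intervention months only, with the
population entering as an exposure (log-offset with coefficient 1).  The
harmonic degree n is chosen by AIC over a candidate range, ties broken toward
the simpler model.  Dispersion follows the size convention
Var = mu + mu**2 / size; internally the NB2 ``alpha = 1/size`` is estimated
jointly with the coefficients, falling back to a profiled likelihood in
log-alpha when the joint optimizer stalls.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize_scalar

from .series import MonthlyCountSeries

logger = logging.getLogger(__name__)

__all__ = ["build_design", "design_column_names", "fit_negative_binomial",
           "select_by_aic", "FittedItsModel", "FitError"]

DEFAULT_MAX_DEGREE = 3

# profile-likelihood bounds for log10(alpha); the lower bound is effectively
# the Poisson limit (size = 1/alpha = 1e8)
_LOG10_ALPHA_LO, _LOG10_ALPHA_HI = -8.0, 1.5


class FitError(RuntimeError):
    """Model fitting failed after all documented restarts."""


def design_column_names(degree: int) -> list[str]:
    names = ["intercept", "trend"]
    for k in range(1, degree + 1):
        names += [f"sin{k}", f"cos{k}"]
    return names


def build_design(month_indices: np.ndarray, degree: int) -> np.ndarray:
    """Design matrix: intercept, linear trend, and sin/cos pairs at period 12.

    Degree 0 is the trend-only candidate.  Raises if the matrix cannot be
    identified from the given months (too many columns, or a harmonic that
    degenerates on the monthly grid, e.g. sin at k = 6).
    """
    x = np.asarray(month_indices, dtype=float)
    if x.size == 0:
        raise ValueError("no months supplied")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    ncol = 2 + 2 * degree
    if ncol >= x.size:
        raise ValueError(
            f"degree {degree} needs {ncol} columns but only {x.size} months "
            "are available (unidentifiable)")
    cols = [np.ones_like(x), x]
    for k in range(1, degree + 1):
        w = 2 * np.pi * k * x / 12.0
        cols += [np.sin(w), np.cos(w)]
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < ncol:
        raise ValueError(
            f"design at degree {degree} is rank deficient on these months "
            "(harmonic degenerates on the monthly grid)")
    return X


@dataclass
class FittedItsModel:
    """A converged pre-window fit: the counterfactual engine.

    ``dispersion`` is the NB size (Var = mu + mu**2/size); ``alpha`` its
    reciprocal.  ``anchor`` records the calendar month at x_t = 0 so that
    prediction can verify index alignment.
    """

    params: pd.Series            # named coefficients (intercept, trend, sin1, ...)
    bse: pd.Series               # standard errors of the coefficients
    cov: pd.DataFrame            # covariance of the coefficients (alpha excluded)
    alpha: float
    llf: float
    degree: int
    month_indices: np.ndarray
    anchor: tuple[int, int]
    offset: np.ndarray
    converged: bool
    method: str                  # "joint-mle" or "profile"
    aic_table: pd.DataFrame | None = None

    @property
    def dispersion(self) -> float:
        return float("inf") if self.alpha == 0 else 1.0 / self.alpha

    @property
    def n_params(self) -> int:
        """Coefficients plus the dispersion parameter."""
        return len(self.params) + 1

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.n_params

    def fitted_means(self) -> np.ndarray:
        X = build_design(self.month_indices, self.degree)
        return np.exp(X @ self.params.to_numpy()) * self.offset

    def summary_dict(self) -> dict:
        d = {
            "degree": self.degree,
            "coefficients": {k: float(v) for k, v in self.params.items()},
            "standard_errors": {k: float(v) for k, v in self.bse.items()},
            "alpha": float(self.alpha),
            "dispersion_size": self.dispersion,
            "log_likelihood": float(self.llf),
            "aic": float(self.aic),
            "fit_window_months": [int(self.month_indices[0]), int(self.month_indices[-1])],
            "anchor_year_month": list(self.anchor),
            "offset_convention": "person-months exposure (log offset, coefficient 1)",
            "converged": bool(self.converged),
            "method": self.method,
        }
        if self.aic_table is not None:
            d["aic_by_degree"] = {int(r.degree): float(r.aic)
                                  for r in self.aic_table.itertuples()}
        return d


def _profile_fit(y: np.ndarray, X: np.ndarray, offset: np.ndarray):
    """Profile the NB2 likelihood over log10(alpha) with GLM inner fits."""
    def glm_at(log10_alpha: float):
        fam = sm.families.NegativeBinomial(alpha=10.0 ** log10_alpha)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return sm.GLM(y, X, family=fam, exposure=offset).fit()

    grid = np.linspace(_LOG10_ALPHA_LO, _LOG10_ALPHA_HI, 25)
    llfs = np.array([glm_at(g).llf for g in grid])
    best = int(np.argmax(llfs))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    if lo == hi:
        opt_log_alpha = grid[best]
    else:
        r = minimize_scalar(lambda g: -glm_at(g).llf, bounds=(lo, hi), method="bounded",
                            options={"xatol": 1e-6})
        opt_log_alpha = float(r.x)
        if -r.fun < llfs[best]:  # refinement must not lose to the grid
            opt_log_alpha = grid[best]
    res = glm_at(opt_log_alpha)
    return res.params, res.bse, res.cov_params(), 10.0 ** opt_log_alpha, float(res.llf)


def fit_negative_binomial(series: MonthlyCountSeries, degree: int,
                          offset: np.ndarray) -> FittedItsModel:
    """Fit the NB model of the given harmonic degree to the pre-window months.

    ``offset`` is the monthly population aligned with the pre-window rows.
    Starting values come from a Poisson fit; non-convergence of the joint
    optimizer triggers the profiled-likelihood fallback and is reported in
    ``method`` — never silently accepted.
    """
    pre = series.pre
    if len(pre) == 0:
        raise ValueError("series has no pre-intervention months")
    y = pre["count"].to_numpy(dtype=float)
    if np.all(y == 0):
        raise FitError(f"subgroup {series.subgroup!r}: all pre-window counts are zero")
    offset = np.asarray(offset, dtype=float)
    if offset.shape != y.shape:
        raise ValueError(f"offset length {offset.size} != pre-window length {y.size}")
    if np.any(offset <= 0):
        raise ValueError("offset must be strictly positive")
    xidx = pre["month_index"].to_numpy()
    X = build_design(xidx, degree)
    names = design_column_names(degree)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        poisson = sm.GLM(y, X, family=sm.families.Poisson(), exposure=offset).fit()

    params = bse = cov = None
    alpha = llf = None
    method = "joint-mle"
    converged = False
    try:
        nb = sm.NegativeBinomial(y, X, exposure=offset)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = nb.fit(start_params=np.r_[poisson.params, 0.1],
                         method="bfgs", maxiter=500, disp=0)
        converged = bool(res.mle_retvals.get("converged", False))
        alpha_hat = float(res.params[-1])
        cov_all = np.asarray(res.cov_params())
        ok = (converged and alpha_hat > 0
              and np.all(np.isfinite(res.params)) and np.all(np.isfinite(cov_all)))
        if ok:
            params, bse = res.params[:-1], res.bse[:-1]
            cov = cov_all[:-1, :-1]
            alpha, llf = alpha_hat, float(res.llf)
    except Exception as exc:  # noqa: BLE001 - any optimizer failure routes to fallback
        logger.info("joint NB fit failed (%s); falling back to profile likelihood", exc)

    if params is None:
        method = "profile"
        logger.info("subgroup %r degree %d: profiled-likelihood fallback",
                    series.subgroup, degree)
        params, bse, cov, alpha, llf = _profile_fit(y, X, offset)
        converged = True

    mu = np.exp(X @ np.asarray(params)) * offset
    if not np.all(np.isfinite(mu)) or np.any(mu <= 0):
        raise FitError(f"subgroup {series.subgroup!r}: fitted means not positive/finite")

    return FittedItsModel(
        params=pd.Series(np.asarray(params), index=names),
        bse=pd.Series(np.asarray(bse), index=names),
        cov=pd.DataFrame(np.asarray(cov), index=names, columns=names),
        alpha=float(alpha),
        llf=float(llf),
        degree=degree,
        month_indices=xidx,
        anchor=series.anchor,
        offset=offset,
        converged=converged,
        method=method,
    )


def select_by_aic(series: MonthlyCountSeries, offset: np.ndarray,
                  degrees=range(0, DEFAULT_MAX_DEGREE + 1)) -> FittedItsModel:
    """Fit every candidate harmonic degree and return the minimal-AIC model.

    Ties (to machine precision) break toward the smaller degree.  The full
    AIC table is attached to the returned model for reporting.  Raises
    :class:`FitError` if no candidate converges.
    """
    degrees = list(degrees)
    if len(degrees) < 2:
        raise ValueError("need at least two candidate degrees")
    fits: list[FittedItsModel] = []
    rows = []
    for n in sorted(degrees):
        try:
            fit = fit_negative_binomial(series, n, offset)
        except (FitError, ValueError) as exc:
            logger.warning("degree %d failed for %r: %s", n, series.subgroup, exc)
            rows.append(dict(degree=n, aic=np.nan, llf=np.nan, method="failed"))
            continue
        fits.append(fit)
        rows.append(dict(degree=n, aic=fit.aic, llf=fit.llf, method=fit.method))
    if not fits:
        raise FitError(f"subgroup {series.subgroup!r}: every candidate degree failed")
    best = min(fits, key=lambda f: (f.aic, f.degree))  # strict tie -> smaller n (sorted)
    best.aic_table = pd.DataFrame(rows)
    return best
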