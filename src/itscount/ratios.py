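"""Counterfactual extrapolation and incidence-ratio inference.

The fitted pre-window model is extrapolated through the intervention window
to give the expected (counterfactual) monthly counts.  Annual sums yield

    oIR = observed annual visits / pre-period average annual visits
    aIR = observed annual visit rate / expected annual visit rate

Under the constant-within-year population assumption the person-year
denominators of the aIR cancel, so the rate ratio equals the count ratio;
the cancellation is asserted numerically whenever an annual population is
supplied.

Uncertainty for the aIR comes from a parametric bootstrap predictive test:
coefficient vectors are drawn from the estimated sampling distribution of the
fit, negative binomial monthly counts are simulated for the intervention year
under the null of no intervention effect, and the observed annual count is
located in that predictive distribution (two-sided p by doubling the smaller
tail, percentile CI from observed / simulated annual counts).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FittedItsModel, build_design
from .series import MonthlyCountSeries

logger = logging.getLogger(__name__)

__all__ = ["predict_expected", "annual_ratios", "air_inference",
           "AirInference", "IncidenceRatioResult", "incidence_ratio_table"]


def _check_alignment(model: FittedItsModel, months: pd.DataFrame) -> None:
    """Hard-fail if month_index does not extend the fit's calendar scheme."""
    ay, am = model.anchor
    expect = (months["year"].to_numpy() * 12 + months["month"].to_numpy() - 1
              - (ay * 12 + am - 1))
    got = months["month_index"].to_numpy()
    if not np.array_equal(expect, got):
        bad = months[expect != got].iloc[0]
        raise ValueError(
            f"month indexing mismatch at {int(bad.year)}-{int(bad.month):02d}: "
            f"index {int(bad.month_index)} does not continue the fitting "
            "window's scheme")


def predict_expected(model: FittedItsModel, months: pd.DataFrame,
                     offset: np.ndarray) -> np.ndarray:
    """Counterfactual expected count per month: exp(X beta) * offset.

    ``months`` must carry ``month_index``, ``year``, ``month`` on the same
    0-based index scheme as the fit; any mismatch is a hard error.
    """
    _check_alignment(model, months)
    offset = np.asarray(offset, dtype=float)
    if offset.shape != (len(months),):
        raise ValueError("offset length does not match prediction months")
    X = build_design_for_prediction(months["month_index"].to_numpy(), model.degree)
    return np.exp(X @ model.params.to_numpy()) * offset


def build_design_for_prediction(month_indices: np.ndarray, degree: int) -> np.ndarray:
    """Design columns for prediction (no identifiability constraint on length)."""
    x = np.asarray(month_indices, dtype=float)
    cols = [np.ones_like(x), x]
    for k in range(1, degree + 1):
        w = 2 * np.pi * k * x / 12.0
        cols += [np.sin(w), np.cos(w)]
    return np.column_stack(cols)


def annual_ratios(observed: MonthlyCountSeries, expected: np.ndarray,
                  population_by_year: dict[int, float] | None = None) -> pd.DataFrame:
    """Per intervention year: observed and expected annual counts, oIR, aIR.

    ``expected`` aligns with the post-window rows of ``observed``.  Partial
    intervention years are refused.  The pre-period average annual count is
    the total pre-window count divided by the number of pre years.
    """
    post = observed.post.copy()
    if len(post) == 0:
        raise ValueError("no intervention months in series")
    expected = np.asarray(expected, dtype=float)
    if expected.shape != (len(post),):
        raise ValueError("expected series does not align with intervention months")
    post["expected"] = expected

    pre = observed.pre
    if len(pre) == 0 or len(pre) % 12 != 0:
        raise ValueError(f"pre window must cover whole years, has {len(pre)} months")
    pre_years = len(pre) / 12
    pre_avg = pre["count"].sum() / pre_years

    rows = []
    for year, grp in post.groupby("year"):
        if len(grp) != 12:
            raise ValueError(
                f"intervention year {year} has {len(grp)} months; partial years "
                "are refused, not prorated")
        obs = int(grp["count"].sum())
        exp = float(grp["expected"].sum())
        if exp <= 0:
            raise ValueError(f"expected annual count for {year} is not positive")
        air = obs / exp
        if population_by_year and year in population_by_year:
            # constant within-year population: person-year denominators cancel
            py = population_by_year[year]
            rate_ratio = (obs / py) / (exp / py)
            assert np.isclose(rate_ratio, air, rtol=1e-12), "rate ratio failed to cancel"
        rows.append(dict(year=int(year), observed=obs, expected=exp,
                         pre_annual_avg=pre_avg, oIR=obs / pre_avg, aIR=air))
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class AirInference:
    """Bootstrap CI and predictive p-value for one intervention year's aIR."""

    ci_low: float
    ci_high: float
    p_value: float
    p_display: str
    replicates: int
    seed: int


def air_inference(model: FittedItsModel, observed_annual: int, months: pd.DataFrame,
                  offset: np.ndarray, replicates: int = 1000, seed: int = 0) -> AirInference:
    """Parametric bootstrap predictive test for one intervention year.

    For each replicate a coefficient vector is drawn from
    N(beta_hat, cov(beta_hat)), monthly means over the year are formed with
    the year's offset, and monthly counts are simulated from the fitted
    negative binomial under the null of no intervention effect.  The
    two-sided p-value doubles the smaller tail of the simulated annual-count
    distribution around the observed count (capped at 1); the 95% CI for the
    aIR is the percentile interval of observed / simulated annual count.
    Zero-exceedance tails are displayed as bounds (e.g. "<0.001" at 1000
    replicates).
    """
    if replicates < 1000:
        raise ValueError("use at least 1000 bootstrap replicates")
    if len(months) != 12:
        raise ValueError("inference runs on one whole intervention year (12 months)")
    _check_alignment(model, months)
    cov = model.cov.to_numpy()
    if not np.all(np.isfinite(cov)):
        raise ValueError("degenerate coefficient covariance")
    # guard tiny negative eigenvalues from the optimizer's Hessian
    w, V = np.linalg.eigh((cov + cov.T) / 2)
    if w.min() < -1e-8 * max(w.max(), 1e-30):
        raise ValueError("degenerate coefficient covariance (not PSD)")
    cov_psd = (V * np.clip(w, 0, None)) @ V.T

    rng = np.random.default_rng(seed)
    X = build_design_for_prediction(months["month_index"].to_numpy(), model.degree)
    betas = rng.multivariate_normal(model.params.to_numpy(), cov_psd,
                                    size=replicates, method="svd")
    mu = np.exp(betas @ X.T) * np.asarray(offset, dtype=float)  # (replicates, 12)
    size = model.dispersion
    if np.isfinite(size):
        counts = rng.negative_binomial(size, size / (size + mu))
    else:
        counts = rng.poisson(mu)
    annual = counts.sum(axis=1)

    upper = float(np.mean(annual >= observed_annual))
    lower = float(np.mean(annual <= observed_annual))
    tail = min(upper, lower)
    p = min(1.0, 2.0 * tail)
    p_display = f"<{1.0 / replicates:g}" if tail == 0 else f"{p:.3g}"

    denom_lo, denom_hi = np.percentile(annual, [2.5, 97.5])
    if denom_lo <= 0:
        logger.warning("lower bootstrap percentile of annual count is 0; CI upper "
                       "bound unbounded")
    ci_low = observed_annual / denom_hi
    ci_high = observed_annual / denom_lo if denom_lo > 0 else float("inf")
    return AirInference(ci_low=float(ci_low), ci_high=float(ci_high), p_value=p,
                        p_display=p_display, replicates=replicates, seed=seed)


@dataclass(frozen=True)
class IncidenceRatioResult:
    """One row of the per-year incidence-ratio table for one subgroup."""

    subgroup: str
    year: int
    observed: int
    pre_annual_avg: float
    expected: float
    oIR: float
    aIR: float
    ci_low: float
    ci_high: float
    p_value: float
    p_display: str
    replicates: int
    seed: int


def incidence_ratio_table(model: FittedItsModel, observed: MonthlyCountSeries,
                          offset_post: np.ndarray,
                          population_by_year: dict[int, float] | None = None,
                          replicates: int = 1000, seed: int = 0) -> list[IncidenceRatioResult]:
    """Full per-year table: point ratios plus bootstrap CI and p per year.

    Each year's bootstrap uses an independent child seed derived from
    ``seed`` so that adding a year never perturbs earlier years' draws.
    """
    post = observed.post
    expected = predict_expected(model, post, offset_post)
    table = annual_ratios(observed, expected, population_by_year)
    results = []
    for i, row in table.iterrows():
        months = post[post["year"] == row.year]
        off = np.asarray(offset_post)[post["year"].to_numpy() == row.year]
        child = int(np.random.SeedSequence([seed, int(row.year)]).generate_state(1)[0] % (2**31))
        inf = air_inference(model, int(row.observed), months, off,
                            replicates=replicates, seed=child)
        results.append(IncidenceRatioResult(
            subgroup=observed.subgroup, year=int(row.year), observed=int(row.observed),
            pre_annual_avg=float(row.pre_annual_avg), expected=float(row.expected),
            oIR=float(row.oIR), aIR=float(row.aIR),
            ci_low=inf.ci_low, ci_high=inf.ci_high,
            p_value=inf.p_value, p_display=inf.p_display,
            replicates=inf.replicates, seed=inf.seed))
    return results


def results_frame(results: list[IncidenceRatioResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
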