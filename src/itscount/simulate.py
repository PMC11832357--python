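"""Synthetic surveillance-count and episode-table generator with known truth.

The monthly generator is the exact inverse of the fitted model: a negative
binomial draw around

    mu_t = exp(beta0 + beta_trend * x_t
               + sum_k [s_k sin(2 pi k x_t / 12) + c_k cos(2 pi k x_t / 12)])
           * population_t * theta_year(t)

with ``theta = 1`` before the intervention.  The dispersion uses the *size*
convention: ``Var(y) = mu + mu**2 / dispersion``, so large ``dispersion``
approaches the Poisson limit.  The true ``mu_t`` is returned alongside every
draw so downstream recovery can be asserted against ground truth.

The episode generator produces row-level visit records with period-dependent
categorical attributes (sex, age band, co-occurring mental-health flags,
28-day death, public-assistance pay code, triage category), shaped like a
before/during characteristics table.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import AGE_BANDS, EpisodeRecord, MH_CATEGORIES
from .series import POST, PRE, MonthlyCountSeries, month_number, month_range

__all__ = [
    "TrueModelParams",
    "ScenarioConfig",
    "simulate_monthly_counts",
    "simulate_episode_table",
    "DEFAULT_ATTRIBUTE_PROBS",
]


@dataclass(frozen=True)
class TrueModelParams:
    """Ground-truth generative parameters for one subgroup's monthly counts.

    Parameters
    ----------
    beta0
        Log rate per person-month at ``x_t = 0`` (before seasonal terms).
    beta_trend
        Per-month slope of the log rate.
    harmonics
        One ``(sin_coef, cos_coef)`` pair per Fourier degree ``k = 1..n``.
    dispersion
        Negative binomial size; ``Var = mu + mu**2/dispersion``; must be > 0.
    effect_by_year
        Multiplicative intervention-period rate factor ``theta`` per calendar
        year; years not listed (and all pre-intervention months) use 1.
    """

    beta0: float
    beta_trend: float
    harmonics: tuple[tuple[float, float], ...] = ()
    dispersion: float = 50.0
    effect_by_year: Mapping[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not np.isfinite(self.dispersion) or self.dispersion <= 0:
            raise ValueError("dispersion must be finite and > 0")
        object.__setattr__(self, "harmonics", tuple(tuple(h) for h in self.harmonics))
        for h in self.harmonics:
            if len(h) != 2:
                raise ValueError("each harmonic is a (sin, cos) coefficient pair")
        for year, theta in self.effect_by_year.items():
            if not np.isfinite(theta) or theta < 0:
                raise ValueError(f"effect for {year} must be finite and >= 0, got {theta}")

    @property
    def degree(self) -> int:
        return len(self.harmonics)


@dataclass(frozen=True)
class ScenarioConfig:
    """Study-window layout and population schedule for one simulated subgroup."""

    start: tuple[int, int]
    end: tuple[int, int]
    intervention: tuple[int, int]  # first month of the intervention window
    population_by_year: Mapping[int, float]
    subgroup: str = "all"
    seed: int = 0

    def __post_init__(self) -> None:
        a, b = month_number(*self.start), month_number(*self.end)
        i = month_number(*self.intervention)
        if not (a < i <= b):
            raise ValueError("intervention month must lie strictly inside the window")
        if i - a < 24:
            raise ValueError(
                f"pre-intervention window has {i - a} months; >= 24 needed to "
                "identify annual seasonality")
        years = range(self.start[0], self.end[0] + 1)
        missing = [y for y in years if y not in self.population_by_year]
        if missing:
            raise ValueError(f"population schedule missing years {missing}")
        if any(p <= 0 for p in self.population_by_year.values()):
            raise ValueError("populations must be strictly positive")


def linear_predictor(params: TrueModelParams, x: np.ndarray) -> np.ndarray:
    """log rate per person-month at month indices ``x`` (no offset, no effect)."""
    eta = params.beta0 + params.beta_trend * x
    for k, (s, c) in enumerate(params.harmonics, start=1):
        w = 2 * np.pi * k * x / 12.0
        eta = eta + s * np.sin(w) + c * np.cos(w)
    return eta


def true_means(params: TrueModelParams, scenario: ScenarioConfig,
               with_effect: bool = True) -> pd.DataFrame:
    """Deterministic generative means mu_t over the scenario window."""
    months = month_range(scenario.start, scenario.end)
    months["month_index"] = np.arange(len(months))
    i0 = month_number(*scenario.intervention) - month_number(*scenario.start)
    months["period"] = np.where(months["month_index"] < i0, PRE, POST)
    pop = months["year"].map(scenario.population_by_year).to_numpy(dtype=float)
    mu = np.exp(linear_predictor(params, months["month_index"].to_numpy())) * pop
    if with_effect:
        theta = np.where(
            months["period"] == POST,
            months["year"].map(lambda y: params.effect_by_year.get(y, 1.0)).to_numpy(dtype=float),
            1.0,
        )
        mu = mu * theta
    bad = ~np.isfinite(mu)
    if bad.any():
        r = months[bad].iloc[0]
        raise FloatingPointError(
            f"non-finite mean at {int(r.year)}-{int(r.month):02d}; "
            "generative coefficients overflow")
    months["population"] = pop
    months["mu"] = mu
    return months


def nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial draw with mean mu and Var = mu + mu**2/dispersion."""
    p = dispersion / (dispersion + np.asarray(mu, dtype=float))
    return rng.negative_binomial(dispersion, p)


def simulate_monthly_counts(params: TrueModelParams, scenario: ScenarioConfig,
                            rng: np.random.Generator | None = None) -> MonthlyCountSeries:
    """Draw one monthly count series from the generative model.

    The returned series carries the true mean in a ``mu`` column and records
    the seed in ``meta`` for reproducibility.
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    months = true_means(params, scenario)
    months["count"] = nb_draw(rng, months["mu"].to_numpy(), params.dispersion)
    data = months[["month_index", "year", "month", "count", "period", "mu", "population"]]
    return MonthlyCountSeries(
        subgroup=scenario.subgroup,
        data=data,
        meta={"seed": scenario.seed,
              "dispersion": params.dispersion,
              "effect_by_year": {str(k): v for k, v in params.effect_by_year.items()}},
    )


# ---------------------------------------------------------------------------
# episode-level generator

# Period-dependent attribute probabilities loosely emulating a large urban
# ED self-harm cohort before/during a population-level disruption: a small
# male shift, fewer 28-day deaths, more co-occurring mental-health diagnoses
# and a drift from critical/emergent toward urgent triage in the later period.
DEFAULT_ATTRIBUTE_PROBS: dict[str, dict] = {
    "pre": {
        "sex": {"female": 0.53, "male": 0.47},
        "age_band": {"teen": 0.10, "young_adult": 0.14, "adult": 0.66, "older_adult": 0.10},
        "mental_health": {"mood": 0.35, "neurosis": 0.15,
                          "alcohol_drug": 0.25, "psychotic_developmental": 0.10},
        "death28": 0.017,
        "pay_assist": 0.215,
        "triage": {1: 0.123, 2: 0.387, 3: 0.419, 4: 0.069, 5: 0.002},
    },
    "post": {
        "sex": {"female": 0.50, "male": 0.50},
        "age_band": {"teen": 0.12, "young_adult": 0.15, "adult": 0.63, "older_adult": 0.10},
        "mental_health": {"mood": 0.40, "neurosis": 0.18,
                          "alcohol_drug": 0.30, "psychotic_developmental": 0.12},
        "death28": 0.011,
        "pay_assist": 0.206,
        "triage": {1: 0.080, 2: 0.330, 3: 0.516, 4: 0.071, 5: 0.003},
    },
}

_PROB_SUM_TOL = 1e-9


def _check_probs(period: str, probs: Mapping) -> None:
    for attr in ("sex", "age_band", "triage"):
        total = sum(probs[attr].values())
        if abs(total - 1.0) > _PROB_SUM_TOL:
            raise ValueError(f"{period} {attr} probabilities sum to {total}, not 1")
    for attr in ("death28", "pay_assist"):
        if not 0 <= probs[attr] <= 1:
            raise ValueError(f"{period} {attr} probability outside [0, 1]")
    for cat, p in probs["mental_health"].items():
        if cat not in MH_CATEGORIES:
            raise ValueError(f"unknown mental-health category {cat!r}")
        if not 0 <= p <= 1:
            raise ValueError(f"{period} mental_health[{cat}] probability outside [0, 1]")


def _draw_dates(rng: np.random.Generator, n: int,
                window: tuple[dt.date, dt.date]) -> list[dt.date]:
    lo, hi = window
    span = (hi - lo).days
    if span < 0:
        raise ValueError("window end precedes start")
    offsets = rng.integers(0, span + 1, size=n)
    return [lo + dt.timedelta(days=int(d)) for d in offsets]


def _draw_categorical(rng: np.random.Generator, n: int, table: Mapping) -> list:
    levels = list(table.keys())
    p = np.asarray([table[k] for k in levels], dtype=float)
    return [levels[i] for i in rng.choice(len(levels), size=n, p=p / p.sum())]


def simulate_episode_table(
    n_pre: int,
    n_post: int,
    attribute_probs: Mapping[str, Mapping] | None = None,
    seed: int = 0,
    pre_window: tuple[dt.date, dt.date] = (dt.date(2016, 1, 1), dt.date(2019, 12, 31)),
    post_window: tuple[dt.date, dt.date] = (dt.date(2020, 1, 1), dt.date(2022, 12, 31)),
) -> list[EpisodeRecord]:
    """Simulate visit-level records with period-dependent attributes.

    Dates are uniform within each period window; attributes are drawn
    independently per record.  Mental-health flags are independent Bernoulli
    draws per category; ``any_mh`` is derived (true iff any flag set).
    """
    if n_pre < 0 or n_post < 0:
        raise ValueError("record counts must be non-negative")
    probs = attribute_probs or DEFAULT_ATTRIBUTE_PROBS
    for period in ("pre", "post"):
        _check_probs(period, probs[period])
    rng = np.random.default_rng(seed)
    records: list[EpisodeRecord] = []
    for period, n, window in (("pre", n_pre, pre_window), ("post", n_post, post_window)):
        if n == 0:
            continue
        p = probs[period]
        dates = _draw_dates(rng, n, window)
        sexes = _draw_categorical(rng, n, p["sex"])
        bands = _draw_categorical(rng, n, p["age_band"])
        ages = [int(rng.integers(AGE_BANDS[b][0], AGE_BANDS[b][1] + 1)) for b in bands]
        flags = {cat: rng.random(n) < p["mental_health"][cat] for cat in p["mental_health"]}
        death = rng.random(n) < p["death28"]
        pay = rng.random(n) < p["pay_assist"]
        triage = _draw_categorical(rng, n, p["triage"])
        for i in range(n):
            mh = frozenset(cat for cat in flags if flags[cat][i])
            records.append(EpisodeRecord(
                attendance_date=dates[i], sex=sexes[i], age=ages[i],
                mental_health=mh, death28=bool(death[i]),
                pay_assist=bool(pay[i]), triage=int(triage[i])))
    records.sort(key=lambda r: r.attendance_date)
    return records
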