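"""Core in-memory containers for monthly count series and population denominators.

A :class:`MonthlyCountSeries` is the dependent variable of the count model:
one row per calendar month, zero-filled, with a 0-based month index ``x_t``
counted from the first month of the study window.  A
:class:`PopulationSeries` holds yearly (or mid-yearly) population anchors for
one sex x age stratum and produces the monthly offset by linear
interpolation between anchors.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PRE = "pre"
POST = "post"

#: columns every monthly series must carry, in canonical order
SERIES_COLUMNS = ["month_index", "year", "month", "count", "period"]


def month_number(year: int, month: int) -> int:
    """Continuous month scale: January of year 0 is 0."""
    return year * 12 + (month - 1)


def month_range(start: tuple[int, int], end: tuple[int, int]) -> pd.DataFrame:
    """All calendar months from ``start`` to ``end`` inclusive, as (year, month) rows."""
    a, b = month_number(*start), month_number(*end)
    if b < a:
        raise ValueError(f"window end {end} precedes start {start}")
    nums = np.arange(a, b + 1)
    return pd.DataFrame({"year": nums // 12, "month": nums % 12 + 1})


@dataclass
class MonthlyCountSeries:
    """Monthly event counts for one subgroup over a contiguous calendar window.

    Parameters
    ----------
    subgroup
        Label of the sex x age-band x condition subgroup.
    data
        One row per month with columns ``month_index`` (0-based, consecutive),
        ``year``, ``month``, ``count`` (non-negative integer) and ``period``
        ("pre" or "post").  An optional ``mu`` column carries the true
        generative mean when the series was simulated.
    meta
        Free-form provenance (seed, generator parameters, config hash).
    """

    subgroup: str
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.data.reset_index(drop=True)
        missing = [c for c in SERIES_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"monthly series missing columns {missing}")
        idx = df["month_index"].to_numpy()
        if len(df) == 0:
            raise ValueError("empty monthly series")
        if not np.array_equal(idx, np.arange(idx[0], idx[0] + len(df))):
            raise ValueError("month_index must be consecutive with no gaps")
        counts = df["count"].to_numpy()
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise ValueError("counts must be non-negative integers")
        bad = set(df["period"]) - {PRE, POST}
        if bad:
            raise ValueError(f"unknown period tags {bad}")
        # month_index and calendar months must advance in lockstep
        cal = df["year"].to_numpy() * 12 + df["month"].to_numpy() - 1
        anchors = cal - idx
        if len(set(anchors)) != 1:
            raise ValueError("month_index is not a consistent offset of the calendar")
        df["count"] = counts.astype(int)
        self.data = df

    @property
    def anchor(self) -> tuple[int, int]:
        """(year, month) corresponding to month_index 0."""
        n = int(self.data["year"].iloc[0] * 12 + self.data["month"].iloc[0] - 1
                - self.data["month_index"].iloc[0])
        return n // 12, n % 12 + 1

    @property
    def pre(self) -> pd.DataFrame:
        return self.data[self.data["period"] == PRE]

    @property
    def post(self) -> pd.DataFrame:
        return self.data[self.data["period"] == POST]

    def to_csv(self, path) -> None:
        """Write the series with a ``#``-comment provenance header."""
        with open(path, "w") as fh:
            fh.write(f"# subgroup={self.subgroup}\n")
            for k, v in sorted(self.meta.items()):
                fh.write(f"# {k}={json.dumps(v, sort_keys=True)}\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "MonthlyCountSeries":
        meta: dict = {}
        subgroup = ""
        skip = 0
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                skip += 1
                key, _, val = line[1:].strip().partition("=")
                if key.strip() == "subgroup":
                    subgroup = val
                else:
                    meta[key.strip()] = json.loads(val)
        df = pd.read_csv(path, skiprows=skip)
        return cls(subgroup=subgroup, data=df, meta=meta)


@dataclass
class PopulationSeries:
    """Population denominators for one stratum, anchored yearly or mid-yearly.

    ``anchors`` has columns ``year``, ``population``, ``anchor_type``
    ("year" places the anchor at January 1, "mid" at July 1).  Populations
    must be strictly positive.
    """

    stratum: str
    anchors: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.anchors.reset_index(drop=True).copy()
        if "anchor_type" not in df.columns:
            df["anchor_type"] = "year"
        if not set(df["anchor_type"]) <= {"year", "mid"}:
            raise ValueError("anchor_type must be 'year' or 'mid'")
        if (df["population"] <= 0).any():
            raise ValueError(f"non-positive population anchor in stratum {self.stratum!r}")
        if len(df) == 0:
            raise ValueError("population series needs at least one anchor")
        self.anchors = df

    def _anchor_times(self) -> tuple[np.ndarray, np.ndarray]:
        t = (self.anchors["year"].to_numpy() * 12
             + np.where(self.anchors["anchor_type"].to_numpy() == "mid", 6, 0))
        order = np.argsort(t)
        return t[order].astype(float), self.anchors["population"].to_numpy()[order].astype(float)

    def monthly(self, start: tuple[int, int], end: tuple[int, int]) -> pd.DataFrame:
        """Piecewise-linear monthly population over the window (inclusive).

        Anchor months reproduce their anchor values exactly; beyond the
        outermost anchors the series is extrapolated as a constant.  A single
        anchor yields a constant series (logged, not an error).
        """
        t, p = self._anchor_times()
        if len(t) == 1:
            logger.warning("stratum %r has a single population anchor; using constant %g",
                           self.stratum, p[0])
        months = month_range(start, end)
        times = months["year"].to_numpy() * 12 + months["month"].to_numpy() - 1
        months["population"] = np.interp(times.astype(float), t, p)
        return months

    def yearly_constant(self, start: tuple[int, int], end: tuple[int, int]) -> pd.DataFrame:
        """Monthly population using each year's anchor for all 12 of its months.

        Years without an anchor fall back to the interpolated January value.
        """
        months = month_range(start, end)
        by_year = {int(r.year): float(r.population) for r in self.anchors.itertuples()}
        t, p = self._anchor_times()
        jan = {y: float(np.interp(y * 12, t, p)) for y in months["year"].unique()}
        months["population"] = [by_year.get(y, jan[y]) for y in months["year"]]
        return months
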