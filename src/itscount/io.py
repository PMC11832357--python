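"""Reading, validating and aggregating episode-level and population inputs.

Episode files are plain CSV with ISO-8601 dates; column names are remappable
through a *dialect* mapping so exports from different record systems can be
read without editing the file.  Parsing is strict: every malformed row is
collected with its line number and reported together — rows are never
silently dropped.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .series import POST, PRE, MonthlyCountSeries, PopulationSeries, month_number, month_range

__all__ = [
    "EpisodeRecord",
    "AGE_BANDS",
    "MH_CATEGORIES",
    "assign_age_band",
    "read_episodes",
    "write_episodes",
    "read_population",
    "aggregate_monthly",
    "interpolate_population",
    "subgroup_predicate",
]

#: co-occurring mental-health diagnosis categories (a configurable vocabulary;
#: upstream code->category mapping is out of scope here)
MH_CATEGORIES = ("mood", "neurosis", "alcohol_drug", "psychotic_developmental")

#: inclusive age bands; everything else is out_of_band
AGE_BANDS: dict[str, tuple[int, int]] = {
    "teen": (12, 17),
    "young_adult": (18, 24),
    "adult": (25, 64),
    "older_adult": (65, 84),
}

OUT_OF_BAND = "out_of_band"

_SEXES = ("female", "male")


@dataclass(frozen=True)
class EpisodeRecord:
    """One emergency-department visit: the atomic input of the pipeline."""

    attendance_date: dt.date
    sex: str
    age: int
    mental_health: frozenset = frozenset()
    death28: bool = False
    pay_assist: bool = False
    triage: int = 3

    def __post_init__(self) -> None:
        if self.sex not in _SEXES:
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age < 0:
            raise ValueError("age must be >= 0")
        if self.triage not in (1, 2, 3, 4, 5):
            raise ValueError(f"triage must be in 1..5, got {self.triage}")
        bad = set(self.mental_health) - set(MH_CATEGORIES)
        if bad:
            raise ValueError(f"unknown mental-health categories {bad}")

    @property
    def any_mh(self) -> bool:
        """True iff any co-occurring mental-health flag is set."""
        return len(self.mental_health) > 0

    @property
    def age_band(self) -> str:
        return assign_age_band(self.age)


def assign_age_band(age: int) -> str:
    """Map integer age (years) to its analysis band; boundaries inclusive.

    Ages below 12 or above 84 return ``out_of_band`` — a value, not an error.
    """
    if age < 0:
        raise ValueError("age must be >= 0")
    for band, (lo, hi) in AGE_BANDS.items():
        if lo <= age <= hi:
            return band
    return OUT_OF_BAND


_COLUMNS = ["attendance_date", "sex", "age", "mental_health",
            "death28", "pay_assist", "triage"]

_BOOL_MAP = {"true": True, "false": False, "1": True, "0": False,
             "yes": True, "no": False}


def _parse_row(row: Mapping[str, str]) -> EpisodeRecord:
    date = dt.date.fromisoformat(str(row["attendance_date"]).strip())
    raw_mh = row.get("mental_health", "")
    raw_mh = "" if raw_mh is None or (isinstance(raw_mh, float) and np.isnan(raw_mh)) else str(raw_mh)
    flags = frozenset(tok.strip() for tok in raw_mh.split(";") if tok.strip())

    def as_bool(key: str) -> bool:
        val = str(row.get(key, "false")).strip().lower()
        if val not in _BOOL_MAP:
            raise ValueError(f"{key} value {row.get(key)!r} is not boolean")
        return _BOOL_MAP[val]

    return EpisodeRecord(
        attendance_date=date,
        sex=str(row["sex"]).strip().lower(),
        age=int(row["age"]),
        mental_health=flags,
        death28=as_bool("death28"),
        pay_assist=as_bool("pay_assist"),
        triage=int(row["triage"]),
    )


def read_episodes(path, dialect: Mapping[str, str] | None = None) -> list[EpisodeRecord]:
    """Read an episode CSV; hard-fail with a line-numbered report on any bad row.

    ``dialect`` maps canonical field names to the column names used in the
    file (e.g. ``{"attendance_date": "adate"}``); unmapped fields use their
    canonical names.
    """
    rename = {v: k for k, v in (dialect or {}).items()}
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df = df.rename(columns=rename)
    missing = [c for c in ("attendance_date", "sex", "age", "triage") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: header missing required columns {missing}")
    records: list[EpisodeRecord] = []
    errors: list[str] = []
    for i, row in enumerate(df.to_dict("records")):
        try:
            records.append(_parse_row(row))
        except (ValueError, KeyError) as exc:  # line 1 is the header
            errors.append(f"line {i + 2}: {exc}")
    if errors:
        head = "\n  ".join(errors[:20])
        more = f"\n  ... and {len(errors) - 20} more" if len(errors) > 20 else ""
        raise ValueError(f"{path}: {len(errors)} unparseable row(s):\n  {head}{more}")
    return records


def write_episodes(records: Iterable[EpisodeRecord], path) -> None:
    rows = [{
        "attendance_date": r.attendance_date.isoformat(),
        "sex": r.sex,
        "age": r.age,
        "mental_health": ";".join(sorted(r.mental_health)),
        "death28": str(r.death28).lower(),
        "pay_assist": str(r.pay_assist).lower(),
        "triage": r.triage,
    } for r in records]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_population(path) -> dict[str, PopulationSeries]:
    """Read a population CSV (stratum, year, population, anchor_type) per stratum."""
    df = pd.read_csv(path)
    required = {"stratum", "year", "population"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: population file needs columns {sorted(required)}")
    if "anchor_type" not in df.columns:
        df["anchor_type"] = "year"
    return {
        str(name): PopulationSeries(stratum=str(name), anchors=grp[["year", "population", "anchor_type"]])
        for name, grp in df.groupby("stratum")
    }


def subgroup_predicate(sex: str | None = None, band: str | None = None,
                       condition: str | None = None) -> Callable[[EpisodeRecord], bool]:
    """Build an episode filter for a sex x age-band x condition subgroup.

    ``condition`` is ``None`` (all episodes), ``"any_mh"`` or one of the
    mental-health categories.
    """
    if sex is not None and sex not in _SEXES:
        raise ValueError(f"unknown sex {sex!r}")
    if band is not None and band not in AGE_BANDS and band != OUT_OF_BAND:
        raise ValueError(f"unknown age band {band!r}")
    if condition is not None and condition != "any_mh" and condition not in MH_CATEGORIES:
        raise ValueError(f"unknown condition {condition!r}")

    def predicate(r: EpisodeRecord) -> bool:
        if sex is not None and r.sex != sex:
            return False
        if band is not None and r.age_band != band:
            return False
        if condition == "any_mh":
            return r.any_mh
        if condition is not None:
            return condition in r.mental_health
        return True

    return predicate


def aggregate_monthly(
    episodes: Iterable[EpisodeRecord],
    window: tuple[tuple[int, int], tuple[int, int]],
    intervention: tuple[int, int],
    subgroup: str = "all",
    predicate: Callable[[EpisodeRecord], bool] | None = None,
) -> MonthlyCountSeries:
    """Count filtered episodes per calendar month over the window, zero-filled.

    Months before the ``intervention`` month are tagged "pre", the rest
    "post".  Episodes outside the window are ignored.
    """
    start, end = window
    months = month_range(start, end)
    if len(months) == 0:
        raise ValueError("empty aggregation window")
    a = month_number(*start)
    counts = np.zeros(len(months), dtype=int)
    for r in episodes:
        if predicate is not None and not predicate(r):
            continue
        m = month_number(r.attendance_date.year, r.attendance_date.month) - a
        if 0 <= m < len(months):
            counts[m] += 1
    months["month_index"] = np.arange(len(months))
    months["count"] = counts
    i0 = month_number(*intervention) - a
    months["period"] = np.where(months["month_index"] < i0, PRE, POST)
    return MonthlyCountSeries(subgroup=subgroup,
                              data=months[["month_index", "year", "month", "count", "period"]])


def interpolate_population(series: PopulationSeries, start: tuple[int, int],
                           end: tuple[int, int]) -> pd.DataFrame:
    """Monthly population by linear interpolation between anchors.

    Yearly anchors sit at January, mid-year anchors at July; beyond the
    outermost anchors the value is held constant.  See
    :meth:`PopulationSeries.monthly`.
    """
    return series.monthly(start, end)
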