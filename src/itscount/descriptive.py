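"""Before/during comparison of episode characteristics.

Binary attributes (sex, 28-day death, any mental-health diagnosis,
public-assistance pay code) are compared with Fisher's exact test on the
2x2 period-by-level table; ordinal/continuous attributes (age in years,
triage category) with the Mann-Whitney U test on raw values.  Percentages
are recomputed from counts and displayed with half-up rounding; full
precision is retained alongside.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

from .io import EpisodeRecord

logger = logging.getLogger(__name__)

__all__ = [
    "FisherResult",
    "MannWhitneyResult",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "CharacteristicsTable",
    "build_characteristics_table",
    "percent",
    "period_change",
]

# relative slack when collecting tables "as or more extreme" by probability;
# guards against ties lost to floating point (same convention as common
# exact-test implementations)
_EXTREME_EPS = 1e-7


class FisherResult(NamedTuple):
    odds_ratio: float
    p_value: float
    flagged: bool = False


class MannWhitneyResult(NamedTuple):
    u_statistic: float
    p_value: float
    flagged: bool = False


def _log_hypergeom_pmf(support: np.ndarray, total: int, row1: int, col1: int) -> np.ndarray:
    """log P(a) for the hypergeometric count in cell (1,1), via log-gamma.

    Exact to near machine precision for cells of order 1e4 and beyond, where
    factorial arithmetic would overflow.
    """
    def logc(n, k):
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    return logc(row1, support) + logc(total - row1, col1 - support) - logc(total, col1)


def fisher_two_sided_pvalues(row1_total: int, row2_total: int,
                             col1_total: int) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Fisher p for every admissible (1,1) cell at fixed margins.

    Returns ``(support, p_values)``: for each count ``a`` in the support of
    the hypergeometric law with these margins, the sum of probabilities of
    all tables as or more extreme than ``a`` by table probability.
    Vectorized over the whole support so exhaustive sweeps stay cheap.
    """
    support = np.arange(max(0, col1_total - row2_total),
                        min(row1_total, col1_total) + 1)
    logp = _log_hypergeom_pmf(support, row1_total + row2_total, row1_total, col1_total)
    # normalise in probability space for a numerically clean tail sum
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    order = np.argsort(prob, kind="stable")
    csum = np.cumsum(prob[order])
    ranks = np.searchsorted(prob[order], prob * (1 + _EXTREME_EPS), side="right") - 1
    pvals = np.minimum(csum[ranks], 1.0)
    return support, pvals


def fisher_exact_2x2(a: int, b: int, c: int, d: int,
                     odds_ratio: bool = True) -> FisherResult:
    """Fisher's exact test for the 2x2 table [[a, b], [c, d]].

    The two-sided p-value sums hypergeometric probabilities of all tables
    with the observed margins whose probability does not exceed the observed
    table's (probability-ordering rule), computed with log-gamma arithmetic
    so cells of order 1e4 remain exact.  The reported odds ratio is the
    conditional maximum-likelihood estimate (skipped when
    ``odds_ratio=False``).  A zero margin makes the table degenerate:
    p = 1 by convention, flagged.
    """
    cells = (a, b, c, d)
    if any(x < 0 or x != int(x) for x in cells):
        raise ValueError(f"cell counts must be non-negative integers, got {cells}")
    a, b, c, d = (int(x) for x in cells)
    r1, r2, c1, c2 = a + b, c + d, a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        logger.warning("degenerate 2x2 table %s (zero margin); p = 1 by convention", cells)
        return FisherResult(odds_ratio=float("nan"), p_value=1.0, flagged=True)
    support, pvals = fisher_two_sided_pvalues(r1, r2, c1)
    p_value = float(pvals[np.searchsorted(support, a)])
    oddsr = float("nan")
    if odds_ratio:
        oddsr = float(stats.contingency.odds_ratio([[a, b], [c, d]],
                                                   kind="conditional").statistic)
    return FisherResult(odds_ratio=oddsr, p_value=p_value)


def mann_whitney_u(sample_x: Sequence[float], sample_y: Sequence[float]) -> MannWhitneyResult:
    """Mann-Whitney U with midrank ties.

    Exact enumeration when both samples have <= 8 observations and the pooled
    data has no ties; otherwise the tie-corrected normal approximation with
    continuity correction.  Identical pooled values give p = 1, flagged.
    """
    x = np.asarray(sample_x, dtype=float)
    y = np.asarray(sample_y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        logger.warning("all %d pooled values identical; p = 1 by convention", len(pooled))
        return MannWhitneyResult(u_statistic=len(x) * len(y) / 2.0, p_value=1.0, flagged=True)
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(x) <= 8 and len(y) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return MannWhitneyResult(u_statistic=float(res.statistic), p_value=float(res.pvalue))


def percent(count: int, total: int, digits: int = 0) -> float:
    """count/total as a percentage rounded half-up to ``digits`` decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    q = Decimal(1).scaleb(-digits)
    return float((Decimal(count) * 100 / Decimal(total)).quantize(q, rounding=ROUND_HALF_UP))


def period_change(pre_total: int, post_total: int) -> dict:
    """Overall N, absolute change and percent change between periods."""
    increase = post_total - pre_total
    return {
        "overall_n": pre_total + post_total,
        "absolute_increase": increase,
        "percent_increase": percent(increase, pre_total, digits=1),
    }


@dataclass
class CharacteristicsTable:
    """Tidy before/during comparison with one row per attribute level."""

    data: pd.DataFrame  # attribute, level, pre_n, pre_pct, post_n, post_pct, test, p_value
    pre_total: int
    post_total: int

    def __post_init__(self) -> None:
        for attr, grp in self.data.groupby("attribute"):
            if grp["pre_n"].notna().all():  # categorical rows partition the period
                if grp["pre_n"].sum() != self.pre_total or grp["post_n"].sum() != self.post_total:
                    raise ValueError(f"{attr}: level counts do not sum to period totals")

    @property
    def summary(self) -> dict:
        return period_change(self.pre_total, self.post_total)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)

    def to_text(self) -> str:
        s = self.summary
        lines = [
            f"Episodes: pre {self.pre_total}, post {self.post_total} "
            f"(overall {s['overall_n']}; change {s['absolute_increase']:+d}, "
            f"{s['percent_increase']:+.1f}%)",
            "",
            f"{'attribute':<22}{'level':<26}{'pre n (%)':>16}{'post n (%)':>16}"
            f"{'test':>14}{'p':>10}",
        ]
        for _, r in self.data.iterrows():
            pre = f"{r.pre_n} ({r.pre_pct_display})" if pd.notna(r.pre_n) else f"{r.pre_stat}"
            post = f"{r.post_n} ({r.post_pct_display})" if pd.notna(r.post_n) else f"{r.post_stat}"
            p = "" if pd.isna(r.p_value) else (f"{r.p_value:.3f}" if r.p_value >= 0.001 else "<.001")
            lines.append(f"{r.attribute:<22}{str(r.level):<26}{pre:>16}{post:>16}"
                         f"{r.test:>14}{p:>10}")
        return "\n".join(lines)


_BINARY_ATTRS = [
    ("sex", lambda r: r.sex, ["female", "male"]),
    ("death28", lambda r: "yes" if r.death28 else "no", ["no", "yes"]),
    ("any_mh", lambda r: "yes" if r.any_mh else "no", ["no", "yes"]),
    ("pay_assist", lambda r: "yes" if r.pay_assist else "no", ["no", "yes"]),
]


def build_characteristics_table(episodes: Iterable[EpisodeRecord],
                                split_date: dt.date) -> CharacteristicsTable:
    """Tabulate and test attribute distributions before vs from ``split_date``.

    Episodes dated strictly before ``split_date`` form the pre period.  Raises
    if either period is empty.
    """
    records = list(episodes)
    pre = [r for r in records if r.attendance_date < split_date]
    post = [r for r in records if r.attendance_date >= split_date]
    if not pre or not post:
        raise ValueError(
            f"both periods need episodes (pre={len(pre)}, post={len(post)}); "
            "is the split date inside the data range?")
    rows = []

    def median_iqr(vals: np.ndarray) -> str:
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        return f"{med:g} ({q3 - q1:g})"

    # age: continuous, Mann-Whitney on raw years
    age_pre = np.array([r.age for r in pre])
    age_post = np.array([r.age for r in post])
    mw = mann_whitney_u(age_pre, age_post)
    rows.append(dict(attribute="age", level="median (IQR)",
                     pre_n=np.nan, pre_pct=np.nan, pre_pct_display=np.nan,
                     post_n=np.nan, post_pct=np.nan, post_pct_display=np.nan,
                     pre_stat=median_iqr(age_pre), post_stat=median_iqr(age_post),
                     test="mann_whitney", p_value=mw.p_value))

    for attr, getter, levels in _BINARY_ATTRS:
        pre_counts = [sum(1 for r in pre if getter(r) == lv) for lv in levels]
        post_counts = [sum(1 for r in post if getter(r) == lv) for lv in levels]
        fisher = fisher_exact_2x2(pre_counts[0], pre_counts[1],
                                  post_counts[0], post_counts[1])
        for lv, pn, qn in zip(levels, pre_counts, post_counts):
            rows.append(dict(attribute=attr, level=lv,
                             pre_n=pn, pre_pct=100 * pn / len(pre),
                             pre_pct_display=percent(pn, len(pre)),
                             post_n=qn, post_pct=100 * qn / len(post),
                             post_pct_display=percent(qn, len(post)),
                             pre_stat="", post_stat="",
                             test="fisher_exact", p_value=fisher.p_value))

    # triage: ordinal codes compared by Mann-Whitney with midranks
    tri_pre = np.array([r.triage for r in pre])
    tri_post = np.array([r.triage for r in post])
    mw = mann_whitney_u(tri_pre, tri_post)
    for lv in (1, 2, 3, 4, 5):
        pn, qn = int((tri_pre == lv).sum()), int((tri_post == lv).sum())
        rows.append(dict(attribute="triage", level=lv,
                         pre_n=pn, pre_pct=100 * pn / len(pre),
                         pre_pct_display=percent(pn, len(pre)),
                         post_n=qn, post_pct=100 * qn / len(post),
                         post_pct_display=percent(qn, len(post)),
                         pre_stat="", post_stat="",
                         test="mann_whitney", p_value=mw.p_value))

    return CharacteristicsTable(data=pd.DataFrame(rows),
                                pre_total=len(pre), post_total=len(post))
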