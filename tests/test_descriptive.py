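"""Exact tests and characteristics-table construction.

Oracles: full hypergeometric enumeration (via scipy's hypergeom pmf, summed
directly) for Fisher's test; exhaustive rank-arrangement enumeration for
Mann-Whitney.
"""

import datetime as dt
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from itscount.descriptive import (build_characteristics_table, fisher_exact_2x2,
                                  fisher_two_sided_pvalues, mann_whitney_u,
                                  percent, period_change)
from itscount.simulate import DEFAULT_ATTRIBUTE_PROBS, simulate_episode_table

from conftest import make_episode


def fisher_oracle(a, b, c, d):
    """Two-sided p by direct hypergeometric enumeration (probability ordering)."""
    r1, r2, c1 = a + b, c + d, a + c
    support = np.arange(max(0, c1 - r2), min(r1, c1) + 1)
    pmf = stats.hypergeom.pmf(support, r1 + r2, r1, c1)
    p_obs = pmf[support == a][0]
    return pmf[pmf <= p_obs * (1 + 1e-7)].sum()


class TestFisherExact:
    def test_small_table_against_enumeration(self):
        # classic tea-tasting-sized table; oracle-enumerated value
        assert fisher_exact_2x2(1, 9, 11, 3).p_value == pytest.approx(
            fisher_oracle(1, 9, 11, 3), rel=1e-10)
        assert fisher_exact_2x2(1, 9, 11, 3).p_value == pytest.approx(0.002759, abs=1e-6)

    def test_no_association_large_table(self):
        res = fisher_exact_2x2(5000, 5000, 5000, 5000)
        assert res.p_value > 0.9

    def test_large_unbalanced_table_significant(self):
        # period x sex table at cohort scale: strongly significant
        assert fisher_exact_2x2(8184, 7175, 8258, 8276).p_value < 0.001

    def test_large_cells_match_scipy_to_high_precision(self):
        ours = fisher_exact_2x2(8184, 7175, 8258, 8276).p_value
        ref = stats.fisher_exact([[8184, 7175], [8258, 8276]]).pvalue
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_zero_margin_flagged(self):
        res = fisher_exact_2x2(0, 0, 5, 7)
        assert res.p_value == 1.0 and res.flagged

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2(-1, 2, 3, 4)

    def test_conditional_odds_ratio_reported(self):
        res = fisher_exact_2x2(7, 3, 2, 8)
        ref = stats.contingency.odds_ratio([[7, 3], [2, 8]], kind="conditional")
        assert res.odds_ratio == pytest.approx(ref.statistic)

    @given(st.tuples(*[st.integers(0, 150)] * 4))
    @settings(derandomize=True, max_examples=150, deadline=None)
    def test_matches_scipy_on_random_tables(self, cells):
        a, b, c, d = cells
        if min(a + b, c + d, a + c, b + d) == 0:
            return
        ours = fisher_exact_2x2(a, b, c, d, odds_ratio=False).p_value
        ref = stats.fisher_exact([[a, b], [c, d]]).pvalue
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-14)

    def test_exhaustive_small_margins_vs_enumeration(self):
        """Every table with margins <= 12 agrees with direct enumeration."""
        for r1, r2 in itertools.product(range(1, 13), repeat=2):
            for c1 in range(max(1, r1 + r2 - 12), min(12, r1 + r2 - 1) + 1):
                support, pvals = fisher_two_sided_pvalues(r1, r2, c1)
                for a, p in zip(support, pvals):
                    assert p == pytest.approx(
                        fisher_oracle(a, r1 - a, c1 - a, r2 - c1 + a), rel=1e-9)


def mw_exact_oracle(x, y):
    """Two-sided exact p by enumerating every allocation of pooled ranks."""
    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        us.append(ranks[list(combo)].sum() - n1 * (n1 + 1) / 2)
    us = np.array(us)
    mid = n1 * (len(y)) / 2
    return np.mean(np.abs(us - mid) >= abs(u_obs - mid) - 1e-9)


class TestMannWhitney:
    def test_tiny_samples_exact(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.u_statistic == 0
        assert res.p_value == pytest.approx(1 / 3)

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_all_identical_values_flagged(self):
        res = mann_whitney_u([5, 5, 5], [5, 5])
        assert res.p_value == 1.0 and res.flagged

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_exact_path_matches_enumeration(self):
        x, y = np.array([1.0, 4.0, 5.0, 9.0]), np.array([2.0, 3.0, 7.0, 8.0])
        assert mann_whitney_u(x, y).p_value == pytest.approx(mw_exact_oracle(x, y))

    @given(st.lists(st.integers(-50, 50), min_size=5, max_size=40),
           st.lists(st.integers(-50, 50), min_size=5, max_size=40))
    @settings(derandomize=True, max_examples=80, deadline=None)
    def test_invariant_under_monotone_transform(self, xs, ys):
        """U and p depend only on ranks, so any strictly increasing map is neutral."""
        x, y = np.array(xs, float), np.array(ys, float)
        base = mann_whitney_u(x, y)
        f = lambda v: np.exp(v / 20.0) + 3 * v  # strictly increasing
        transformed = mann_whitney_u(f(x), f(y))
        assert transformed.u_statistic == base.u_statistic
        assert transformed.p_value == pytest.approx(base.p_value, rel=1e-12)

    def test_power_under_large_shift(self):
        rng = np.random.default_rng(0)
        hits = 0
        for _ in range(50):
            x = rng.normal(0, 1, 60)
            y = rng.normal(3, 1, 60)
            hits += mann_whitney_u(x, y).p_value < 0.001
        assert hits >= 50 * 0.99


class TestPercentages:
    @pytest.mark.parametrize("count,total,expected", [
        (8184, 15359, 53), (6429, 15359, 42), (29, 15359, 0), (4878, 16534, 30),
    ])
    def test_half_up_integer_display(self, count, total, expected):
        assert percent(count, total) == expected

    def test_exact_half_rounds_up(self):
        assert percent(1, 8) == 13  # 12.5 -> 13 under half-up

    def test_period_change(self):
        change = period_change(15359, 16534)
        assert change == {"overall_n": 31893, "absolute_increase": 1175,
                          "percent_increase": 7.7}


class TestCharacteristicsTable:
    SPLIT = dt.date(2020, 1, 1)

    def hand_fixture(self):
        d = dt.date
        return [
            make_episode(d(2016, 2, 1), "female", 30, {"mood"}, triage=2),
            make_episode(d(2017, 5, 9), "male", 45, set(), death28=True, triage=1),
            make_episode(d(2018, 7, 3), "female", 15, {"neurosis"}, triage=3),
            make_episode(d(2019, 11, 30), "male", 70, set(), pay_assist=True, triage=3),
            make_episode(d(2019, 12, 31), "female", 22, {"alcohol_drug"}, triage=4),
            make_episode(d(2020, 1, 1), "male", 33, {"mood", "alcohol_drug"}, triage=3),
            make_episode(d(2021, 3, 15), "female", 28, set(), triage=2),
            make_episode(d(2021, 8, 8), "male", 55, {"psychotic_developmental"}, triage=3),
            make_episode(d(2022, 6, 20), "female", 80, set(), pay_assist=True, triage=5),
            make_episode(d(2022, 12, 31), "male", 19, {"mood"}, death28=True, triage=2),
        ]

    def test_counts_match_hand_tally(self):
        table = build_characteristics_table(self.hand_fixture(), self.SPLIT)
        assert table.pre_total == 5 and table.post_total == 5
        df = table.data.set_index(["attribute", "level"])
        assert df.loc[("sex", "female"), "pre_n"] == 3
        assert df.loc[("sex", "male"), "post_n"] == 3
        assert df.loc[("death28", "yes"), "pre_n"] == 1
        assert df.loc[("any_mh", "yes"), "post_n"] == 3
        assert df.loc[("pay_assist", "yes"), "post_n"] == 1
        assert df.loc[("triage", 3), "pre_n"] == 2

    def test_totals_conserved(self):
        table = build_characteristics_table(self.hand_fixture(), self.SPLIT)
        assert table.summary["overall_n"] == 10
        for attr in ("sex", "death28", "any_mh", "pay_assist", "triage"):
            grp = table.data[table.data["attribute"] == attr]
            assert grp["pre_n"].sum() == table.pre_total
            assert grp["post_n"].sum() == table.post_total

    def test_percent_columns_recompute_from_counts(self):
        table = build_characteristics_table(self.hand_fixture(), self.SPLIT)
        cat = table.data[table.data["pre_n"].notna()]
        assert np.allclose(cat["pre_pct"], 100 * cat["pre_n"] / table.pre_total)

    def test_empty_period_rejected(self):
        pre_only = [make_episode(dt.date(2016, 1, 1))]
        with pytest.raises(ValueError, match="both periods"):
            build_characteristics_table(pre_only, self.SPLIT)

    def test_null_calibration_of_fisher_rows(self):
        """Identical attribute probabilities both periods: ~uniform p-values."""
        probs = {"pre": DEFAULT_ATTRIBUTE_PROBS["pre"],
                 "post": DEFAULT_ATTRIBUTE_PROBS["pre"]}
        rejections = 0
        n_seeds = 100
        for seed in range(n_seeds):
            records = simulate_episode_table(400, 400, attribute_probs=probs, seed=seed)
            table = build_characteristics_table(records, self.SPLIT)
            p_sex = table.data.query("attribute == 'sex'")["p_value"].iloc[0]
            rejections += p_sex < 0.05
        # Fisher's test is exact (conservative): level at most ~5% plus noise
        assert rejections / n_seeds <= 0.10
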