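"""Nonparametric comparison battery: summaries, tests, cohort plan."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from roimeth.errors import ValidationError
from roimeth.stats import (
    compare_groups,
    mann_whitney_u,
    median_iqr,
    results_to_frame,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# independent enumeration oracles
# ---------------------------------------------------------------------------

def mwu_enumeration_p(x, y):
    """Two-sided exact Mann-Whitney p by enumerating all label assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    ranks = {}
    for v in pooled:
        ranks[v] = sum(1 for w in pooled if w < v) + 1  # tie-free midrank
    u_obs = sum(ranks[v] for v in x) - n1 * (n1 + 1) / 2
    us = []
    for combo in itertools.combinations(range(len(pooled)), n1):
        r = sum(ranks[pooled[i]] for i in combo)
        us.append(r - n1 * (n1 + 1) / 2)
    cdf = sum(1 for u in us if u <= u_obs) / len(us)
    sf = sum(1 for u in us if u >= u_obs) / len(us)
    return min(1.0, 2.0 * min(cdf, sf))


def wilcoxon_enumeration_p(diffs):
    """Two-sided exact signed-rank p by enumerating all 2^n sign patterns."""
    d = [v for v in diffs if v != 0]
    n = len(d)
    ranks = [sum(1 for w in d if abs(w) < abs(v)) + 1 for v in d]
    t_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    ts = []
    for signs in itertools.product([0, 1], repeat=n):
        ts.append(sum(r for r, s in zip(ranks, signs) if s))
    cdf = sum(1 for t in ts if t <= t_obs) / len(ts)
    sf = sum(1 for t in ts if t >= t_obs) / len(ts)
    return min(1.0, 2.0 * min(cdf, sf))


class TestMedianIqr:
    def test_linear_rule_odd_n(self):
        s = median_iqr([1, 2, 3, 4, 5])
        assert (s.median, s.q1, s.q3) == (3.0, 2.0, 4.0)

    def test_weibull_rule_differs_for_small_n(self):
        s = median_iqr([1, 2, 3, 4, 5], rule="weibull")
        assert (s.median, s.q1, s.q3) == (3.0, 1.5, 4.5)

    def test_single_value(self):
        s = median_iqr([7])
        assert s.median == s.q1 == s.q3 == 7.0 and s.n == 1

    def test_all_equal(self):
        s = median_iqr([2.5] * 6)
        assert s.median == s.q1 == s.q3 == 2.5

    def test_missing_dropped_then_empty_rejected(self):
        s = median_iqr([np.nan, 4.0, np.nan])
        assert s.median == 4.0 and s.n == 1
        with pytest.raises(ValidationError):
            median_iqr([np.nan])

    def test_quartiles_ordered(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = median_iqr(rng.normal(size=rng.integers(1, 30)))
            assert s.q1 <= s.median <= s.q3


class TestMannWhitney:
    def test_separated_groups_exact(self):
        r = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.1)
        assert r.method == "exact"

    def test_single_observations(self):
        assert mann_whitney_u([1], [2]).p_value == 1.0

    def test_identical_samples_p_one(self):
        assert mann_whitney_u([1, 2, 3], [1, 2, 3]).p_value == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for n1, n2 in [(2, 3), (3, 3), (4, 5), (6, 6)]:
            for _ in range(5):
                x = rng.normal(size=n1)
                y = rng.normal(size=n2)
                r = mann_whitney_u(x, y, mode="exact")
                assert r.p_value == pytest.approx(mwu_enumeration_p(x, y))

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            x = rng.normal(size=7)
            y = rng.normal(size=9)
            assert mann_whitney_u(x, y).p_value == pytest.approx(
                mann_whitney_u(y, x).p_value
            )

    def test_exact_approximate_agreement_tie_free(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            p_exact = mann_whitney_u(x, y, mode="exact").p_value
            p_approx = mann_whitney_u(x, y, mode="approximate").p_value
            assert abs(p_exact - p_approx) < 0.01

    def test_ties_fall_back_to_approximation(self):
        r = mann_whitney_u([1, 1, 2], [1, 2, 2])
        assert r.method == "approximate"
        assert 0.0 < r.p_value <= 1.0


class TestWilcoxon:
    def test_all_positive_small(self):
        r = wilcoxon_signed_rank([1, 2, 3])
        assert r.statistic == 0.0
        assert r.p_value == pytest.approx(0.25)
        assert r.method == "exact"

    def test_perfect_symmetry(self):
        assert wilcoxon_signed_rank([1, -1]).p_value == 1.0

    def test_all_zero_differences_degenerate(self):
        r = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert r.degenerate and r.p_value == 1.0

    def test_zeros_dropped_before_ranking(self):
        r1 = wilcoxon_signed_rank([0.0, 1.0, 2.0, 3.0])
        r2 = wilcoxon_signed_rank([1.0, 2.0, 3.0])
        assert r1.p_value == r2.p_value and r1.statistic == r2.statistic

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank([])

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(8)
        for n in (3, 5, 8, 10):
            for _ in range(5):
                d = rng.normal(size=n)
                r = wilcoxon_signed_rank(d, mode="exact")
                assert r.p_value == pytest.approx(wilcoxon_enumeration_p(d))

    def test_sign_flip_symmetry(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            d = rng.normal(size=15)
            assert wilcoxon_signed_rank(d).p_value == pytest.approx(
                wilcoxon_signed_rank(-d).p_value
            )

    def test_exact_approximate_agreement_tie_free(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            d = rng.normal(size=12)
            p_exact = wilcoxon_signed_rank(d, mode="exact").p_value
            p_approx = wilcoxon_signed_rank(d, mode="approximate").p_value
            assert abs(p_exact - p_approx) < 0.02


def _design():
    rows = [("MC1", "MC", ""), ("MC2", "MC", ""), ("MC3", "MC", ""),
            ("HC1", "HC", "")]
    for i in range(1, 6):
        rows.append((f"P{i}-GBM1", "GBM1", f"P{i}"))
        rows.append((f"P{i}-GBM2", "GBM2", f"P{i}"))
    return pd.DataFrame(rows, columns=["sample_id", "group", "pair_id"])


def _measures(design, measure="M1", rng_seed=0, skip=()):
    rng = np.random.default_rng(rng_seed)
    rows = []
    for r in design.itertuples():
        if r.sample_id in skip:
            continue
        rows.append((r.sample_id, measure, float(rng.normal())))
    return pd.DataFrame(rows, columns=["sample_id", "measure", "value"])


class TestCompareGroups:
    def test_full_plan_per_measure(self):
        design = _design()
        results = compare_groups(_measures(design), design)
        comparisons = {(r.comparison, r.test) for r in results}
        assert comparisons == {
            ("MC vs GBM1", "Mann-Whitney U"),
            ("MC vs GBM2", "Mann-Whitney U"),
            ("GBM1 vs GBM2", "Wilcoxon signed-rank"),
        }

    def test_control_group_auto_prefers_mc_with_data(self):
        design = _design()
        measures = _measures(design, skip=("HC1",))
        results = compare_groups(measures, design)
        assert all(r.comparison.startswith(("MC", "GBM")) for r in results)
        # with MC values absent, HC becomes the control
        measures_hc = _measures(design, skip=("MC1", "MC2", "MC3"))
        results_hc = compare_groups(measures_hc, design)
        assert any(r.comparison == "HC vs GBM1" for r in results_hc)

    def test_pairwise_complete_rule(self):
        design = _design()
        measures = _measures(design, skip=("P3-GBM2",))
        (paired,) = [r for r in compare_groups(measures, design)
                     if r.test == "Wilcoxon signed-rank"]
        assert paired.n1 == paired.n2 == 4  # pair P3 excluded

    def test_unmatched_pair_rejected(self):
        design = _design()
        design = design[design["sample_id"] != "P2-GBM2"]  # partner missing
        measures = _measures(design)
        with pytest.raises(ValidationError, match="P2"):
            compare_groups(measures, design)

    def test_sample_without_pair_id_rejected(self):
        design = _design()
        design.loc[design["sample_id"] == "P1-GBM1", "pair_id"] = ""
        with pytest.raises(ValidationError, match="P1-GBM1"):
            compare_groups(_measures(design), design)

    def test_unknown_sample_rejected(self):
        design = _design()
        measures = pd.concat([
            _measures(design),
            pd.DataFrame([("ghost", "M1", 1.0)],
                         columns=["sample_id", "measure", "value"]),
        ])
        with pytest.raises(ValidationError, match="ghost"):
            compare_groups(measures, design)

    def test_bh_adjustment_attached(self):
        design = _design()
        measures = pd.concat([_measures(design, measure=f"M{i}", rng_seed=i)
                              for i in range(4)])
        results = compare_groups(measures, design, bh=True)
        frame = results_to_frame(results)
        assert "p_value_bh" in frame.columns
        assert (frame["p_value_bh"] >= frame["p_value"] - 1e-12).all()
        assert frame["p_value_bh"].le(1.0).all()

    def test_significance_flags(self):
        design = _design()
        # strong separation: controls near 10, tumors near 0
        rows = []
        for r in design.itertuples():
            value = 10.0 + 0.1 * hash(r.sample_id) % 3 if r.group == "MC" else \
                float(hash(r.sample_id) % 5) / 10
            rows.append((r.sample_id, "M1", value))
        measures = pd.DataFrame(rows, columns=["sample_id", "measure", "value"])
        frame = results_to_frame(compare_groups(measures, design))
        mc_gbm1 = frame[frame["comparison"] == "MC vs GBM1"].iloc[0]
        assert bool(mc_gbm1["significant_0.05"]) == (mc_gbm1["p_value"] < 0.05)
        assert set(frame.columns) >= {"group1_median", "group1_q1", "group1_q3",
                                      "group2_median", "group2_q1", "group2_q3"}
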