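from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from copecba.did import (
    TestFamily,
    bonferroni_threshold,
    bootstrap_ci,
    dyad_deltas,
    did_table,
    rank_sum_test,
)
from copecba.errors import DataError, ParameterError


def enumerate_rank_sum_p(x, y) -> float:
    """Brute-force two-sided rank-sum p-value by enumerating every
    assignment of pooled ranks to the first sample (no ties assumed)."""
    pooled = np.concatenate([x, y])
    n1, n = len(x), len(pooled)
    order = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    w_obs = sum(order[v] for v in x)
    mean = n1 * (n + 1) / 2
    sums = [sum(c) for c in combinations(range(1, n + 1), n1)]
    hits = sum(abs(s - mean) >= abs(w_obs - mean) - 1e-9 for s in sums)
    return hits / len(sums)


class TestDyadDeltas:
    def test_hand_computed_fixture(self, three_dyad_cost_lines):
        d = dyad_deltas(three_dyad_cost_lines)
        assert d.loc["A", "meals"] == 0.0          # 100 -> 100
        assert d.loc["A", "inpatient"] == 250.0    # absent baseline = 0
        assert d.loc["B", "nursing_home"] == -300.0
        assert d.loc["C", "meals"] == -40.0        # absent month12 = 0
        assert d.loc["A", "total"] == 250.0

    def test_subtotals_are_component_sums(self, three_dyad_cost_lines):
        d = dyad_deltas(three_dyad_cost_lines)
        assert d.loc["A", "subtotal_health_care"] == 250.0
        assert d.loc["A", "subtotal_formal_social"] == 0.0

    def test_dyad_in_both_arms_rejected(self, three_dyad_cost_lines):
        bad = three_dyad_cost_lines.copy()
        bad.loc[len(bad)] = ("A", "usual_care", "baseline", "meals", 1.0)
        with pytest.raises(DataError, match="both arms"):
            dyad_deltas(bad)


class TestRankSum:
    def test_identical_samples_p_one(self):
        assert rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)

    def test_all_tied_p_one(self):
        assert rank_sum_test([5.0, 5.0], [5.0, 5.0, 5.0]) == 1.0

    def test_complete_separation_exact(self):
        # 2 / C(6,3) = 0.1: only the two extreme orderings are as extreme
        assert rank_sum_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_empty_sample_rejected(self):
        with pytest.raises(ParameterError):
            rank_sum_test([], [1.0])

    @pytest.mark.parametrize("n1,n2", [(2, 3), (4, 4), (5, 6), (6, 6)])
    def test_matches_enumeration_on_random_layouts(self, n1, n2):
        rng = np.random.default_rng(n1 * 100 + n2)
        for _ in range(10):
            vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            x, y = vals[:n1], vals[n1:]
            assert rank_sum_test(x, y) == pytest.approx(
                enumerate_rank_sum_p(x, y), abs=1e-12
            )

    def test_large_sample_uses_tie_corrected_normal_approximation(self):
        rng = np.random.default_rng(0)
        x = np.round(rng.normal(0, 1, 40), 1)   # rounding induces ties
        y = np.round(rng.normal(0.5, 1, 45), 1)
        expected = stats.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
        assert rank_sum_test(x, y) == pytest.approx(float(expected))


class TestBonferroni:
    def test_published_threshold(self):
        assert bonferroni_threshold(TestFamily(18, 0.05)) == 0.00278

    @pytest.mark.parametrize(
        "n,alpha,expected", [(1, 0.05, 0.05), (4, 0.10, 0.025)]
    )
    def test_simple_families(self, n, alpha, expected):
        assert bonferroni_threshold(TestFamily(n, alpha)) == pytest.approx(expected)

    def test_zero_tests_rejected(self):
        with pytest.raises(ParameterError):
            TestFamily(n_tests=0)


class TestBootstrapCI:
    def test_constant_data_zero_width(self):
        lo, hi = bootstrap_ci([5.0] * 10, [2.0] * 8, B=200, seed=1)
        assert lo == hi == pytest.approx(3.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=25)
        assert bootstrap_ci(x, y, B=500, seed=9) == bootstrap_ci(x, y, B=500, seed=9)

    def test_single_dyad_degenerates_with_warning(self):
        with pytest.warns(UserWarning, match="single dyad"):
            lo, hi = bootstrap_ci([3.0], [1.0], B=100, seed=0)
        assert lo == hi == 2.0

    def test_agrees_with_normal_theory(self):
        """On normal data the percentile interval should be within 5% of
        the closed-form CI width for a difference of means."""
        rng = np.random.default_rng(7)
        n1, n2 = 200, 180
        x = rng.normal(10, 2, n1)
        y = rng.normal(7, 3, n2)
        lo, hi = bootstrap_ci(x, y, B=10_000, seed=42)
        se = np.sqrt(x.var(ddof=1) / n1 + y.var(ddof=1) / n2)
        width_theory = 2 * 1.959964 * se
        assert (hi - lo) == pytest.approx(width_theory, rel=0.05)
        assert lo <= x.mean() - y.mean() <= hi


def _lines_from_deltas(cope, usual, category="meals"):
    """Cost lines with the given month-12 costs (baseline 0)."""
    rows = []
    for i, v in enumerate(cope):
        rows.append((f"c{i}", "cope", "month12", category, float(v)))
    for i, v in enumerate(usual):
        rows.append((f"u{i}", "usual_care", "month12", category, float(v)))
    return pd.DataFrame(
        rows, columns=["dyad_id", "arm", "period", "report_category", "cost_usd2019"]
    )


class TestDIDTable:
    def test_identical_arms_give_zero_did_p_one(self):
        lines = _lines_from_deltas([10, 20, 30], [10, 20, 30])
        t = did_table(lines, B=200, seed=1).set_index("row")
        assert t["did"].abs().max() == pytest.approx(0.0)
        assert t.loc["meals", "p_value"] == pytest.approx(1.0)

    def test_shifted_control(self):
        t = did_table(_lines_from_deltas([10, 20, 30], [15, 25, 35]),
                      B=200, seed=1).set_index("row")
        assert t.loc["meals", "did"] == pytest.approx(-5.0)
        assert t.loc["total", "did"] == pytest.approx(-5.0)

    def test_point_estimate_inside_ci(self):
        rng = np.random.default_rng(3)
        lines = _lines_from_deltas(rng.exponential(100, 40), rng.exponential(80, 35))
        t = did_table(lines, B=2000, seed=5)
        varying = t[t.row.isin(["meals", "subtotal_formal_social", "total"])]
        assert ((varying.ci_low <= varying.did) & (varying.did <= varying.ci_high)).all()

    def test_subtotal_additivity_exact(self):
        rng = np.random.default_rng(4)
        frames = [
            _lines_from_deltas(rng.exponential(50, 20), rng.exponential(60, 18), cat)
            for cat in ("meals", "transportation", "adult_day", "social_worker")
        ]
        t = did_table(pd.concat(frames), B=200, seed=2).set_index("row")
        members = ["meals", "transportation", "adult_day", "social_worker"]
        assert t.loc["subtotal_formal_social", "did"] == pytest.approx(
            t.loc[members, "did"].sum(), abs=1e-9
        )
        subtotal_names = ["subtotal_delivery", "subtotal_health_care",
                          "subtotal_formal_social", "subtotal_caregiver_time"]
        assert t.loc["total", "did"] == pytest.approx(
            t.loc[subtotal_names, "did"].sum(), abs=1e-9
        )

    def test_arm_swap_antisymmetry(self):
        rng = np.random.default_rng(6)
        x, y = rng.exponential(100, 30), rng.exponential(120, 28)
        t1 = did_table(_lines_from_deltas(x, y), B=200, seed=1).set_index("row")
        t2 = did_table(_lines_from_deltas(y, x), B=200, seed=1).set_index("row")
        assert t2.loc["meals", "did"] == pytest.approx(-t1.loc["meals", "did"])
        assert t2.loc["meals", "p_value"] == pytest.approx(t1.loc["meals", "p_value"])

    def test_zero_variance_row_reports_na_not_crash(self):
        # constant 100 in cope only: deterministic difference, no rank test
        lines = _lines_from_deltas([100, 100, 100], [0, 0, 0], "lab_testing")
        lines = lines[lines.cost_usd2019 > 0]
        lines = pd.concat([
            lines,
            _lines_from_deltas([1, 2, 3], [1, 3, 5], "meals"),
        ])
        t = did_table(lines, B=200, seed=1).set_index("row")
        assert np.isnan(t.loc["lab_testing", "p_value"])
        assert t.loc["lab_testing", "did"] == pytest.approx(100.0)

    def test_missing_arm_rejected(self):
        lines = _lines_from_deltas([1, 2], [])
        with pytest.raises(DataError, match="both arms"):
            did_table(lines, B=100, seed=1)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(8)
        lines = _lines_from_deltas(rng.exponential(10, 25), rng.exponential(10, 22))
        t1 = did_table(lines, B=500, seed=3)
        t2 = did_table(lines, B=500, seed=3)
        pd.testing.assert_frame_equal(t1, t2)
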