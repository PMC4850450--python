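"""Tests of the threshold sweep and the group statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nirsnet import (
    SimulationConfig,
    check_bounds,
    compare_groups,
    critical_r,
    simulate_recording,
    subject_metrics,
    threshold_grid,
)
from tests.test_connectivity import matrix_from


class TestThresholdGrid:
    def test_default_grid(self):
        grid = threshold_grid()
        assert grid[0] == pytest.approx(0.275)
        assert grid[-1] == pytest.approx(0.625)
        assert len(grid) == 1 + round((0.625 - 0.275) / 0.025)
        assert np.allclose(np.diff(grid), 0.025)

    def test_single_value(self):
        assert threshold_grid(0.4, 0.4, 0.025).tolist() == [0.4]

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            threshold_grid(0.5, 0.3, 0.025)
        with pytest.raises(ValueError):
            threshold_grid(0.3, 0.5, 0.0)


class TestCheckBounds:
    def test_critical_r_closed_form(self):
        # t = r sqrt((n-2)/(1-r^2)) inverted at the t-quantile
        n = 130
        r = critical_r(n, alpha=0.05)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        assert t == pytest.approx(stats.t.ppf(0.975, n - 2), abs=1e-10)

    def test_huge_sample_admits_whole_grid(self, rng):
        vals = rng.uniform(-0.9, 0.9, (5, 5))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        res = check_bounds([matrix_from(vals)], n_samples=10**7)
        assert res.t_min_ok == pytest.approx(0.275)

    def test_complete_graph_matrices_admit_top(self):
        vals = np.ones((24, 24))
        res = check_bounds([matrix_from(vals)], n_samples=130)
        assert res.t_max_ok == pytest.approx(0.625)

    def test_connectivity_ceiling(self):
        # correlations of 0.5 everywhere: edges exist only up to T = 0.5
        vals = np.full((24, 24), 0.5)
        np.fill_diagonal(vals, 1.0)
        res = check_bounds([matrix_from(vals)], n_samples=130)
        assert res.t_max_ok == pytest.approx(0.5)


@pytest.fixture(scope="module")
def tiny_cohort():
    config = SimulationConfig(n_subjects=2, n_trials_per_case=4, seed=21)
    return [
        simulate_recording(config, f"S{i + 1:02d}", "spontaneous") for i in range(2)
    ]


class TestSubjectMetrics:
    def test_row_counts(self, tiny_cohort):
        grid = np.array([0.3, 0.4, 0.5])
        table = subject_metrics(tiny_cohort, "win-win", grid=grid, null_n=3, seed=0)
        assert len(table) == 2 * 3
        assert set(table["threshold"].round(3)) == {0.3, 0.4, 0.5}

    def test_identical_recordings_have_zero_sd(self, tiny_cohort):
        clones = [tiny_cohort[0], tiny_cohort[0]]
        grid = np.array([0.3, 0.5])
        table = subject_metrics(clones, "win-win", grid=grid, null_n=3, seed=0)
        for _, sub in table.groupby("threshold"):
            assert sub["C"].std(ddof=1) == 0.0
            assert sub["K_mean"].std(ddof=1) == 0.0

    def test_deterministic_given_seed(self, tiny_cohort):
        grid = np.array([0.35])
        a = subject_metrics(tiny_cohort, "win-win", grid=grid, null_n=4, seed=9)
        b = subject_metrics(tiny_cohort, "win-win", grid=grid, null_n=4, seed=9)
        pd.testing.assert_frame_equal(a, b)


def synthetic_table(values_by_metric, group, thresholds=(0.3, 0.4)):
    rows = []
    for t in thresholds:
        for i, _ in enumerate(values_by_metric["K_mean"]):
            rows.append(
                {
                    "subject_id": f"S{i:02d}",
                    "group": group,
                    "case": "win-win",
                    "threshold": t,
                    "C": values_by_metric["C"][i],
                    "L": values_by_metric["L"][i],
                    "K_mean": values_by_metric["K_mean"][i],
                    "sigma": values_by_metric["sigma"][i],
                    "connected": True,
                }
            )
    return pd.DataFrame(rows)


def welch_t(a, b):
    """Closed-form Welch statistic, independent of scipy."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    return (a.mean() - b.mean()) / np.sqrt(va + vb)


class TestCompareGroups:
    a_vals = [3.1, 2.8, 3.5, 3.0, 3.3]
    b_vals = [2.5, 2.9, 2.2, 2.6, 2.4]

    def tables(self):
        mk = lambda vals, g: synthetic_table(
            {"C": vals, "L": vals, "K_mean": vals, "sigma": vals}, g
        )
        return mk(self.a_vals, "spontaneous"), mk(self.b_vals, "control")

    def test_identical_groups_give_null_result(self):
        ta, _ = self.tables()
        tb = ta.copy()
        tb["group"] = "control"
        res = compare_groups(ta, tb)
        assert np.allclose(res.stats["t"], 0.0)
        assert np.allclose(res.stats["p"], 1.0)

    def test_matches_closed_form_welch(self):
        ta, tb = self.tables()
        res = compare_groups(ta, tb)
        expected = welch_t(self.a_vals, self.b_vals)
        assert np.allclose(res.stats["t"], expected, atol=1e-10)

    def test_matches_closed_form_pooled(self):
        ta, tb = self.tables()
        res = compare_groups(ta, tb, equal_var=True)
        a, b = np.asarray(self.a_vals), np.asarray(self.b_vals)
        sp = np.sqrt(
            ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
            / (len(a) + len(b) - 2)
        )
        expected = (a.mean() - b.mean()) / (sp * np.sqrt(1 / len(a) + 1 / len(b)))
        assert np.allclose(res.stats["t"], expected, atol=1e-10)

    def test_label_swap_negates_t(self):
        ta, tb = self.tables()
        fwd = compare_groups(ta, tb)
        rev = compare_groups(tb, ta)
        assert np.allclose(fwd.stats["t"], -rev.stats["t"], atol=1e-12)
        assert np.allclose(fwd.stats["p"], rev.stats["p"], atol=1e-12)

    def test_grid_mismatch_rejected(self):
        ta, tb = self.tables()
        tb["threshold"] = tb["threshold"] + 0.05
        with pytest.raises(ValueError, match="grids"):
            compare_groups(ta, tb)

    def test_too_few_subjects_rejected(self):
        ta, tb = self.tables()
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups(ta, tb[tb["subject_id"] == "S00"])

    def test_paired_matches_scipy(self):
        ta, tb = self.tables()
        res = compare_groups(ta, tb, paired=True)
        t, p = stats.ttest_rel(self.a_vals, self.b_vals)
        assert np.allclose(res.stats["t"], t, atol=1e-10)
        assert np.allclose(res.stats["p"], p, atol=1e-10)

    def test_fdr_flag_adds_adjusted_p(self):
        ta, tb = self.tables()
        res = compare_groups(ta, tb, fdr=True)
        assert "p_fdr" in res.stats
        assert (res.stats["p_fdr"] >= res.stats["p"] - 1e-15).all()

    def test_significant_fraction_helper(self):
        ta, tb = self.tables()
        res = compare_groups(ta, tb)
        assert res.significant_fraction("K_mean") in (0.0, 0.5, 1.0)
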