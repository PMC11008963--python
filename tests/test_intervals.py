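"""Trimming, interval construction, volume proportions, PCA and the
interval-count convergence rule."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mandifem.intervals import (
    IntervalProfile,
    StressSample,
    build_intervals,
    build_profile,
    choose_interval_count,
    convergence_select,
    interval_volume_proportions,
    pca_profiles,
    trim_top_stress,
)


def make_sample(values, volumes=None, label="s"):
    values = np.asarray(values, dtype=float)
    vol = np.ones_like(values) if volumes is None else np.asarray(volumes, float)
    return StressSample(label, values, vol)


class TestTrim:
    def test_removes_two_of_hundred(self):
        s = make_sample(np.arange(1.0, 101.0))
        t = trim_top_stress(s, 0.02)
        assert t.n == 98
        assert t.sigma_vm.max() == 98.0

    def test_ceiling_rule_101(self):
        s = make_sample(np.arange(1.0, 102.0))
        assert trim_top_stress(s, 0.02).n == 101 - 3  # ceil(2.02) = 3

    def test_fraction_zero_identity(self):
        s = make_sample([3.0, 1.0, 2.0])
        t = trim_top_stress(s, 0.0)
        np.testing.assert_array_equal(t.sigma_vm, s.sigma_vm)

    def test_ties_broken_by_element_order(self):
        s = make_sample([5.0, 5.0, 5.0, 1.0], volumes=[1, 2, 3, 4])
        t = trim_top_stress(s, 0.25)  # remove exactly 1: the first 5.0
        assert t.n == 3
        np.testing.assert_array_equal(t.volume, [2, 3, 4])

    def test_trim_is_idempotent_with_zero_refraction(self):
        s = make_sample(np.linspace(0.1, 9.0, 57))
        once = trim_top_stress(s, 0.02)
        again = trim_top_stress(once, 0.0)
        np.testing.assert_array_equal(once.sigma_vm, again.sigma_vm)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            trim_top_stress(make_sample([]), 0.02)


class TestBuildIntervals:
    def test_uniform_pooled_quantile(self):
        """Log-stresses uniform on [0, 1]: upper threshold at 0.75 and the
        top interval captures 25% of the values."""
        logs = np.linspace(0.0, 1.0, 1001)
        s = make_sample(np.exp(logs))
        edges = build_intervals([s], 10)
        assert edges[0] == pytest.approx(0.0, abs=1e-12)
        assert edges[-1] == pytest.approx(0.75, abs=1e-9)
        row = interval_volume_proportions(s, edges)
        assert row[-1] == pytest.approx(0.25, abs=1.0 / 1001)

    def test_smallest_interval_count(self):
        s = make_sample(np.exp(np.linspace(0, 1, 100)))
        edges = build_intervals([s], 2)
        assert edges.size == 2  # FTL and FTU; top interval is implicit

    def test_identical_samples_identical_rows(self):
        base = np.exp(np.linspace(0, 2, 200))
        samples = [make_sample(base, label=f"s{i}") for i in range(8)]
        profile = build_profile(samples, 15)
        for row in profile.proportions[1:]:
            np.testing.assert_allclose(row, profile.proportions[0], atol=1e-15)

    def test_constant_values_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_intervals([make_sample(np.full(50, 2.0))], 5)


class TestProportions:
    def test_one_hot_when_all_in_one_interval(self):
        s = make_sample([3.0, 3.2, 3.1])
        edges = np.log(np.array([0.5, 2.0, 10.0, 20.0]))
        row = interval_volume_proportions(s, edges)
        np.testing.assert_allclose(row, [0, 1, 0, 0], atol=1e-15)

    def test_volume_weighting(self):
        s = make_sample([1.0, 10.0], volumes=[1.0, 3.0])
        edges = np.log(np.array([0.5, 5.0, 50.0]))
        row = interval_volume_proportions(s, edges)
        np.testing.assert_allclose(row, [0.25, 0.75, 0.0])

    def test_value_at_upper_threshold_stays_below_top(self):
        s = make_sample([1.0, np.e])  # log = 0 and 1
        edges = np.array([0.0, 0.5, 1.0])
        row = interval_volume_proportions(s, edges)
        assert row[-1] == 0.0  # exactly at FTU -> last body interval
        assert row[1] == pytest.approx(0.5)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(2, 60), st.integers(0, 2**31 - 1))
    def test_row_sums_to_one(self, n_intervals, seed):
        rng = np.random.default_rng(seed)
        s = make_sample(
            rng.lognormal(0.0, 1.5, size=73), volumes=rng.uniform(0.1, 5.0, size=73)
        )
        edges = build_intervals([s], n_intervals)
        assert interval_volume_proportions(s, edges).sum() == pytest.approx(1.0, abs=1e-12)

    def test_refinement_consistency_with_nested_edges(self):
        """Merging adjacent body intervals of a fine profile reproduces the
        coarse profile when the edge grids nest (4 body -> 2 body)."""
        rng = np.random.default_rng(3)
        s = make_sample(rng.lognormal(0, 1, 500), volumes=rng.uniform(0.5, 2, 500))
        coarse = build_intervals([s], 3)  # 2 body intervals
        fine = build_intervals([s], 5)  # 4 body intervals, nested grid
        np.testing.assert_allclose(fine[::2], coarse, atol=1e-12)
        row_f = interval_volume_proportions(s, fine)
        row_c = interval_volume_proportions(s, coarse)
        merged = [row_f[0] + row_f[1], row_f[2] + row_f[3], row_f[4]]
        np.testing.assert_allclose(merged, row_c, atol=1e-12)


class TestPca:
    def test_variance_sums_to_100_and_monotone(self):
        rng = np.random.default_rng(0)
        profile = IntervalProfile(
            [f"s{i}" for i in range(8)], rng.dirichlet(np.ones(12), size=8), np.zeros(11)
        )
        pca = pca_profiles(profile)
        assert pca.variance_pct.sum() == pytest.approx(100.0)
        assert np.all(np.diff(pca.variance_pct) <= 1e-9)

    def test_identical_rows_identical_scores(self):
        rng = np.random.default_rng(1)
        X = rng.dirichlet(np.ones(6), size=7)
        X[4] = X[2]
        pca = pca_profiles(IntervalProfile([f"s{i}" for i in range(7)], X, np.zeros(5)))
        np.testing.assert_allclose(pca.scores[4], pca.scores[2], atol=1e-10)

    def test_matches_dense_eigendecomposition_oracle(self):
        """Scores from the SVD route equal (up to sign) those from a direct
        eigendecomposition of the correlation matrix."""
        rng = np.random.default_rng(7)
        X = rng.uniform(size=(5, 5))
        pca = pca_profiles(X)
        Xs = (X - X.mean(0)) / X.std(0, ddof=1)
        C = Xs.T @ Xs / (X.shape[0] - 1)
        w, V = np.linalg.eigh(C)
        order = np.argsort(w)[::-1]
        w, V = w[order], V[:, order]
        scores_ref = Xs @ V
        var_ref = 100 * w / w.sum()
        np.testing.assert_allclose(pca.variance_pct, var_ref, atol=1e-10)
        for j in range(5 - 1):  # last component may be numerically null
            assert np.allclose(pca.scores[:, j], scores_ref[:, j], atol=1e-8) or np.allclose(
                pca.scores[:, j], -scores_ref[:, j], atol=1e-8
            )

    def test_zero_variance_columns_dropped_and_recorded(self):
        X = np.column_stack([np.full(6, 0.3), np.linspace(0, 1, 6), np.linspace(1, 0, 6)])
        pca = pca_profiles(X)
        assert pca.dropped_columns == [0]

    def test_single_row_rejected(self):
        with pytest.raises(ValueError, match="2 rows"):
            pca_profiles(np.ones((1, 4)))


class TestConvergence:
    def test_flat_r2_chooses_second_candidate(self):
        """Identical element data at every interval count: all successive-PC
        regressions are ~perfect, so the rule stops at the first comparison."""
        rng = np.random.default_rng(11)
        samples = [
            make_sample(rng.lognormal(0.1 * i, 1.0, 400), label=f"s{i}") for i in range(8)
        ]
        trace = convergence_select(samples, candidates=(5, 10, 15, 25))
        assert trace.chosen == 10
        assert all(r > 0.9 for r in trace.r2_pc1)

    def test_rule_boundary_cases(self):
        cands = (5, 10, 15, 25, 50, 75)
        # strictly increasing with final jump > epsilon -> last candidate
        assert choose_interval_count(cands, [0.2, 0.4, 0.6, 0.8, 0.99], 0.01) == 75
        # increase stops at the 50 -> 75 pair -> 50 chosen
        assert choose_interval_count(cands, [0.5, 0.7, 0.9, 0.97, 0.975], 0.01) == 50
        # immediate stall -> second candidate
        assert choose_interval_count(cands, [0.9, 0.9, 0.95, 0.99, 1.0], 0.01) == 10

    def test_needs_three_candidates(self):
        with pytest.raises(ValueError, match="3 candidate"):
            convergence_select([make_sample([1.0, 2.0])], candidates=(5, 10))
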