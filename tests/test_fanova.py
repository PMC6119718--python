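"""Local polynomial smoothing, the CvM-type statistic, and the bootstrap test."""

import numpy as np
import pytest

import affectfanova as af
from affectfanova.data_model import StructuralError, ValidationError
from affectfanova.fanova import (
    BandwidthError,
    BootstrapSpec,
    ConfigError,
    FunctionalANOVA,
    SmoothingSpec,
    cvm_statistic,
    default_bandwidth_grid,
    select_bandwidth,
    smooth_local_poly,
    smoother_matrix,
)
from affectfanova.synthetic_data import simulate_two_group_curves


class TestSmoothing:
    def test_constant_reproduced_exactly_any_degree(self):
        t = np.arange(30.0)
        y = np.full(30, 0.37)
        for degree in (0, 1, 2):
            out = smooth_local_poly(y, t, SmoothingSpec(degree=degree, bandwidth=6.0))
            np.testing.assert_allclose(out, y, atol=1e-12)

    @pytest.mark.parametrize("h", [2.0, 5.0, 14.0])
    def test_local_linear_exact_on_linear_input(self, h):
        t = np.arange(50.0)
        y = 0.013 * t - 0.4
        out = smooth_local_poly(y, t, SmoothingSpec(degree=1, bandwidth=h))
        np.testing.assert_allclose(out, y, atol=1e-10)

    def test_gaussian_kernel_matches_statsmodels_kernelreg(self):
        statsmodels_np = pytest.importorskip("statsmodels.nonparametric.kernel_regression")
        rng = np.random.default_rng(4)
        t = np.arange(40.0)
        y = np.sin(t / 6) * 0.5 + rng.normal(0, 0.1, 40)
        h = 3.0
        mine = smooth_local_poly(y, t, SmoothingSpec(kernel="gaussian", bandwidth=h))
        kr = statsmodels_np.KernelReg(y, t, var_type="c", reg_type="ll", bw=[h])
        theirs, _ = kr.fit(t)
        np.testing.assert_allclose(mine, theirs, atol=1e-8)

    def test_noise_reduction_on_noisy_sine(self):
        t = np.arange(120.0)
        truth = 0.6 * np.sin(2 * np.pi * t / 60)
        wins = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            noisy = truth + rng.normal(0, 0.2, len(t))
            sm = smooth_local_poly(noisy, t, SmoothingSpec(bandwidth=6.0))
            if np.mean((sm - truth) ** 2) < np.mean((noisy - truth) ** 2):
                wins += 1
        assert wins == 50

    def test_too_small_bandwidth_rejected(self):
        t = np.arange(20.0)
        with pytest.raises(BandwidthError):
            smoother_matrix(t, 0.5)

    def test_too_few_points_rejected(self):
        with pytest.raises(StructuralError):
            smoother_matrix(np.arange(4.0), 2.0)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ConfigError):
            SmoothingSpec(degree=3)
        with pytest.raises(ConfigError):
            SmoothingSpec(kernel="box")
        with pytest.raises(ConfigError):
            SmoothingSpec(bandwidth=-1)


class TestBandwidthSelection:
    def test_linear_curves_take_smallest_feasible_candidate(self):
        t = np.arange(60.0)
        curves = np.vstack([0.01 * t - 0.3, 0.005 * t])
        cands = np.array([3.0, 6.0, 12.0, 24.0])
        # cross-validation error is zero everywhere on linear input, so the
        # tie breaks to the smallest candidate the CV window allows
        assert select_bandwidth(curves, t, candidates=cands) == 6.0
        assert select_bandwidth(curves, t, candidates=cands, cv_gap=0) == 3.0

    def test_deterministic_given_input(self):
        t, a, b = simulate_two_group_curves(n_a=6, n_b=6, duration=60, seed=9)
        curves = np.vstack([a, b])
        assert select_bandwidth(curves, t) == select_bandwidth(curves, t)

    def test_bandwidth_nondecreasing_in_noise_level(self):
        t = np.arange(120.0)
        truth = 0.5 * np.sin(2 * np.pi * t / 40)
        for seed in (0, 1, 2):
            rng = np.random.default_rng(seed)
            z = rng.normal(size=(8, len(t)))
            selected = [
                select_bandwidth(truth + sigma * z, t)
                for sigma in (0.05, 0.2, 0.5)
            ]
            assert selected[0] <= selected[1] <= selected[2]

    def test_candidate_grid_spans_step_to_quarter_span(self):
        t = np.arange(120.0)
        grid = default_bandwidth_grid(t)
        assert grid[0] == pytest.approx(2.0)
        assert grid[-1] == pytest.approx(119 / 4)


class TestCvmStatistic:
    def test_identical_groups_give_zero(self, rng):
        t = np.arange(50.0)
        g = rng.normal(0, 0.2, size=(5, 50)).clip(-1, 1)
        assert cvm_statistic([g, g], t, bandwidth=5.0) == pytest.approx(0.0, abs=1e-20)

    @pytest.mark.parametrize("n,delta,T", [(5, 0.3, 50), (26, 0.1, 120), (4, 0.8, 45)])
    def test_constant_shift_closed_form(self, n, delta, T):
        t = np.arange(float(T))
        a = np.zeros((n, T))
        b = np.full((n, T), delta)
        C = cvm_statistic([a, b], t, bandwidth=6.0)
        assert C == pytest.approx(n / 2 * delta**2 * (T - 1), abs=1e-9)

    def test_symmetric_in_group_order(self, rng):
        t = np.arange(60.0)
        a = rng.normal(0, 0.2, size=(6, 60)).clip(-1, 1)
        b = rng.normal(0.1, 0.2, size=(9, 60)).clip(-1, 1)
        assert cvm_statistic([a, b], t, bandwidth=5.0) == pytest.approx(
            cvm_statistic([b, a], t, bandwidth=5.0)
        )

    def test_invariant_to_common_time_trend(self, rng):
        t = np.arange(60.0)
        a = rng.normal(0, 0.15, size=(6, 60))
        b = rng.normal(0.2, 0.15, size=(6, 60))
        trend = 0.3 * np.sin(t / 9)
        base = cvm_statistic([a, b], t, bandwidth=5.0)
        moved = cvm_statistic([a + trend, b + trend], t, bandwidth=5.0)
        assert moved == pytest.approx(base, rel=1e-9)

    def test_three_group_statistic_sums_pairwise_terms(self):
        t = np.arange(45.0)
        g = [np.full((4, 45), v) for v in (0.0, 0.2, 0.5)]
        C = cvm_statistic(g, t, bandwidth=5.0)
        expected = sum(
            4 * 4 / 8 * (vi - vj) ** 2 * 44
            for i, vi in enumerate((0.0, 0.2, 0.5))
            for vj in (0.0, 0.2, 0.5)[i + 1 :]
        )
        assert C == pytest.approx(expected, abs=1e-9)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(StructuralError):
            cvm_statistic([np.zeros((3, 50)), np.zeros((3, 40))], np.arange(50.0))


class TestBootstrapTest:
    def test_large_shift_hits_minimum_p(self):
        for seed in range(10):
            t, a, b = simulate_two_group_curves(
                n_a=20,
                n_b=20,
                duration=60,
                noise_sigma_a=0.05,
                bump_amplitude=0.0,
                seed=seed,
            )
            b = np.clip(b - 1.0, -1, 1)  # gross level shift between groups
            res = af.functional_bootstrap_test(
                a, b, t, bootstrap=BootstrapSpec(n_boot=199, seed=seed)
            )
            assert res.p_value == pytest.approx(1 / 200)

    def test_same_seed_reproduces_identical_result(self):
        t, a, b = simulate_two_group_curves(n_a=8, n_b=8, duration=60, seed=21)
        spec = BootstrapSpec(n_boot=199, seed=33)
        r1 = af.functional_bootstrap_test(a, b, t, bootstrap=spec)
        r2 = af.functional_bootstrap_test(a, b, t, bootstrap=spec)
        assert r1.p_value == r2.p_value and r1.statistic == r2.statistic
        np.testing.assert_array_equal(r1.bootstrap_statistics, r2.bootstrap_statistics)

    def test_p_values_live_on_the_bootstrap_grid(self):
        B = 99
        for seed in range(6):
            t, a, b = simulate_two_group_curves(n_a=6, n_b=6, duration=50, seed=seed)
            res = af.functional_bootstrap_test(
                a, b, t, bootstrap=BootstrapSpec(n_boot=B, seed=seed)
            )
            k = res.p_value * (B + 1)
            assert k == pytest.approx(round(k))
            assert 1 / (B + 1) <= res.p_value <= 1.0

    def test_power_monotone_in_bump_amplitude_on_matched_seeds(self):
        # same seeds across amplitudes: only the group-b mean differs
        powers = [
            af.power_simulation(
                amp, n_reps=15, seed=99, n_boot=199, duration=80, bump_width=8.0
            )
            for amp in (0.0, 0.1, 0.3)
        ]
        assert powers[0] <= powers[1] <= powers[2]
        assert powers[2] > powers[0]

    def test_insufficient_bootstrap_rejected(self):
        with pytest.raises(ConfigError):
            BootstrapSpec(n_boot=50)

    def test_degenerate_groups_rejected(self):
        t = np.arange(50.0)
        with pytest.raises(ValidationError):
            FunctionalANOVA([np.zeros((1, 50)), np.zeros((5, 50))], t)

    def test_summary_reports_key_quantities(self):
        t, a, b = simulate_two_group_curves(n_a=5, n_b=7, duration=50, seed=2)
        res = FunctionalANOVA([a, b], t, group_names=("low", "high")).fit(
            bootstrap=BootstrapSpec(n_boot=99, seed=1)
        )
        text = res.summary()
        assert "low (n=5)" in text and "high (n=7)" in text
        assert "p-value" in text and "bandwidth" in text

    def test_from_dataset_builds_two_group_model(self, tiny_study):
        dataset, _ = tiny_study
        factors = af.build_grouping_factors(dataset.participants)
        model = FunctionalANOVA.from_dataset(dataset, "m1", "valence", factors["Gender"])
        assert sum(g.shape[0] for g in model.groups) == len(dataset.participants)
        res = model.fit(bootstrap=BootstrapSpec(n_boot=99, seed=0))
        assert 0 < res.p_value <= 1
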