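import math

import numpy as np
import pytest

from mgatp.errors import AnalysisError, ConvergenceError, MgatpError
from mgatp.free_energy import (
    LambdaSeries,
    WorkSet,
    bar_estimate,
    discard_equilibration,
    exponential_averaging_bounds,
    forward_backward_sd,
    slice_convergence,
    subsample_snapshots,
    ti_integrate,
)
from mgatp.structures import SampleSeries
from mgatp.synthetic import (
    WorkConfig,
    gaussian_bar_standard_error,
    gaussian_work_samples,
    gaussian_work_series,
    lambda_profile,
    synthetic_dhdl,
)


def fixed_point_bar(wf, wr, beta=1.0, iterations=2000):
    """Independent BAR oracle: damped fixed-point iteration on the
    self-consistency identity, no root bracketing."""
    m = math.log(len(wf) / len(wr))
    df = 0.5 * (np.mean(wf) - np.mean(wr))
    for _ in range(iterations):
        lhs = np.sum(1.0 / (1.0 + np.exp(np.clip(m + beta * (wf - df), -500, 500))))
        rhs = np.sum(1.0 / (1.0 + np.exp(np.clip(-m + beta * (wr + df), -500, 500))))
        df = df - 0.05 * (lhs - rhs) / (beta * len(wf))
    return df


class TestDiscardEquilibration:
    def test_standard_window_retains_400_of_500(self):
        series = SampleSeries(times=np.arange(500.0), values=np.zeros(500))
        kept = discard_equilibration(series, 100.0)
        assert len(kept) == 400
        assert kept.times[0] == 100.0

    def test_zero_discard_is_identity(self):
        series = SampleSeries(times=np.arange(10.0), values=np.arange(10.0))
        kept = discard_equilibration(series, 0.0)
        assert np.array_equal(kept.values, series.values)

    def test_discarding_everything_is_error(self):
        series = SampleSeries(times=np.arange(10.0), values=np.zeros(10))
        with pytest.raises(AnalysisError):
            discard_equilibration(series, 100.0)


class TestBar:
    def test_identical_directions_give_zero(self):
        # forward and backward work distributions coincide iff ΔF = 0 under
        # the work-of-each-perturbation sign convention
        w = np.random.default_rng(0).normal(1.0, 1.5, 2000)
        est = bar_estimate(WorkSet(forward=w, backward=w.copy(), beta=1.0))
        assert est.delta_g == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_gaussian_crooks_recovery(self, seed):
        delta_f, sigma, n = 2.0, 2.0, 100_000
        ws = gaussian_work_samples(WorkConfig(delta_f, sigma, n, beta=1.0, seed=seed))
        est = bar_estimate(ws)
        se = gaussian_bar_standard_error(delta_f, sigma, 1.0, n)
        assert abs(est.delta_g - delta_f) < 3 * se
        # the estimator's own asymptotic SE agrees with the analytic one
        assert est.uncertainty == pytest.approx(se, rel=0.05)

    def test_agrees_with_independent_fixed_point_oracle(self):
        ws = gaussian_work_samples(WorkConfig(1.5, 1.0, 5000, beta=1.0, seed=9))
        est = bar_estimate(ws)
        oracle = fixed_point_bar(ws.forward, ws.backward, beta=1.0)
        assert est.delta_g == pytest.approx(oracle, abs=1e-6)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5, 6, 7])
    def test_lies_between_exponential_averaging_bounds(self, seed):
        """In the dissipative regime the finite-sample one-sided estimators
        bracket BAR: forward exponential averaging misses the low-work tail
        (biased high), reverse averaging is biased low."""
        ws = gaussian_work_samples(WorkConfig(1.0, 4.0, 500, beta=1.0, seed=seed))
        est = bar_estimate(ws)
        fwd, rev = exponential_averaging_bounds(ws)
        lo, hi = sorted((fwd, rev))
        assert lo - 1e-9 <= est.delta_g <= hi + 1e-9

    def test_sample_order_invariance(self):
        ws = gaussian_work_samples(WorkConfig(1.0, 1.0, 1000, beta=1.0, seed=4))
        shuffled = WorkSet(forward=ws.forward[::-1].copy(),
                           backward=np.random.default_rng(1).permutation(ws.backward),
                           beta=1.0)
        assert bar_estimate(ws).delta_g == pytest.approx(
            bar_estimate(shuffled).delta_g, abs=1e-12)

    def test_non_overlapping_distributions_raise_with_diagnostic(self):
        # huge dissipation in both directions: forward work near +1e6 while
        # the negated backward work sits near -1e6 — no overlap to bridge
        ws = WorkSet(forward=np.random.default_rng(0).normal(1e6, 1.0, 100),
                     backward=np.random.default_rng(1).normal(1e6, 1.0, 100),
                     beta=1.0)
        with pytest.raises(ConvergenceError) as err:
            bar_estimate(ws)
        assert "forward_mean" in err.value.diagnostic

    def test_empty_direction_rejected(self):
        with pytest.raises(MgatpError):
            WorkSet(forward=np.array([]), backward=np.array([1.0]))


class TestTi:
    def test_constant_profile_exact(self):
        series = synthetic_dhdl("constant", noise_sigma=0.0)
        assert ti_integrate(series).delta_g == pytest.approx(1.0, abs=1e-12)

    def test_linear_profile_exact_on_uneven_grid(self):
        fn, integral = lambda_profile("linear", slope=2.0, intercept=0.0)
        grid = np.array([0.0, 0.13, 0.5, 0.52, 0.9, 1.0])
        series = synthetic_dhdl(fn, lambda_grid=grid, noise_sigma=0.0)
        assert ti_integrate(series).delta_g == pytest.approx(1.0, abs=1e-12)

    def test_cubic_profile_matches_dense_grid_quadrature(self):
        fn, _ = lambda_profile("cubic", a=1.0, b=1.0, c=1.0, d=1.0)
        coarse = ti_integrate(synthetic_dhdl(fn, noise_sigma=0.0)).delta_g
        dense_grid = np.linspace(0.0, 1.0, 20001)
        dense = float(np.trapezoid(fn(dense_grid), dense_grid))
        assert abs(coarse - dense) / abs(dense) < 1e-4

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(MgatpError):
            LambdaSeries(
                lambda_values=[0.0, 0.5, 0.4],
                dhdl_samples=[SampleSeries([0.0], [1.0])] * 3,
            )

    def test_equilibration_discard_applied_per_window(self):
        times = np.arange(500.0)
        windows = []
        for lam in (0.0, 1.0):
            values = np.where(times < 100.0, 100.0, 2.0)  # junk early samples
            windows.append(SampleSeries(times=times, values=values))
        series = LambdaSeries(lambda_values=[0.0, 1.0], dhdl_samples=windows)
        assert ti_integrate(series, t_eq_ps=100.0).delta_g == pytest.approx(2.0)


class TestForwardBackwardSd:
    def test_equal_estimates_zero(self):
        assert forward_backward_sd(5.0, 5.0) == 0.0

    def test_two_point_sample_sd(self):
        got = forward_backward_sd(10.0, 12.0)
        assert got == pytest.approx(abs(10 - 12) / math.sqrt(2))
        assert got == pytest.approx(float(np.std([10.0, 12.0], ddof=1)))

    def test_symmetric(self):
        assert forward_backward_sd(3.0, 8.0) == forward_backward_sd(8.0, 3.0)


class TestSliceConvergence:
    def stationary_pair(self, seed=3):
        return gaussian_work_series(
            WorkConfig(delta_f=1.0, sigma=1.5, n_samples=500, beta=1.0, seed=seed),
            spacing_ps=1.0,
        )

    def test_stationary_slices_agree(self):
        report = slice_convergence(self.stationary_pair(), beta=1.0)
        assert all(e is not None for e in report.slices)
        assert not report.drift_flagged
        for i in range(len(report.slices)):
            for j in range(i + 1, len(report.slices)):
                a, b = report.slices[i], report.slices[j]
                combined = math.hypot(a.uncertainty, b.uncertainty)
                assert abs(a.delta_g - b.delta_g) <= 3 * combined

    def test_full_coverage_slice_reproduces_full_estimate(self):
        fwd, bwd = self.stationary_pair()
        report = slice_convergence((fwd, bwd), slice_windows=[(0.0, 1e9)], beta=1.0)
        full = bar_estimate(WorkSet(forward=fwd.values, backward=bwd.values, beta=1.0))
        assert report.slices[0].delta_g == pytest.approx(full.delta_g, abs=1e-12)

    def test_planted_drift_is_flagged(self):
        fwd, bwd = gaussian_work_series(
            WorkConfig(delta_f=1.0, sigma=1.5, n_samples=500, beta=1.0, seed=3),
            spacing_ps=1.0, forward_drift_per_ps=0.02,
        )
        report = slice_convergence((fwd, bwd), beta=1.0)
        assert report.drift_flagged

    def test_empty_slice_reported_without_killing_others(self):
        report = slice_convergence(
            self.stationary_pair(),
            slice_windows=[(100.0, 300.0), (1e6, 2e6)], beta=1.0,
        )
        assert report.slices[0] is not None
        assert report.slices[1] is None
        assert report.errors[1] is not None

    def test_ti_input_sliced_in_time(self):
        fn, integral = lambda_profile("linear")
        series = synthetic_dhdl(fn, noise_sigma=0.0, n_samples_per_window=50)
        report = slice_convergence(series, slice_windows=[(0.0, 250.0), (250.0, 500.0)])
        for est in report.slices:
            assert est.delta_g == pytest.approx(integral, abs=1e-12)


class TestSubsampling:
    def test_standard_schedule_yields_900(self):
        times = np.arange(1000) * 100.0  # 100 ns at 100 ps spacing
        indices = subsample_snapshots(times, start_ps=10_000.0, stride_ps=100.0)
        assert len(indices) == 900
        assert indices[0] == 100

    def test_stride_beyond_span(self):
        times = np.arange(10) * 1.0
        assert len(subsample_snapshots(times, 0.0, 1000.0)) == 1

    def test_indices_strictly_increasing_on_grid(self):
        times = np.arange(200) * 10.0
        indices = subsample_snapshots(times, 500.0, 30.0)
        assert all(b > a for a, b in zip(indices, indices[1:]))
        picked = times[np.array(indices)]
        assert np.all(np.diff(picked) >= 30.0 - 1e-9)
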