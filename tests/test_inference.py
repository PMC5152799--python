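"""Three-step inference: calibration, occupancy, rate fits, resampling."""

import numpy as np
import pytest

from burstkin import (
    SimulationSpec,
    TwoStateParams,
    TraceSet,
    build_loop_function,
    calibrate,
    corrected_model_curve,
    empirical_connected_autocorrelation,
    estimate_pon,
    fit_rates,
    resample_uncertainty,
    run_inference,
    simulate_trace_set,
)


def _stationary_set(model, construct, n, T, seed, i0=1.0):
    spec = SimulationSpec(model=model, construct=construct, n_traces=n,
                          duration_s=T, dt_s=6.0, seed=seed, i0=i0)
    return simulate_trace_set(spec)


class TestCalibration:
    def test_saturated_traces_recover_intensity_scale_exactly(self, loop_3p):
        q = 3.7
        values = np.full((8, 20), q * loop_3p.total)
        ts = TraceSet.from_matrix(np.arange(20) * 6.0, values)
        i0, norm = calibrate(ts, loop_3p)
        assert i0 == pytest.approx(q)
        np.testing.assert_allclose(norm.values, loop_3p.total)

    def test_scale_equivariance(self, construct_3p, loop_3p):
        ts = _stationary_set(TwoStateParams(0.01, 0.01), construct_3p, 40, 300, 8)
        i0_a, norm_a = calibrate(ts, loop_3p)
        i0_b, norm_b = calibrate(ts.scaled(5.0), loop_3p)
        assert i0_b == pytest.approx(5.0 * i0_a)
        np.testing.assert_allclose(norm_a.values, norm_b.values)

    def test_all_zero_traces_rejected(self, loop_3p):
        ts = TraceSet.from_matrix(np.arange(10) * 6.0, np.zeros((3, 10)))
        with pytest.raises(ValueError, match="calibration"):
            calibrate(ts, loop_3p)


class TestPonEstimate:
    def test_saturated_and_dark_limits(self, loop_3p):
        t = np.arange(12) * 6.0
        full = TraceSet.from_matrix(t, np.full((4, 12), loop_3p.total))
        dark = TraceSet.from_matrix(t, np.zeros((4, 12)))
        assert estimate_pon(full, loop_3p) == pytest.approx(1.0)
        assert estimate_pon(dark, loop_3p) == 0.0

    def test_overshooting_calibration_flagged(self, loop_3p):
        ts = TraceSet.from_matrix(np.arange(5) * 6.0, np.full((2, 5), 2 * loop_3p.total))
        with pytest.raises(ValueError, match="calibration"):
            estimate_pon(ts, loop_3p)

    def test_pipeline_recovers_half_occupancy(self, construct_3p, loop_3p):
        # anterior-like kinetics: k_on = k_off, true P_on = 1/2
        ts = _stationary_set(TwoStateParams(0.015, 0.015), construct_3p, 200, 600, 13, i0=2.5)
        i0, norm = calibrate(ts, loop_3p)
        p = estimate_pon(norm, loop_3p)
        assert p == pytest.approx(0.5, rel=0.10)

    def test_pon_invariant_under_intensity_rescaling(self, construct_3p):
        ts = _stationary_set(TwoStateParams(0.01, 0.02), construct_3p, 60, 480, 14)
        ts = ts.with_window(0, 480)
        r1 = run_inference(ts, "two_state", construct_3p, n_subsets=0)
        r2 = run_inference(ts.scaled(12.0), "two_state", construct_3p, n_subsets=0)
        assert r1.p_on == pytest.approx(r2.p_on, rel=1e-9)
        assert r1.k_sum == pytest.approx(r2.k_sum, rel=1e-9)


class TestRateFit:
    def test_two_state_recovery_at_moderate_rates(self, construct_3p):
        truth = 0.04
        estimates = [
            fit_rates(
                _stationary_set(TwoStateParams(0.004, 0.036), construct_3p, 200, 600, 500 + s)
                .with_window(0, 600),
                "two_state",
                construct_3p,
                p_on=0.1,
            ).k_sum
            for s in range(3)
        ]
        assert np.median(estimates) == pytest.approx(truth, rel=0.15)

    def test_objective_at_truth_beats_doubled_rates(self, construct_3p, loop_3p):
        m = TwoStateParams(0.004, 0.036)
        ts = _stationary_set(m, construct_3p, 2000, 600, 15).with_window(0, 600)
        curve = empirical_connected_autocorrelation(ts.steady_state())
        K, dt = ts.steady_state().n_times, 6.0
        sl = slice(1, 37)
        w = curve.pair_counts[sl].astype(float)

        def mse(model):
            mc = corrected_model_curve(model, loop_3p, dt, K)
            return np.average((curve.values[sl] - mc[sl]) ** 2, weights=w)

        assert mse(m) < mse(TwoStateParams(0.008, 0.072))
        assert mse(m) < mse(TwoStateParams(0.002, 0.018))

    def test_poisson_needs_no_curve_fit(self, construct_3p):
        ts = _stationary_set(TwoStateParams(0.01, 0.01), construct_3p, 30, 300, 16)
        res = fit_rates(ts.with_window(0, 300), "poisson", construct_3p, p_on=0.4)
        assert res.model_family == "poisson"
        assert res.rates["firing_rate"] > 0
        assert np.isnan(res.k_sum)

    def test_unmarked_steady_state_refused(self, construct_3p):
        ts = _stationary_set(TwoStateParams(0.01, 0.01), construct_3p, 20, 300, 17)
        ts = TraceSet(times_s=ts.times_s, values=ts.values, meta=ts.meta, steady_window=None)
        with pytest.raises(ValueError, match="steady-state"):
            fit_rates(ts, "two_state", construct_3p, p_on=0.5)

    def test_gamma_family_fits_scale_at_fixed_shape_grid(self, construct_3p):
        from burstkin import GammaParams

        m = GammaParams(k_off=0.0075, alpha=2.0, beta=0.005)  # P_on = 1/4
        ts = _stationary_set(m, construct_3p, 400, 600, 18).with_window(0, 600)
        res = fit_rates(ts, "gamma", construct_3p, p_on=0.25, alpha_grid=(2.0,))
        assert res.rates["beta"] == pytest.approx(0.005, rel=0.5)
        assert res.rates["k_off"] == pytest.approx(
            res.rates["beta"] * (1 / 0.25 - 1) / 2.0
        )


class TestResampling:
    def test_identical_traces_have_zero_spread(self, construct_3p):
        base = _stationary_set(TwoStateParams(0.005, 0.015), construct_3p, 1, 600, 19)
        values = np.repeat(base.values, 30, axis=0)
        ts = TraceSet.from_matrix(base.times_s, values, steady_window=(0, 600))
        sd = resample_uncertainty(ts, "two_state", construct_3p, p_on=0.25, n_subsets=6, seed=1)
        assert sd["k_sum"] == pytest.approx(0.0, abs=1e-12)

    def test_same_seed_same_uncertainties(self, construct_3p):
        ts = _stationary_set(TwoStateParams(0.004, 0.036), construct_3p, 60, 600, 20)
        ts = ts.with_window(0, 600)
        kw = dict(p_on=0.1, n_subsets=5, seed=3)
        a = resample_uncertainty(ts, "two_state", construct_3p, **kw)
        b = resample_uncertainty(ts, "two_state", construct_3p, **kw)
        assert a == b

    def test_too_few_traces_rejected(self, construct_3p):
        ts = _stationary_set(TwoStateParams(0.01, 0.01), construct_3p, 5, 300, 21)
        with pytest.raises(ValueError, match="at least 10"):
            resample_uncertainty(ts.with_window(0, 300), "two_state", construct_3p, p_on=0.5)

    def test_subset_spread_brackets_truth_most_of_the_time(self, construct_3p):
        # coverage check: the inferred value should sit within ~2 subset SDs
        # of the truth in a clear majority of independent datasets
        truth = 0.04
        hits = 0
        n_rep = 5
        for s in range(n_rep):
            ts = _stationary_set(
                TwoStateParams(0.004, 0.036), construct_3p, 120, 600, 700 + s
            ).with_window(0, 600)
            res = fit_rates(ts, "two_state", construct_3p, p_on=0.1)
            sd = resample_uncertainty(
                ts, "two_state", construct_3p, p_on=0.1, n_subsets=10, seed=s
            )["k_sum"]
            hits += abs(res.k_sum - truth) <= 2.5 * sd
        assert hits >= 3
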