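"""Promoter models: occupancies, propagators, dwell laws, autocovariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.linalg import expm

from burstkin import (
    CycleParams,
    GammaParams,
    PoissonLikeParams,
    TwoStateParams,
    effective_on_rate,
    gamma_waiting_pdf,
    occupancy_time_average,
    on_on_propagator,
    promoter_autocovariance,
    stationary_on_probability,
)
from burstkin.models import model_from_config

rates = st.floats(1e-3, 0.2, allow_nan=False)


class TestStationaryOccupancy:
    def test_symmetric_two_state_is_half(self):
        assert stationary_on_probability(TwoStateParams(0.03, 0.03)) == pytest.approx(0.5)

    def test_cycle_occupancy_fraction(self):
        # 1/k_off = 100 s ON vs 100 + 50 s OFF
        m = CycleParams(k_off=0.01, off_rates=(0.01, 0.02))
        assert stationary_on_probability(m) == pytest.approx(0.4)

    def test_cycle_occupancy_matches_simulation(self):
        m = CycleParams(k_off=0.01, off_rates=(0.01, 0.02))
        occ = occupancy_time_average(m, duration_s=2e4, n_realizations=400, seed=7)
        se = occ.std(ddof=1) / np.sqrt(occ.size)
        assert abs(occ.mean() - 0.4) < 4 * se

    def test_poisson_saturates_at_fast_firing(self):
        assert stationary_on_probability(
            PoissonLikeParams(firing_rate=1e9, tau_block=6.0)
        ) == pytest.approx(1.0, abs=1e-8)

    def test_gamma_formula(self):
        m = GammaParams(k_off=0.01, alpha=2.0, beta=0.01)
        # mean ON 100 s vs mean OFF alpha/beta = 200 s
        assert stationary_on_probability(m) == pytest.approx(1.0 / 3.0)


class TestPropagator:
    @pytest.mark.parametrize(
        "model",
        [
            TwoStateParams(0.01, 0.02),
            CycleParams(k_off=0.02, off_rates=(0.01, 0.03)),
            PoissonLikeParams(firing_rate=0.05),
        ],
    )
    def test_starts_at_one_and_relaxes_to_occupancy(self, model):
        assert on_on_propagator(model, 0.0) == pytest.approx(1.0)
        far = float(on_on_propagator(model, 5000.0, step_time_s=6.0))
        assert far == pytest.approx(stationary_on_probability(model), abs=1e-6)

    def test_two_state_printed_form_vs_discrete_chain_oracle(self):
        # exact per-step chain: A(n) = P_on + delta^n (1 - P_on),
        # delta = 1 - (k_on + k_off) dt.  The exponential form
        # e^{(delta - 1) n} agrees to O(rate^2) for per-step rates < 0.1.
        k = 0.1  # per-step with step_time 1 s
        m = TwoStateParams(k, k)
        P = np.array([[1 - k, k], [k, 1 - k]])  # [ON, OFF] chain
        # closed form of the gap: 0.5 (e^{-0.2 n} - 0.8^n), maximal ~0.020
        # around n = 5 for these rates
        for n in (1, 2, 5, 10, 50):
            chain = np.linalg.matrix_power(P, n)[0, 0]
            printed = float(on_on_propagator(m, n, step_time_s=1.0))
            assert abs(printed - chain) < 0.025
        assert float(on_on_propagator(m, 1, step_time_s=1.0)) == pytest.approx(
            0.5 + 0.5 * np.exp(-0.2)
        )

    def test_cycle_with_one_off_state_is_the_telegraph(self):
        two = TwoStateParams(0.013, 0.027)
        one = CycleParams(k_off=0.027, off_rates=(0.013,))
        n = np.arange(0, 60)
        np.testing.assert_allclose(
            on_on_propagator(one, n), on_on_propagator(two, n), atol=1e-10
        )

    def test_two_state_monotone_decrease_toward_occupancy(self):
        m = TwoStateParams(0.004, 0.016)
        a = on_on_propagator(m, np.arange(0, 200))
        assert np.all(np.diff(a) <= 1e-12)
        assert np.all(a >= stationary_on_probability(m) - 1e-12)

    def test_cycle_chain_conserves_probability(self):
        m = CycleParams(k_off=0.02, off_rates=(0.005, 0.05))
        Q = m.transition_matrix
        for t in (0.0, 10.0, 300.0, 5000.0):
            rows = expm(Q * t).sum(axis=1)
            np.testing.assert_allclose(rows, 1.0, atol=1e-9)

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError):
            on_on_propagator(TwoStateParams(0.01, 0.01), -1)

    def test_gamma_has_no_closed_form_propagator(self):
        with pytest.raises(ValueError, match="frequency"):
            on_on_propagator(GammaParams(0.01, 2.0, 0.01), 3)


class TestEffectiveOnRate:
    def test_harmonic_sum(self):
        assert effective_on_rate(
            CycleParams(k_off=0.01, off_rates=(0.02, 0.02))
        ) == pytest.approx(0.01)

    def test_single_off_state(self):
        assert effective_on_rate(CycleParams(k_off=0.01, off_rates=(0.03,))) == 0.03
        assert effective_on_rate(TwoStateParams(0.03, 0.01)) == 0.03

    def test_fast_first_state_limit(self):
        m = CycleParams(k_off=0.01, off_rates=(1e6, 0.02))
        assert effective_on_rate(m) == pytest.approx(0.02, rel=1e-4)


class TestGammaWaitingTimes:
    def test_normalized_with_mean_alpha_over_beta(self):
        p = GammaParams(k_off=0.01, alpha=2.0, beta=0.01)
        t = np.linspace(0, 4000, 400_001)
        pdf = gamma_waiting_pdf(p, t)
        assert np.trapezoid(pdf, t) == pytest.approx(1.0, abs=1e-4)
        assert np.trapezoid(t * pdf, t) == pytest.approx(200.0, rel=1e-3)

    def test_shape_one_is_exponential(self):
        p = GammaParams(k_off=0.01, alpha=1.0, beta=0.02)
        t = np.linspace(0, 300, 500)
        np.testing.assert_allclose(gamma_waiting_pdf(p, t), 0.02 * np.exp(-0.02 * t), rtol=1e-10)

    def test_mode_location(self):
        p = GammaParams(k_off=0.01, alpha=3.0, beta=0.02)
        t = np.linspace(0, 1000, 100_001)
        assert t[np.argmax(gamma_waiting_pdf(p, t))] == pytest.approx((3 - 1) / 0.02, abs=0.05)


class TestPromoterAutocovariance:
    def test_gamma_shape_one_reduces_to_telegraph(self):
        t = np.linspace(0, 600, 121)
        g_gamma = promoter_autocovariance(GammaParams(k_off=0.01, alpha=1.0, beta=0.005), t_max=700)(t)
        g_two = promoter_autocovariance(TwoStateParams(0.005, 0.01))(t)
        np.testing.assert_allclose(g_gamma, g_two, atol=3e-4)

    def test_gamma_integer_shape_equals_equal_rate_cycle(self):
        # Erlang(2, k) is exactly the OFF dwell law of a 2-step cycle with
        # equal rates, so both models are the same process.
        t = np.linspace(0, 600, 121)
        g_gamma = promoter_autocovariance(GammaParams(k_off=0.005, alpha=2.0, beta=0.01), t_max=700)(t)
        g_cycle = promoter_autocovariance(CycleParams(k_off=0.005, off_rates=(0.01, 0.01)))(t)
        np.testing.assert_allclose(g_gamma, g_cycle, atol=3e-4)

    @settings(deadline=None, max_examples=25)
    @given(k_on=rates, k_off=rates)
    def test_two_state_variance_and_decay(self, k_on, k_off):
        m = TwoStateParams(k_on, k_off)
        g = promoter_autocovariance(m)
        p = stationary_on_probability(m)
        assert g(np.array([0.0]))[0] == pytest.approx(p * (1 - p))
        vals = g(np.linspace(0, 400, 50))
        assert np.all(np.diff(vals) <= 1e-12)

    def test_poisson_triangular_support(self):
        m = PoissonLikeParams(firing_rate=0.05, tau_block=6.0)
        g = promoter_autocovariance(m)
        p = m.p_on
        assert g(np.array([0.0]))[0] == pytest.approx(p * (1 - p))
        assert g(np.array([3.0]))[0] == pytest.approx(0.5 * p * (1 - p))
        assert g(np.array([6.0]))[0] == 0.0
        assert g(np.array([60.0]))[0] == 0.0


class TestConfig:
    @pytest.mark.parametrize(
        "cfg, cls",
        [
            ({"family": "two_state", "k_on": 0.01, "k_off": 0.02}, TwoStateParams),
            ({"family": "cycle", "k_off": 0.02, "off_rates": [0.01, 0.02]}, CycleParams),
            ({"family": "gamma", "k_off": 0.01, "alpha": 2, "beta": 0.01}, GammaParams),
            ({"family": "poisson", "p_on": 0.3, "tau_block": 6}, PoissonLikeParams),
        ],
    )
    def test_families(self, cfg, cls):
        assert isinstance(model_from_config(cfg), cls)

    def test_cycle_rates_canonicalized_ascending(self):
        m = CycleParams(k_off=0.01, off_rates=(0.05, 0.002))
        assert m.off_rates == (0.002, 0.05)

    def test_unknown_family(self):
        with pytest.raises(ValueError):
            model_from_config({"family": "hmm"})
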