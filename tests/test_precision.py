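"""Readout precision: closed forms, Monte-Carlo, spatial and lineage estimators."""

import numpy as np
import pandas as pd
import pytest

from burstkin import (
    CycleParams,
    PoissonLikeParams,
    TraceSet,
    TwoStateParams,
    empirical_relative_error,
    integration_time_factor,
    lineage_integrated_error,
    relative_error_monte_carlo,
    relative_error_poisson,
    relative_error_two_state,
)


class TestClosedForms:
    def test_two_state_anterior_like_value(self):
        # tau_i = 33 s, P_on = 1/2, T = 240 s -> sqrt(2*33*0.5/(240*0.5))
        est = relative_error_two_state(k_on=1 / 66, k_off=1 / 66, window_s=240.0)
        assert est.value == pytest.approx(np.sqrt(0.275), rel=1e-9)
        assert est.value == pytest.approx(0.524, abs=0.001)

    def test_two_state_limits(self):
        assert relative_error_two_state(0.01, 0.01, 1e12).value == pytest.approx(0.0, abs=1e-4)
        near_full = relative_error_two_state(1.0, 1e-9, 240.0)
        assert near_full.value < 1e-4

    def test_poisson_boundary_and_anterior_values(self):
        assert relative_error_poisson(6.0, 240.0, p_on=0.1).value == pytest.approx(0.15)
        assert relative_error_poisson(6.0, 240.0, p_on=0.5).value == pytest.approx(0.1118, abs=5e-4)
        assert relative_error_poisson(6.0, 240.0, p_on=1.0).value == 0.0

    @pytest.mark.parametrize("T", [240.0, 960.0, 3840.0])
    def test_errors_fall_as_inverse_sqrt_window(self, T):
        two = relative_error_two_state(0.01, 0.02, T).value * np.sqrt(T)
        ref = relative_error_two_state(0.01, 0.02, 240.0).value * np.sqrt(240.0)
        assert two == pytest.approx(ref, rel=1e-12)
        poi = relative_error_poisson(6.0, T, p_on=0.3).value * np.sqrt(T)
        ref_p = relative_error_poisson(6.0, 240.0, p_on=0.3).value * np.sqrt(240.0)
        assert poi == pytest.approx(ref_p, rel=1e-12)


class TestMonteCarlo:
    def test_two_state_matches_closed_form_at_long_windows(self):
        m = TwoStateParams(1 / 66, 1 / 66)  # tau_i = 33 s
        mc = relative_error_monte_carlo(m, window_s=3300.0, n_realizations=4000, seed=5)
        theory = relative_error_two_state(m.k_on, m.k_off, 3300.0)
        assert mc.value == pytest.approx(theory.value, rel=0.10)

    def test_cycle_beats_two_state_at_matched_total_rate(self):
        # same k_on_eff + k_off; the cycle's more regular OFF dwells average
        # the readout better
        two = TwoStateParams(k_on=0.005, k_off=0.015)
        cyc = CycleParams(k_off=0.015, off_rates=(0.01, 0.01))
        e_two = relative_error_monte_carlo(two, 600.0, 4000, seed=6).value
        e_cyc = relative_error_monte_carlo(cyc, 600.0, 4000, seed=7).value
        assert e_cyc < e_two

    def test_few_realizations_warns(self):
        with pytest.warns(UserWarning, match="realizations"):
            relative_error_monte_carlo(TwoStateParams(0.01, 0.01), 600.0, 50, seed=1)


class TestOrderings:
    def test_poisson_always_more_precise_than_two_state_at_equal_occupancy(self):
        for p_on in (0.1, 0.3, 0.5, 0.7, 0.9):
            for k_sum in (0.01, 0.03, 0.1, 1 / 6):
                two = relative_error_two_state(p_on * k_sum, (1 - p_on) * k_sum, 240.0)
                poi = relative_error_poisson(6.0, 240.0, p_on=p_on)
                assert poi.value < two.value


class TestEmpirical:
    def _ts(self, values, positions, window=None):
        t = np.arange(values.shape[1]) * 10.0
        meta = pd.DataFrame(
            {"embryo_id": "e1", "cycle": 13, "nucleus_id": np.arange(values.shape[0]),
             "ap_position": positions}
        )
        return TraceSet(times_s=t, values=values, meta=meta, steady_window=window)

    def test_identical_traces_have_zero_error(self):
        v = np.tile(np.linspace(1, 2, 12), (6, 1))
        ts = self._ts(v, np.full(6, 0.2))
        (est,) = empirical_relative_error(ts)
        assert est.value == 0.0

    def test_heterogeneous_bin_has_positive_error_and_small_bins_skipped(self):
        rng = np.random.default_rng(0)
        v = rng.random((8, 12)) + np.linspace(0.5, 2.0, 8)[:, None]
        pos = np.array([0.22] * 6 + [0.91] * 2)
        with pytest.warns(UserWarning, match="nuclei"):
            out = empirical_relative_error(ts := self._ts(v, pos))
        assert len(out) == 1
        assert out[0].value > 0

    def test_binary_indicator_is_zero_when_all_nuclei_active(self):
        rng = np.random.default_rng(1)
        v = rng.random((10, 15)) + 1.0
        out = empirical_relative_error(self._ts(v, np.full(10, 0.3)), binary=True)
        assert out[0].value == 0.0

    def test_missing_positions_rejected(self):
        v = np.ones((4, 8)) + np.arange(4)[:, None]
        ts = self._ts(v, np.full(4, np.nan))
        with pytest.raises(ValueError, match="position"):
            empirical_relative_error(ts)


class TestLineage:
    def _cycle_set(self, cycle, values, mothers, positions):
        t = np.arange(values.shape[1]) * 10.0
        meta = pd.DataFrame(
            {"embryo_id": "e1", "cycle": cycle, "nucleus_id": np.arange(values.shape[0]),
             "ap_position": positions, "mother_id": mothers}
        )
        return TraceSet(times_s=t, values=values, meta=meta)

    def test_single_cycle_reduces_to_integrated_intensity_error(self):
        rng = np.random.default_rng(2)
        v = rng.random((6, 10)) + np.linspace(1, 3, 6)[:, None]
        pos = np.full(6, 0.25)
        only = {13: self._cycle_set(13, v, pd.array([pd.NA] * 6), pos)}
        (est,) = lineage_integrated_error(only)
        integrals = v.sum(axis=1)
        assert est.value == pytest.approx(integrals.std(ddof=1) / integrals.mean())

    def test_weighted_sum_oracle_with_explicit_lineage(self):
        # 2 mothers (cc12) with 2 daughters each (cc13); constant traces make
        # the weighted totals exactly computable: own + mother/2 + grandma/4
        gma = self._cycle_set(11, np.array([[4.0] * 5]), pd.array([pd.NA]), np.array([0.2]))
        mothers = self._cycle_set(
            12, np.array([[2.0] * 5, [6.0] * 5]), pd.array([0, 0]), np.array([0.2, 0.2])
        )
        daughters = self._cycle_set(
            13,
            np.array([[1.0] * 5, [3.0] * 5, [5.0] * 5, [7.0] * 5]),
            pd.array([0, 0, 1, 1]),
            np.full(4, 0.2),
        )
        (est,) = lineage_integrated_error({11: gma, 12: mothers, 13: daughters})
        dt = 10.0
        own = np.array([1, 3, 5, 7.0]) * 5 * dt
        mother = np.array([2, 2, 6, 6.0]) * 5 * dt
        grand = np.full(4, 4.0) * 5 * dt
        totals = own + mother / 2 + grand / 4
        assert est.value == pytest.approx(totals.std(ddof=1) / totals.mean())

    def test_zero_intensity_grandmothers_change_nothing(self):
        gma0 = self._cycle_set(11, np.zeros((1, 5)), pd.array([pd.NA]), np.array([0.2]))
        mothers = self._cycle_set(
            12, np.array([[2.0] * 5, [6.0] * 5]), pd.array([0, 0]), np.array([0.2, 0.2])
        )
        daughters = self._cycle_set(
            13, np.array([[1.0] * 5, [3.0] * 5, [5.0] * 5, [7.0] * 5]),
            pd.array([0, 0, 1, 1]), np.full(4, 0.2),
        )
        with_gma = lineage_integrated_error({11: gma0, 12: mothers, 13: daughters})
        without = lineage_integrated_error({12: mothers, 13: daughters})
        assert with_gma[0].value == pytest.approx(without[0].value)

    def test_broken_links_skipped_with_warning(self):
        mothers = self._cycle_set(12, np.array([[2.0] * 5]), pd.array([pd.NA]), np.array([0.2]))
        daughters = self._cycle_set(
            13, np.array([[1.0] * 5, [3.0] * 5, [5.0] * 5, [7.0] * 5]),
            pd.array([0, 0, pd.NA, 9]), np.full(4, 0.2),
        )
        with pytest.warns(UserWarning, match="lineage"):
            out = lineage_integrated_error({12: mothers, 13: daughters}, min_nuclei=2)
        assert out[0].n == 2


class TestIntegrationFactor:
    @pytest.mark.parametrize(
        "current, target, expected",
        [(0.5, 0.1, 25.0), (0.3, 0.3, 1.0), (1.5, 0.1, 225.0), (0.05, 0.1, 0.25)],
    )
    def test_square_law(self, current, target, expected):
        assert integration_time_factor(current, target) == pytest.approx(expected)

    def test_positive_errors_required(self):
        with pytest.raises(ValueError):
            integration_time_factor(0.0, 0.1)
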