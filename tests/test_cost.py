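"""Cost metrics: masked RMSE, correlation, analytic closed form + partials."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lifmap import (DEFAULT_PARAMS, LIFParams, StimulusSpec, Trace,
                    analytic_partials, analytic_rmse, compare_traces,
                    pearson_correlation, rank_parameters, rmse,
                    simulate_reference, subthreshold_mask, voltage_mask)
from lifmap.errors import DegenerateTraceError, MaskError


def make_trace(values, spike_steps=(), dt=1.0):
    values = np.asarray(values, dtype=float)
    return Trace(dt=dt, values=values,
                 spike_times=np.asarray(spike_steps, dtype=float) * dt,
                 duration=(values.size - 1) * dt)


class TestRmse:
    def test_identical_sequences_give_zero(self):
        y = np.array([1.0, -2.0, 3.0])
        assert rmse(y, y) == 0.0

    def test_constant_offset_gives_its_magnitude(self):
        y = np.linspace(0, 1, 20)
        assert rmse(y, y - 0.37) == pytest.approx(0.37, rel=1e-12)

    def test_hand_computed_value(self):
        assert rmse([0, 0, 0], [3, 4, 0]) == pytest.approx(math.sqrt(25 / 3), rel=1e-12)
        assert rmse([0, 0, 0], [3, 4, 0]) == pytest.approx(2.8868, abs=5e-5)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.floats(-1e3, 1e3), min_size=1, max_size=30))
    def test_symmetric_and_nonnegative(self, ys):
        a = np.asarray(ys)
        b = a[::-1]
        assert rmse(a, b) == rmse(b, a) >= 0.0

    def test_error_contracts(self):
        with pytest.raises(MaskError):
            rmse([1, 2], [1, 2, 3])
        with pytest.raises(MaskError):
            rmse([1, 2], [1, 2], mask=np.array([False, False]))


class TestMasks:
    def test_no_spikes_means_all_true(self):
        a = make_trace(np.zeros(10))
        assert subthreshold_mask(a, a).all()

    def test_single_spike_masks_guard_window(self):
        a = make_trace(np.zeros(10), spike_steps=[5])
        b = make_trace(np.zeros(10))
        mask = subthreshold_mask(a, b, guard=1)
        assert list(np.nonzero(~mask)[0]) == [4, 5, 6]

    def test_two_trace_mask_is_conjunction(self):
        a = make_trace(np.zeros(20), spike_steps=[4])
        b = make_trace(np.zeros(20), spike_steps=[12])
        both = subthreshold_mask(a, b)
        expected = subthreshold_mask(a, a) & subthreshold_mask(b, b)
        assert np.array_equal(both, expected)

    def test_voltage_mask_covers_reset_landing(self):
        a = make_trace(np.zeros(10), spike_steps=[5])
        mask = voltage_mask(a, make_trace(np.zeros(10)), guard=1)
        assert list(np.nonzero(~mask)[0]) == [4, 5, 6, 7]

    def test_misaligned_traces_rejected(self):
        with pytest.raises(MaskError):
            subthreshold_mask(make_trace(np.zeros(5)), make_trace(np.zeros(6)))


class TestPearsonCorrelation:
    def test_self_correlation_is_one(self):
        t = make_trace(np.sin(np.linspace(0, 3, 40)))
        assert pearson_correlation(t, t) == pytest.approx(1.0)

    def test_negation_about_mean_is_minus_one(self):
        v = np.sin(np.linspace(0, 3, 40))
        t = make_trace(v)
        neg = make_trace(2 * v.mean() - v)
        assert pearson_correlation(t, neg) == pytest.approx(-1.0)

    def test_small_noise_keeps_high_correlation(self):
        rng = np.random.default_rng(0)
        v = np.sin(np.linspace(0, 6, 400))
        noisy = make_trace(v + 1e-4 * np.ptp(v) * rng.standard_normal(v.size))
        assert pearson_correlation(make_trace(v), noisy) > 0.999

    def test_constant_trace_is_degenerate(self):
        with pytest.raises(DegenerateTraceError):
            pearson_correlation(make_trace(np.zeros(10)), make_trace(np.ones(10)))


class TestAnalyticRmse:
    def test_rest_with_no_current_is_zero(self):
        out = analytic_rmse(DEFAULT_PARAMS, 1e-3, np.full(10, -70.0), 0.0)
        assert np.all(out.e_values == 0.0)
        assert out.rmse_analytic == 0.0

    def test_single_sample_perfect_square_identity(self):
        p, Ie, V, Vs = DEFAULT_PARAMS, 200.0, -60.0, 1e-3
        lin = (V - p.EL) / p.tau_v - Ie / p.C
        out = analytic_rmse(p, Vs, np.array([V]), Ie)
        assert out.rmse_analytic == pytest.approx(abs(lin) / abs(Vs - 1), rel=1e-12)

    def test_matches_direct_rmse_on_residual_construction(self):
        """The closed form equals the direct RMSE of the factored residuals
        r_i = [(V_i-EL)/tau - Ie/C] / (Vs - 1) to 1e-12, on 1000 random draws."""
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            p = LIFParams(C=rng.uniform(50, 400), tau_v=rng.uniform(5, 50),
                          EL=rng.uniform(-80, -60))
            Ie = rng.uniform(-300, 300)
            Vs = rng.uniform(1e-4, 0.9)
            V = rng.uniform(-90, -40, size=rng.integers(1, 30))
            residuals = ((V - p.EL) / p.tau_v - Ie / p.C) / (Vs - 1.0)
            direct = rmse(residuals, np.zeros_like(residuals))
            out = analytic_rmse(p, Vs, V, Ie)
            assert out.rmse_analytic == pytest.approx(direct, rel=1e-12, abs=1e-15)

    def test_degenerate_scale_rejected(self):
        with pytest.raises(ValueError):
            analytic_rmse(DEFAULT_PARAMS, 1.0, np.array([-60.0]), 200.0)


class TestAnalyticPartials:
    @staticmethod
    def bracket(p, V, Ie):
        dV = V - p.EL
        return (dV ** 2 / p.tau_v ** 2 + Ie ** 2 / p.C ** 2
                - 2 * dV * Ie / (p.tau_v * p.C))

    def test_all_partials_vanish_at_rest_without_current(self):
        dC, dtau, dEL = analytic_partials(DEFAULT_PARAMS, np.array([-70.0]), 0.0)
        assert dC == 0.0 and dtau == 0.0 and dEL == 0.0

    def test_el_partial_root_at_balance_point(self):
        p, Ie = DEFAULT_PARAMS, 200.0
        V = p.EL + p.tau_v * Ie / p.C  # (V-EL) = tau*Ie/C
        _, _, dEL = analytic_partials(p, np.array([V]), Ie)
        assert dEL == pytest.approx(0.0, abs=1e-15)

    def test_partials_match_central_finite_differences(self):
        rng = np.random.default_rng(77)
        h = 1e-5
        for _ in range(50):
            p = LIFParams(C=rng.uniform(100, 300), tau_v=rng.uniform(10, 40),
                          EL=rng.uniform(-80, -60))
            Ie = rng.uniform(-300, 300)
            V = np.array([rng.uniform(-90, -40)])
            dC, dtau, dEL = analytic_partials(p, V, Ie)
            fd_C = (self.bracket(p.replace(C=p.C + h), V, Ie)
                    - self.bracket(p.replace(C=p.C - h), V, Ie)) / (2 * h)
            fd_tau = (self.bracket(p.replace(tau_v=p.tau_v + h), V, Ie)
                      - self.bracket(p.replace(tau_v=p.tau_v - h), V, Ie)) / (2 * h)
            fd_EL = (self.bracket(p.replace(EL=p.EL + h), V, Ie)
                     - self.bracket(p.replace(EL=p.EL - h), V, Ie)) / (2 * h)
            scale = max(1.0, abs(fd_C))
            assert dC == pytest.approx(fd_C, rel=1e-6, abs=1e-6 * scale)
            assert dtau == pytest.approx(fd_tau, rel=1e-6, abs=1e-6)
            assert dEL == pytest.approx(fd_EL, rel=1e-6, abs=1e-6)

    def test_bracket_is_quadratic_in_el_only(self):
        """Second finite differences: zero for EL (affine partial), nonzero
        for C and tau_v (nonlinear partials)."""
        p, Ie, V, h = DEFAULT_PARAMS, 200.0, np.array([-60.0]), 0.1

        def second_diff(param):
            lo = self.bracket(p.replace(**{param: getattr(p, param) - h}), V, Ie)
            mid = self.bracket(p, V, Ie)
            hi = self.bracket(p.replace(**{param: getattr(p, param) + h}), V, Ie)
            return float(((hi - 2 * mid + lo) / h ** 2).item())

        d2 = self.bracket(p.replace(EL=p.EL + h), V, Ie) \
            - 2 * self.bracket(p, V, Ie) \
            + self.bracket(p.replace(EL=p.EL - h), V, Ie)
        # quadratic in EL: second difference equals exactly 2h^2/tau^2
        assert float((d2 / h ** 2).item()) == pytest.approx(2.0 / p.tau_v ** 2, abs=1e-9)
        # and the *partial derivative* dE/dEL is affine in EL: its own second
        # difference vanishes
        del_lo = analytic_partials(p.replace(EL=p.EL - h), V, Ie)[2]
        del_mid = analytic_partials(p, V, Ie)[2]
        del_hi = analytic_partials(p.replace(EL=p.EL + h), V, Ie)[2]
        assert abs(del_hi - 2 * del_mid + del_lo) <= 1e-9
        assert abs(second_diff("C")) > 1e-9
        assert abs(second_diff("tau_v")) > 1e-9


class TestRankParameters:
    def test_descending_with_declared_tie_order(self):
        ranked = rank_parameters({"EL": 0.42, "tau_v": 0.002, "Cm": 0.002})
        assert ranked == ["EL", "tau_v", "Cm"]

    def test_singleton(self):
        assert rank_parameters({"EL": 1.0}) == ["EL"]

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            rank_parameters({"EL": math.nan})


class TestCompareTraces:
    def test_default_run_report_fields(self, base_params, bias_stim, mapping):
        from lifmap import map_lif_to_loihi, simulate_emulator, rescale_state
        ref = simulate_reference(base_params, bias_stim)
        cfg, u = map_lif_to_loihi(base_params, bias_stim, mapping)
        emu = simulate_emulator(cfg, u_steps=u,
                                v0=rescale_state(base_params.EL, base_params.Vr, mapping))
        report = compare_traces(ref, emu.to_trace(base_params.Vr, mapping.Vs, mapping.dt))
        assert 0.0 < report.rmse < 0.01
        assert report.correlation > 0.999
        assert 0.0 < report.masked_fraction < 0.5
        assert set(report.to_dict()) == {"rmse_mv_per_ms", "correlation",
                                         "n_samples", "masked_fraction",
                                         "voltage_rmse_mv"}
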