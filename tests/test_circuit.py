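"""Circuit-model unit and property tests.

The independent oracle for the linear simulation is the per-segment
closed-form exponential; for the nonlinear model, the algebraic steady
state and qualitative monotonicity.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import coflowrheo as cf
from coflowrheo.errors import IntegrationDomainError, ValidityRangeError


class TestCorrectionFactor:
    @pytest.mark.parametrize(
        "alpha,expected",
        [(0.5, 1.008725), (0.1, 1.30402708), (0.9, 1.3034
          )],
    )
    def test_polynomial_values(self, alpha, expected):
        assert cf.correction_factor(alpha) == pytest.approx(expected, abs=1e-4)

    def test_strict_mode_rejects_out_of_range(self):
        with pytest.raises(ValidityRangeError):
            cf.correction_factor(0.95)
        with pytest.raises(ValidityRangeError):
            cf.correction_factor(np.array([0.5, 0.05]))

    def test_clamp_mode_evaluates_at_boundary(self):
        with pytest.warns(UserWarning):
            val = cf.correction_factor(0.95, mode="clamp")
        assert val == pytest.approx(cf.correction_factor(0.9))


class TestLaneResistance:
    def test_hand_converted_value(self):
        # 1 cP, 1 mm lane, 1000 um x 100 um cross-section
        geom = cf.ChannelGeometry(W_um=1000, h_um=100, L_cc_um=1000)
        assert cf.lane_resistance(geom, 1.0) == pytest.approx(1.2e10, rel=1e-9)

    def test_scalings(self):
        geom = cf.ChannelGeometry(L_cc_um=1000)
        base = cf.lane_resistance(geom, 1.0)
        doubled_L = cf.lane_resistance(cf.ChannelGeometry(L_cc_um=2000), 1.0)
        halved_h = cf.lane_resistance(cf.ChannelGeometry(L_cc_um=1000, h_um=50), 1.0)
        assert doubled_L == pytest.approx(2 * base)
        assert halved_h == pytest.approx(8 * base)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            cf.ChannelGeometry(h_um=-1)
        with pytest.raises(ValueError):
            cf.lane_resistance(cf.ChannelGeometry(), 0.0)


class TestSteadyState:
    def test_no_test_fluid(self):
        assert cf.steady_state_beta(0.0, 1.0, 1.0, 1.0) == pytest.approx(1.0)
        assert cf.steady_state_alpha(0.0, 1.0, 1.0, 1.0) == pytest.approx(0.0)

    def test_matched_conditions(self):
        assert cf.steady_state_beta(1, 1, 1, 1) == pytest.approx(1.88574, abs=1e-5)

    def test_blood_like_ratio(self):
        beta = cf.steady_state_beta(1, 1, 2.95, 1.0)
        assert beta == pytest.approx(3.61293, abs=1e-5)
        assert cf.steady_state_alpha(1, 1, 2.95, 1.0) == pytest.approx(0.72321, abs=1e-5)

    def test_zero_reference_flow_rejected(self):
        with pytest.raises(ValueError):
            cf.steady_state_beta(1.0, 0.0, 1.0, 1.0)

    def test_viscosity_round_trip(self):
        # steady_state_beta and the constant-flow viscosity formula are
        # exact algebraic inverses
        for mu in (1.0, 3.0, 6.0):
            beta = cf.steady_state_beta(0.5, 0.5, mu, 1.0)
            assert cf.viscosity_constant_flow(beta, 1.0) == pytest.approx(mu, rel=1e-12)


class TestTimeConstantFromCompliance:
    def test_linear_in_compliance_and_resistance(self, geometry, fluids):
        lam1 = cf.time_constant_from_compliance(0.1, geometry, fluids.mu_T_cP)
        lam2 = cf.time_constant_from_compliance(0.2, geometry, fluids.mu_T_cP)
        assert lam2 == pytest.approx(2 * lam1, rel=1e-12)
        geom2 = cf.ChannelGeometry(L_cc_um=2 * geometry.L_cc_um)
        lam3 = cf.time_constant_from_compliance(0.1, geom2, fluids.mu_T_cP)
        assert lam3 == pytest.approx(2 * lam1, rel=1e-12)

    def test_equals_F1_F2_CT_RWT(self, geometry, fluids):
        C_T = 0.05
        R = cf.lane_resistance(geometry, fluids.mu_T_cP)
        expected = 1.112 * 1.129 * C_T * 1e-9 * R
        assert cf.time_constant_from_compliance(C_T, geometry, fluids.mu_T_cP) == (
            pytest.approx(expected, rel=1e-12)
        )


class TestSimulateLinear:
    def test_single_on_step_matches_closed_form(self, fluids):
        p = cf.PumpProtocol(period_s=120, duty=0.999, Q_R_mLh=0.5,
                            Q_T_on_mLh=0.5, n_periods=1)
        comp = cf.CompliancePack(lambda_on_s=10.0, lambda_off_s=10.0)
        tr = cf.simulate_linear(p, comp, fluids, beta_init=1.0)
        bss = cf.steady_state_beta(0.5, 0.5, fluids.mu_T_cP, fluids.mu_R_cP)
        on = tr.t <= 120 * 0.999
        closed = bss + (1.0 - bss) * np.exp(-tr.t[on] / 10.0)
        assert np.max(np.abs(tr.beta[on] - closed) / closed) < 1e-6

    def test_full_protocol_matches_piecewise_closed_form(self, fluids):
        p = cf.PumpProtocol(n_periods=2)
        comp = cf.CompliancePack(lambda_on_s=10.0, lambda_off_s=20.0)
        tr = cf.simulate_linear(p, comp, fluids)
        bss_on = cf.steady_state_beta(p.Q_T_on_mLh, p.Q_R_mLh,
                                      fluids.mu_T_cP, fluids.mu_R_cP)
        beta = np.empty_like(tr.t)
        state = 1.0
        for t0, t1, on in p.segments():
            bss, lam = (bss_on, 10.0) if on else (1.0, 20.0)
            mask = (tr.t >= t0) & (tr.t <= t1)
            beta[mask] = bss + (state - bss) * np.exp(-(tr.t[mask] - t0) / lam)
            state = bss + (state - bss) * np.exp(-(t1 - t0) / lam)
        assert np.max(np.abs(tr.beta - beta) / beta) < 1e-6

    def test_fast_relaxation_reaches_steady_state_in_one_sample(self, fluids):
        p = cf.PumpProtocol(n_periods=1)
        comp = cf.CompliancePack(lambda_on_s=0.01, lambda_off_s=0.01)
        tr = cf.simulate_linear(p, comp, fluids)
        bss = cf.steady_state_beta(p.Q_T_on_mLh, p.Q_R_mLh,
                                   fluids.mu_T_cP, fluids.mu_R_cP)
        assert tr.beta[1] == pytest.approx(bss, rel=1e-4)

    def test_off_segment_relaxes_close_to_unity(self, fluids):
        p = cf.PumpProtocol(n_periods=1)
        comp = cf.CompliancePack(lambda_on_s=5.0, lambda_off_s=20.0)
        tr = cf.simulate_linear(p, comp, fluids)
        assert abs(tr.beta[-1] - 1.0) < 0.01

    def test_bounds_and_monotonicity(self, fluids):
        p = cf.PumpProtocol(n_periods=3)
        comp = cf.CompliancePack(lambda_on_s=8.0, lambda_off_s=30.0)
        tr = cf.simulate_linear(p, comp, fluids)
        assert np.all(tr.beta >= 1.0)
        assert np.all((tr.alpha >= 0) & (tr.alpha < 1))
        bss_on = cf.steady_state_beta(p.Q_T_on_mLh, p.Q_R_mLh,
                                      fluids.mu_T_cP, fluids.mu_R_cP)
        for t0, t1, on in p.segments():
            mask = (tr.t >= t0) & (tr.t <= t1)
            seg = tr.beta[mask]
            diffs = np.diff(seg)
            # monotone toward the segment's own steady state
            target = bss_on if on else 1.0
            sign = np.sign(target - seg[0])
            assert np.all(sign * diffs >= -1e-9)

    def test_rejects_beta_below_one(self, fluids, protocol):
        comp = cf.CompliancePack(lambda_on_s=5.0, lambda_off_s=5.0)
        with pytest.raises(ValueError):
            cf.simulate_linear(protocol, comp, fluids, beta_init=0.9)


class TestSimulateNonlinear:
    def test_steady_state_agrees_with_linearization(self):
        a_nl = cf.steady_state_alpha_nonlinear(1, 1, 1, 1)
        a_lin = cf.steady_state_alpha(1, 1, 1, 1)
        assert abs(a_nl - a_lin) / a_nl < 0.06

    def test_decays_monotonically_when_pump_off(self, geometry):
        fl = cf.FluidPair(mu_T_cP=1.0)
        # slow drain (large compliance) over a short hold so alpha stays
        # inside the validity interval for the whole run
        p = cf.PumpProtocol(period_s=40, duty=0.5, Q_R_mLh=1.0,
                            Q_T_on_mLh=0.0, Q_T_off_mLh=0.0, n_periods=1)
        C_T = 100.0 / (1.112 * 1.129 * 1e-9 * cf.lane_resistance(geometry, 1.0))
        tr = cf.simulate_nonlinear(p, C_T, geometry, fl, alpha_init=0.8)
        assert np.all(np.diff(tr.alpha) < 0)

    def test_small_amplitude_trace_matches_linear_model(self, geometry):
        # Q toggling 0.8 <-> 1.2 mL/h keeps alpha mid-range; the linear
        # model with lambda = F1 F2 C_T R_WT must track the nonlinear one
        fl = cf.FluidPair(mu_T_cP=1.0)
        p = cf.PumpProtocol(period_s=240, duty=0.5, Q_R_mLh=1.0,
                            Q_T_on_mLh=1.2, Q_T_off_mLh=0.8, n_periods=1)
        C_T = 20.0 / (1.112 * 1.129 * 1e-9 * cf.lane_resistance(geometry, 1.0))
        lam = cf.time_constant_from_compliance(C_T, geometry, 1.0)
        a0 = cf.steady_state_alpha_nonlinear(0.8, 1.0, 1.0, 1.0)
        nl = cf.simulate_nonlinear(p, C_T, geometry, fl, alpha_init=a0)
        lin = cf.simulate_linear(
            p, cf.CompliancePack(lambda_on_s=lam, lambda_off_s=lam), fl,
            beta_init=1.0 / (1.0 - a0),
        )
        sel = (nl.alpha >= 0.15) & (nl.alpha <= 0.85)
        assert np.max(np.abs(nl.beta[sel] - lin.beta[sel]) / nl.beta[sel]) <= 0.10

    def test_strict_mode_raises_when_lane_drains(self, geometry, fluids):
        p = cf.PumpProtocol(n_periods=1)
        C_T = 10.0 / (1.112 * 1.129 * 1e-9 * cf.lane_resistance(geometry, fluids.mu_T_cP))
        with pytest.raises(IntegrationDomainError) as exc:
            cf.simulate_nonlinear(p, C_T, geometry, fluids, alpha_init=0.3)
        assert exc.value.time_s is not None
        assert 120 < exc.value.time_s < 240  # during the off segment

    def test_rejects_alpha_init_outside_validity(self, geometry, fluids, protocol):
        with pytest.raises(ValidityRangeError):
            cf.simulate_nonlinear(protocol, 0.05, geometry, fluids, alpha_init=0.95)


class TestProtocol:
    def test_grid_and_switching(self):
        p = cf.PumpProtocol(period_s=240, duty=0.5, n_periods=2, dt_s=0.5)
        t = p.time_grid()
        assert t[0] == 0 and t[-1] == pytest.approx(480)
        q = p.q_t(t)
        assert q[0] == p.Q_T_on_mLh
        assert q[t == 130][0] == p.Q_T_off_mLh

    @pytest.mark.parametrize("bad", [
        dict(period_s=0), dict(duty=1.0), dict(dt_s=0), dict(Q_R_mLh=0),
        dict(n_periods=0),
    ])
    def test_validation(self, bad):
        with pytest.raises(ValueError):
            cf.PumpProtocol(**bad)


@settings(derandomize=True, deadline=None, max_examples=50)
@given(alpha=st.floats(min_value=0.0, max_value=0.99))
def test_alpha_beta_round_trip(alpha):
    beta = 1.0 / (1.0 - alpha)
    tr = cf.InterfaceTrace.from_beta([0.0], [beta])
    assert tr.alpha[0] == pytest.approx(alpha, abs=1e-12)
    assert tr.beta[0] == pytest.approx(beta, rel=1e-12)


@settings(derandomize=True, deadline=None, max_examples=30)
@given(
    c_t=st.floats(min_value=1e-3, max_value=1.0),
    scale=st.floats(min_value=0.5, max_value=4.0),
)
def test_time_constant_scales_linearly(c_t, scale):
    geometry = cf.ChannelGeometry()
    lam = cf.time_constant_from_compliance(c_t, geometry, 2.0)
    lam_scaled = cf.time_constant_from_compliance(scale * c_t, geometry, 2.0)
    assert lam_scaled == pytest.approx(scale * lam, rel=1e-9)
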