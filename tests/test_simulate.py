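"""Master-equation integration, GHK currents, gating currents and the
acquisition chain (filtering, artifacts, P/N subtraction)."""

import numpy as np
import pytest

import navleak
from navleak import protocols
from navleak.model_core import (
    Epoch,
    Parameterization,
    Subtraction,
    VoltageProtocol,
    build_state_model,
)
from navleak.simulate import (
    AcquisitionSettings,
    gating_charge,
    gating_current,
    ghk_flux,
    integrate_occupancies,
    ionic_current,
    run_protocol,
)
from conftest import two_state_model


def _hold_protocol(v, duration=10.0):
    return VoltageProtocol(holding=v, epochs=(Epoch(duration, v),),
                           sample_interval=0.02)


class TestIntegration:
    def test_stationary_at_holding(self, wt_model, cond_na):
        """A model held at its equilibrium voltage stays put."""
        occ = integrate_occupancies(wt_model, _hold_protocol(-80.0), 0.0, cond_na)
        assert np.max(np.abs(occ.occupancy - occ.occupancy[0])) < 1e-9

    def test_two_state_closed_form(self, cond_na):
        """Two-state relaxation matches p_inf + (p0-p_inf) exp(-t/tau) with
        tau = 1/(k12+k21)."""
        k12, k21 = 0.8, 0.3
        m = two_state_model(k12, k21)
        proto = VoltageProtocol(holding=-80.0, epochs=(Epoch(20.0, 0.0),),
                                sample_interval=0.01)
        # z = 0: rates voltage independent; start from equilibrium
        occ = integrate_occupancies(m, proto, 0.0, cond_na, tau_clamp=0.0,
                                    pre_holding=0.0)
        p_inf = k12 / (k12 + k21)
        p0 = occ.occupancy[0, 1]
        tau = 1.0 / (k12 + k21)
        expected = p_inf + (p0 - p_inf) * np.exp(-occ.time / tau)
        assert np.max(np.abs(occ.occupancy[:, 1] - expected)) < 1e-6

    def test_occupancy_conservation(self, wt_model, cond_na):
        occ = integrate_occupancies(wt_model, protocols.step_protocol(), 0.0,
                                    cond_na)
        assert np.max(np.abs(occ.occupancy.sum(axis=1) - 1.0)) < 1e-8
        assert occ.occupancy.min() >= 0.0

    def test_expm_and_ode_backends_agree(self, wt_model, cond_na):
        proto = protocols.step_protocol(duration=5.0, tail_duration=3.0)
        a = integrate_occupancies(wt_model, proto, 0.0, cond_na, backend="expm")
        b = integrate_occupancies(wt_model, proto, 0.0, cond_na, backend="ode")
        assert np.max(np.abs(a.occupancy - b.occupancy)) < 1e-6


class TestGHK:
    def test_zero_current_at_nernst(self, cond_na):
        v_rev = cond_na.rt_over_f * np.log(57.5 / 12.0)
        assert abs(ghk_flux(v_rev, 1, 12.0, 57.5, cond_na.rt_over_f)) < 1e-9

    def test_symmetric_zero(self, cond_na):
        assert ghk_flux(0.0, 1, 50.0, 50.0, cond_na.rt_over_f) == pytest.approx(0.0)

    def test_small_voltage_slope(self, cond_na):
        """Numeric slope at V = +/-0.01 mV matches the analytic small-V limit
        z (c_i - c_o) + V z^2 (c_i + c_o) / (2 RT/F) per unit permeability."""
        rt_f = cond_na.rt_over_f
        ci, co, z = 12.0, 57.5, 1
        i_p = ghk_flux(0.01, z, ci, co, rt_f)
        i_m = ghk_flux(-0.01, z, ci, co, rt_f)
        slope = (i_p - i_m) / 0.02
        analytic = z**2 * (ci + co) / (2 * rt_f)
        assert slope == pytest.approx(analytic, rel=1e-4)
        assert 0.5 * (i_p + i_m) == pytest.approx(z * (ci - co), rel=1e-4)

    def test_continuity_at_zero(self, cond_na):
        v = np.array([-1e-5, -1e-7, 0.0, 1e-7, 1e-5])
        y = ghk_flux(v, 1, 12.0, 57.5, cond_na.rt_over_f)
        assert np.all(np.diff(y) > 0) or np.max(np.abs(np.diff(y, 2))) < 1e-10


class TestGatingCurrent:
    def test_zero_charge_zero_trace(self, cond_na, wt_model):
        par = Parameterization(name="noq", rate_overrides={
            f"{a}-{b}.q_gating": ("=", 0.0)
            for a, b in [(1, 2), (3, 4), (5, 6), (7, 8), (1, 3), (2, 4)]})
        m = build_state_model(par)
        occ = integrate_occupancies(m, protocols.step_protocol(), 0.0, cond_na)
        with pytest.raises(ValueError, match="no gating charge"):
            gating_current(occ, m)

    def test_on_off_charge_balance(self, wt_model, cond_na):
        """Q_on equals -Q_off over a complete pulse cycle that returns to the
        holding equilibrium: the cumulative charge (exact time integral of
        the gating current) comes back to its starting value within 1e-6 of
        Q_on, and the rendered-trace integral agrees to quadrature accuracy."""
        proto = VoltageProtocol(holding=-120.0,
                                epochs=(Epoch(25.0, 60.0), Epoch(120.0, -120.0)),
                                sample_interval=0.02)
        occ = integrate_occupancies(wt_model, proto, 0.0, cond_na)
        q = gating_charge(occ, wt_model, scale=1.0)
        t_step = 1.0 + 25.0
        q_on = q[np.searchsorted(occ.time, t_step)] - q[0]
        assert abs(q[-1] - q[0]) < 1e-6 * abs(q_on)
        ig = gating_current(occ, wt_model, scale=1.0)
        q_net_trace = np.trapezoid(ig, occ.time)
        assert abs(q_net_trace) < 0.02 * abs(q_on)

    def test_saturating_step_moves_total_charge(self, wt_model, cond_na):
        """A step to saturating voltage moves the full allocated gating
        charge."""
        proto = VoltageProtocol(holding=-150.0, epochs=(Epoch(40.0, 80.0),),
                                sample_interval=0.02)
        occ = integrate_occupancies(wt_model, proto, 0.0, cond_na)
        q = gating_charge(occ, wt_model, scale=1.0)
        assert q[-1] - q[0] == pytest.approx(wt_model.total_gating_charge,
                                             rel=1e-4)


class TestAcquisition:
    def test_same_seed_identical_sweepset(self, cond_na):
        acq = AcquisitionSettings(noise_sigma=0.01)
        a = run_protocol("WT", protocols.step_protocol(duration=5.0,
                                                       tail_duration=2.0),
                         cond_na, acq, seed=42)
        b = run_protocol("WT", protocols.step_protocol(duration=5.0,
                                                       tail_duration=2.0),
                         cond_na, acq, seed=42)
        for k in a.sweeps:
            assert np.array_equal(a.sweeps[k], b.sweeps[k])

    def test_noise_requires_seed(self, cond_na):
        acq = AcquisitionSettings(noise_sigma=0.01)
        with pytest.raises(ValueError, match="seed"):
            run_protocol("WT", protocols.step_protocol(duration=5.0,
                                                       tail_duration=2.0),
                         cond_na, acq, seed=None)

    def test_p4_cancels_linear_components(self, cond_na):
        """With a purely linear (leak + capacitive) response, P/-4 subtraction
        leaves a residual below 1e-10 of the raw amplitude."""
        par = Parameterization(
            name="linear_only",
            rate_overrides={f"{a}-{b}.q_gating": ("=", 0.0)
                            for a, b in [(1, 2), (3, 4), (5, 6), (7, 8),
                                         (1, 3), (2, 4)]},
            perm_overrides={sid: {"Na": 0.0, "K": 0.0} for sid in range(1, 9)})
        m = build_state_model(par)
        proto = VoltageProtocol(
            holding=-100.0, epochs=(Epoch(10.0, 40.0), Epoch(8.0, -100.0)),
            subtraction=Subtraction(-4, -120.0), sample_interval=0.01)
        acq = AcquisitionSettings(leak_conductance=0.01, capacitance=0.05,
                                  apply_subtraction=True, filter_cutoff_kHz=0.0)
        ss = run_protocol("WT", proto, cond_na, acq, model=m)
        acq_raw = AcquisitionSettings(leak_conductance=0.01, capacitance=0.05,
                                      filter_cutoff_kHz=0.0)
        raw = run_protocol("WT", proto, cond_na, acq_raw, model=m)
        amp = np.max(np.abs(raw.sweeps[0.0]))
        assert np.max(np.abs(ss.sweeps[0.0])) < 1e-10 * amp

    def test_gating_charge_survives_subtraction_from_qv_plateau(self,
                                                                cond_gating):
        """Nonlinear gating charge is preserved by P/4 subtraction when the
        subtraction holding sits on the Q-V plateau (+20 mV)."""
        proto = VoltageProtocol(
            holding=-120.0, epochs=(Epoch(20.0, 0.0), Epoch(20.0, -120.0)),
            subtraction=Subtraction(4, 20.0), sample_interval=0.02)
        plain = run_protocol("WT", proto, cond_gating,
                             AcquisitionSettings(), kind="gating")
        sub = run_protocol("WT", proto, cond_gating,
                           AcquisitionSettings(apply_subtraction=True),
                           kind="gating")
        t, y0, y1 = plain.time, plain.sweeps[0.0], sub.sweeps[0.0]
        on = (t >= 1.0) & (t <= 21.0)
        q0 = np.trapezoid(y0[on], t[on])
        q1 = np.trapezoid(y1[on], t[on])
        assert q1 == pytest.approx(q0, rel=0.10)


class TestRunProtocol:
    def test_wt_transient_then_near_zero_steady(self, step_sweeps):
        ss = step_sweeps["WT"]
        y = ss.sweeps[0.0]
        t = ss.time
        pulse = (t > 1.3) & (t < 31.0)
        peak = np.max(np.abs(y[pulse]))
        steady = np.abs(y[(t > 28.0) & (t < 31.0)]).mean()
        assert steady < 0.03 * peak

    def test_diiiaa_sustained_steady_current(self, step_sweeps):
        ss = step_sweeps["DIIIAA"]
        y, t = ss.sweeps[0.0], ss.time
        peak = np.max(np.abs(y[(t > 1.3) & (t < 31.0)]))
        steady = np.abs(y[(t > 28.0) & (t < 31.0)]).mean()
        assert steady > 0.1 * peak

    def test_zero_amplitude_steps_give_flat_traces(self, cond_na, acq):
        proto = VoltageProtocol(holding=-100.0,
                                epochs=(Epoch(10.0, -100.0), Epoch(5.0, -100.0)),
                                sample_interval=0.02)
        ss = run_protocol("WT", proto, cond_na, acq)
        assert np.ptp(ss.sweeps[0.0]) < 1e-8

    def test_ttx_mode_kills_ionic_leaves_gating(self, cond_na, acq):
        """Forcing every permeability to zero silences the ionic current while
        the gating current is untouched (the TTX separation logic)."""
        proto = protocols.step_protocol(duration=8.0, tail_duration=4.0)
        par = Parameterization(
            name="WT_ttx",
            perm_overrides={sid: {"Na": 0.0, "K": 0.0} for sid in range(1, 9)})
        m_ttx = build_state_model(par)
        m = build_state_model("WT")
        occ = integrate_occupancies(m, proto, 0.0, cond_na)
        occ_ttx = integrate_occupancies(m_ttx, proto, 0.0, cond_na)
        with pytest.raises(ValueError, match="no conducting state"):
            ionic_current(occ_ttx, cond_na, m_ttx)
        g0 = gating_current(occ, m)
        g1 = gating_current(occ_ttx, m_ttx)
        assert np.allclose(g0, g1, atol=1e-12)

    def test_duration_family_shares_longest_grid(self, diiiaa_tails):
        n = len(diiiaa_tails.time)
        for y in diiiaa_tails.sweeps.values():
            assert len(y) == n
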