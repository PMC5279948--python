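"""Unit and property tests for the whole-cell current model."""

import dataclasses
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cavcmi import channel_model as cmod
from cavcmi import ephys_metrics as emet
from cavcmi.channel_model import (GatingParams, InductionSchedule,
                                  InfeasibleError, VoltageProtocol)


class TestActivationCurve:
    def test_midpoint_is_half(self, default_params):
        assert cmod.activation_curve(default_params.v_half, default_params) \
            == pytest.approx(0.5)

    def test_saturates_at_one(self, default_params):
        assert cmod.activation_curve(200.0, default_params) \
            == pytest.approx(1.0, abs=1e-9)

    def test_boltzmann_value(self):
        # 1/(1 + e^-1) evaluated independently to high precision
        p = GatingParams(v_half=-20.0, k_slope=7.0)
        assert cmod.activation_curve(-13.0, p) \
            == pytest.approx(0.7310585786300049, rel=1e-12)

    @given(v1=st.floats(-100, 100), v2=st.floats(-100, 100))
    @settings(max_examples=50, deadline=None)
    def test_monotone_increasing(self, v1, v2):
        p = GatingParams()
        lo, hi = sorted([v1, v2])
        assert cmod.activation_curve(lo, p) <= cmod.activation_curve(hi, p)


class TestCdiGate:
    def test_no_inactivation_at_onset(self, default_params):
        assert cmod.cdi_gate(0.0, -10.0, default_params) == pytest.approx(1.0)

    def test_steady_state_at_max_current_voltage(self, default_params):
        # -10 mV is the family voltage of maximal current for the defaults
        assert cmod.cdi_gate(1e7, -10.0, default_params) \
            == pytest.approx(default_params.r_inf_max, rel=1e-6)

    def test_exponential_value(self, default_params):
        # 0.20 + 0.80 * e^(-50/15), independent evaluation
        assert cmod.cdi_gate(50.0, -10.0, default_params) \
            == pytest.approx(0.2 + 0.8 * math.exp(-50.0 / 15.0), rel=1e-12)

    def test_rejects_negative_time(self, default_params):
        with pytest.raises(ValueError):
            cmod.cdi_gate(-1.0, -10.0, default_params)


class TestSimulateStepCurrent:
    def test_baseline_s_ca(self, default_params, single_step):
        trace = cmod.simulate_step_current(default_params, single_step)
        assert emet.trace_indices(trace).s_ca == pytest.approx(0.77, abs=0.005)

    def test_ultrastrong_cmi_is_flat_at_end_stage(self, default_params):
        p = dataclasses.replace(default_params, w=1.0)
        trace = cmod.simulate_step_current(p)
        ix = emet.trace_indices(trace)
        assert ix.s_ca == pytest.approx(0.0, abs=1e-12)
        assert ix.i_peak == pytest.approx(ix.i_300, rel=1e-12)
        assert np.ptp(trace.current) == pytest.approx(0.0, abs=1e-9)

    def test_cmi_peak_fraction(self, default_params, cmi_params):
        base = cmod.simulate_step_current(default_params)
        cmi = cmod.simulate_step_current(cmi_params)
        ratio = abs(emet.trace_indices(cmi).i_peak) \
            / abs(emet.trace_indices(base).i_peak)
        assert ratio == pytest.approx(0.35, abs=0.0005)

    def test_rejects_bad_inputs(self, default_params, single_step):
        with pytest.raises(ValueError):
            dataclasses.replace(default_params, w=1.5)
        with pytest.raises(ValueError):
            cmod.simulate_step_current(default_params, single_step, cm=-1.0)

    def test_ba_trace_is_slow_vdi_only(self, default_params):
        trace = cmod.simulate_step_current(default_params, carrier="Ba")
        r50 = emet.trace_indices(trace).r_50
        assert r50 == pytest.approx(math.exp(-50.0 / 1640.0), rel=1e-9)

    def test_vdi_on_ca_multiplies_both_populations(self, cmi_params):
        plain = cmod.simulate_step_current(cmi_params)
        vdi = cmod.simulate_step_current(cmi_params, vdi_on_ca=True)
        factor = np.exp(-plain.time / cmi_params.tau_vdi)
        assert np.allclose(vdi.current, plain.current * factor, rtol=1e-12)


class TestConstantI300:
    """The current at 300 ms is the CMI-invariant quantity."""

    @pytest.mark.parametrize("w", [0.0, 0.1, 0.25, 0.5, 0.8125, 0.99, 1.0])
    def test_i300_invariant_in_w(self, default_params, w):
        base = cmod.simulate_step_current(default_params)
        test = cmod.simulate_step_current(
            dataclasses.replace(default_params, w=w))
        i300_b = emet.trace_indices(base).i_300
        i300_t = emet.trace_indices(test).i_300
        assert abs(i300_t - i300_b) <= 1e-9 * abs(i300_b)

    def test_peak_strictly_decreasing_in_w(self, default_params):
        peaks = []
        for w in np.linspace(0, 1, 11):
            tr = cmod.simulate_step_current(
                dataclasses.replace(default_params, w=float(w)))
            peaks.append(abs(emet.trace_indices(tr).i_peak))
        assert all(a > b for a, b in zip(peaks, peaks[1:]))

    @given(w=st.floats(0, 1))
    @settings(max_examples=25, deadline=None)
    def test_peak_never_below_end_stage_floor(self, w):
        p = GatingParams(w=w)
        ix = emet.trace_indices(cmod.simulate_step_current(p))
        assert abs(ix.i_peak) >= abs(ix.i_300) - 1e-9 * abs(ix.i_300)


class TestMixtureWeight:
    def test_no_inhibition(self):
        assert cmod.mixture_weight_for_peak_fraction(1.0, 0.2) == 0.0

    def test_floor_gives_ultrastrong(self):
        assert cmod.mixture_weight_for_peak_fraction(0.2, 0.2) \
            == pytest.approx(1.0)

    def test_printed_scenario_weight(self):
        assert cmod.mixture_weight_for_peak_fraction(0.35, 0.2) \
            == pytest.approx(0.8125)

    def test_below_floor_is_infeasible(self):
        with pytest.raises(InfeasibleError):
            cmod.mixture_weight_for_peak_fraction(0.1, 0.2)

    def test_matches_simulated_peak_ratio_on_grid(self, default_params):
        # scan w and invert the simulated peak ratio; closed form must agree
        base_peak = abs(emet.trace_indices(
            cmod.simulate_step_current(default_params)).i_peak)
        r_end = cmod.end_stage_fraction(-10.0, default_params)
        for w in np.linspace(0.0, 1.0, 21):
            tr = cmod.simulate_step_current(
                dataclasses.replace(default_params, w=float(w)))
            frac = abs(emet.trace_indices(tr).i_peak) / base_peak
            w_back = cmod.mixture_weight_for_peak_fraction(frac, r_end)
            assert w_back == pytest.approx(w, abs=1e-4)


def _grid_oracle(s_b, pf, s_c, r_step=1e-3, tau_lo=5.0, tau_hi=40.0,
                 tau_step=0.05):
    """Brute-force 2-D grid over (r_inf, tau_cdi) minimizing the residuals
    of the three index constraints; independent of the closed-form path."""
    r50 = 1.0 - s_b
    r = np.arange(r_step, r50, r_step)
    tau = np.arange(tau_lo, tau_hi, tau_step)
    R, T = np.meshgrid(r, tau, indexing="ij")
    h50 = R + (1 - R) * np.exp(-50.0 / T)
    W = (1.0 - pf) / (1.0 - R)
    peak = 1.0 - W * (1.0 - R)
    r50_mix = (W * R + (1 - W) * h50) / peak
    resid = (h50 - r50) ** 2 + (r50_mix - (1.0 - s_c)) ** 2 \
        + np.where(W <= 1.0, 0.0, np.inf)
    i, j = np.unravel_index(np.argmin(resid), resid.shape)
    return float(T[i, j]), float(R[i, j]), float(W[i, j])


class TestCalibration:
    def test_printed_triple(self):
        cal = cmod.calibrate_cdi_params(0.77, 0.35, 0.41)
        assert cal.r_inf_max == pytest.approx(0.20, abs=0.005)
        assert cal.w == pytest.approx(0.81, abs=0.005)
        assert cal.tau_cdi == pytest.approx(15.0, abs=0.2)

    def test_agrees_with_grid_oracle(self):
        cal = cmod.calibrate_cdi_params(0.77, 0.35, 0.41)
        tau_g, r_g, w_g = _grid_oracle(0.77, 0.35, 0.41)
        assert cal.r_inf_max == pytest.approx(r_g, abs=2e-3)
        assert cal.tau_cdi == pytest.approx(tau_g, abs=0.1)
        assert cal.w == pytest.approx(w_g, abs=5e-3)

    def test_round_trip_recovers_generator(self, single_step):
        gen = GatingParams(tau_cdi=22.0, r_inf_max=0.3, w=0.6)
        base = cmod.simulate_step_current(dataclasses.replace(gen, w=0.0),
                                          single_step)
        cmi = cmod.simulate_step_current(gen, single_step)
        ib, ic = emet.trace_indices(base), emet.trace_indices(cmi)
        cal = cmod.calibrate_cdi_params(
            ib.s_ca, abs(ic.i_peak) / abs(ib.i_peak), ic.s_ca)
        assert cal.tau_cdi == pytest.approx(gen.tau_cdi, rel=0.01)
        assert cal.r_inf_max == pytest.approx(gen.r_inf_max, rel=0.01)
        assert cal.w == pytest.approx(gen.w, rel=0.01)

    def test_inconsistent_inputs_are_infeasible(self):
        # near-untouched peak cannot coexist with strongly attenuated CDI:
        # the implied floor exceeds r50
        with pytest.raises(InfeasibleError):
            cmod.calibrate_cdi_params(0.77, 0.95, 0.41)
        with pytest.raises(InfeasibleError):
            cmod.calibrate_cdi_params(0.41, 0.35, 0.77)  # ordering violated


class TestBlockAndRundown:
    def test_identity_block(self, default_params):
        assert cmod.apply_block(default_params, 0.0) == default_params

    def test_block_scales_peak_not_gating(self, default_params):
        base = emet.trace_indices(cmod.simulate_step_current(default_params))
        blocked = emet.trace_indices(
            cmod.simulate_step_current(cmod.apply_block(default_params, 0.28)))
        assert abs(blocked.i_peak) / abs(base.i_peak) \
            == pytest.approx(0.72, rel=1e-12)
        assert blocked.s_ca == pytest.approx(base.s_ca, abs=1e-10)

    def test_block_composes_multiplicatively(self, default_params):
        twice = cmod.apply_block(cmod.apply_block(default_params, 0.5), 0.5)
        assert twice.g_density \
            == pytest.approx(0.25 * default_params.g_density, rel=1e-12)

    def test_block_fraction_domain(self, default_params):
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                cmod.apply_block(default_params, bad)

    def test_rundown_declines_peak_and_i300_together(self, default_params):
        sweeps = cmod.simulate_rundown_timecourse(
            default_params, decay_tau=120.0, n_sweeps=3, sweep_interval=60.0)
        ix = [emet.trace_indices(tr) for tr in sweeps]
        # sweep at t=120 s sits at e^-1 of sweep 1, equally for peak and I300
        assert abs(ix[2].i_peak) / abs(ix[0].i_peak) \
            == pytest.approx(math.exp(-1.0), rel=1e-9)
        assert abs(ix[2].i_300) / abs(ix[0].i_300) \
            == pytest.approx(math.exp(-1.0), rel=1e-9)
        s_cas = [x.s_ca for x in ix]
        assert max(s_cas) - min(s_cas) < 1e-10


class TestInductionTimecourse:
    def test_control_sweeps_identical(self, default_params):
        sched = InductionSchedule(w_final=0.0, n_sweeps=5)
        sweeps = cmod.simulate_induction_timecourse(default_params, sched)
        for tr in sweeps[1:]:
            assert np.array_equal(tr.current, sweeps[0].current)

    def test_asymptotic_cmi_indices(self, default_params):
        sched = InductionSchedule(t_onset=0.0, tau_perfusion=75.0,
                                  w_final=0.8125, n_sweeps=21,
                                  sweep_interval=30.0)
        sweeps = cmod.simulate_induction_timecourse(default_params, sched)
        first = emet.trace_indices(sweeps[0])
        last = emet.trace_indices(sweeps[-1])
        # 10 min of perfusion: indices approach the plateau values
        assert last.s_ca == pytest.approx(0.41, abs=0.01)
        assert abs(last.i_peak) / abs(first.i_peak) == pytest.approx(0.35,
                                                                     abs=0.01)

    def test_peak_nonincreasing_i300_constant(self, default_params):
        sched = InductionSchedule(t_onset=30.0, w_final=0.9, n_sweeps=15)
        sweeps = cmod.simulate_induction_timecourse(default_params, sched)
        ix = [emet.trace_indices(tr) for tr in sweeps]
        peaks = [abs(x.i_peak) for x in ix]
        assert all(a >= b - 1e-12 for a, b in zip(peaks, peaks[1:]))
        i300 = [abs(x.i_300) for x in ix]
        assert max(i300) - min(i300) <= 1e-6 * i300[0]

    def test_w_timecourse_saturating(self):
        sched = InductionSchedule(t_onset=30.0, tau_perfusion=75.0,
                                  w_final=0.8125)
        ts = np.linspace(0, 600, 61)
        ws = [sched.w_at(t) for t in ts]
        assert all(a <= b + 1e-15 for a, b in zip(ws, ws[1:]))
        assert max(ws) <= sched.w_final
        # plateau (>97%) within 4-5 min of onset
        assert sched.w_at(30.0 + 270.0) > 0.97 * sched.w_final


class TestOracleEquivalence:
    """Closed-form indices must match trace-based measurement."""

    @pytest.mark.parametrize("w", [0.0, 0.4, 0.8125])
    @pytest.mark.parametrize("v", [-30.0, -10.0, 10.0])
    def test_closed_form_matches_trace(self, w, v):
        p = GatingParams(w=w)
        proto = VoltageProtocol.default_single(step_potential=v)
        ix = emet.trace_indices(cmod.simulate_step_current(p, proto))
        cf = cmod.closed_form_indices(p, v=v)
        assert ix.i_peak == pytest.approx(cf["i_peak"], rel=1e-6)
        assert ix.r_50 == pytest.approx(cf["r_50"], rel=1e-6)
        assert ix.r_300 == pytest.approx(cf["r_300"], rel=1e-6)


class TestUVMirror:
    def test_cdi_deepest_at_voltage_of_max_current(self, default_params,
                                                   family_protocol):
        traces = cmod.simulate_family(default_params, family_protocol)
        ix = [emet.trace_indices(tr) for tr in traces]
        s_ca = np.array([x.s_ca for x in ix])
        j_peak = np.array([abs(x.j_peak) for x in ix])
        assert int(np.argmax(s_ca)) == int(np.argmax(j_peak))


class TestProtocolValidation:
    def test_sample_interval_bound(self):
        with pytest.raises(ValueError):
            VoltageProtocol(step_duration=300.0, sample_interval=5.0)

    def test_family_has_thirteen_steps(self, family_protocol):
        assert family_protocol.voltages() == tuple(range(-70, 51, 10))

    def test_family_rejected_by_single_step_simulator(self, default_params,
                                                      family_protocol):
        with pytest.raises(ValueError):
            cmod.simulate_step_current(default_params, family_protocol)
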