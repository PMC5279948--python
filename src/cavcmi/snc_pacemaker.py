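"""Minimal SNc dopaminergic-neuron model carrying the Cav1.3 CMI mechanism.

A single-compartment conductance-based model with instantaneous-activation
spiking currents (Na with inactivation, delayed-rectifier K), a leak, and the
Cav1.3 L-type current whose CDI is driven by a one-pool submembrane Ca2+
concentration.  CMI is the two-population weighting of the trace model: a
fraction ``1 - w`` of L-type conductance carries dynamic CDI (gate h) and a
fraction ``w`` is locked at the end-stage fraction ``r_inf_max`` — the
dynamic counterpart of pinning the non-inactivating current at end-stage
amplitude, which preserves the constant-I300 rule.  Dihydropyridine-style
block scales the whole L-type conductance by ``1 - block_fraction``.

The slow pacemaker/oscillation cycle is Ca2+-driven: L-type current
depolarizes, Ca2+ accumulates, CDI shuts the L-type current, the membrane
sags while Ca2+ is extruded, CDI recovers and the cycle restarts.  Reducing
Ca2+ influx (CMI or block) therefore slows both the subthreshold oscillation
(g_Na = 0, TTX-like) and spiking pacemaking.

Integration is fixed-step RK4 (default dt = 0.025 ms): deterministic,
bit-identical across runs, simple to regression-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .channel_model import CurrentTrace, VoltageProtocol

__all__ = [
    "NeuronParams",
    "PacemakerResult",
    "RateEstimate",
    "SimulationUnstableError",
    "simulate",
    "measure_rate",
    "ca_influx",
    "sweep_cmi",
    "voltage_clamp_step",
]


class SimulationUnstableError(RuntimeError):
    """The membrane potential left the physical range (|V| > 200 mV)."""


@dataclass(frozen=True)
class NeuronParams:
    """Free parameters of the minimal SNc model.

    Conductances in nS, capacitance in pF, potentials in mV, time in ms,
    submembrane Ca2+ in uM.  ``ca_influx_factor`` converts L-type current to
    concentration rate (uM per pA*ms); it is large because the relevant pool
    is a thin submembrane shell.  ``mode='oscillation'`` forces g_na = 0
    (TTX-like) to expose the subthreshold Ca2+ oscillation.

    The defaults were tuned once to an SNc-typical 1-4 Hz pacemaking baseline
    and frozen; they are regression-tested, not fitted to data.
    """

    capacitance: float = 40.0
    g_na: float = 600.0
    g_k: float = 60.0
    g_leak: float = 1.5
    g_cal: float = 3.0
    e_na: float = 50.0
    e_k: float = -90.0
    e_leak: float = -62.0
    e_ca: float = 45.0
    # Na kinetics (instantaneous m^3, inactivation h)
    na_m_half: float = -30.0
    na_m_slope: float = 6.0
    na_h_half: float = -52.0
    na_h_slope: float = 6.0
    # K kinetics (single gate n^2)
    k_n_half: float = -20.0
    k_n_slope: float = 9.0
    # L-type activation (instantaneous)
    cal_m_half: float = -45.0
    cal_m_slope: float = 4.0
    # submembrane Ca2+ pool
    ca_influx_factor: float = 1e-4   # uM per pA*ms (thin submembrane shell)
    ca_tau: float = 200.0            # ms, extrusion
    # Ca2+-driven CDI
    k_cdi: float = 0.2               # uM, half-inactivation
    hill_n: float = 4.0
    tau_h: float = 55.0              # ms
    r_inf_max: float = 0.20
    # CMI / block
    w: float = 0.0
    block_fraction: float = 0.0
    mode: str = "pacemaking"

    def __post_init__(self) -> None:
        for name in ("capacitance", "g_na", "g_k", "g_leak", "g_cal"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if not 0.0 <= self.block_fraction < 1.0:
            raise ValueError("block_fraction must lie in [0, 1)")
        if self.mode not in ("pacemaking", "oscillation"):
            raise ValueError("mode must be 'pacemaking' or 'oscillation'")

    @property
    def effective_g_na(self) -> float:
        return 0.0 if self.mode == "oscillation" else self.g_na


@dataclass(frozen=True)
class PacemakerResult:
    """Simulation output: recorded state, events, and summary scalars."""

    time: np.ndarray        # ms
    v: np.ndarray           # mV
    ca_sub: np.ndarray      # uM
    i_cal: np.ndarray       # pA
    spike_times: list       # ms (mode-appropriate events)
    rate: float             # Hz, (n_events - 1)/span
    ca_influx_per_s: float  # pC/s, mean |I_CaL|
    params: NeuronParams
    dt: float


class RateEstimate(NamedTuple):
    rate_hz: float
    n_events: int
    quiescent: bool


def _sigmoid(v: float, half: float, slope: float) -> float:
    return 1.0 / (1.0 + math.exp(-(v - half) / slope))


def simulate(params: NeuronParams, duration: float = 20000.0,
             dt: float = 0.025, record_every: int = 4,
             v0: float = -60.0) -> PacemakerResult:
    """Integrate the model with fixed-step RK4.

    ``duration`` and ``dt`` are in ms (dt must be <= 0.05 for accuracy;
    durations of at least ~5 s are needed for a stable rate estimate).
    State is recorded every ``record_every`` steps.  Deterministic: identical
    inputs give bit-identical output.
    """
    if dt > 0.05:
        raise ValueError("dt must be <= 0.05 ms")
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(duration / dt))

    c = params.capacitance
    g_na = params.effective_g_na
    g_k, g_leak = params.g_k, params.g_leak
    g_cal_eff = params.g_cal * (1.0 - params.block_fraction)
    e_na, e_k, e_leak, e_ca = params.e_na, params.e_k, params.e_leak, params.e_ca
    kappa, ca_tau = params.ca_influx_factor, params.ca_tau
    k_cdi, hill_n, tau_h = params.k_cdi, params.hill_n, params.tau_h
    r_inf = params.r_inf_max
    w = params.w
    nm_h, nm_s = params.na_m_half, params.na_m_slope
    nh_h, nh_s = params.na_h_half, params.na_h_slope
    kn_h, kn_s = params.k_n_half, params.k_n_slope
    cm_h, cm_s = params.cal_m_half, params.cal_m_slope
    exp = math.exp

    def deriv(v, h_na, n, h, ca):
        m_na = 1.0 / (1.0 + exp(-(v - nm_h) / nm_s))
        h_na_inf = 1.0 / (1.0 + exp((v - nh_h) / nh_s))
        tau_h_na = 0.4 + 6.0 / (1.0 + exp((v + 45.0) / 8.0))
        n_inf = 1.0 / (1.0 + exp(-(v - kn_h) / kn_s))
        tau_n = 1.0 + 4.0 / (1.0 + exp((v + 30.0) / 10.0))
        m_cal = 1.0 / (1.0 + exp(-(v - cm_h) / cm_s))
        gate = (1.0 - w) * h + w * r_inf
        i_cal = g_cal_eff * m_cal * gate * (v - e_ca)
        i_na = g_na * m_na * m_na * m_na * h_na * (v - e_na)
        i_k = g_k * n * n * (v - e_k)
        i_leak = g_leak * (v - e_leak)
        dv = -(i_na + i_k + i_cal + i_leak) / c
        dh_na = (h_na_inf - h_na) / tau_h_na
        dn = (n_inf - n) / tau_n
        ratio = (ca / k_cdi) ** hill_n
        h_inf = r_inf + (1.0 - r_inf) / (1.0 + ratio)
        dh = (h_inf - h) / tau_h
        dca = -kappa * i_cal - ca / ca_tau
        return dv, dh_na, dn, dh, dca, i_cal

    # steady-state gates at v0, fully recovered CDI, resting Ca2+
    v = v0
    h_na = 1.0 / (1.0 + exp((v - nh_h) / nh_s))
    n = 1.0 / (1.0 + exp(-(v - kn_h) / kn_s))
    h = 1.0
    ca = 0.0

    n_rec = n_steps // record_every + 1
    t_rec = np.empty(n_rec)
    v_rec = np.empty(n_rec)
    ca_rec = np.empty(n_rec)
    ical_rec = np.empty(n_rec)
    abs_ical_sum = 0.0

    k = 0
    for step in range(n_steps + 1):
        if step % record_every == 0 and k < n_rec:
            d0 = deriv(v, h_na, n, h, ca)
            t_rec[k] = step * dt
            v_rec[k] = v
            ca_rec[k] = ca
            ical_rec[k] = d0[5]
            k += 1
        if step == n_steps:
            break
        k1 = deriv(v, h_na, n, h, ca)
        k2 = deriv(v + 0.5 * dt * k1[0], h_na + 0.5 * dt * k1[1],
                   n + 0.5 * dt * k1[2], h + 0.5 * dt * k1[3],
                   ca + 0.5 * dt * k1[4])
        k3 = deriv(v + 0.5 * dt * k2[0], h_na + 0.5 * dt * k2[1],
                   n + 0.5 * dt * k2[2], h + 0.5 * dt * k2[3],
                   ca + 0.5 * dt * k2[4])
        k4 = deriv(v + dt * k3[0], h_na + dt * k3[1], n + dt * k3[2],
                   h + dt * k3[3], ca + dt * k3[4])
        v += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        h_na += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
        n += dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2])
        h += dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3])
        ca += dt / 6.0 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4])
        abs_ical_sum += abs(k1[5]) * dt
        if abs(v) > 200.0:
            raise SimulationUnstableError(
                f"|V| exceeded 200 mV at t = {step * dt:.2f} ms "
                f"(V = {v:.1f} mV); check parameters/dt")

    t_rec, v_rec = t_rec[:k], v_rec[:k]
    ca_rec, ical_rec = ca_rec[:k], ical_rec[:k]
    influx = abs_ical_sum / duration  # mean |I_CaL| in pA == pC/s

    result = PacemakerResult(time=t_rec, v=v_rec, ca_sub=ca_rec,
                             i_cal=ical_rec, spike_times=[], rate=0.0,
                             ca_influx_per_s=influx, params=params, dt=dt)
    est = measure_rate(result, params.mode)
    events = _event_times(result, params.mode)
    return replace(result, spike_times=events, rate=est.rate_hz)


def _event_times(result: PacemakerResult, mode: str,
                 discard_ms: float = 1000.0) -> list[float]:
    """Upward-crossing event times (0 mV for spikes, mean V for oscillation).

    The first second is discarded as initial transient.  Oscillation
    crossings use a +/-1 mV hysteresis band around the mean so that the
    sub-mV wiggle of a trace settling to rest does not register as events.
    """
    t, v = result.time, result.v
    keep = t >= discard_ms
    if keep.sum() < 2:
        keep = np.ones_like(t, dtype=bool)
    t, v = t[keep], v[keep]
    events: list[float] = []
    if mode == "pacemaking":
        level, refractory = 0.0, 2.0
        above = v >= level
        crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
        for idx in crossings:
            ti = float(t[idx])
            if not events or ti - events[-1] >= refractory:
                events.append(ti)
    else:
        level, refractory, band = float(np.mean(v)), 50.0, 1.0
        armed = v[0] < level - band
        for i in range(1, v.size):
            if v[i] < level - band:
                armed = True
            elif armed and v[i] >= level + band:
                ti = float(t[i])
                if not events or ti - events[-1] >= refractory:
                    events.append(ti)
                armed = False
    return events


def measure_rate(result: PacemakerResult, mode: str | None = None) -> RateEstimate:
    """Event rate in Hz: (n_events - 1) / span between first and last event.

    Pacemaking counts upward 0-mV crossings (2-ms refractory); oscillation
    counts upward crossings of the mean-V level (50-ms refractory).  Fewer
    than 2 events gives rate 0 with the quiescent flag set.
    """
    mode = mode or result.params.mode
    events = _event_times(result, mode)
    if len(events) < 2:
        return RateEstimate(rate_hz=0.0, n_events=len(events), quiescent=True)
    span_ms = events[-1] - events[0]
    return RateEstimate(rate_hz=1000.0 * (len(events) - 1) / span_ms,
                        n_events=len(events), quiescent=False)


def ca_influx(result: PacemakerResult, window: tuple[float, float] | None = None
              ) -> float:
    """Mean |I_CaL| over the window (ms) — numerically equal to pC/s."""
    if window is None:
        return result.ca_influx_per_s
    lo, hi = window
    if lo < result.time[0] or hi > result.time[-1] or hi <= lo:
        raise ValueError("window must lie within the simulated span")
    mask = (result.time >= lo) & (result.time <= hi)
    return float(np.trapezoid(np.abs(result.i_cal[mask]),
                              result.time[mask]) / (hi - lo))


def sweep_cmi(params: NeuronParams, w_values: Sequence[float],
              duration: float = 20000.0, dt: float = 0.025) -> pd.DataFrame:
    """Rate and Ca2+ influx across CMI weights; one row per w."""
    rows = []
    for w in w_values:
        if not 0.0 <= w <= 1.0:
            raise ValueError("w values must lie in [0, 1]")
        res = simulate(replace(params, w=float(w)), duration=duration, dt=dt)
        rows.append({"w": float(w), "rate_hz": res.rate,
                     "influx_pC_per_s": res.ca_influx_per_s})
    return pd.DataFrame(rows)


def voltage_clamp_step(params: NeuronParams,
                       protocol: VoltageProtocol | None = None,
                       dt: float = 0.025,
                       cm: float | None = None) -> CurrentTrace:
    """Voltage-clamp harness for the same I_CaL mechanism.

    Clamps V to the step potential with the Ca2+/CDI dynamics running and
    returns the L-type current as a :class:`CurrentTrace` — the dynamic
    analogue of the trace-model step, letting the trace indices (S_Ca, late
    current) be measured on the neuron mechanism itself.
    """
    if protocol is None:
        protocol = VoltageProtocol.default_single()
    if protocol.is_family:
        raise ValueError("voltage_clamp_step needs a single step potential")
    v = float(protocol.step_potential)  # type: ignore[arg-type]
    exp = math.exp
    m_cal = 1.0 / (1.0 + exp(-(v - params.cal_m_half) / params.cal_m_slope))
    g_eff = params.g_cal * (1.0 - params.block_fraction)
    w, r_inf = params.w, params.r_inf_max
    kappa, ca_tau = params.ca_influx_factor, params.ca_tau
    k_cdi, hill_n, tau_h = params.k_cdi, params.hill_n, params.tau_h

    def deriv(h, ca):
        gate = (1.0 - w) * h + w * r_inf
        i_cal = g_eff * m_cal * gate * (v - params.e_ca)
        h_inf = r_inf + (1.0 - r_inf) / (1.0 + (ca / k_cdi) ** hill_n)
        return (h_inf - h) / tau_h, -kappa * i_cal - ca / ca_tau, i_cal

    h, ca = 1.0, 0.0
    times = protocol.times()
    sample_every = int(round(protocol.sample_interval / dt))
    n_steps = int(round(protocol.step_duration / dt))
    out = np.empty(times.size)
    k = 0
    for step in range(n_steps + 1):
        if step % sample_every == 0 and k < out.size:
            out[k] = deriv(h, ca)[2]
            k += 1
        if step == n_steps:
            break
        k1 = deriv(h, ca)
        k2 = deriv(h + 0.5 * dt * k1[0], ca + 0.5 * dt * k1[1])
        k3 = deriv(h + 0.5 * dt * k2[0], ca + 0.5 * dt * k2[1])
        k4 = deriv(h + dt * k3[0], ca + dt * k3[1])
        h += dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0])
        ca += dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1])
    return CurrentTrace(time=times, current=out, carrier="Ca",
                        cm=cm or params.capacitance, protocol=protocol,
                        meta={"step_mV": v, "w": w, "clamp": True})
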