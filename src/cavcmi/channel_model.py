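"""Phenomenological whole-cell Cav1.3 current model with CMI mixture weighting.

The model produces voltage-step current traces in which Ca2+-dependent
inactivation (CDI) is a single exponential decaying to a voltage-scaled floor,
and C-terminus-mediated inhibition (CMI) is a two-population mixture: a
fraction ``1 - w`` of channels retains full CDI while a fraction ``w`` is
locked in a non-inactivating state pinned at the end-stage (300 ms) amplitude
of the CDI-capable population.  Pinning at the end-stage level makes the
current at 300 ms exactly invariant in ``w`` — the defining signature that
separates CMI from conventional inhibition (block, run-down), where peak and
late current fall together.

Conventions: inward current is negative; time is in ms and starts at step
onset; conductance density is in nS/pF so that ``g * (V - e_rev)`` is a
current density in pA/pF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "END_STAGE_MS",
    "VoltageProtocol",
    "GatingParams",
    "CurrentTrace",
    "InductionSchedule",
    "CalibrationResult",
    "InfeasibleError",
    "activation_curve",
    "peak_drive_weight",
    "voltage_r_inf",
    "cdi_gate",
    "end_stage_fraction",
    "simulate_step_current",
    "simulate_family",
    "closed_form_indices",
    "mixture_weight_for_peak_fraction",
    "calibrate_cdi_params",
    "apply_block",
    "simulate_induction_timecourse",
    "simulate_rundown_timecourse",
]

#: Reference time (ms) at which CDI is taken to have reached its end stage.
#: The non-inactivating CMI population is pinned at the CDI-capable
#: population's remaining fraction at this time.
END_STAGE_MS = 300.0

DEFAULT_CM_PF = 20.0


class InfeasibleError(ValueError):
    """Requested inhibition/calibration lies outside the model's reach."""


@dataclass(frozen=True)
class VoltageProtocol:
    """A square voltage-step protocol.

    ``step_potential`` may be a single potential (mV) or a tuple of potentials
    for a step family.  The default family spans -70 to +50 mV in 10-mV
    increments from a -70 mV holding potential; the default single step is
    -10 mV for 300 ms, sampled every 0.5 ms, repeated every 30 s.
    """

    holding_potential: float = -70.0
    step_potential: float | tuple[float, ...] = -10.0
    step_duration: float = 300.0
    sample_interval: float = 0.5
    repetition_interval: float = 30.0

    def __post_init__(self) -> None:
        if self.step_duration <= 0:
            raise ValueError("step_duration must be positive")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        if self.sample_interval > self.step_duration / 100.0:
            raise ValueError(
                "sample_interval must be <= step_duration/100 "
                f"({self.sample_interval} > {self.step_duration / 100.0})"
            )

    @classmethod
    def default_single(cls, step_potential: float = -10.0,
                       step_duration: float = 300.0) -> "VoltageProtocol":
        return cls(step_potential=step_potential, step_duration=step_duration)

    @classmethod
    def default_family(cls, step_duration: float = 300.0) -> "VoltageProtocol":
        return cls(step_potential=tuple(float(v) for v in range(-70, 51, 10)),
                   step_duration=step_duration)

    @property
    def is_family(self) -> bool:
        return isinstance(self.step_potential, tuple)

    def voltages(self) -> tuple[float, ...]:
        if self.is_family:
            return tuple(self.step_potential)  # type: ignore[arg-type]
        return (float(self.step_potential),)  # type: ignore[arg-type]

    def times(self) -> np.ndarray:
        n = int(round(self.step_duration / self.sample_interval))
        return np.arange(n + 1) * self.sample_interval


#: Voltage grid used to normalize the CDI floor; matches the default family.
_FAMILY_GRID = tuple(float(v) for v in range(-70, 51, 10))


def _default_g_density() -> float:
    # chosen so that J_peak at -10 mV is -20 pA/pF with the default activation
    m = 1.0 / (1.0 + math.exp(-(-10.0 - (-20.0)) / 7.0))
    return 20.0 / (m * abs(-10.0 - 45.0))


@dataclass(frozen=True)
class GatingParams:
    """Activation, CDI, VDI and conductance parameters plus the CMI weight.

    ``w`` is the CMI mixture weight (0 = no CMI, 1 = ultrastrong CMI).
    ``r_inf_max`` is the end-stage remaining fraction at the voltage of
    maximal Ca2+ current; ``tau_vdi`` is the slow Ba2+/VDI time constant
    (the default 1640 ms gives r_50,Ba ~ 0.97, close to 1).
    """

    v_half: float = -20.0
    k_slope: float = 7.0
    e_rev: float = 45.0
    g_density: float = field(default_factory=_default_g_density)
    tau_act: float = 0.0
    tau_cdi: float = 15.0
    r_inf_max: float = 0.20
    tau_vdi: float = 1640.0
    w: float = 0.0

    def __post_init__(self) -> None:
        if self.k_slope == 0:
            raise ValueError("k_slope must be nonzero")
        if not 0.0 < self.r_inf_max < 1.0:
            raise ValueError("r_inf_max must lie in (0, 1)")
        if self.tau_cdi <= 0:
            raise ValueError("tau_cdi must be positive")
        if math.isfinite(self.tau_vdi) and self.tau_vdi <= self.tau_cdi:
            raise ValueError("tau_vdi must exceed tau_cdi (VDI is much slower)")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError(f"CMI weight w must lie in [0, 1], got {self.w}")
        if self.tau_act < 0:
            raise ValueError("tau_act must be >= 0")
        if self.g_density <= 0:
            raise ValueError("g_density must be positive")


@dataclass(frozen=True)
class CurrentTrace:
    """A sampled whole-cell current record (inward negative)."""

    time: np.ndarray          # ms, strictly increasing, starts at 0
    current: np.ndarray       # pA
    carrier: str              # "Ca" or "Ba"
    cm: float                 # pF
    protocol: VoltageProtocol | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        i = np.asarray(self.current, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "current", i)
        if t.size != i.size:
            raise ValueError("time and current must have equal length")
        if t.size == 0:
            raise ValueError("empty trace")
        if t[0] != 0.0 or (t.size > 1 and np.any(np.diff(t) <= 0)):
            raise ValueError("time must start at 0 and increase strictly")
        if self.carrier not in ("Ca", "Ba"):
            raise ValueError("carrier must be 'Ca' or 'Ba'")
        if self.cm <= 0:
            raise ValueError("cm must be positive")

    @property
    def step_potential(self) -> float | None:
        if "step_mV" in self.meta:
            return float(self.meta["step_mV"])
        if self.protocol is not None and not self.protocol.is_family:
            return float(self.protocol.step_potential)  # type: ignore[arg-type]
        return None


def activation_curve(v, params: GatingParams):
    """Boltzmann steady-state activation m_inf(V) in [0, 1]."""
    v = np.asarray(v, dtype=float)
    out = 1.0 / (1.0 + np.exp(-(v - params.v_half) / params.k_slope))
    return float(out) if out.ndim == 0 else out


def _drive_magnitude(v, params: GatingParams):
    """|m_inf(V) * (V - e_rev)|, proportional to the peak current magnitude."""
    v = np.asarray(v, dtype=float)
    return np.abs(activation_curve(v, params) * (v - params.e_rev))


def peak_drive_weight(v, params: GatingParams,
                      family: Sequence[float] = _FAMILY_GRID):
    """Peak Ca2+ current magnitude at V, normalized to its family maximum.

    This weight u(V) in [0, 1] scales the CDI floor so the inactivation
    profile mirrors the V-shaped current-density profile (U-shaped CDI,
    deepest where the current is largest).
    """
    ref = float(np.max(_drive_magnitude(np.asarray(family, float), params)))
    u = _drive_magnitude(v, params) / ref
    u = np.minimum(u, 1.0)
    return float(u) if np.ndim(u) == 0 else u


def voltage_r_inf(v, params: GatingParams):
    """Steady-state remaining fraction r_inf(V) = 1 - (1-r_inf_max)*u(V)."""
    u = peak_drive_weight(v, params)
    return 1.0 - (1.0 - params.r_inf_max) * u


def cdi_gate(t, v: float, params: GatingParams):
    """CDI gate h_Ca(t, V) of the CDI-capable population; h(0) = 1."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0")
    r = voltage_r_inf(v, params)
    h = r + (1.0 - r) * np.exp(-t / params.tau_cdi)
    return float(h) if h.ndim == 0 else h


def end_stage_fraction(v: float, params: GatingParams) -> float:
    """Remaining fraction at the 300-ms end stage; the CMI pinning level."""
    return float(cdi_gate(END_STAGE_MS, v, params))


def _vdi_gate(t, params: GatingParams):
    if not math.isfinite(params.tau_vdi):
        return np.ones_like(np.asarray(t, dtype=float))
    return np.exp(-np.asarray(t, dtype=float) / params.tau_vdi)


def simulate_step_current(params: GatingParams,
                          protocol: VoltageProtocol | None = None,
                          carrier: str = "Ca",
                          cm: float = DEFAULT_CM_PF,
                          vdi_on_ca: bool = False,
                          meta: dict | None = None) -> CurrentTrace:
    """Simulate one whole-cell current trace under a single voltage step.

    For Ca2+ the current is::

        I(t) = cm * g * m_inf(V) * (V - e_rev) * m(t)
               * [(1 - w) * h_Ca(t, V) + w * h_Ca(300 ms, V)]

    i.e. a mixture of the CDI-capable population and a non-inactivating CMI
    population pinned at the end-stage amplitude, which leaves I(300 ms)
    exactly unchanged for every w.  For Ba2+ only the slow VDI exponential
    applies.  ``m(t) = 1 - exp(-t/tau_act)`` (identically 1 when tau_act = 0).
    VDI on the Ca2+ carrier is negligible on a 300-ms step and off by
    default (``vdi_on_ca=True`` enables it, applied equally to both mixture
    populations).
    """
    if protocol is None:
        protocol = VoltageProtocol.default_single()
    if protocol.is_family:
        raise ValueError("simulate_step_current needs a single step; "
                         "use simulate_family for a step family")
    if cm <= 0:
        raise ValueError("cm must be positive")
    v = float(protocol.step_potential)  # type: ignore[arg-type]
    t = protocol.times()
    amp = cm * params.g_density * activation_curve(v, params) * (v - params.e_rev)
    if params.tau_act > 0:
        m_t = 1.0 - np.exp(-t / params.tau_act)
    else:
        m_t = 1.0
    if carrier == "Ca":
        gate = (1.0 - params.w) * cdi_gate(t, v, params) \
            + params.w * end_stage_fraction(v, params)
        if vdi_on_ca:
            gate = gate * _vdi_gate(t, params)
    elif carrier == "Ba":
        gate = _vdi_gate(t, params)
    else:
        raise ValueError("carrier must be 'Ca' or 'Ba'")
    current = amp * m_t * gate
    info = {"step_mV": v, "w": params.w}
    if meta:
        info.update(meta)
    return CurrentTrace(time=t, current=current, carrier=carrier, cm=cm,
                        protocol=protocol, meta=info)


def simulate_family(params: GatingParams,
                    protocol: VoltageProtocol | None = None,
                    carrier: str = "Ca",
                    cm: float = DEFAULT_CM_PF,
                    vdi_on_ca: bool = False) -> list[CurrentTrace]:
    """Simulate a full step-family of traces (one per family voltage)."""
    if protocol is None:
        protocol = VoltageProtocol.default_family()
    traces = []
    for v in protocol.voltages():
        single = replace(protocol, step_potential=float(v))
        traces.append(simulate_step_current(params, single, carrier=carrier,
                                            cm=cm, vdi_on_ca=vdi_on_ca))
    return traces


def closed_form_indices(params: GatingParams, v: float = -10.0,
                        cm: float = DEFAULT_CM_PF) -> dict:
    """Analytic I_peak, r_50, r_300 and S_Ca for a Ca2+ step (tau_act = 0).

    Serves as the independent oracle for trace-based measurements.
    """
    if params.tau_act != 0:
        raise ValueError("closed forms hold only for instantaneous activation")
    amp = cm * params.g_density * activation_curve(v, params) * (v - params.e_rev)
    pin = end_stage_fraction(v, params)
    h50 = float(cdi_gate(50.0, v, params))
    h300 = float(cdi_gate(300.0, v, params))
    w = params.w
    peak_gate = (1.0 - w) * 1.0 + w * pin
    g50 = (1.0 - w) * h50 + w * pin
    g300 = (1.0 - w) * h300 + w * pin
    return {
        "i_peak": amp * peak_gate,
        "i_50": amp * g50,
        "i_300": amp * g300,
        "r_50": g50 / peak_gate,
        "r_300": g300 / peak_gate,
        "s_ca": 1.0 - g50 / peak_gate,
        "j_peak": amp * peak_gate / cm,
        "j_300": amp * g300 / cm,
    }


def mixture_weight_for_peak_fraction(f_remaining: float, r_inf: float) -> float:
    """Invert the peak-reduction relation: w = (1 - f) / (1 - r_inf).

    ``f_remaining`` is the desired peak as a fraction of the no-CMI peak;
    ``r_inf`` is the end-stage remaining fraction (the CMI floor).  A mixture
    cannot push the peak below the floor, so f < r_inf is infeasible.
    """
    if not 0.0 < r_inf < 1.0:
        raise ValueError("r_inf must lie in (0, 1)")
    if f_remaining > 1.0:
        raise ValueError("f_remaining cannot exceed 1")
    if f_remaining < r_inf:
        raise InfeasibleError(
            f"requested peak fraction {f_remaining} is below the end-stage "
            f"floor {r_inf}: inhibition exceeds the CMI lower limit")
    return (1.0 - f_remaining) / (1.0 - r_inf)


@dataclass(frozen=True)
class CalibrationResult:
    tau_cdi: float
    r_inf_max: float
    w: float


def calibrate_cdi_params(s_ca_baseline: float,
                         peak_fraction_cmi: float,
                         s_ca_cmi: float) -> CalibrationResult:
    """Solve (tau_cdi, r_inf_max, w) from three measured indices.

    Inputs: the baseline CDI index S_Ca, the CMI peak as a fraction of the
    baseline peak, and the CMI-state CDI index.  The consistency system ::

        r50            = 1 - s_ca_baseline
        peak_fraction  = 1 - w * (1 - r_inf)
        (w*r_inf + (1-w)*r50) / peak_fraction = 1 - s_ca_cmi
        r50            = r_inf + (1 - r_inf) * exp(-50 / tau_cdi)

    is linear in r_inf after substituting w, so it is solved exactly.
    Raises :class:`InfeasibleError` when the three inputs are mutually
    inconsistent (no parameter set in the valid domain reproduces them).
    """
    if not 0.0 < s_ca_cmi < s_ca_baseline < 1.0:
        raise InfeasibleError("require 0 < s_ca_cmi < s_ca_baseline < 1")
    if not 0.0 < peak_fraction_cmi < 1.0:
        raise InfeasibleError("peak_fraction_cmi must lie in (0, 1)")
    r50 = 1.0 - s_ca_baseline
    a = 1.0 - peak_fraction_cmi              # = w * (1 - r_inf)
    q = (1.0 - s_ca_cmi) * peak_fraction_cmi  # = w*r_inf + (1-w)*r50
    denom = a - r50 + q
    if denom == 0:
        raise InfeasibleError("degenerate index combination")
    r_inf = (a * r50 - r50 + q) / denom
    if not 0.0 < r_inf < r50:
        raise InfeasibleError(
            f"implied end-stage fraction {r_inf:.4f} outside (0, r50={r50:.4f})")
    w = a / (1.0 - r_inf)
    if not 0.0 < w <= 1.0:
        raise InfeasibleError(f"implied mixture weight {w:.4f} outside (0, 1]")
    c = (r50 - r_inf) / (1.0 - r_inf)
    if not 0.0 < c < 1.0:
        raise InfeasibleError("no positive CDI time constant fits the inputs")
    tau_cdi = -50.0 / math.log(c)
    return CalibrationResult(tau_cdi=tau_cdi, r_inf_max=r_inf, w=w)


def apply_block(params: GatingParams, block_fraction: float) -> GatingParams:
    """Conventional (pore) block: scale conductance, leave gating untouched."""
    if not 0.0 <= block_fraction < 1.0:
        raise ValueError("block_fraction must lie in [0, 1)")
    return replace(params, g_density=params.g_density * (1.0 - block_fraction))


@dataclass(frozen=True)
class InductionSchedule:
    """Perfusion-limited drug-induction time course of the CMI weight.

    w(t) = w_final * (1 - exp(-max(t - t_onset, 0) / tau_perfusion)), with
    t in seconds.  The default tau_perfusion of 75 s brings w to >97% of its
    plateau within 4-5 min, the speed of full solution exchange.
    """

    t_onset: float = 30.0
    tau_perfusion: float = 75.0
    w_final: float = 0.8125
    n_sweeps: int = 21
    sweep_interval: float = 30.0

    def __post_init__(self) -> None:
        if self.tau_perfusion <= 0:
            raise ValueError("tau_perfusion must be positive")
        if not 0.0 <= self.w_final <= 1.0:
            raise ValueError("w_final must lie in [0, 1]")
        if self.n_sweeps < 1:
            raise ValueError("n_sweeps must be >= 1")
        if self.sweep_interval <= 0:
            raise ValueError("sweep_interval must be positive")

    def w_at(self, t_s: float) -> float:
        dt = max(t_s - self.t_onset, 0.0)
        return self.w_final * (1.0 - math.exp(-dt / self.tau_perfusion))

    def sweep_times(self) -> np.ndarray:
        return np.arange(self.n_sweeps) * self.sweep_interval


def simulate_induction_timecourse(params: GatingParams,
                                  schedule: InductionSchedule,
                                  protocol: VoltageProtocol | None = None,
                                  cm: float = DEFAULT_CM_PF,
                                  vdi_on_ca: bool = False) -> list[CurrentTrace]:
    """One trace per sweep with w following the perfusion time course."""
    traces = []
    for t_s in schedule.sweep_times():
        p = replace(params, w=schedule.w_at(float(t_s)))
        tr = simulate_step_current(p, protocol, carrier="Ca", cm=cm,
                                   vdi_on_ca=vdi_on_ca,
                                   meta={"sweep_time_s": float(t_s)})
        traces.append(tr)
    return traces


def simulate_rundown_timecourse(params: GatingParams,
                                decay_tau: float,
                                protocol: VoltageProtocol | None = None,
                                cm: float = DEFAULT_CM_PF,
                                n_sweeps: int = 21,
                                sweep_interval: float = 30.0,
                                vdi_on_ca: bool = False) -> list[CurrentTrace]:
    """Run-down: conductance decays exponentially across sweeps (seconds).

    Gating is untouched, so S_Ca is constant while I_peak and I_300 decline
    with identical fractional loss — the conventional-inhibition signature.
    """
    if decay_tau <= 0:
        raise ValueError("decay_tau must be positive")
    traces = []
    for k in range(n_sweeps):
        t_s = k * sweep_interval
        scale = math.exp(-t_s / decay_tau) if math.isfinite(decay_tau) else 1.0
        p = replace(params, g_density=params.g_density * scale)
        tr = simulate_step_current(p, protocol, carrier="Ca", cm=cm,
                                   vdi_on_ca=vdi_on_ca,
                                   meta={"sweep_time_s": float(t_s)})
        traces.append(tr)
    return traces


#: Scenario presets named after the channel variants / peptide combinations
#: they emulate; labels only, no molecular model implied.
SCENARIOS: dict[str, float] = {
    "alpha1DS": 0.0,              # short variant, no CMI
    "alpha1DS-PCRD-DCRD": 0.95,   # fused trio, ultrastrong CMI
    "combination-I": 0.8125,      # IQv + PCRD-DCRD peptide
    "combination-II": 0.8125,     # IQv-PCRD + DCRD peptide
    "combination-III": 0.70,      # IQv-DCRD + PCRD peptide
}


def scenario_params(name: str, base: GatingParams | None = None) -> GatingParams:
    base = base or GatingParams()
    try:
        w = SCENARIOS[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; known: {sorted(SCENARIOS)}")
    return replace(base, w=w)
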