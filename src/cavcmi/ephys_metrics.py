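"""Gating indices and profiles computed from whole-cell current traces.

All indices are defined on current magnitudes (traces store inward current as
negative).  ``r_50`` is the fraction of the peak current remaining at 50 ms;
the CDI-strength index ``S_Ca = 1 - r_50`` (Ca2+ carrier only, conventionally
quoted at -10 mV).  ``I_300`` marks end-stage CDI and sets the lower limit of
CMI.  Timepoint reads use nearest-sample lookup (no interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .channel_model import CurrentTrace

__all__ = [
    "TraceIndices",
    "VoltageProfiles",
    "TraceTooShortError",
    "AmbiguousPeakError",
    "trace_indices",
    "mean_indices",
    "cdi_profile",
    "vga_profile",
    "timecourse_summary",
    "classify_inhibition",
]


class TraceTooShortError(ValueError):
    """The trace does not cover a requested timepoint."""


class AmbiguousPeakError(ValueError):
    """The peak is indistinguishable from the noise floor."""


@dataclass(frozen=True)
class TraceIndices:
    """Scalar gating indices of one trace (signed currents, pA)."""

    i_peak: float
    t_peak: float
    i_50: float
    i_100: float | None
    i_300: float | None
    i_1000: float | None
    r_50: float
    r_300: float | None
    s_ca: float | None     # 1 - r_50, Ca2+ carrier only
    j_peak: float          # pA/pF
    j_300: float | None    # pA/pF
    carrier: str
    cm: float


def _nearest(trace: CurrentTrace, t: float) -> float | None:
    """Current at the sample nearest to t, or None beyond coverage."""
    dt = trace.time[1] - trace.time[0] if trace.time.size > 1 else 0.0
    if t > trace.time[-1] + dt / 2:
        return None
    idx = int(np.argmin(np.abs(trace.time - t)))
    return float(trace.current[idx])


def _noise_floor(current: np.ndarray) -> float:
    # RMS of first differences / sqrt(2) estimates white-noise sd on samples
    if current.size < 3:
        return 0.0
    return float(np.std(np.diff(current)) / np.sqrt(2.0))


def trace_indices(trace: CurrentTrace) -> TraceIndices:
    """Compute all scalar indices of one trace.

    The peak is the largest-magnitude sample over the step; timed amplitudes
    are read at the nearest sample.  Raises :class:`TraceTooShortError` when
    the trace does not reach 50 ms and :class:`AmbiguousPeakError` when the
    peak does not rise above 3x the estimated noise floor.
    """
    i = trace.current
    idx = int(np.argmax(np.abs(i)))
    i_peak = float(i[idx])
    t_peak = float(trace.time[idx])
    noise = _noise_floor(i)
    # 5x: the max of several hundred pure-noise samples reaches ~3.3 sd
    if noise > 0 and abs(i_peak) < 5.0 * noise:
        raise AmbiguousPeakError(
            f"|i_peak|={abs(i_peak):.3g} pA below 5x noise floor {noise:.3g} pA")
    i_50 = _nearest(trace, 50.0)
    if i_50 is None:
        raise TraceTooShortError("trace must cover at least 50 ms")
    i_100 = _nearest(trace, 100.0)
    i_300 = _nearest(trace, 300.0)
    i_1000 = _nearest(trace, 1000.0)
    if i_peak == 0.0:
        raise AmbiguousPeakError("zero peak current")
    r_50 = abs(i_50) / abs(i_peak)
    r_300 = abs(i_300) / abs(i_peak) if i_300 is not None else None
    s_ca = (1.0 - r_50) if trace.carrier == "Ca" else None
    return TraceIndices(
        i_peak=i_peak, t_peak=t_peak, i_50=i_50, i_100=i_100, i_300=i_300,
        i_1000=i_1000, r_50=r_50, r_300=r_300, s_ca=s_ca,
        j_peak=i_peak / trace.cm,
        j_300=(i_300 / trace.cm) if i_300 is not None else None,
        carrier=trace.carrier, cm=trace.cm,
    )


def mean_indices(per_cell: Sequence[TraceIndices]) -> TraceIndices:
    """Cohort-mean indices (indices are computed per cell, then averaged)."""
    if not per_cell:
        raise ValueError("empty cohort")

    def avg(attr):
        vals = [getattr(x, attr) for x in per_cell]
        if any(v is None for v in vals):
            return None
        return float(np.mean(vals))

    first = per_cell[0]
    return TraceIndices(
        i_peak=avg("i_peak"), t_peak=avg("t_peak"), i_50=avg("i_50"),
        i_100=avg("i_100"), i_300=avg("i_300"), i_1000=avg("i_1000"),
        r_50=avg("r_50"), r_300=avg("r_300"), s_ca=avg("s_ca"),
        j_peak=avg("j_peak"), j_300=avg("j_300"),
        carrier=first.carrier, cm=avg("cm"),
    )


@dataclass(frozen=True)
class VoltageProfiles:
    """Full-range voltage profiles of inactivation and current density."""

    voltages: tuple[float, ...]
    r50_ca: tuple[float, ...] | None = None
    r50_ba: tuple[float, ...] | None = None
    cdi_diff: tuple[float, ...] | None = None   # r50_ba - r50_ca
    j_peak: tuple[float, ...] | None = None
    j_300: tuple[float, ...] | None = None
    s_ca_at_minus10: float | None = None
    j_ca_at_minus10: float | None = None


def _family_voltages(traces: Sequence[CurrentTrace]) -> tuple[float, ...]:
    vs = []
    for tr in traces:
        v = tr.step_potential
        if v is None:
            raise ValueError("trace lacks a step potential (step_mV meta)")
        vs.append(v)
    return tuple(vs)


def cdi_profile(traces_ca: Sequence[CurrentTrace],
                traces_ba: Sequence[CurrentTrace]) -> VoltageProfiles:
    """Inactivation profiles r50(V) per carrier and the CDI index.

    Both families must share the same voltage grid.  The simplified CDI
    strength is 1 - r50_Ca at -10 mV; the strict index r50_Ba - r50_Ca is
    exposed elementwise as ``cdi_diff``.
    """
    v_ca = _family_voltages(traces_ca)
    v_ba = _family_voltages(traces_ba)
    if v_ca != v_ba:
        raise ValueError("Ca and Ba families must share the same voltage grid")
    r50_ca = tuple(trace_indices(tr).r_50 for tr in traces_ca)
    r50_ba = tuple(trace_indices(tr).r_50 for tr in traces_ba)
    cdi_diff = tuple(b - a for a, b in zip(r50_ca, r50_ba))
    s_ca_m10 = None
    if -10.0 in v_ca:
        s_ca_m10 = 1.0 - r50_ca[v_ca.index(-10.0)]
    return VoltageProfiles(voltages=v_ca, r50_ca=r50_ca, r50_ba=r50_ba,
                           cdi_diff=cdi_diff, s_ca_at_minus10=s_ca_m10)


def vga_profile(traces_ca: Sequence[CurrentTrace],
                cm: float | None = None) -> VoltageProfiles:
    """Current-density profiles J_peak(V) and J_300(V) (pA/pF)."""
    voltages = _family_voltages(traces_ca)
    j_peak, j_300 = [], []
    for tr in traces_ca:
        c = cm if cm is not None else tr.cm
        if c <= 0:
            raise ValueError("cm must be positive")
        ix = trace_indices(tr)
        j_peak.append(ix.i_peak / c)
        j_300.append(ix.i_300 / c if ix.i_300 is not None else np.nan)
    j_m10 = None
    if -10.0 in voltages:
        j_m10 = j_peak[voltages.index(-10.0)]
    return VoltageProfiles(voltages=voltages, j_peak=tuple(j_peak),
                           j_300=tuple(j_300), j_ca_at_minus10=j_m10)


def timecourse_summary(sweeps: Sequence[CurrentTrace]) -> pd.DataFrame:
    """Per-sweep table of (time_s, s_ca, i_peak_normalized, i_300_normalized).

    Peak and I300 are normalized to sweep 1, the presentation used for
    induction time courses.
    """
    if len(sweeps) < 2:
        raise ValueError("need at least 2 sweeps")
    rows = []
    ref = trace_indices(sweeps[0])
    for k, tr in enumerate(sweeps):
        ix = trace_indices(tr)
        t_s = tr.meta.get("sweep_time_s")
        if t_s is None:
            rep = tr.protocol.repetition_interval if tr.protocol else 30.0
            t_s = k * rep
        rows.append({
            "time_s": float(t_s),
            "s_ca": ix.s_ca,
            "i_peak_normalized": abs(ix.i_peak) / abs(ref.i_peak),
            "i_300_normalized": (abs(ix.i_300) / abs(ref.i_300)
                                 if ix.i_300 is not None and ref.i_300
                                 else np.nan),
        })
    return pd.DataFrame(rows)


def classify_inhibition(baseline: TraceIndices, test: TraceIndices,
                        tol_rel: float = 0.10) -> str:
    """Classify an inhibition as 'cmi', 'conventional', 'mixed' or 'none'.

    CMI drops the peak and S_Ca but keeps I_300 constant; conventional
    inhibition (block, run-down) drops peak and I_300 together with S_Ca
    unaltered.  'Significant' means a relative drop greater than ``tol_rel``.
    """
    if baseline.carrier != test.carrier:
        raise ValueError("baseline and test must share the carrier")
    if baseline.s_ca is None or test.s_ca is None:
        raise ValueError("classification requires Ca2+ traces (S_Ca defined)")

    def drop(b, t):
        if b is None or t is None or b == 0:
            return False
        return (abs(b) - abs(t)) / abs(b) > tol_rel

    d_peak = drop(baseline.i_peak, test.i_peak)
    d_i300 = drop(baseline.i_300, test.i_300)
    d_s = drop(baseline.s_ca, test.s_ca)
    if d_peak and d_s and not d_i300:
        return "cmi"
    if d_peak and d_i300 and not d_s:
        return "conventional"
    if not (d_peak or d_i300 or d_s):
        return "none"
    return "mixed"


def metrics_table(traces: Sequence[CurrentTrace]) -> pd.DataFrame:
    """Flat metrics table for a set of traces (one row per trace)."""
    rows = []
    for tr in traces:
        ix = trace_indices(tr)
        rows.append({
            "scenario": tr.meta.get("scenario", ""),
            "V_mV": tr.step_potential,
            "carrier": tr.carrier,
            "i_peak_pA": ix.i_peak,
            "r50": ix.r_50,
            "s_ca": ix.s_ca,
            "j_peak_pApF": ix.j_peak,
            "j300_pApF": ix.j_300,
        })
    return pd.DataFrame(rows)
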