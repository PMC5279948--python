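"""Synthetic cohorts with the statistical structure of the real recordings.

Emulated features: per-cell membrane capacitance and channel-expression
variability (lognormal — strictly positive and right-skewed, as expected for
transient transfection), additive Gaussian recording noise on current traces
(scaled to the cell's peak current; leak assumed perfectly subtracted),
perfusion-limited drug-induction time courses, and FRET cohorts drawn from
the binding isotherm with per-cell Gaussian noise on FR and log-uniform
Dfree (spanning the saturating curve evenly).

Everything is reproducible from an integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import channel_model as cmod
from .channel_model import (CurrentTrace, GatingParams, InductionSchedule,
                            VoltageProtocol)
from .fret_binding import FretCell, fr_model

__all__ = [
    "CohortSpec",
    "SyntheticCell",
    "make_cell_cohort",
    "make_fret_cohort",
    "make_induction_dataset",
]


@dataclass(frozen=True)
class CohortSpec:
    """Statistical description of a synthetic patch-clamp cohort."""

    n_cells: int = 5
    seed: int = 0
    cm_mean: float = 20.0        # pF, typical transfected HEK cell
    cm_cv: float = 0.3
    amplitude_cv: float = 0.3    # expression (conductance) variability
    noise_rms: float = 0.02      # additive trace noise, fraction of |i_peak|
    scenario: str | None = None  # channel_model scenario label, or None
    params: GatingParams = field(default_factory=GatingParams)
    #: separate stream for recording noise; defaults to ``seed``.  Keeping it
    #: distinct lets the same cells be "re-recorded" with fresh noise
    #: (paired designs: time controls, before/after drug).
    noise_seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for name in ("cm_cv", "amplitude_cv", "noise_rms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def gating_params(self) -> GatingParams:
        if self.scenario is None:
            return self.params
        return cmod.scenario_params(self.scenario, self.params)


@dataclass(frozen=True)
class SyntheticCell:
    """One synthetic cell: its capacitance and trace(s)."""

    cm: float
    traces: tuple[CurrentTrace, ...]
    conductance_scale: float


def _lognormal(rng: np.random.Generator, mean: float, cv: float) -> float:
    """Lognormal draw parameterized by its arithmetic mean and CV."""
    if cv == 0:
        return mean
    sigma2 = np.log1p(cv ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return float(rng.lognormal(mu, np.sqrt(sigma2)))


def _add_noise(trace: CurrentTrace, noise_rms: float,
               rng: np.random.Generator) -> CurrentTrace:
    if noise_rms == 0:
        return trace
    sd = noise_rms * float(np.max(np.abs(trace.current)))
    noisy = trace.current + rng.normal(0.0, sd, size=trace.current.size)
    return replace(trace, current=noisy)


def make_cell_cohort(spec: CohortSpec,
                     protocol: VoltageProtocol | None = None,
                     carrier: str = "Ca") -> list[SyntheticCell]:
    """Draw a cohort of cells, each with a trace (or family) plus noise.

    Per cell: cm ~ lognormal(cm_mean, cm_cv); conductance scale ~
    lognormal(1, amplitude_cv); traces from the channel model with additive
    Gaussian noise of sd = noise_rms * |i_peak|.
    """
    if protocol is None:
        protocol = VoltageProtocol.default_single()
    params = spec.gating_params()
    rng_cells = np.random.default_rng(spec.seed)
    noise_seed = spec.seed if spec.noise_seed is None else spec.noise_seed
    rng_noise = np.random.default_rng(noise_seed)
    cells = []
    for _ in range(spec.n_cells):
        cm = _lognormal(rng_cells, spec.cm_mean, spec.cm_cv)
        scale = _lognormal(rng_cells, 1.0, spec.amplitude_cv)
        p = replace(params, g_density=params.g_density * scale)
        if protocol.is_family:
            clean = cmod.simulate_family(p, protocol, carrier=carrier, cm=cm)
        else:
            clean = [cmod.simulate_step_current(p, protocol, carrier=carrier,
                                                cm=cm)]
        traces = tuple(_add_noise(tr, spec.noise_rms, rng_noise)
                       for tr in clean)
        cells.append(SyntheticCell(cm=cm, traces=traces,
                                   conductance_scale=scale))
    return cells


def make_fret_cohort(n: int, kd: float, fr_max: float,
                     d_range: tuple[float, float] = (100.0, 30000.0),
                     noise_sd: float = 0.15,
                     seed: int = 0,
                     pair_label: str | None = None) -> list[FretCell]:
    """Draw n cells from the binding isotherm with Gaussian FR noise.

    Dfree is log-uniform over ``d_range``; FR = isotherm + N(0, noise_sd^2),
    floored at 0.5 (a FRET ratio cannot drop arbitrarily below baseline).
    """
    lo, hi = d_range
    if not 0 < lo < hi:
        raise ValueError("d_range must be positive and increasing")
    rng = np.random.default_rng(seed)
    d = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    fr = fr_model(d, kd, fr_max) + rng.normal(0.0, noise_sd, size=n)
    fr = np.maximum(fr, 0.5)
    return [FretCell(d_free=float(di), fr=float(fi), pair_label=pair_label)
            for di, fi in zip(d, fr)]


def make_induction_dataset(spec: CohortSpec,
                           schedule: InductionSchedule,
                           protocol: VoltageProtocol | None = None
                           ) -> list[list[CurrentTrace]]:
    """A cohort of drug-induction sweep series (one list of sweeps per cell).

    Each cell gets its own capacitance/expression draw; per-sweep noise is
    independent.  With n_cells=1 and zero noise/CV this reduces exactly to
    :func:`cavcmi.channel_model.simulate_induction_timecourse`.
    """
    if protocol is None:
        protocol = VoltageProtocol.default_single()
    params = spec.gating_params()
    rng_cells = np.random.default_rng(spec.seed)
    noise_seed = spec.seed if spec.noise_seed is None else spec.noise_seed
    rng_noise = np.random.default_rng(noise_seed)
    cohort = []
    for _ in range(spec.n_cells):
        cm = _lognormal(rng_cells, spec.cm_mean, spec.cm_cv)
        scale = _lognormal(rng_cells, 1.0, spec.amplitude_cv)
        p = replace(params, g_density=params.g_density * scale)
        sweeps = cmod.simulate_induction_timecourse(p, schedule, protocol,
                                                    cm=cm)
        cohort.append([_add_noise(tr, spec.noise_rms, rng_noise)
                       for tr in sweeps])
    return cohort


def write_manifest(path, entries: Sequence[dict]) -> None:
    """Write a plain-text manifest listing generated files with seed/scenario."""
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump({"files": list(entries)}, fh, sort_keys=False)
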