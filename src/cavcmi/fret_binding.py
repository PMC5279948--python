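"""FRET two-hybrid binding model and Kd/FRmax estimation.

The three-cube FRET two-hybrid assay reports, per cell, a FRET ratio FR and
an equivalent free-donor fluorescence intensity Dfree.  Binding of the
YFP-tagged acceptor construct to the CFP-tagged donor follows a single-site
isotherm in Dfree::

    FR(Dfree) = 1 + (FRmax - 1) / (1 + Kd / Dfree)

with FR -> 1 at vanishing donor and FR -> FRmax at saturation.  Kd is in
donor-cube fluorescence-intensity units and is therefore instrument-relative;
only ratios of Kd between pairs measured on the same setup are interpretable.

Cells are conventionally displayed and fitted after averaging over groups of
five adjacent cells sorted by Dfree (:func:`bin_cells`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "FretCell",
    "BindingFit",
    "AffinityComparison",
    "UnidentifiableFitError",
    "fr_model",
    "bin_cells",
    "fit_binding",
    "compare_affinity",
]

#: Minimum Dfree fold-range for an identifiable Kd.
MIN_DFREE_FOLD_RANGE = 10.0


class UnidentifiableFitError(ValueError):
    """The data cannot constrain (Kd, FRmax) — flat or range-deficient."""


@dataclass(frozen=True)
class FretCell:
    """One cell's (Dfree, FR) measurement."""

    d_free: float
    fr: float
    pair_label: str | None = None

    def __post_init__(self) -> None:
        if self.d_free <= 0:
            raise ValueError("d_free must be positive")


@dataclass(frozen=True)
class BindingFit:
    """Fitted binding isotherm with diagnostics."""

    kd: float
    fr_max: float
    rss: float
    n_points: int
    converged: bool
    kd_interval: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kd <= 0:
            raise ValueError("kd must be positive")
        if self.rss < 0:
            raise ValueError("rss must be >= 0")


def fr_model(d_free, kd: float, fr_max: float):
    """Binding isotherm FR = 1 + (FRmax - 1) / (1 + Kd / Dfree)."""
    if kd <= 0:
        raise ValueError("kd must be positive")
    d = np.asarray(d_free, dtype=float)
    if np.any(d <= 0):
        raise ValueError("d_free must be positive")
    out = 1.0 + (fr_max - 1.0) / (1.0 + kd / d)
    return float(out) if out.ndim == 0 else out


def bin_cells(cells: Sequence[FretCell], bin_size: int = 5) -> list[FretCell]:
    """Average consecutive groups of ``bin_size`` cells sorted by Dfree.

    A final partial bin of at least ceil(bin_size/2) cells is kept; smaller
    remainders are dropped.  ``bin_size=1`` is the identity (modulo sorting).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    if not cells:
        raise ValueError("empty input")
    ordered = sorted(cells, key=lambda c: c.d_free)
    out: list[FretCell] = []
    for start in range(0, len(ordered), bin_size):
        group = ordered[start:start + bin_size]
        if len(group) < bin_size and len(group) < math.ceil(bin_size / 2):
            break
        out.append(FretCell(
            d_free=float(np.mean([c.d_free for c in group])),
            fr=float(np.mean([c.fr for c in group])),
            pair_label=group[0].pair_label,
        ))
    return out


def fit_binding(points: Sequence[FretCell],
                init: tuple[float, float] | None = None,
                n_boot: int = 0,
                seed: int | None = None) -> BindingFit:
    """Unweighted least-squares fit of the isotherm over (Kd, FRmax).

    Kd is optimized on a log scale (positivity, conditioning); initialization
    defaults to (median Dfree, max FR).  With ``n_boot > 0`` a nonparametric
    bootstrap (resampling points with replacement) yields a 95% percentile
    interval for Kd.

    Raises :class:`UnidentifiableFitError` when the Dfree range spans less
    than 10-fold or when the fitted FRmax - 1 is below 3x the residual RMS
    (flat data, indicative of very weak binding).
    """
    if len(points) < 4:
        raise ValueError("need at least 4 points")
    d = np.array([c.d_free for c in points], dtype=float)
    f = np.array([c.fr for c in points], dtype=float)
    if d.max() / d.min() < MIN_DFREE_FOLD_RANGE:
        raise UnidentifiableFitError(
            f"d_free spans {d.max() / d.min():.2f}-fold; "
            f"need >= {MIN_DFREE_FOLD_RANGE:.0f}-fold for identifiability")

    log_kd0 = math.log(float(np.median(d)) if init is None else init[0])
    fr_max0 = max(float(f.max()), 1.01) if init is None else init[1]

    def residuals(theta):
        kd, fr_max = math.exp(theta[0]), theta[1]
        return 1.0 + (fr_max - 1.0) / (1.0 + kd / d) - f

    sol = least_squares(residuals, x0=[log_kd0, fr_max0],
                        bounds=([math.log(1e-6 * d.min()), 1.0],
                                [math.log(1e6 * d.max()), 100.0]))
    kd = math.exp(sol.x[0])
    fr_max = float(sol.x[1])
    rss = float(np.sum(sol.fun ** 2))
    resid_rms = math.sqrt(rss / len(points))
    # the fitted curve must rise clearly above the noise: both its asymptotic
    # amplitude and its observed span across the measured Dfree range
    span = float(fr_model(d.max(), kd, fr_max) - fr_model(d.min(), kd, fr_max))
    if min(fr_max - 1.0, span) < 3.0 * resid_rms:
        raise UnidentifiableFitError(
            f"fitted FRmax-1 = {fr_max - 1.0:.3f}, observed span = {span:.3f} "
            f"vs 3x residual RMS {3 * resid_rms:.3f}: flat data, Kd "
            f"unidentifiable (very weak binding)")

    kd_interval = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        boots = []
        n = len(points)
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            db, fb = d[idx], f[idx]
            if db.max() / db.min() < MIN_DFREE_FOLD_RANGE:
                continue

            def res_b(theta, db=db, fb=fb):
                return 1.0 + (theta[1] - 1.0) / (1.0 + math.exp(theta[0]) / db) - fb

            try:
                s = least_squares(res_b, x0=[sol.x[0], sol.x[1]],
                                  bounds=([math.log(1e-6 * d.min()), 1.0],
                                          [math.log(1e6 * d.max()), 100.0]))
            except Exception:
                continue
            if s.success:
                boots.append(math.exp(s.x[0]))
        if len(boots) >= max(10, n_boot // 2):
            kd_interval = (float(np.percentile(boots, 2.5)),
                           float(np.percentile(boots, 97.5)))

    return BindingFit(kd=kd, fr_max=fr_max, rss=rss, n_points=len(points),
                      converged=bool(sol.success), kd_interval=kd_interval)


@dataclass(frozen=True)
class AffinityComparison:
    ratio: float          # kd_b / kd_a
    ordering: str         # 'a_higher_affinity' | 'b_higher_affinity' | 'comparable'


def compare_affinity(fit_a: BindingFit, fit_b: BindingFit,
                     equivalence_band: float = 0.10) -> AffinityComparison:
    """Compare two binding fits; the smaller Kd is the higher affinity.

    Kd ratios within ``equivalence_band`` (default 10%, symmetric on the log
    scale) count as 'comparable' — the no-appreciable-change regime.
    """
    for fit in (fit_a, fit_b):
        if not fit.converged:
            raise ValueError("refusing to compare a non-converged fit")
    ratio = fit_b.kd / fit_a.kd
    if abs(math.log(ratio)) <= math.log1p(equivalence_band):
        ordering = "comparable"
    elif ratio > 1.0:
        ordering = "a_higher_affinity"
    else:
        ordering = "b_higher_affinity"
    return AffinityComparison(ratio=ratio, ordering=ordering)
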