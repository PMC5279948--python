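# Methods

This note records the models implemented in `cavcmi`, the reasoning behind
the defaults, and what the synthetic-data tests do and do not establish.

## Whole-cell current model

A voltage step from a holding potential activates a Boltzmann conductance
m∞(V) = 1/(1+exp(−(V−V½)/k)) driving a linear current
A(V) = C_m·g·m∞(V)·(V−E_rev) (inward negative).  The driving force is
linear, not GHK: every index in scope (r₅₀, S_Ca, peak fractions, density
ratios) is a ratio or a relative amplitude, so only relative driving
amplitudes matter.

**CDI** is phenomenological: the CDI-capable population decays as
h(t,V) = r∞(V) + (1−r∞(V))·e^(−t/τ_CDI) toward a voltage-scaled floor
1−r∞(V) = (1−r∞,max)·u(V), where u(V) is the peak-current magnitude at V
normalized to its maximum over the default −70…+50 mV step family.  This
makes the inactivation profile mirror the V-shaped current-density profile
(the U-shape of CDI, deepest at the voltage of maximal current) without
modelling intracellular Ca²⁺ explicitly.  A Ca²⁺-flux-driven CDI exists
only in the neuron model, where it is needed.

**CMI** is a two-population mixture with weight w ∈ [0,1]: a fraction 1−w
keeps full CDI and a fraction w is non-inactivating, pinned at the
**300-ms end-stage amplitude** h(300 ms, V) of the CDI population.  Pinning
at the 300-ms level (rather than the t→∞ asymptote r∞) makes the current at
300 ms invariant in w to machine precision, which is the defining rule of
the mechanism; with τ_CDI = 15 ms the two pinning choices differ by
(1−r∞)·e^(−20) ≈ 2·10⁻⁹ of the amplitude and are indistinguishable in any
index quoted to two decimals.  Consequences used throughout:

- I_peak(w)/I_peak(0) = 1 − w·(1−r_end), with r_end the end-stage fraction;
  inverted by `mixture_weight_for_peak_fraction`.
- S_Ca falls continuously from its baseline to 0 as w → 1; at w = 1 the
  trace is flat at the end-stage level (the lower limit of CMI).

**VDI** is a slow single exponential with τ_VDI = 1640 ms, giving
r₅₀,Ba = e^(−50/1640) ≈ 0.97.  Ba²⁺ traces carry only VDI (Ba²⁺ does not
engage calmodulin).  On Ca²⁺ traces VDI is opt-in (`vdi_on_ca=True`) and
off by default: on a 300-ms step it changes r₅₀ by 3% and would drag every
calibrated index off its measured value, while the measured indices already
absorb whatever slow inactivation the real cells had.  When enabled it
multiplies both mixture populations equally, so constant-I₃₀₀ across w is
preserved exactly.

**Defaults** (config-overridable): V½ = −20 mV, k = 7 mV, E_rev = +45 mV,
g chosen so J_peak(−10 mV) = −20 pA/pF, τ_act = 0 (peak at step onset, so
the calibration closed forms are exact), τ_CDI = 15 ms, r∞,max = 0.20.
τ_CDI and r∞,max come from `calibrate_cdi_params` applied to the measured
index triple (S_Ca,baseline, peak fraction, S_Ca,CMI) = (0.77, 0.35, 0.41);
V½/k/E_rev/J are plausibility values for Caᵥ1.3 in HEK cells, with no
measured counterpart in scope.  Protocol defaults: −70 mV holding, −10 mV
step, 300 ms, 0.5-ms sampling, 30-s repetition; family −70…+50 mV in 10-mV
increments.

**Calibration.**  The consistency system linking (τ_CDI, r∞, w) to the
index triple is linear in r∞ once w = (1−peak_fraction)/(1−r∞) is
substituted, so it is solved in closed form;
r∞ = (a·r₅₀ − r₅₀ + q)/(a − r₅₀ + q) with a = 1−peak_fraction and
q = (1−S_Ca,CMI)·peak_fraction, then τ_CDI from the 50-ms relation.
Infeasibility (no valid parameter set) is reported when the implied r∞
leaves (0, r₅₀), w leaves (0, 1], or the exponential argument leaves (0,1).
The test suite cross-checks the solution against a brute-force 2-D grid
over (r∞, τ_CDI).

**Inhibition modalities.** Conventional block and run-down scale only the
conductance — S_Ca is exactly invariant while peak and late current fall
together.  Drug-induced CMI follows a perfusion-limited saturating
exponential w(t) = w_final·(1−e^(−(t−t₀)/τ_perf)) with τ_perf = 75 s, which
puts the indices at >97% of plateau within 4–5 minutes — the time course of
full bath-solution exchange, the rate-limiting step for the induced
inhibition being modelled.  The functional form is the simplest monotone
saturating choice; nothing in scope constrains its shape beyond onset and
plateau.

## Gating indices

Timepoint amplitudes are read at the nearest sample, not interpolated
(reproducibility; at 0.5-ms sampling the distinction is < 10⁻⁴ of the
amplitude).  The peak is the largest-magnitude sample; a peak below 5× the
estimated noise floor (RMS of first differences / √2) is refused as
ambiguous.  All indices are defined on magnitudes; S_Ca is defined only for
the Ca²⁺ carrier.  Cohort statistics are computed per cell and then
averaged, never on averaged traces.

The classifier compares a test against a baseline `TraceIndices` with a
fixed relative-change tolerance (default 10%): CMI = significant drops in
|I_peak| and S_Ca with I₃₀₀ maintained; conventional = drops in |I_peak|
and |I₃₀₀| with S_Ca maintained; none = no significant drops; anything
else = mixed.  Fixed tolerances replace significance tests deliberately:
the decision rule is then deterministic and sample-size-independent.

## FRET two-hybrid binding

FR(D_free) = 1 + (FR_max−1)/(1 + K_d/D_free).  Fits are unweighted least
squares over (log K_d, FR_max) — the log parameterization keeps K_d
positive and conditions the problem — initialized at (median D_free,
max FR).  Data are binned in groups of five adjacent cells sorted by
D_free before fitting (the display convention of this assay); a final
partial bin of ≥ ⌈5/2⌉ cells is kept, smaller remainders dropped.  Binning
a curved isotherm introduces a small Jensen bias (≈3% in K_d for 60-cell
cohorts, quadratically smaller for narrower bins); raw-cell fitting is
available when that matters.

A fit is declared unidentifiable when the D_free span is below 10-fold, or
when the fitted curve fails to rise above the noise — both FR_max−1 and
the curve's span across the measured D_free range must exceed 3× the
residual RMS.  This is the quantitative encoding of the "flat FR ≈ 1,
very weak K_d" regime.  K_d is in donor-cube fluorescence-intensity units
and is instrument-relative: only within-setup ratios are interpretable,
which is why `compare_affinity` works on ratios with a 10% equivalence
band (the scale of K_d differences reported as "no appreciable change").

Bootstrap intervals are nonparametric (resample cells, refit, 2.5/97.5
percentiles), seed-controlled.

## SNc pacemaker model

A single compartment (C = 40 pF) with:

- I_Na = g_Na·m∞³(V)·h_Na·(V−E_Na), instantaneous activation
  (V½ = −30 mV, k = 6), inactivation h_Na with V-dependent τ (0.4–6.4 ms);
- I_K = g_K·n²·(V−E_K), n with V½ = −25... −20 mV region and τ of 1–5 ms,
  positioned so K⁺ current shapes spikes but stays small at subthreshold V;
- I_leak = g_leak·(V−E_leak), E_leak = −62 mV;
- I_CaL = g_CaL·(1−block)·m∞(V)·[(1−w)·h + w·r∞,max]·(V−E_Ca) with
  m∞ V½ = −45 mV (low-threshold, Caᵥ1.3-like);
- dh/dt = (h∞(Ca) − h)/τ_h, h∞ = r∞,max + (1−r∞,max)/(1+(Ca/K_CDI)⁴),
  τ_h = 55 ms, K_CDI = 0.2 µM;
- dCa/dt = −κ·I_CaL − Ca/τ_Ca, κ = 10⁻⁴ µM/(pA·ms), τ_Ca = 200 ms (a thin
  submembrane shell, hence fast concentration changes per unit current).

CMI scales the non-CDI population to r∞,max — the dynamic counterpart of
the trace model's end-stage pinning — and block scales the whole L-type
conductance.  The slow rhythm is Ca²⁺-driven: L-type current depolarizes,
submembrane Ca²⁺ crosses K_CDI, CDI closes the channels, the membrane sags
while Ca²⁺ is extruded, CDI recovers and the cycle repeats.  The Hill
exponent of 4 puts a sharp threshold between resting Ca²⁺ (a few tens of
nM at the hyperpolarized phase) and the µM range reached while
depolarized; the hysteresis of the fast V-subsystem between the recovered
(h≈1) and inactivated (h≈r∞) branches is what converts that slow feedback
into a relaxation oscillation.  With Na⁺ available each depolarized phase
triggers spiking (pacemaking, ~3.8 Hz at default parameters, within the
1–4 Hz SNc-typical band); with g_Na = 0 (oscillation mode, the TTX
condition) the same loop is a subthreshold oscillation of ~30 mV at
~1.5 Hz.

The host neuron is intentionally minimal — the mechanism of interest is
the Caᵥ1.3 substitution and its CMI weighting, so the claims made (and
tested) are ordinal only: rate and Ca²⁺ influx are non-increasing in w,
a 28% conductance block reduces both, and across all interventions rate is
a non-decreasing function of Ca²⁺ influx.  Default parameters were tuned
once to the 1–4 Hz baseline and frozen; they are regression-tested, not
data-fitted.  Integration is fixed-step RK4 at dt = 0.025 ms (deterministic
and bit-reproducible; halving dt changes the rate by < 2%).  Event
detection: upward 0-mV crossings with a 2-ms refractory period
(pacemaking) or upward crossings of the mean potential with a ±1 mV
hysteresis band and 50-ms refractory (oscillation); the first second is
discarded as initial transient.  A voltage-clamp harness runs the same
I_CaL/Ca²⁺ mechanism at a clamped step so the trace indices can be
measured on the dynamic model (S_Ca decreases with w; the late current is
w-insensitive within 10% because submembrane Ca²⁺ saturates the Hill
term under clamp).

## Synthetic data

Cohorts emulate: lognormal cell capacitance (mean 20 pF, CV 0.3) and
channel-expression scale (CV 0.3) — strictly positive and right-skewed, as
transient transfection produces; additive white Gaussian trace noise with
sd = 2% of that cell's peak (leak assumed perfectly subtracted, no 1/f or
line components); FRET cohorts with log-uniform D_free (even coverage of
the saturating curve) and homoscedastic Gaussian FR noise (sd 0.15).  The
noise magnitudes are round figures of the right order for clean whole-cell
recordings and single-cell FRET ratios, exercised only in
tolerance-banded tests.  A separate noise seed lets the same cells be
re-recorded with fresh noise, which is how paired designs (time controls,
before/after drug) are emulated.

Passing tests on these cohorts show that the estimators and the classifier
behave correctly under the stated statistical structure.  They do not
establish robustness to structured noise (line pickup, seal instability),
imperfect leak subtraction, series-resistance error, spectral
bleed-through in FRET, or cell-to-cell parameter heterogeneity beyond
amplitude scaling — none of which are modelled.

## Problem sizes

The test suite and the acceptance script use: 601-sample traces (300 ms at
0.5 ms); 13-voltage families; cohorts of 5–25 cells (200 for convergence
checks); 60-cell FRET cohorts binned by 5, 20 seeds for recovery
statistics, 200 bootstrap refits; neuron simulations of 12–20 s simulated
time per parameter point.  These sizes give stable estimates for every
quantity asserted (rate granularity ~0.05 Hz at 20 s; cohort-mean index
noise well below the tested tolerances).

## Known limitations

- The channel model is not mechanistic: no Markov states, no
  apoCaM-concentration dynamics, no NSCaTE/EF-hand transduction; w is an
  abstract weight, and the presets mapping construct names to w values are
  labels, not molecular claims.
- Activation kinetics default to instantaneous; τ_act > 0 shifts the peak
  off step onset and the calibration closed forms no longer apply exactly.
- Whether CMI also shifts the activation midpoint is left out: w does not
  touch V½ (prior reports of a depolarizing shift exist, but the model
  being implemented states none).
- The neuron model omits dendritic structure, SK/other K⁺ channel
  diversity, mitochondrial stress and dopamine handling; its numeric rates
  are not predictions, only its orderings are.
- Absolute K_d values from the FRET module inherit the arbitrary intensity
  units of the instrument; cross-setup comparisons are meaningless.
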