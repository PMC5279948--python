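# cavcmi

Modelling and analysis tools for **C-terminus-mediated inhibition (CMI)** of
Caᵥ1.3 L-type Ca²⁺ channels.

Caᵥ1.3 channels normally carry apo-calmodulin pre-associated with their
proximal C-terminus, which endows them with strong Ca²⁺-dependent
inactivation (CDI).  The channel's own distal C-terminal module complex
(IQᵥ/PCRD/DCRD) can compete apoCaM off the channel, producing a distinctive
inhibition: the **peak** current and CDI are strongly attenuated while the
**late** (end-stage, 300-ms) current is left untouched.  This package
implements that mechanism as a quantitative model and the analysis around
it, for electrophysiologists and modellers studying Caᵥ1 gating or
CMI-based channel inhibitors:

- `cavcmi.channel_model` — whole-cell Ca²⁺/Ba²⁺ current traces under
  voltage steps.  CMI is a two-population mixture with weight *w*: a
  fraction 1−*w* of channels retains full CDI,
  *h*(t) = *r*∞(V) + (1−*r*∞(V))·e^(−t/τ_CDI), and a fraction *w* is
  non-inactivating, pinned at the end-stage amplitude — so
  I_peak = (1−*w*(1−*r*∞))·I_peak(*w*=0) while I₃₀₀ is invariant in *w*.
  Includes conventional block, run-down, drug-induction time courses, and
  calibration of (τ_CDI, *r*∞, *w*) from measured indices.
- `cavcmi.ephys_metrics` — the gating indices: I_peak, I₅₀, I₃₀₀, I₁₀₀₀,
  r₅₀ = I₅₀/I_peak, the CDI strength **S_Ca = 1 − r₅₀** (at −10 mV), current
  densities J_peak and J₃₀₀ (pA/pF), full voltage profiles, induction
  time-course summaries, and a classifier that separates CMI
  (peak↓, S_Ca↓, I₃₀₀ constant) from conventional inhibition
  (peak↓, I₃₀₀↓, S_Ca constant).
- `cavcmi.fret_binding` — the FRET two-hybrid binding isotherm
  FR = 1 + (FR_max−1)/(1 + K_d/D_free), 5-cell binning by D_free, nonlinear
  least-squares estimation of (K_d, FR_max) with identifiability checks and
  bootstrap intervals, and affinity comparison between binding pairs.
- `cavcmi.snc_pacemaker` — a minimal single-compartment substantia-nigra
  dopaminergic neuron (Na/K spiking + leak + Caᵥ1.3 with Ca²⁺-driven CDI and
  the same CMI weighting) reproducing autonomous 1–4 Hz pacemaking and,
  with Na⁺ channels silenced, subthreshold Ca²⁺ oscillation; CMI and
  dihydropyridine-style block both reduce Ca²⁺ influx and slow both rhythms.
- `cavcmi.synthetic_data` — seed-reproducible synthetic patch-clamp and
  FRET cohorts (capacitance/expression variability, recording noise,
  perfusion-limited induction) so every analysis is testable without data
  downloads.
- `cavcmi.cli_io` — the `cavcmi` command-line interface plus text-based
  trace/table/config round-tripping.

## Worked example

Simulate the no-CMI baseline and a CMI-engaged channel, then index both
traces:

```
$ cavcmi simulate-current --out base.csv
$ cavcmi simulate-current --w 0.8125 --out cmi.csv
$ cavcmi metrics base.csv cmi.csv
scenario,V_mV,carrier,i_peak_pA,r50,s_ca,j_peak_pApF,j300_pApF
,-10.0,Ca,-400.0,0.22853919467775,0.77146080532225,-20.0,-4.00000003298
,-10.0,Ca,-140.000000536,0.5867174273015676,0.4132825726984324,-7.0000000267999996,-4.00000003298
```

The baseline trace (20 pF cell, −10 mV step) peaks at −400 pA with strong
CDI (S_Ca = 0.77).  With mixture weight w = 0.8125 the peak drops to 35%
(−140 pA, ~65% inhibition) and CDI is attenuated (S_Ca = 0.41) — yet the
current density at 300 ms, J₃₀₀ = −4 pA/pF, is identical in both rows.
That constant late current is the CMI signature.

The inverse problem — which (τ_CDI, r∞, w) reproduce a measured index
triple — is solved by the calibrator:

```
$ cavcmi calibrate --s-ca 0.77 --peak-fraction 0.35 --s-ca-cmi 0.41
{"r_inf_max": 0.2011, "w": 0.8136, "tau_cdi_ms": 15.06}
```

And the neuron-level consequence of CMI:

```
$ cavcmi pacemaker --duration-s 12 --w 0
rate_hz: 3.8317
influx_pC_per_s: 10.0596
$ cavcmi pacemaker --duration-s 12 --w 1
rate_hz: 0.0
influx_pC_per_s: 1.0378
```

Ultrastrong CMI cuts the mean Ca²⁺ influx by ~90% and silences autonomous
pacemaking.

See `docs/methods.md` for the model equations, parameter choices and
limitations.

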