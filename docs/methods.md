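# Methods

## Equivalent-circuit models

Each electrode is a lumped linear network between the cardiac source
voltage and the amplifier input; the measured voltage is the drop across
the amplifier load `R_load ∥ C_load`, and every transfer function is
derived by series/parallel impedance-divider algebra:

* **Needle (invasive)** — source → `C_EH ∥ R_EH` (probe–hemolymph
  interface) → `R_Body` (hemocoel bulk) → load. Defaults:
  `C_EH = 100 nF`, `R_EH = 1 MΩ`, `R_Body = 50 kΩ`, `R_load = 10 MΩ`,
  `C_load = 0`.
* **Gelled (wet, noninvasive)** — source → `C_PH ∥ R_PH`
  (puparium–hemolymph interface) → `R_P` (puparium bulk) → `R_E`
  (electrolyte bulk) → `C_EE ∥ R_EE` (electrode–electrolyte interface) →
  load. The puparium is ion-semipermeable, so a Nernst potential `E_PE`
  appears in series; because it is a DC/motion-artifact offset in a
  linear network, it is exposed as a separate additive term rather than
  folded into the (offset-free) transfer function.
* **GaIn (dry, noninvasive)** — source → `R_series` (bulk DC resistance)
  → `R_IP ∥ C_IP` (liquid-metal–puparium interface) → load.

`E_PE = (R·T)/(z·F) · ln(c_out/c_in)` with CODATA constants
(R = 8.314462618 J mol⁻¹ K⁻¹, F = 96485.33212 C mol⁻¹).

With zero capacitances every model collapses to a resistive divider
(e.g. needle DC gain `R_load/(R_load + R_EH + R_Body)`); the tests pin
these limits and verify rational-function evaluation against direct
complex nodal arithmetic at random component values to 1e-9 relative.

### The relative transfer H(s) and its low-pass character

`H(s) = V_GaIn/V_needle` is the ratio of the two divider transfer
functions, reduced by cancelling shared poles/zeros to numerical
tolerance. A subtlety worth documenting: with a purely **resistive**
amplifier load, a series `R_IP ∥ C_IP` interface makes the GaIn path
slightly *high*-pass (the capacitance shorts the interface at high
frequency). The observed low-pass behaviour of dry-contact recordings
arises when the large interface resistance drives the amplifier's input
capacitance; `|H|` is then monotonically non-increasing whenever the
interface zero `1/(R_IP C_IP)` lies above the load pole. The default GaIn
model (`R_IP = 100 MΩ`, `C_IP = 10 pF`, `R_series = 100 kΩ`,
`R_load = 10 MΩ`, `C_load = 560 pF`) sits in that regime and places the
H corner near 26 Hz — inside the signal band so the low-pass effect on
beat morphology is clearly visible. All component values are
illustrative engineering choices (no published values exist for this
preparation); the property tests sample the zero-above-pole regime
rather than arbitrary component combinations.

### Discretization

`simulate_response` maps H(s) to a digital filter with the bilinear
(Tustin) transform at the trace sampling rate, without frequency
pre-warping (corners of interest sit far below the 1302 Hz Nyquist). The
trapezoid rule implies a half-sample input convention: the discrete step
response of `1/(τs+1)` matches `1 − exp(−(t + Δt/2)/τ)`, with residual
error O((Δt/τ)²) ≈ 0.07 % for τ = 5 ms at 2604 Hz. A warning (not an
error) is logged when the dominant pole exceeds Nyquist.

## Signal processing

* **Notch**: `scipy.signal.iirnotch(60, 10, fs=2604)` — a constrained
  biquad with unit-circle zeros at ±2π·60/fs, unity gain at DC and
  Nyquist, −3 dB rejection bandwidth 6 Hz (Q = center/bandwidth = 10).
  Applied causally (plain IIR).
* **Moving average**: 200 points, **centered** (zero phase) rather than
  causal — analysis is offline and beat timing must not be skewed; edges
  shrink the window symmetrically to what fits. At 2604 Hz the window
  spans 77 ms, so beats are substantially smoothed; the beat detector's
  relative threshold makes detection insensitive to this.
* **Beat detection** (no published detector exists; this one is designed
  here): baseline = trace median; robust peak = 99.5th percentile;
  threshold = baseline + 0.5·(peak − baseline); beats at upward
  crossings, refined to the local maximum while above threshold, with a
  100 ms refractory lockout. The 99.5th (not a lower) percentile is
  needed because a 0.5 Hz heart with a 60 ms beat occupies only ~3 % of
  samples — a 95th-percentile "peak" would be baseline. Beat times snap
  to the sample grid (0.38 ms quantization, negligible against 200–2000 ms
  periods); no sub-sample interpolation.
* **Period summaries**: mean ± SD of the **first ≥ 20** periods starting
  at the first beat at or after each offset (10/100/1000 s); a summary is
  flagged invalid, with the achievable count, when fewer remain.
* **Stability analysis**: beats detected once over the whole trace;
  per non-overlapping 60 s window, mean beat-peak amplitude above the
  trace median (peak, not RMS — peak is what drifting electrode contact
  degrades most directly) and mean period. `amplitude_trend` is the
  least-squares slope of window means versus time as a fraction of the
  first window's mean per minute; `period_cv` is the SD/mean of all
  periods. Windows with fewer than 2 beats are excluded from the trend.

## Waveform features

Per beat: positive duration between the baseline (trace median)
up-crossing and down-crossing around the peak; depolarization and
repolarization slopes as least-squares fits over the 10–90 % amplitude
segment of the rising and falling edges ("polarization slope" is read as
the falling-edge slope). The median baseline makes the features immune
to AC-coupling offsets; 10–90 % fitting is robust to smoothing. Reported
values are across-beat means; beats clipped by the trace edges are
skipped and counted.

One degenerate case to be aware of: on a strictly noise-free trace the
median baseline is exactly zero and a low-pass-filtered beat's
exponential tail only re-crosses it at float underflow, so measured
positive durations are inflated. Any realistic noise floor (the
generator's default amplifier noise suffices) makes the down-crossing
physical; direction-of-effect comparisons are unaffected either way.

`fit_relative_transfer` fits the first-order model `g/(τs+1)` — one
pole, matching the single `R_IP ∥ C_IP` element that dominates the
interface — by minimising RMS error between the simulated and measured
noninvasive trace, using a deterministic 10×11 coarse grid over
(g ∈ [0.2, 2], τ ∈ {0} ∪ [0.1, 100] ms log-spaced) followed by
Nelder–Mead refinement in (g, log τ). No random starts, so fits are
exactly reproducible; higher-order fits are out of scope.

## Synthetic data: what it emulates and what it does not

The generator emulates the statistical structure the analysis chain
assumes: a trapezoidal beat (linear rise/plateau/fall, optional
triangular undershoot — piecewise-linear so positive duration and both
slopes are known analytically), i.i.d. normal per-beat period jitter
truncated to keep periods above the beat width, 60 Hz powerline pickup,
white amplifier noise, sinusoidal baseline wander, and the instability
of invasive preparations as compound multiplicative amplitude decay
`A(t) = A₀(1 − r)^(t/60 s)` plus additive period inflation
`T(t) = T₀(1 + q·t/60 s)`. True beat onsets are kept in trace metadata
as ground truth for calibration tests.

Defaults are the package's study conditions: 2604 Hz sampling, 1 mV
trapezoid (10/30/20 ms rise/plateau/fall), phenotype presets CS 4 Hz,
NP 3 Hz, SERCA-depleted 1.5 Hz (chosen to honour the observed ordering
only — no numeric rates or amplitudes are published for these strains),
3 %/min amplitude and 2 %/min period drift for "invasive-like" traces.
An optional AC-coupled amplifier stage (first-order band-pass
5 Hz–10 kHz plus gain, off by default) models the recording front end.

Real pupal ECGs differ in ways the generator does not capture: beat
morphology is not piecewise linear, jitter is autocorrelated rather than
i.i.d., drift is not a clean exponential, and noise is not white.
Passing tests therefore demonstrate that the pipeline is *calibrated and
internally consistent* under controlled conditions — detector counts and
periods match construction, injected drift is recovered, filter
characteristics meet design — not that it is validated on animal data.

Note that the least-squares linear trend systematically under-reports a
compound 3 %/min decay over 15 minutes by ~18 % (the exponential's
curvature flattens the fitted slope); this is an inherent property of
the linear summary, documented rather than corrected.

## File formats

Traces are plain text: `#`-prefixed key/value header
(`sampling_rate_hz`, `units` ∈ {V, mV, uV/µV, nV}, `start_time_s`, plus
free metadata) followed by `time_s`/`voltage` columns at fixed precision
(10 decimals for time, 13 significant digits for voltage — round trips
are lossless to 1e-12 V). The time grid must be uniform to 1 ns; the
first non-conforming row is named in the error. Generator and electrode
configs are flat YAML mirroring the dataclass fields (exponents without
a sign, like `2.0e8`, are coerced to numbers despite YAML 1.1). Every
CLI output embeds the parameter set used in its header.

## Problem sizes

The shipped tests and the acceptance script use 8–30 s traces for
calibration and feature checks, 20 s per rate for the 0.5–5 Hz beat-count
sweep, a 3×3 (g, τ) grid with and without 40 dB SNR noise for fit
recovery, and paired 15-minute traces for the stability contrast —
sizes at which every quantity of interest is already stable.
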