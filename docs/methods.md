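# Methods

## Signal model

A synthetic sweep is a sum of interpretable components on a uniform time
base (default 2 kHz, 300 ms, flash at 30 ms):

```
v(t) = −A(I)·g_a(t) + max(B(I)−A(I), 0)·g_b(t) + OP(t) + mains(t) + ε(t)
```

* `g_a` is a unit-amplitude gamma transient `(t/t_p)^4·exp(4(1−t/t_p))`
  with its trough `t_p` = 15 ms after the flash — a sharp negative
  photoreceptor deflection.
* `g_b` is a slower gamma dome (shape 2) that begins exactly at the
  a-trough time and peaks 60 ms after the flash.
* `A(I)` and `B(I)` are Hill functions of linear flash intensity.  The
  b-kernel coefficient is `B−A` (clipped at zero) rather than `B` so that
  the **measured trough-to-peak b-wave amplitude equals `B(I)` exactly** on
  clean traces: the conventional b-wave measurement runs from the a-trough
  (−A below baseline) to the peak (B−A above it), and it is this
  trough-to-peak quantity that intensity-response analyses fit with the
  Hill equation.  Tying the generative truth to the measured convention is
  what makes closed-loop parameter recovery exact.
* `OP(t)` is a Gabor wavelet (Gaussian-windowed cosine): center frequency
  170 Hz, Gaussian σ 12 ms, centered 55 ms post-flash, hard-confined to
  the 120 ms post-flash window.  A Gabor is used instead of a one-sided
  damped sinusoid because an exponential envelope has Lorentzian spectral
  skirts that would put several percent of the packet energy below 120 Hz;
  the Gaussian envelope keeps ≥ 95 % of the energy above 120 Hz, so the
  OP high-pass preserves ≥ 90 % of the OP area while the 60 Hz low-pass
  removes ≥ 99 % of it.  The default amplitude (35 µV) puts the OP area
  near 700 µV·ms, the scale observed at mid-range flashes in this design.
* `mains(t)` is a 60 Hz sinusoid with a phase drawn uniformly per sweep:
  the power line is not synchronized to the flash, and randomizing the
  phase keeps the pre-flash deterministic signal exactly zero (a module
  invariant) while letting sweep averaging attenuate the interference.
* `ε(t)` is white Gaussian noise (default SD 8 µV per sweep, so ~3.6 µV
  after a five-sweep average — the scale of a quiet rodent ERG setup).

All deterministic components vanish before the flash, so the pre-flash
segment estimates the baseline.

### Stimulus ladder

The default ladder is 13 flashes equally spaced in log intensity from
−2.01 to 4.09 (step 6.10/12 ≈ 0.508 log units).  Step 8 falls at 1.548,
within 0.02 log units of the 1.56 quoted for nominal ~0.5-log hardware
ladders, whose true spacing is never exactly uniform; an explicit
intensity list can be supplied where the calibrated ladder is known.

### Cohorts

Per-eye parameters are drawn from normal distributions truncated at zero
for strictly positive quantities (`k` in log units may be negative and is
not truncated).  The default two-group study uses the group sizes of the
motivating design (15 control vs 12 treated eyes, ≥ 5 sweeps per flash,
two eyes per animal generated as independent eyes, which is how such
studies usually treat them).  The a-wave truth distributions are
V_max 377.3 ± 87.5 µV, k 2.67 ± 0.50 log, n 0.79 ± 0.24 (control-like) and
259.7 ± 121.1 µV, 2.52 ± 0.39 log, 0.77 ± 0.26 (treated-like).  For the
b-wave only the central values (763.9/646.8 µV, k 1.46/1.47 log,
n 0.31/0.34) are available; the between-eye SDs are not, so the generator
uses 180 µV for V_max and 0.12 for n — coefficients of variation
comparable to the a-wave's — as a fixed, documented choice.

## Filtering

* **Averaging before filtering.** All operations are linear, so the order
  is immaterial for the mean; averaging first is documented, not
  configurable.
* **Notch (60 Hz).** Implemented as a spectral projection: the DFT bins
  within ±1 Hz of the mains frequency (always at least the nearest bin)
  are zeroed.  On a finite record this is the only notch that honors all
  the contracts at once — it is exactly linear, exactly zero-phase,
  exactly idempotent, and cancels an on-bin sinusoid of any phase
  completely.  An IIR notch narrow enough to spare the ERG rings longer
  than the 300 ms record (a Q = 30 biquad leaves ~14 % of a 60 Hz tone even
  with maximal edge padding), and one wide enough to cancel within the
  record visibly distorts the sharp a-trough.  The default layout puts
  60 Hz exactly on an analysis bin (18 cycles in 300 ms); off-bin mains
  (drifting line frequency) is attenuated less — the standard
  finite-record limitation, worth remembering with real recordings.
* **Band splitting.** 4th-order Butterworth low-pass at 60 Hz (b-wave
  branch) and high-pass at 120 Hz (OP branch), each applied
  forward-backward (zero phase) with odd-symmetric edge extension of three
  ring times, so pass-band extrema move by at most one sample.

## Measurement conventions

* **a-wave**: minimum of the **raw** average within 50 ms of the flash;
  amplitude = baseline − trough, reported positive; latency =
  flash-to-trough.  Measuring on the raw rather than the notched average
  follows the convention of measuring the a-wave directly on the raw
  traces, and it matters quantitatively: notch ripple from the large
  b-wave (a fraction of a µV) would otherwise dominate the smallest
  a-waves and break sub-1 % recovery at low flashes.
* **b-wave**: maximum of the low-passed trace strictly after the a-trough
  and within 150 ms of the flash; amplitude = peak − (baseline − a_amp),
  i.e. the trough reference is the raw a-trough.  Taking the trough from
  the low-passed trace instead would blunt the sharp trough by a few
  percent of `A` and bias the b-amplitude accordingly.
* **OP area**: Σ |(vᵢ+vᵢ₊₁)/2|·Δt over [flash, flash+120 ms] of the
  high-passed trace, in µV·ms.  The trapezoid-of-absolute-value rule has a
  deterministic kink bias at rectified zero crossings of
  ≈ 3.3/(samples-per-cycle)²; at 2 kHz this is ~2–3 % for 150–200 Hz
  oscillations.  Both groups are measured with the identical rule, so the
  bias cancels from comparisons; validation against closed-form integrals
  uses test frequencies with ≥ 32 samples per cycle, where the rule is
  accurate to < 0.5 %.
* Traces with no negative (or no positive) deflection yield amplitude 0
  plus a QC flag; ratios whose denominator is a flagged zero are excluded,
  not propagated.  At the lowest flashes the a-wave of a realistic
  (noisy, OP-bearing) trace is below the residual floor of the raw
  average, so per-trace b/a ratios there are floor-limited — as they are
  with real recordings.

## Hill fitting

Nonlinear least squares on the model in linear intensity with `k`
parameterized as `log₁₀ k` (the stable form `V_max/(1+10^{n(k_log−I_log)})`
is used throughout).  Initialization is deterministic — `V_max⁰` = max
amplitude, `k⁰` = interpolated half-max crossing, `n⁰` = 1 — with bounds
`V_max ∈ (0, 10·max]`, `n ∈ [0.1, 5]`, `k_log` within the data range ± 2
log units; ordinary (unweighted) least squares via Levenberg-Marquardt
(lmfit).  The same data always produce the same fit, regardless of point
order.  All-zero or non-positive series return `converged = False` rather
than raising.  Requires ≥ 4 points spanning ≥ 1 log unit.

When the semi-saturation constant sits near the top of the ladder (as in
the control a-wave truth, k = 2.67 with the ladder ending at 4.09), the
saturated amplitude is only weakly identified and per-eye `V_max`
estimates are noticeably more variable than for curves that saturate
mid-ladder; this is visible in the Monte-Carlo study and is a property of
the design, not of the fitter.

OP areas are never curve-fitted (their intensity relation is biphasic);
the areas at the designated intermediate (rod-driven) and final
(mixed rod/cone) ladder steps — defaults 8 and 13 — are carried into the
group comparison directly.

## Statistics

Shapiro-Wilk at α = 0.05 per group (constant samples are auto-classified
non-normal); both groups normal → two-tailed F test of variances at
α = 0.05 choosing Student vs Welch t; otherwise two-tailed Mann-Whitney
with the exact null when `n₁·n₂ ≤ 400` and no ties, else the normal
approximation with tie and continuity corrections.  Both groups' U values
are recorded (they sum to `n₁·n₂`).  Bonferroni: the decision threshold is
`0.05/m` on both paths — dividing α (parametric) and dividing the
significance level for p (nonparametric) are the same rule, and both
quantities are stored.  Summary-statistic t tests reproduce the raw-sample
t exactly from (n, mean, SD) triples, which is how published mean ± SD
tables are re-tested.  OLS lines report adjusted R² = 1−(1−R²)(n−1)/(n−2).

## Densitometry

Pixel-in-polygon uses pixel-center containment with a top/left boundary
rule (a center on a shared edge belongs to the polygon to its right/below),
making sums over edge-sharing polygons exactly additive.  The "red value"
is the summed red-channel signal over the polygon; absolute units are
arbitrary because every treated section is normalized to its same-slide
control partner, which cancels slide-level gain exactly.  Whole-retina
totals sum ten images (fewer triggers a warning and a flag).  Blot optical
density subtracts the median of a user-designated background strip times
the band width before integration — a flat shared background cancels from
the target/actin ratio.  The synthetic section generator draws four
horizontal bands (OPL/INL/IPL/GCL) with configurable means and optional
Poisson noise.

## QC exclusion

Eye-level flags (inadequate electrode contact) discard only the affected
eye; animal-level flags (anesthesia failure, death during the session)
discard every eye of that animal.  The pipeline reconciles feature-row
counts against the exclusion log.

## What the generator does and does not emulate

It reproduces the statistical structure the analysis relies on: Hill-shaped
amplitude growth with between-eye parameter spread, OP packets confined in
time and band, mains plus white noise, group size asymmetry, and QC
metadata.  It does not model phototransduction biophysics (no Lamb-Pugh
kinetics), cone/rod mixture shifts across the ladder, amplitude-dependent
latency changes, drifting baselines, blink/movement artifacts, or
inter-eye correlation within an animal.  Passing tests therefore certify
the measurement chain and inference machinery, not any biological claim
about real retinas.

## Problem sizes

Defaults keep every stage desk-scale: 600-sample sweeps, 5 sweeps × 13
flashes × 27 eyes per cohort (~1 s per full pipeline run), 200 Monte-Carlo
replicates for the group-pattern study, 2 000 null datasets for the type-I
calibration, and 500 replicates for densitometry ratio recovery.
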