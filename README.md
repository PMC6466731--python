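# retinoscope

Analysis toolkit for **full-field scotopic electroretinograms (ERGs)** in
rodent studies, with a synthetic-data generator, plus the densitometry and
small-sample statistics that typically accompany such studies.

A dark-adapted flash ERG contains three measurable components: the
**a-wave** (negative photoreceptor deflection, measured baseline-to-trough),
the **b-wave** (positive ON-bipolar-cell deflection, measured from the
a-trough to the peak after a 60 Hz low-pass removes the oscillations), and
the **oscillatory potentials** (OPs, >120 Hz wavelets from amacrine-cell
activity, quantified as the absolute trapezoid area over the 120 ms after
the flash).  Across a ladder of flash strengths the a- and b-wave
amplitudes follow the Hill (Naka-Rushton) relation

```
V(I) = V_max · Iⁿ / (kⁿ + Iⁿ)
```

with saturated amplitude `V_max` (µV), semi-saturation intensity `k`
(reported as log₁₀ photons·µm⁻²·s⁻¹) and slope `n`.  Group comparisons use
a normality-gated workflow: Shapiro-Wilk per group, then either an F-test
plus Student/Welch t test (normal data, means ± SD reported) or a
two-tailed Mann-Whitney test (medians reported), with Bonferroni
adjustment over the comparisons sharing a dataset.

The package is aimed at retinal electrophysiologists and at anyone who
needs a fully testable stand-in for an ERG rig: every stage can be
exercised against synthetic cohorts with known ground truth.

## Worked example

```python
import numpy as np, retinoscope as rs

stim = rs.make_default_stimulus()              # 13 flashes, −2.01 … 4.09 log
x = np.array(stim.intensities_log)
truth = rs.CTR_A_WAVE                          # control-group mean a-wave truth
y = rs.hill_amplitude_log(x, truth["Vmax"][0], truth["k_log"][0], truth["n"][0])
fit = rs.fit_hill(x, y)
print(fit.Vmax_uV, fit.k_log, fit.n_slope)
```

prints

```
377.29999999999995 2.67 0.79
```

i.e. the fitter returns the generating saturated amplitude (377.3 µV),
semi-saturation constant (2.67 log) and slope (0.79) of the control-group
a-wave curve to machine precision from a noiseless 13-point series.

The `examples/` directory holds one short script per capability:

| script | shows |
| --- | --- |
| `decompose_sweep.py` | averaging, filtering and a/b/OP measurement of one sweep set |
| `fit_intensity_response.py` | deterministic Hill-parameter recovery |
| `full_pipeline.py` | simulate a 15 vs 12-eye study and run all group statistics |
| `gated_statistics.py` | the normality-gated test and summary-statistic t tests |
| `densitometry.py` | layer fluorescence sums, slide-pair normalization, blot ratios |

Running `examples/full_pipeline.py` reproduces the canonical result
pattern of this study design: the a-wave `V_max` separates the groups
(smaller in the treated group) while `k`, `n`, the b-wave parameters and
the OP areas do not, and the OP/a and OP/b ratios shift because a normal
inner-retinal output rides on a reduced photoreceptor drive.

## Layout

```
src/retinoscope/
  synth.py      synthetic sweeps, eyes, cohorts (ground truth attached)
  filters.py    averaging, spectral notch, zero-phase Butterworth branches
  features.py   a-wave, b-wave, OP area, ratios
  hill.py       Hill evaluation and deterministic fitting
  stats.py      gated two-sample workflow, summary t, paired t, OLS lines
  immuno.py     layer densitometry and immunoblot ratios
  pipeline.py   cohort orchestration, QC exclusion, results tables
  io.py         CSV/JSON trace serialization, YAML cohort specs
```

See `docs/methods.md` for the model, parameter defaults and numerical
choices.
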