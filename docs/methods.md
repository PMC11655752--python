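# Methods

## Signal model of the synthetic generator

Each trial's voltage at time *t* (ms, relative to word onset) and
electrode *e* is

```
v(t, e) = A_N · w_N(e) · K_N(t)  +  A_P · w_P(e) · K_P(t)
        + s · (t − t_start) / 1000
        + a · sin(2π f t / 1000 + φ)
        + c_subject + ε(t, e)
```

* **Components.** K_N is a gaussian kernel (peak 1 at 400 ms, sd 80 ms);
  K_P is a plateau equal to 1 on 600–1000 ms with raised-cosine ramps of
  50 ms on each side. The kernels are scaled so that the latent amplitudes
  A_N (µV, negative = larger N400) and A_P (µV, positive) are approximately
  recovered by the corresponding window averages (the gaussian's mean over
  300–500 ms is ≈ 0.79, the plateau's over 600–1000 ms ≈ 0.97). The
  topography w puts both components maximal at Pz (Pz 1.0, Cz 0.7,
  Fz 0.4); the exact weights are free parameters.
* **Latent coupling.** (A_N, A_P) are bivariate normal per condition with
  means (µ_N400, µ_P600), sds (sd_n400, sd_p600) and correlation
  `coupling_rho` — the ground-truth within-trial N400–P600 coupling.
* **Nuisance structure.** A per-trial linear drift with slope
  s ~ N(0, drift_sd) µV per second, anchored at the epoch start (−200 ms);
  an alpha sinusoid with uniform random phase per trial; a per-subject
  constant offset; and i.i.d. gaussian sample noise. Drift is linear
  because single-trial drifts present as monotone trends; higher-order
  drift is out of scope.

Conditions rotate over items in a pseudo-Latin square (subject *i*, item
*j* → condition (i + j) mod k), balancing per-subject condition counts
without full crossing. Everything is drawn from one `numpy` Generator
seeded by the config, so identical configs give byte-identical data.

### Default study conditions

The biphasic preset emulates a two-condition expectancy experiment:
40 subjects × 120 items, 250 Hz sampling, epochs −200..1200 ms.
Expected: µ_N400 = −1, µ_P600 = +1 µV; Unexpected: −4 / +4 µV — ≈3 µV
N400 and P600 effects at Pz, typical of robust language-ERP contrasts.
Latent sds are 2 µV and coupling_rho = −0.4 in both conditions. The
monophasic preset has three conditions in which, relative to Baseline
(−1/+1), one condition moves only µ_P600 (+4: a P600-only contrast) and
one only µ_N400 (−4: an N400-only contrast), with the same within-condition
coupling everywhere.

Nuisance defaults: drift_sd 8 µV/s (single-trial drifts of up to ~±10 µV
across the epoch, large relative to the 2 µV component sds, so raw window
averages are drift-dominated as in real single-trial EEG); noise_sd 10 µV
per sample (low single-trial SNR; window averaging over ≥50 samples leaves
≈1.4 µV); alpha 2 µV at 10 Hz (its average over the 200 ms N400 window and
the 1200 ms segment is ≈0, so it acts as band-limited noise); subject
offsets 2 µV. The sampling rate and noise magnitudes are calibrated
qualitatively to realistic recordings, not to a specific dataset.

What the generator does **not** emulate: volume conduction / correlated
sensor noise, eye or muscle artifacts, component latency jitter,
item-specific effects, non-linear drifts, and any dependence between
trials. Passing tests therefore show that the *analysis* behaves correctly
under the modelled structure, not that real data satisfy that structure.

## Analysis conventions

* **Baseline correction** subtracts the per-trial, per-electrode mean of
  −200..0 ms. Window endpoints are inclusive on both sides (windows used
  here never abut). The Segment window starts at 0 ms, so the baseline
  interval never enters predictors.
* **Grand averages** are two-stage (trials → subject means → group mean);
  the ribbon unit is the subject and plotted ERP ribbons are 95% CIs
  (±1.96·se; the multiplier is a documented choice). Bin waveform ribbons
  default to the standard error across trials within a bin, with an option
  for across-subject units, since "across quantiles" is ambiguous.
* **Tertile binning** ranks scores ascending with stable tie order;
  remainder trials go to the lowest bins (deterministic, order-independent
  given scores). Bin means weighted by bin sizes reproduce the overall
  mean exactly — displayed voltages are never altered by the scoring.
* **Correlations** pool trials across subjects and conditions at a single
  electrode by default; within-subject centering before pooling is
  available as an option (both behaviours are provided because pooling
  conventions differ between labs).
* **Predictors** are per-electrode window averages, z-standardized with
  the sample sd (n − 1) and inverted (× −1). The default standardization
  group is pooled across all trials entering a fit, giving one scale per
  electrode so coefficients are comparable across subjects before
  averaging; per-subject standardization is available. Per-condition fits
  re-standardize within the condition subset (keeping the mean-0/sd-1
  contract valid there); reusing the global standardization is an option.
* **OLS per cell.** Each subject × electrode shares one design matrix
  across time samples, so fits are vectorized: β = (XᵀX)⁻¹XᵀY with the
  classical per-cell standard error. Rank-deficient designs raise an
  error; subjects with fewer than 4 trials are skipped with a warning.
  Cells are fit independently — no smoothing across time.
* **Coefficient summaries** average coefficients across subjects
  unweighted (each subject one unit, the grand-average convention). The
  default ribbon is the across-subject standard error; the averaged
  per-cell OLS standard error is retained as an option.
* **Neutralization** sets a predictor exactly to 0 (its mean after
  z-standardization) when computing forward estimates, never refitting.
  Estimates are stored per trial so condition summaries of estimates and
  residuals derive from one object.

## Identifiability of the coupling coefficient

The Segment predictor (0–1200 ms mean) necessarily contains both
components: the N400 kernel's mean over the segment is ≈ 0.17 and the
P600 plateau's ≈ 0.38. A consequence, easy to verify with the generator,
is that the N400 coefficient in the P600 window is **not** zero-centered
when the latent coupling is zero: in the noise- and drift-free limit the
two predictors reconstruct A_P algebraically as
A_P ∝ Segment − (0.17/0.38)·N400avg, forcing a positive β1 on the
(inverted) N400 predictor of ≈ +0.9 µV per predictor-sd; with the default
drift and noise the null value is ≈ +2.7 µV. Drift itself *is* handled —
the drift contribution to the conditional association cancels — but
component leakage into the Segment window is structural. True negative
latent coupling shifts β1 further positive (≈ +3.0 at ρ = −0.4 under the
defaults). The P600-window β1 should therefore be read as a *relative*
quantity (compared across designs or against a coupling-free reference
computed with this generator), not as an absolute zero-anchored test of
coupling. The same explaining-away mechanism makes the Segment-partialed
correlation negative even at ρ = 0. This caveat applies equally to any
analysis that conditions on a whole-segment average containing the
components of interest.

## Problem sizes

Exact identities are checked on 5-subject × 40-item simulations; the
Monte-Carlo replicate checks use 100 replicates of 20 subjects × 100 items
(2 000 trials, matching the scale of a typical single-experiment trial
count) for the correlation and coefficient signatures, and 10 × 100
drift-only replicates for the binning artifact. `scripts/acceptance.py`
analyses one full-scale 40 × 120 experiment plus the same replicate sets.

## Known limitations

* The N400/Segment predictors are derived from the analysed signal itself;
  see the identifiability note above for what their coefficients can and
  cannot establish.
* No statistical inference is attached to correlations or condition
  effects (no permutation tests or mixed models); conclusions rest on
  coefficient sign patterns and residual magnitudes.
* The CSV reader targets the package's own long format; binary EEG formats
  need external conversion.
* Per-cell OLS assumes homoskedastic errors within a cell; the
  across-subject ribbon does not propagate per-cell uncertainty.
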