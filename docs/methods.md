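# Methods

This document records the modelling assumptions, parameter defaults and
numerical conventions of the `fpvstag` package. Nothing here is an empirical
claim about real data; every number is either a definition or a quantity
computed by the test suite / acceptance script on synthetic data.

## 1. Paradigms and frequency bookkeeping

- **Oddball**: base rate 5 Hz, deviant every 4th stimulus → oddball rate
  5/4 = 1.25 Hz. The discrimination response is quantified as the summed
  baseline-subtracted amplitude over the first five oddball harmonics that
  are not integer multiples of the 5 Hz base rate: 1.25, 2.5, 3.75, 6.25,
  7.5 Hz (5 Hz excluded). Exclusion uses exact rational arithmetic
  (`fractions.Fraction` with denominator limit 10⁶), so 0.6-vs-1.8-type
  near-misses in binary floating point cannot mis-classify a harmonic.
- **Multi-input**: two streams at 4.61 Hz and 5 Hz, four harmonics each,
  ceilings 18.44 Hz and 20 Hz. Stream responses are quantified at the
  medial-occipital ROI.
- A recording of duration `T` has frequency resolution `1/T` Hz (1/60 Hz at
  the default 60 s). 4.61 Hz is not on that grid; the simulator and the
  analysis both use the *snapped* fundamental (nearest bin, 277/60 Hz at
  60 s) and define stream harmonics as integer multiples of the snapped
  fundamental — the stimulus is periodic at the snapped rate, so its
  harmonics are exactly bin-aligned. Requesting a bin more than 0.25 bin
  widths from a target frequency is a hard error, never a silent rounding.

## 2. Spectral statistics

The amplitude spectrum is the single-sided FFT amplitude of the demeaned
signal, `2/N` scaling (`1/N` at DC and Nyquist). No windowing, filtering or
artifact correction is applied: the synthetic data contain none of the
artifacts those steps address, and omitting them keeps every stage exactly
linear.

For a target bin `t` with surrounding-bin set `S` (10 bins per side,
excluding the bin immediately adjacent on each side, |S| = 20):

- `SNR = a_t / mean(a_S)`
- `baseline-subtracted amplitude = a_t − mean(a_S)` (µV)
- `Z = (a_t − mean(a_S)) / SD(a_S)` with the sample SD (ddof = 1).

Degenerate neighbourhoods (zero mean or zero SD, possible only on
noise-free synthetic data) yield infinite sentinels with a warning rather
than an exception.

**Harmonic retention.** Z is evaluated on grand-averaged spectra (amplitude
domain, averaged across subjects, then across ROI electrodes) for every
ROI × group × content cell. A candidate harmonic passes if Z > 1.64 in all
cells; the retained set is the prefix of candidates ending before the first
run of two consecutive failures. 1.64 is the one-sided standard normal
critical value at α = .05 rounded to two decimals (the acceptance script
verifies `round(Φ⁻¹(0.95), 2) = 1.64`).

**Null calibration.** The z > 1.64 exceedance rate at noise-only bins is
*not* exactly 5% even for ideal data: with a 20-bin sample SD the statistic
has a t(19)-like tail, `P(t₁₉ > 1.64/√(1+1/20)) ≈ 0.063`, and single-subject
amplitude bins are Rayleigh-distributed (right-skewed), which inflates the
single-spectrum rate to ≈ 0.085. On grand averages of ~48 spectra the bins
are near-Gaussian by the central limit theorem and the measured rate is
≈ 0.065 — this is the regime in which the retention rule is actually
applied, and what the acceptance checks evaluate.

**Quantification bias.** Baseline subtraction is biased low under noise:
the target amplitude `E|A + ν|` exceeds `A` only by ≈ `s²/A`, while the
subtracted neighbour mean is the full noise-floor amplitude `s√(π/2)`. The
default noise level (below) keeps this bias under 10% of the injected
summed response; noise-free recovery is exact to machine precision.

## 3. Regions of interest

| ROI | electrodes | role |
|-----|------------|------|
| LOT | P7, P9, PO7 | oddball quantification (left occipito-temporal) |
| MO | Iz, Oz, O1, O2 | multi-input quantification (medial occipital) |
| ROT | P8, P10, PO8 | oddball quantification (right occipito-temporal) |

Channel sums are averaged within an ROI after per-channel harmonic
summation; all steps are linear, so the order is a reproducibility
convention, not a modelling choice.

## 4. Gaze analysis

A fixation at `(x, y)` with calibration error `σ` (px) contributes to AOI
rectangle `[x₀,x₁]×[y₀,y₁]` the product of two 1-D Gaussian interval
masses, `[Φ((x₁−x)/σ) − Φ((x₀−x)/σ)] · [Φ((y₁−y)/σ) − Φ((y₀−y)/σ)]`;
`σ = 0` degenerates to hard point-in-rectangle assignment. The remainder of
the unit mass is attributed to `outside`, so weights always sum to one and
AOIs must be non-overlapping. Proportional looking time is the
fixation-duration-weighted average of these weights. Fixations with
non-finite coordinates are dropped and counted in the log.

## 5. Outlier screening and coding conventions

- Outliers are removed per measurement cell (oddball: ROI × content;
  multi-input neural: valence × content × rate; gaze: valence × content)
  when `|x − median| / (1.4826 · MAD) > 3`. A zero MAD flags nothing and
  warns.
- Two-level factors are coded ±0.5 (`group_c`: control = +0.5; `content_c`:
  social = +0.5; `valence_c`: neutral = +0.5; `sex_c`: female = +0.5), so
  main effects are average differences and interactions are
  difference-in-differences on the response scale. ROI enters through
  sum-to-zero contrasts (`C(roi, Sum)`).
- Continuous adversity/symptom scores are standardized at the subject level
  across the modelled subset (Models 2–3 run within the adversity group
  only).

## 6. Mixed-model engine

All inference uses a random-intercept linear mixed model
`y_ij = x_ijᵀβ + u_i + ε_ij`, `u_i ~ N(0, τ²)`, `ε_ij ~ N(0, σ²)`, fitted
by REML. Implementation choices:

- The covariance `V_i = σ²(I + θ J)` with `θ = τ²/σ²` is profiled out:
  a 1-D bounded optimisation over `log θ ∈ [−14, 14]`, plus an exact
  evaluation at the boundary `θ = 0`; whichever has the lower −2·REML wins.
  On data with no between-subject variance the engine therefore reproduces
  fixed-effects ANOVA F statistics exactly (the acceptance checks verify
  agreement with a closed-form two-way ANOVA oracle to < 1e-6 relative).
- Per-group sufficient statistics (`XᵀX` minus scaled outer products of
  group sums) make the fit O(p²) per group, independent of group size.
- Type-III Wald F tests use the sum-to-zero/±0.5 coding above and test each
  model term's coefficient block.
- Denominator degrees of freedom follow the between-within (containment)
  rule: terms constant within subject get `n_subjects − p_between`; terms
  varying within subject get `n_obs − n_subjects − p_within`.
- Post-hoc comparisons are Tukey-adjusted contrasts of estimated marginal
  means over the factor reference grid (covariates at their means),
  `p = P(q_{k,df} > |t|√2)` with the studentized-range distribution.
- Rank-deficient designs raise an error naming the aliased columns.

## 7. Synthetic-data generator

### EEG (`simulate_eeg`)

Signal: one sinusoid per tagged harmonic with uniformly random phase,
per-ROI topography gains, plus 1/f ("pink") and white Gaussian noise.

| parameter | default | rationale |
|-----------|---------|-----------|
| sampling rate | 256 Hz | > 2 × highest quantified harmonic (20 Hz) with ample margin |
| duration | 60 s | 1/60 Hz resolution; places 4.61 Hz within 0.007 Hz of a bin |
| base amplitudes | 1.0, 0.6, 0.4, 0.3 µV (5, 10, 15, 20 Hz) | decaying base response |
| oddball amplitudes | 0.2 µV × 5 harmonics | summed injected response 1.0 µV |
| stream amplitudes | 0.5, 0.35, 0.25, 0.15 µV | decaying stream response |
| pink noise SD | 0.5 µV (exponent 1) | see below |
| white noise SD | 0.25 µV | see below |
| base-response topography | LOT 0.8, MO 1.2, ROT 0.8 | medial-occipital dominance of the base response |

The noise SDs are calibrated so the per-subject noise floor keeps the
summed baseline-subtracted quantification bias (§2) under 10%; with these
defaults the measured 100-replicate mean recovery error is ≈ 7%.

### Cohort outcome tables (`simulate_cohort`)

Group sizes default to 43 controls / 48 adversity (EEG) and 28 / 41 (gaze).
Effects are specified in units of the within-subject SD (default σ_w =
0.4 µV, between-subject SD 0.3 µV):

- `group_content_gap_sd = 1.0` — controls get ±gap/2 by content (social
  positive), i.e. a pure group × content interaction plus a content main
  effect, with no group main effect.
- `threat_content_slope_sd = −1.0`, `neglect_content_slope_sd = 0.5` —
  content-contrast slopes of the standardized threat/neglect scores within
  the adversity group.
- `valence_main_sd = 1.0`, `valence_content_sd = 1.0` — multi-input neutral
  salience advantage and its social-context enhancement.
- A shared latent factor (SD 1.5, gaze loading 0.1) couples the neural and
  gaze valence contrasts, producing gaze–neural difference-score
  correlations in the 0.6–0.85 range at the default group sizes (the
  attenuation is closed-form: `r = γσ_s² / (√(σ_s²+σ_n²)·√(γ²σ_s²+σ_g²))`).
- Threat scores are Gamma-distributed in the adversity group and zero in
  controls; symptom scores are correlated with adversity.

### Fixations (`simulate_fixations`)

True fixation targets are drawn uniformly inside the chosen AOI with a
3σ margin from its borders (or outside both AOIs with the same margin), so
the Gaussian-mass recovery of dwell proportions is unbiased; reported
positions add isotropic Gaussian calibration scatter (default 30 px on a
1920×1080 screen); durations are Gamma-distributed (mean 0.3 s).

### Determinism

All randomness flows from `np.random.default_rng([seed, *stream])` where
sub-stream identifiers hash subject/condition labels with CRC-32 (stable
across processes, unlike Python's salted `hash`). Identical configurations
and seeds give bit-identical recordings, tables, fixations and exported
files.

### What the generator does *not* emulate

Eye blinks/movement artifacts, channel-specific noise topographies,
non-sinusoidal (steady-state) response waveshapes, inter-electrode
correlation beyond shared signal, saccade dynamics, missing data, or any
preprocessing (filtering, re-referencing, artifact rejection). The
generator exists to validate the analysis code, not to imitate raw
recordings.

## 8. Pipeline and file formats

`fpvstag run-oddball | run-multiinput | run-all` simulate a cohort, scale
each subject's injected EEG response to the cohort table's ground truth,
run harmonic selection on group-averaged spectra, quantify per subject,
fit Models 1–3, compute Tukey contrasts and gaze–neural correlations, and
export tidy CSVs plus a JSON report (including the full configuration and
package version). EEG is exported as long-format CSV
(`channel, time_s, amplitude_uv`); configurations are YAML with unknown
keys rejected.

## 9. Limitations

- Denominator df use the containment rule, not Satterthwaite approximation;
  the two differ on unbalanced data.
- The mixed model supports a single random intercept (no random slopes,
  crossed or nested factors).
- Baseline-subtracted quantification inherits the negative noise-floor bias
  described in §2; between-condition contrasts are unaffected to first
  order, absolute response magnitudes are underestimated at low SNR.
- The harmonic-retention z tail is ≈ 0.065 rather than 0.05 for the reasons
  in §2; this matches the estimator's actual sampling distribution, not a
  software defect.
- Gaze AOIs must be axis-aligned, non-overlapping rectangles.
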