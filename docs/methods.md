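# Methods

## The analysis in brief

`neurovar` quantifies how well moment-to-moment variability of a
single-channel (Cz) EEG response encodes interindividual differences in
sensory intensity discriminability, and whether that code is separable from
the evoked (ERP) amplitude.

Per subject, epoched single-trial EEG (−500 … +1000 ms around stimulus
onset, 1 kHz) is reduced to windowed metric tracks with a 100 ms sliding
window stepped at 1 ms:

- **temporal SD** — the population-form standard deviation of the samples
  in the window, `sqrt(sum((x_i − mean)²) / n)` (divisor *n*, matching the
  metric's printed definition; not the *n−1* sample form),
- **permutation entropy (PE)** — the Shannon entropy (natural log) of the
  ordinal-pattern distribution of length-*m* embedding vectors
  (defaults m = 4, τ = 1; a 100-point window yields 97 vectors; range
  [0, log m!]),
- **windowed amplitude** — the window mean, serving as the ERP-amplitude
  covariate,
- **CV** — SD divided by the window mean, provided for completeness only:
  near-zero window means make it unstable, so it returns an infinite
  sentinel there and is not used as a primary metric.

Tracks are computed per trial and then trial-averaged within each intensity
condition (a trial-averaged-signal mode exists as a flag); the per-subject
contrast is the high-minus-low difference track (ΔSD, ΔAmplitude).
Discriminability is scored from the 0–10 NRS ratings as
ΔRating = mean(high) − mean(low), with AUC (probability of superiority,
ties = 1/2) and d′ (pooled-variance normalisation, *n−1* variances) as
scale-bias-robust alternatives.

Inference is point-by-point across subjects: Pearson (or Spearman for
small-N) correlation of the Δ track with the scores at every window center;
partial correlation controlling ΔAmplitude at the same time point
(residual-correlation identity, *t* with n−3 df, two-tailed); BH-FDR at
α = 0.05 over the post-stimulus window centers only (one channel, one
analysis = one family; pre-stimulus points are excluded from the family and
never flagged); a JZS Bayes factor per point. Dominance analysis splits the
two-predictor regression R² into total dominances
`td_a = (R²_full − R²_b + R²_a)/2`, which for two predictors equals the
ordering-average definition and sums exactly to R²_full. Robustness is
probed by (a) adding baseline-sampled noise at scales 0–2 (step 0.2, 11
scales) to post-stimulus samples and re-estimating the ROI partial
correlation, and (b) bootstrap power maps over subject and trial counts
(100 resamples per size by default), with the smallest size reaching 80%
detection probability.

## Windowing conventions

Window timestamps are **centers**; only full windows are evaluated, so a
1500-sample epoch yields 1401 window positions at a 100-sample window and
1-sample step, spanning −450.5 … +949.5 ms. Centered stamps keep ΔSD peaks
directly comparable to ERP component latencies. Peak search for the ROI
(±10 ms, i.e. 21 centers at 1 kHz) is restricted to post-stimulus centers;
PE uses the trough instead of the peak because the planted effect lowers
entropy. Fast tracks use cumulative-sum windowed moments; the scalar
`temporal_sd` is the direct two-pass formula, and a partition-consistency
test ties the two paths together.

PE ties are broken by order of appearance (stable argsort). Real EEG is
continuous-valued so exact ties have measure zero, but integer-valued test
vectors need a deterministic rule. The log base is natural; any base only
rescales PE and all assertions are base-invariant.

## Statistical details

- **JZS Bayes factor.** The correlation BF is the one-predictor
  Zellner–Siow regression BF: the g-prior integral with an
  inverse-gamma(1/2, n·s²/2) mixing density, scale s = √2/2
  (unit-information default, configurable). It is evaluated by adaptive
  quadrature after mapping g to (0, 1), with a log-space max-shift so large
  n·r² cannot overflow; non-convergence raises with diagnostics. An
  independent fine-grid trapezoid integration serves as the test oracle
  (1% tolerance). Evidence bins follow Kass–Raftery
  (1–3.3 / 3.3–10 / 10–100 / >100; boundaries go to the upper bin; BF < 1
  is reported as the reciprocal favoring the null).
- **Comparing correlations.** For two dependent correlations sharing a
  variable, Steiger's z (Fisher-z form with the mean-r covariance
  simplification); for disjoint groups (e.g. rating-matched subgroups), the
  independent-groups Fisher-z test. Both are exposed; the matched-contrast
  path uses the independent-groups form because matched pain and non-pain
  subgroups are disjoint subject sets.
- **Intra-individual analysis.** Per subject, single-trial metric values
  are correlated with single-trial ratings over trials; Fisher-z
  coefficients are tested against zero with a one-sample t per time point,
  FDR over post-stimulus centers. Subjects with zero rating variance are
  excluded and logged.
- **Sensitivity analysis.** Condition-pooled mean SD tracks versus mean
  ratings ([high+low]/2), partial on pooled mean amplitude — the
  between-subject sensory-sensitivity control.
- **Degenerate designs.** A covariate numerically collinear with either
  variable leaves nothing to correlate after residualization; the partial r
  is defined as 0 with p = 1 (rather than NaN), and rank-deficient
  dominance designs raise. Negative total dominance (suppressor structure)
  is returned as-is, never clamped.

## Synthetic cohort

The generator emulates the structure the analyses target, per subject i,
condition c, trial k:

    x(t) = a_{i,c}·ERP(t) + (σ_base,i + level(c)·Δσ_i)·g(t)·osc_k(t) + ε_k(t)

- `ERP(t)`: fixed biphasic template — Gaussian-windowed deflections at
  200 ms (negative, N2-like) and 400 ms (positive, P2-like), widths 50 ms,
  amplitudes −2.5/+4 µV, zero before onset. `a_{i,low} = 1`;
  `a_{i,high}` has mean 1.3 (SD 0.1).
- `g(t)`: Gaussian post-stimulus envelope (center 350 ms, width 150 ms),
  exactly zero pre-stimulus.
- `osc_k(t)`: unit-SD 1–30 Hz band-limited Gaussian noise drawn
  independently per trial, so the induced term cancels in the trial average
  while its windowed SD carries the per-subject gain Δσ_i
  (σ_base = 0.8 µV; Δσ mean 0.6, SD 0.6 µV).
- `ε_k(t)`: 1–30 Hz background noise (SD 0.5 µV) throughout the epoch,
  matching the broadband analysis filter so the generator's spectrum is
  consistent with the preprocessing band.
- Ratings: `r = μ_i + level(c)·D_i + η`, η ~ N(0, 0.8 NRS), clipped to
  [0, 10] (clipping is logged because it biases D recovery at scale ends);
  μ_i ~ N(3, 0.5); D_i has mean 2, SD 1 — the mean matching the canonical
  worked example (ratings 5 and 3 → ΔRating 2).

Per-subject latents (D_i, Δσ_i, amplitude gain) are drawn by a Cholesky
construction with D as the shared factor, so the sample realizes the
configured correlations `rho_var_discrim` (default 0.5) and
`rho_amp_discrim` (default 0.4). Optional fields `sigma_base_sd` and
`rho_base_rating` couple the per-subject baseline induced level to the
rating offset μ_i, providing a positive control for the sensitivity
analysis. Within-subject rating SD is not an observable the source designs
report; 0.8 NRS is a free default and stays configurable.

**Calibration.** The free amplitude/noise defaults were chosen so that the
between-subject variance of the ROI ΔSD is dominated by the planted Δσ
spread rather than by trial-sampling noise or the evoked within-window SD:
with the defaults, the ROI partial correlation at n = 200 subjects and 15
trials/condition averages ≈ 0.45 against a planted 0.5 — essentially at
the theoretical ceiling of ≈ 0.47 implied by partialling an amplitude
covariate itself correlated 0.4 with discriminability. Cohort sizes in the
bundled drivers (200 subjects) mirror the multi-hundred-subject cohorts the
method is designed for; trials per condition default to 15.

**What the generator does not emulate** — multi-channel topographies and
volume conduction, artifacts (blinks, muscle) beyond stationary band-limited
noise, non-Gaussian rating distributions, serial dependence across trials,
and any nonlinearity of the psychometric function. Passing tests therefore
demonstrate that the pipeline recovers planted effects of the assumed form
at realistic sizes and noise levels — not that real EEG satisfies those
assumptions.

## Preprocessing and store

Band-pass filtering is a 4th-order Butterworth applied forward–backward
(zero phase, so N2/P2-like latencies are not shifted), with reflect padding
of three periods of the low edge because a 1 Hz edge transient otherwise
leaks into a 1.5 s epoch. Baseline correction subtracts the per-trial mean
over the pre-stimulus interval. Canonical bands: delta 1–4, theta 4–8,
alpha 8–12, beta 12–30 Hz, verbatim half-power edges with no gap/overlap
correction. The epoch is fixed at 1500 samples (−500 … +999 ms inclusive
at 1 kHz); the nominal +1000 ms endpoint is treated as exclusive.

The cohort store is one directory: `meta.json` (channel, rate, time axis,
subject list), `trials.tsv` (per-trial condition/modality), one `.npy`
array per subject (trials × time float64), `ratings.tsv`
(subject/modality/condition/trial/rating, validated to [0, 10] with unique
keys). Round-trips are lossless at float64.

## Rating matching

Pain subjects are visited in ascending subject-id order (the greedy
procedure is order-dependent; the order is therefore fixed and documented).
For a pain subject with mean ratings (h, l), candidates are unused
other-modality subjects within ±0.5 NRS on both conditions; among
candidates the smallest |Δhigh| + |Δlow| wins, exact ties broken uniformly
with the seeded generator. Every returned pair is guaranteed within
tolerance and the pairing is injective (hard invariants). Each modality
pairing is matched independently. Matching quality is validated by the
error bound plus a two-sample t on matched ΔRating distributions rather
than an omnibus interaction test.

## Noise injection and resampling

Noise traces are built from the pre-stimulus baselines of donor trials
drawn with replacement from the same subject — preserving that subject's
real noise structure — and two donor segments are stitched (then trimmed)
because the 500 ms baseline is shorter than the 1000 ms post-stimulus
interval. Scaled noise is added to post-stimulus samples only; scale 0 is a
bit-identical identity. Resampling is bootstrap with replacement; when
resampling trials all subjects are used and vice versa. The subject-axis
grid defaults to 20…N in steps of 10.

## Problem sizes in the bundled runs

The acceptance/driver scripts use 200 subjects for parameter recovery and
matching (20 seeds for the recovery average), 40–80-subject cohorts with a
boosted planted effect (rho 0.8) for the qualitative noise/power/band
reproductions, and 5–25 ms track steps where point-by-point resolution is
not itself under test. These sizes are the package's own choices: large
enough that the planted-effect orderings are stable across seeds, small
enough to run on a laptop.

## Known limitations

- The greedy matcher is not an optimal assignment; a different iteration
  order changes the pairing (by design, mirroring the described procedure).
- The JZS quadrature is specified for |r| < 1 and n ≥ 5; perfect
  correlations must be clipped by the caller (the track path clips at
  1 − 1e−12).
- PE sliding tracks construct a one-hot pattern cumulative sum; memory
  grows with (trials × time × observed patterns) and m > 5 embeddings are
  not practical at full step resolution.
- Power maps with very small resample sizes can produce zero-variance
  Δ tracks (e.g. duplicate subjects); such columns are treated as
  non-significant rather than erroring.
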