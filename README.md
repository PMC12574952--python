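# neurovar

Windowed neural-variability analysis of sensory intensity discriminability
from epoched EEG.

Some people can tell a strong painful stimulus from a weaker one much more
reliably than others. `neurovar` implements an analysis pipeline for the
hypothesis that this interindividual difference is encoded in the
*moment-to-moment variability* of the stimulus-evoked EEG — over and above
the evoked (ERP) amplitude. It is aimed at researchers analysing epoched
single-channel (typically Cz) EEG with per-trial intensity ratings, and it
ships a synthetic-cohort generator with planted effects so the whole chain
is testable without any recording.

## What it computes

For subject *i* with single-trial epochs x(t) (−500…+1000 ms, 1 kHz) and
0–10 NRS ratings:

- **Temporal SD** in a 100 ms sliding window (1 ms steps):
  `tempSD = sqrt( Σ_i (x_i − x̄)² / n )` — computed per trial, averaged
  within condition; **permutation entropy** `PE = −Σ_p p·log p` over
  ordinal patterns (m = 4, τ = 1) as an amplitude-insensitive companion;
  the windowed mean as the **ERP amplitude** covariate.
- **Discriminability**: ΔRating = mean(high) − mean(low); alternatives
  AUC (probability of superiority) and d′ = ΔRating / √(½(s²_h + s²_l)).
- **Point-by-point inference** across subjects: r(ΔSD, ΔRating) at every
  window center; the partial correlation controlling ΔAmplitude at the
  same point; BH-FDR (α = 0.05) over post-stimulus centers; JZS Bayes
  factors (Zellner–Siow g-prior, scale √2/2) with Kass–Raftery bins.
- **Dominance analysis**: total dominance
  td_SD = (R²_full − R²_amp + R²_SD)/2 per time point, summing exactly to
  the full-model R².
- **Robustness**: baseline-sampled noise injection at scales 0–2 (step
  0.2) and bootstrap power maps over subject/trial counts with the 80%
  detection contour.
- **Rating matching**: greedy cross-modality pairing with per-condition
  mean-rating error ≤ 0.5 NRS, for amplitude-matched pain vs non-pain
  comparisons; **band profiles**: the partial-correlation analyses repeated
  in delta/theta/alpha/beta.

See `docs/methods.md` for conventions, priors and the generator model.

## Worked example

```python
from neurovar.simulate import GeneratorConfig, generate_cohort
from neurovar.cohort import cohort_tracksets, delta_tracks, roi_partial_analysis
from neurovar.discrim import discriminability_scores

cohort, ratings, truth = generate_cohort(GeneratorConfig(n_subjects=200, seed=1))
scores = discriminability_scores(ratings)          # per-subject ΔRating
var_d  = delta_tracks(cohort_tracksets(cohort, "tempSD"))     # ΔSD tracks
amp_d  = delta_tracks(cohort_tracksets(cohort, "amplitude"))  # ΔAmplitude
res = roi_partial_analysis(var_d, amp_d, scores)
print(f"ROI {res.interval[0]:.0f}-{res.interval[1]:.0f} ms: "
      f"partial r = {res.r:.3f}, p = {res.p:.2e}, BF = {res.bf:.3g}")
```

prints

```
ROI 318-338 ms: partial r = 0.435, p = 1.37e-10, BF = 6.28e+07
```

The cohort was generated with a planted correlation of 0.5 between each
subject's induced-variability gain Δσ_i and their rating difference D_i
(the realized sample value here is 0.538). The analysis finds the
subject-averaged ΔSD peak at 328 ms, and the per-subject ΔSD in the ±10 ms
window around it correlates with ΔRating at r = 0.435 *after* controlling
the amplitude difference at the same time point — decisive Bayesian
evidence (BF ≫ 100) that the variability code is not an amplitude artifact.
The recovered 0.435 sits at the theoretical ceiling (≈ 0.47) implied by
partialling a covariate itself correlated 0.4 with discriminability.

The numbered drivers under `analysis/` run the full story on this cohort
and write tables to `results/`: simulation (`01`), metric tracks (`02`),
(partial) correlation tracks and the induced-response control (`03`),
dominance decomposition (`04`), noise sweep and power maps (`05` — with the
default planted effect, SD-based detection reaches 80% power at ~4 trials
while amplitude-based detection needs more), rating matching (`06`), and
band profiles (`07`).

There is also a CLI: `neurovar simulate|metrics|associate|dominance|robustness|match|bands|run-all`
(see `neurovar --help`); every stage is seeded and every figure has a TSV
twin.

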