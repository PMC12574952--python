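"""Noise-injection stress tests and bootstrap power maps.

Two robustness procedures:

* **Noise injection** — noise traces are sampled from the pre-stimulus
  baseline of randomly chosen trials of the same subject (so the real noise
  structure is respected), scaled by a "noise scale" factor, and added to
  the post-stimulus samples of one or both intensity conditions; the ROI
  partial-correlation analysis is then repeated per scale.
* **Resampling power maps** — subjects (or trials) are bootstrapped with
  replacement; per resample the Δ-track correlation with discriminability
  is FDR-thresholded, and the per-time-point probability of significance is
  estimated over repetitions, with the size needed for ≥80% detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import cohort_tracksets, delta_tracks, roi_partial_analysis
from .io import EpochSet
from .stats import _align_scores, _columnwise_r, _r_to_p, fdr_bh
from .variability import TrackSet

__all__ = [
    "NoiseConfig",
    "PowerMap",
    "inject_noise",
    "noise_sweep",
    "power_map",
    "min_size_for_power",
]

DEFAULT_SCALES = tuple(np.round(np.arange(0.0, 2.01, 0.2), 10))


@dataclass
class NoiseConfig:
    """Noise-injection sweep settings (scales 0-2 in steps of 0.2 by default)."""

    scales: tuple[float, ...] = DEFAULT_SCALES
    target: str = "high"                      # low / high / both
    baseline_interval: tuple[float, float] = (-500.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.scales):
            raise ValueError("noise scales must be >= 0")
        if self.target not in ("low", "high", "both"):
            raise ValueError("target must be low, high or both")
        if self.baseline_interval[1] > 0:
            raise ValueError("baseline interval must be pre-stimulus")


def inject_noise(
    e: EpochSet,
    scale: float,
    target: str = "high",
    seed: int | np.random.Generator = 0,
    baseline_interval: tuple[float, float] = (-500.0, 0.0),
) -> EpochSet:
    """Add scaled baseline-sampled noise to post-stimulus samples.

    For each targeted trial a noise trace is built by concatenating the
    baseline segments of trials drawn with replacement from the same
    subject (the post-stimulus interval is longer than the baseline, so two
    or more donor segments are stitched and trimmed), multiplied by
    ``scale`` and added to the t >= 0 samples only.  Pre-stimulus samples
    are untouched; scale 0 returns a bit-identical copy.
    """
    if scale < 0:
        raise ValueError("scale must be >= 0")
    if target not in ("low", "high", "both"):
        raise ValueError("target must be low, high or both")
    targets = ("low", "high") if target == "both" else (target,)
    for cond in targets:
        if not np.any(e.condition == cond):
            raise ValueError(f"condition {cond!r} absent from epochs")
    out = e.copy()
    if scale == 0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    base_mask = (e.times >= baseline_interval[0]) & (e.times < baseline_interval[1])
    post_mask = e.times >= 0
    n_base = int(base_mask.sum())
    n_post = int(post_mask.sum())
    if n_base == 0:
        raise ValueError("no baseline samples in the requested interval")
    n_donors = -(-n_post // n_base)  # ceil
    trial_rows = np.flatnonzero(np.isin(e.condition, targets))
    for k in trial_rows:
        donors = rng.integers(0, e.n_trials, size=n_donors)
        trace = np.concatenate([e.data[d, base_mask] for d in donors])[:n_post]
        out.data[k, post_mask] += scale * trace
    return out


def noise_sweep(
    cohort: list[EpochSet],
    scores,
    config: NoiseConfig,
    window_ms: float = 100.0,
    step_ms: float = 1.0,
    support_log10bf: float = 0.5,
) -> pd.DataFrame:
    """ROI partial correlation and Bayes factor under each noise scale.

    For every scale the cohort is perturbed, ΔSD and ΔAmplitude tracks are
    recomputed, and the ROI partial correlation of ΔSD with the scores
    (controlling ΔAmplitude) is evaluated.  A row is flagged ``supported``
    when log10(BF) meets the support threshold (default 0.5, i.e. BF ≥
    about 3.2).
    """
    targets = ("low", "high") if config.target == "both" else (config.target,)
    rows = []
    root = np.random.default_rng(config.seed)
    for scale in config.scales:
        seed = int(root.integers(0, 2**31 - 1))
        for tgt in targets:
            rng = np.random.default_rng(seed)
            perturbed = [
                inject_noise(e, scale, tgt, rng, config.baseline_interval) for e in cohort
            ]
            var_d = delta_tracks(cohort_tracksets(perturbed, "tempSD", window_ms, step_ms))
            amp_d = delta_tracks(cohort_tracksets(perturbed, "amplitude", window_ms, step_ms))
            res = roi_partial_analysis(var_d, amp_d, scores)
            rows.append(
                {
                    "scale": scale,
                    "target": tgt,
                    "partial_r": res.r,
                    "p": res.p,
                    "bf": res.bf,
                    "log10_bf": np.log10(res.bf),
                    "supported": np.log10(res.bf) >= support_log10bf,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PowerMap:
    """Probability-of-significance grid over (resample size x time)."""

    axis: str                      # "subjects" or "trials"
    sizes: np.ndarray
    times: np.ndarray
    prob: np.ndarray               # (n_sizes, n_times) in [0, 1]
    contour80: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes)
        self.prob = np.asarray(self.prob, dtype=float)
        if self.prob.shape != (self.sizes.size, self.times.size):
            raise ValueError("prob must be sizes x times")
        if np.any((self.prob < 0) | (self.prob > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        self.contour80 = self.prob >= 0.8


def _condition_stack(tracksets: list[TrackSet], cond: str) -> np.ndarray:
    """(subjects, trials, times) array of one condition's single-trial tracks."""
    per = [ts.values[ts.condition == cond] for ts in tracksets]
    counts = {a.shape[0] for a in per}
    if len(counts) != 1:
        raise ValueError(f"unequal {cond!r} trial counts across subjects")
    return np.stack(per)


def power_map(
    cohort: list[EpochSet],
    scores,
    axis: str,
    sizes,
    n_reps: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
    metric: str = "tempSD",
    window_ms: float = 100.0,
    step_ms: float = 1.0,
    high: str = "high",
    low: str = "low",
) -> PowerMap:
    """Bootstrap probability of FDR-significant correlation per time point.

    Resampling is with replacement along ``axis``; when resampling trials
    all subjects are used (and vice versa).  Per resample the per-subject
    Δ track is correlated with the scores across subjects and thresholded
    with BH-FDR at ``alpha`` over the post-stimulus family.
    """
    if axis not in ("subjects", "trials"):
        raise ValueError("axis must be 'subjects' or 'trials'")
    sizes = np.asarray(sizes, dtype=int)
    rng = np.random.default_rng(seed)
    tracksets = cohort_tracksets(cohort, metric, window_ms, step_ms)
    times = tracksets[0].times
    post = times >= 0
    sids = [ts.subject_id for ts in tracksets]
    y_full = _align_scores(scores, sids)
    n_sub = len(sids)

    H = _condition_stack(tracksets, high)
    L = _condition_stack(tracksets, low)
    if axis == "subjects":
        if sizes.max() > n_sub:
            raise ValueError("requested more subjects than available")
        D = H.mean(axis=1) - L.mean(axis=1)          # (S, T)
    else:
        n_tr = min(H.shape[1], L.shape[1])
        if sizes.max() > n_tr:
            raise ValueError("requested more trials than available")

    prob = np.zeros((sizes.size, times.size))
    for i, k in enumerate(sizes):
        hits = np.zeros(times.size)
        for _ in range(n_reps):
            if axis == "subjects":
                idx = rng.integers(0, n_sub, size=k)
                X, y = D[idx], y_full[idx]
            else:
                hi = rng.integers(0, H.shape[1], size=(n_sub, k))
                li = rng.integers(0, L.shape[1], size=(n_sub, k))
                Xh = np.take_along_axis(H, hi[:, :, None], axis=1).mean(axis=1)
                Xl = np.take_along_axis(L, li[:, :, None], axis=1).mean(axis=1)
                X, y = Xh - Xl, y_full
            sd_ok = (X.std(axis=0) > 0) & (y.std() > 0)
            r = np.zeros(times.size)
            r[sd_ok] = _columnwise_r(X[:, sd_ok], y)
            p = _r_to_p(r, X.shape[0] - 2)
            p[~sd_ok] = 1.0
            sig = np.zeros(times.size, dtype=bool)
            sig[post] = fdr_bh(p[post], alpha=alpha)
            hits += sig
        prob[i] = hits / n_reps
    return PowerMap(axis=axis, sizes=sizes, times=times, prob=prob)


def min_size_for_power(pmap: PowerMap, threshold: float = 0.8) -> np.ndarray:
    """Smallest resample size reaching the detection threshold per time point.

    Returns a float vector over time; NaN marks time points where the
    threshold is never reached.
    """
    out = np.full(pmap.times.size, np.nan)
    for j in range(pmap.times.size):
        reached = np.flatnonzero(pmap.prob[:, j] >= threshold)
        if reached.size:
            out[j] = float(pmap.sizes[reached[0]])
    return out
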