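"""Windowed neural-variability and windowed-amplitude tracks.

Moment-to-moment variability of the EEG is quantified within short sliding
windows.  The primary metric is the temporal SD — the population-form
standard deviation of the samples inside a window — computed at the
single-trial level and then averaged across trials of a condition.
Permutation entropy (PE), an ordinal-pattern complexity measure, serves as
an amplitude-insensitive companion metric, and the windowed mean serves as
the amplitude track the variability results are controlled against.

Window timestamps refer to window *centers*; only full windows are
evaluated (no padding), so a track on an epoch spanning [t0, t1] covers
[t0 + w/2, t1 - w/2].
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace

import numpy as np

from .io import EpochSet

__all__ = [
    "MetricTrack",
    "TrackSet",
    "temporal_sd",
    "permutation_entropy",
    "coefficient_of_variation",
    "sliding_track",
    "condition_average",
    "diff_track",
    "induced_epochs",
    "peak_roi",
    "roi_value",
]

logger = logging.getLogger(__name__)

METRICS = ("tempSD", "PE", "CV", "amplitude")
CV_SENTINEL = math.inf
_MEAN_TOL = 1e-12


@dataclass
class MetricTrack:
    """A per-subject, per-condition windowed metric time series."""

    subject_id: str
    metric: str
    condition: str           # a condition label, or "diff" for high-low
    window_ms: float
    step_ms: float
    times: np.ndarray        # window-center times, ms
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")


@dataclass
class TrackSet:
    """Single-trial metric tracks for one subject: trials x windows."""

    subject_id: str
    metric: str
    window_ms: float
    step_ms: float
    times: np.ndarray                 # window centers, ms
    values: np.ndarray                # (n_trials, n_windows)
    condition: np.ndarray             # per-trial labels

    def __post_init__(self) -> None:
        if self.values.shape != (self.condition.size, self.times.size):
            raise ValueError("values must be trials x windows")


def temporal_sd(x: np.ndarray) -> float:
    """Temporal SD of one window: sqrt(mean squared deviation), divisor n.

    The population form (divisor n, not n-1) is used throughout.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("temporal SD needs at least 2 samples")
    d = x - x.mean()
    return float(np.sqrt(np.mean(d * d)))


def _ordinal_pattern_codes(x: np.ndarray, m: int, tau: int) -> np.ndarray:
    """Integer code of each length-m ordinal pattern along the last axis.

    Embedding vectors are (x_t, x_{t+tau}, ..., x_{t+(m-1)tau}); the pattern
    is the permutation produced by a stable argsort, so ties are broken by
    order of appearance.  Codes are the base-m digits of that permutation.
    """
    x = np.asarray(x, dtype=float)
    span = (m - 1) * tau + 1
    if x.shape[-1] < span:
        raise ValueError(f"need at least {(m - 1) * tau + 1} samples for m={m}, tau={tau}")
    emb = np.lib.stride_tricks.sliding_window_view(x, span, axis=-1)[..., ::tau]
    perm = np.argsort(emb, axis=-1, kind="stable")
    weights = m ** np.arange(m)
    return perm @ weights


def _entropy_from_counts(counts: np.ndarray) -> np.ndarray:
    """Shannon entropy (natural log) of relative frequencies along last axis."""
    total = counts.sum(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / total
        term = np.where(counts > 0, p * np.log(p), 0.0)
    return -term.sum(axis=-1)


def permutation_entropy(x: np.ndarray, m: int = 4, tau: int = 1) -> float:
    """Permutation entropy of one window (natural log).

    From a window of n samples, n - (m-1)*tau embedding vectors are ranked
    into ordinal patterns; PE is the Shannon entropy of the pattern
    relative-frequency distribution.  Range [0, log(m!)].
    """
    if m < 2:
        raise ValueError("embedding dimension m must be >= 2")
    if tau < 1:
        raise ValueError("delay tau must be >= 1")
    codes = _ordinal_pattern_codes(np.atleast_1d(np.asarray(x, float)), m, tau)
    _, counts = np.unique(codes, return_counts=True)
    return float(_entropy_from_counts(counts.astype(float)))


def coefficient_of_variation(x: np.ndarray) -> float:
    """CV = temporal SD / window mean; infinite sentinel for a near-zero mean.

    Unstable when the mean is small — provided for completeness, not used as
    the primary variability metric.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("CV needs at least 2 samples")
    mu = x.mean()
    if abs(mu) < _MEAN_TOL:
        return CV_SENTINEL
    return temporal_sd(x) / mu


# ---------------------------------------------------------------------------
# Sliding windows
# ---------------------------------------------------------------------------

def _window_geometry(e: EpochSet, window_ms: float, step_ms: float):
    w = int(round(window_ms * e.sfreq / 1000.0))
    step = int(round(step_ms * e.sfreq / 1000.0))
    n = e.times.size
    if w < 2 or w > n:
        raise ValueError(f"window of {w} samples invalid for {n}-sample epoch")
    if step < 1:
        raise ValueError("step must be at least one sample")
    starts = np.arange(0, n - w + 1, step)
    centers = (e.times[starts] + e.times[starts + w - 1]) / 2.0
    return w, starts, centers


def _windowed_moments(data: np.ndarray, w: int, starts: np.ndarray):
    """Windowed mean and population SD via cumulative sums (O(n) per trial)."""
    c1 = np.cumsum(np.concatenate([np.zeros(data.shape[:-1] + (1,)), data], axis=-1), axis=-1)
    c2 = np.cumsum(
        np.concatenate([np.zeros(data.shape[:-1] + (1,)), data * data], axis=-1), axis=-1
    )
    s1 = c1[..., starts + w] - c1[..., starts]
    s2 = c2[..., starts + w] - c2[..., starts]
    mean = s1 / w
    var = np.maximum(s2 / w - mean * mean, 0.0)
    return mean, np.sqrt(var)


def _windowed_pe(data: np.ndarray, w: int, starts: np.ndarray, m: int, tau: int):
    codes = _ordinal_pattern_codes(data, m, tau)
    n_patterns = math.factorial(m)
    # map base-m permutation codes to a dense 0..m!-1 index
    uniq = np.unique(codes)
    lookup = np.full(int(uniq.max()) + 1, -1)
    lookup[uniq] = np.arange(uniq.size)
    dense = lookup[codes]
    onehot = np.zeros(codes.shape + (uniq.size,))
    np.put_along_axis(onehot, dense[..., None], 1.0, axis=-1)
    cum = np.cumsum(
        np.concatenate([np.zeros(codes.shape[:-1] + (1, uniq.size)), onehot], axis=-2), axis=-2
    )
    n_vec = w - (m - 1) * tau
    if n_vec < 1:
        raise ValueError("window too short for the PE embedding")
    counts = cum[..., starts + n_vec, :] - cum[..., starts, :]
    pe = _entropy_from_counts(counts)
    return pe, n_patterns


def sliding_track(
    e: EpochSet,
    metric: str,
    window_ms: float = 100.0,
    step_ms: float = 1.0,
    m: int = 4,
    tau: int = 1,
    mode: str = "single-trial",
) -> TrackSet:
    """Evaluate a windowed metric in every full sliding window of every trial.

    ``metric`` is one of ``tempSD``, ``PE``, ``CV``, ``amplitude`` (windowed
    mean).  ``mode="trial-average"`` computes the metric on the per-condition
    trial-averaged waveform instead (one row per condition).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")
    if mode not in ("single-trial", "trial-average"):
        raise ValueError(f"unknown mode {mode!r}")
    w, starts, centers = _window_geometry(e, window_ms, step_ms)
    if mode == "trial-average":
        conds = list(dict.fromkeys(e.condition))
        data = np.vstack([e.data[e.condition == c].mean(axis=0) for c in conds])
        labels = np.asarray(conds, dtype=object)
    else:
        data, labels = e.data, e.condition
    if metric == "tempSD":
        _, values = _windowed_moments(data, w, starts)
    elif metric == "amplitude":
        values, _ = _windowed_moments(data, w, starts)
    elif metric == "CV":
        mean, sd = _windowed_moments(data, w, starts)
        with np.errstate(divide="ignore", invalid="ignore"):
            values = np.where(np.abs(mean) < _MEAN_TOL, CV_SENTINEL, sd / mean)
    else:  # PE
        values, _ = _windowed_pe(data, w, starts, m, tau)
    return TrackSet(
        subject_id=e.subject_id,
        metric=metric,
        window_ms=window_ms,
        step_ms=step_ms,
        times=centers,
        values=values,
        condition=labels,
    )


def condition_average(tracks: TrackSet, condition: str) -> MetricTrack:
    """Trial-mean track within one condition."""
    mask = tracks.condition == condition
    if not mask.any():
        raise ValueError(f"no trials with condition {condition!r}")
    return MetricTrack(
        subject_id=tracks.subject_id,
        metric=tracks.metric,
        condition=condition,
        window_ms=tracks.window_ms,
        step_ms=tracks.step_ms,
        times=tracks.times.copy(),
        values=tracks.values[mask].mean(axis=0),
    )


def diff_track(high: MetricTrack, low: MetricTrack) -> MetricTrack:
    """Pointwise high - low difference track (ΔSD, ΔAmplitude, ...)."""
    if high.metric != low.metric or high.times.size != low.times.size or not np.allclose(
        high.times, low.times
    ):
        raise ValueError("tracks differ in metric or window geometry")
    return replace(high, condition="diff", values=high.values - low.values)


def induced_epochs(e: EpochSet) -> EpochSet:
    """Remove the evoked (trial-averaged) waveform per condition.

    The remaining induced single-trial responses have a trial average of
    (numerically) zero within each condition; phase-inconsistent activity
    such as the planted induced component survives.
    """
    out = e.copy()
    for cond in np.unique(e.condition):
        mask = e.condition == cond
        if mask.sum() < 2:
            raise ValueError(f"condition {cond!r} has fewer than 2 trials")
        out.data[mask] -= e.data[mask].mean(axis=0, keepdims=True)
    return out


def peak_roi(
    track: MetricTrack, halfwidth_ms: float = 10.0, mode: str = "max"
) -> tuple[float, float]:
    """Interval centered on the post-stimulus peak of a subject-averaged track.

    The search runs over window centers at t >= 0.  ``mode="min"`` locates a
    trough instead (used for PE, whose planted effect lowers entropy).
    """
    post = track.times >= 0
    if not post.any():
        raise ValueError("track has no post-stimulus window centers")
    v = track.values[post]
    t = track.times[post]
    idx = int(np.argmin(v)) if mode == "min" else int(np.argmax(v))
    if np.all(v == v[0]) and v.size > 1:
        logger.warning("track is flat; using first extremum for the ROI")
    peak = t[idx]
    return (peak - halfwidth_ms, peak + halfwidth_ms)


def roi_value(track, interval: tuple[float, float]):
    """Mean of a track (or of each trial row of a TrackSet) over an ROI."""
    lo, hi = interval
    mask = (track.times >= lo - 1e-9) & (track.times <= hi + 1e-9)
    if not mask.any():
        raise ValueError("ROI interval contains no window centers")
    if isinstance(track, TrackSet):
        return track.values[:, mask].mean(axis=1)
    return float(track.values[mask].mean())
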