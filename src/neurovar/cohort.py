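"""Cohort-level conveniences: tracks for every subject, Δ tracks, ROI analysis.

These glue functions chain the per-subject primitives over a list of
EpochSets so the robustness, band-profiling and pipeline stages share one
code path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import EpochSet
from .stats import bf_from_r, partial_corr, pearson
from .variability import (
    MetricTrack,
    TrackSet,
    condition_average,
    diff_track,
    peak_roi,
    roi_value,
    sliding_track,
)

__all__ = [
    "cohort_tracksets",
    "delta_tracks",
    "grand_average",
    "RoiResult",
    "roi_partial_analysis",
    "tracks_frame",
]


def cohort_tracksets(
    cohort: list[EpochSet],
    metric: str = "tempSD",
    window_ms: float = 100.0,
    step_ms: float = 1.0,
    **kwargs,
) -> list[TrackSet]:
    """Single-trial metric tracks for every subject."""
    return [sliding_track(e, metric, window_ms, step_ms, **kwargs) for e in cohort]


def delta_tracks(
    tracksets: list[TrackSet], high: str = "high", low: str = "low"
) -> list[MetricTrack]:
    """High-minus-low trial-averaged track per subject (ΔSD, ΔAmplitude, ...)."""
    return [
        diff_track(condition_average(ts, high), condition_average(ts, low))
        for ts in tracksets
    ]


def grand_average(tracks: list[MetricTrack]) -> MetricTrack:
    """Subject-mean of aligned tracks (used to locate the ROI peak)."""
    first = tracks[0]
    vals = np.vstack([t.values for t in tracks]).mean(axis=0)
    return MetricTrack(
        subject_id="grand", metric=first.metric, condition=first.condition,
        window_ms=first.window_ms, step_ms=first.step_ms,
        times=first.times, values=vals,
    )


@dataclass
class RoiResult:
    """Partial-correlation analysis at the peak of the subject-averaged Δ track."""

    peak_ms: float
    interval: tuple[float, float]
    r: float                      # partial r of ROI Δvar with scores given ROI Δamp
    p: float
    bf: float
    r_simple: float               # plain correlation, no covariate
    p_simple: float
    roi_var: np.ndarray           # per-subject ROI Δvariability
    roi_amp: np.ndarray           # per-subject ROI Δamplitude
    n: int


def roi_partial_analysis(
    var_deltas: list[MetricTrack],
    amp_deltas: list[MetricTrack],
    scores,
    halfwidth_ms: float = 10.0,
    peak_mode: str = "max",
) -> RoiResult:
    """ΔSD-vs-discriminability at the group-peak ROI, controlling ΔAmplitude.

    The ROI is the ±halfwidth window centred at the post-stimulus peak of
    the subject-averaged Δvariability track; per-subject ROI means of ΔSD
    and ΔAmplitude enter a partial correlation with the scores, with a JZS
    Bayes factor on the partial coefficient.
    """
    from .stats import _align_scores  # local import to keep the public surface tidy

    ga = grand_average(var_deltas)
    interval = peak_roi(ga, halfwidth_ms=halfwidth_ms, mode=peak_mode)
    roi_var = np.array([roi_value(t, interval) for t in var_deltas])
    roi_amp = np.array([roi_value(t, interval) for t in amp_deltas])
    sids = [t.subject_id for t in var_deltas]
    y = _align_scores(scores, sids)
    r, p = partial_corr(roi_var, y, roi_amp)
    r_simple, p_simple = pearson(roi_var, y)
    return RoiResult(
        peak_ms=float((interval[0] + interval[1]) / 2),
        interval=interval,
        r=r, p=p, bf=bf_from_r(r, len(sids)),
        r_simple=r_simple, p_simple=p_simple,
        roi_var=roi_var, roi_amp=roi_amp, n=len(sids),
    )


def tracks_frame(tracks: list[MetricTrack]) -> pd.DataFrame:
    """Long-format (subject, metric, condition, time_ms, value) export."""
    frames = [
        pd.DataFrame(
            {
                "subject_id": t.subject_id,
                "metric": t.metric,
                "condition": t.condition,
                "time_ms": t.times,
                "value": t.values,
            }
        )
        for t in tracks
    ]
    return pd.concat(frames, ignore_index=True)
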