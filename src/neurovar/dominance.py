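"""Dominance decomposition of explained discriminability variance.

At each time point the discriminability score is regressed on the
variability difference (ΔSD) and the amplitude difference (ΔAmplitude).
Total dominance splits the full model's R² between the two predictors:
with predictors a and b,

    td_a = (R²_full - R²_b + R²_a) / 2,    td_b = (R²_full - R²_a + R²_b) / 2,

so td_a + td_b = R²_full exactly.  For two predictors this closed form
equals the general dominance-analysis average of each predictor's R²
increments over all predictor orderings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stats import _align_scores, _stack_tracks
from .variability import MetricTrack

__all__ = ["DominanceTrack", "total_dominance", "dominance_track"]


@dataclass
class DominanceTrack:
    times: np.ndarray
    r2_full: np.ndarray
    td_var: np.ndarray
    td_amp: np.ndarray

    def __post_init__(self) -> None:
        if not np.allclose(self.td_var + self.td_amp, self.r2_full, atol=1e-10):
            raise ValueError("total dominances must sum to the full R²")


def _r2(y: np.ndarray, X: np.ndarray) -> float:
    """Centred R² of an intercept-included least-squares fit."""
    design = np.column_stack([np.ones(y.size), X])
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise ValueError("response has zero variance")
    return float(1.0 - np.sum(resid**2) / tss)


def total_dominance(y, x1, x2) -> tuple[float, float, float]:
    """(R²_full, total dominance of x1, total dominance of x2).

    Fits the two-predictor model and both single-predictor models.  Raises
    on a rank-deficient design (x1 proportional to x2).  Negative total
    dominance is possible with suppressor structure and is returned as-is.
    """
    y = np.asarray(y, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    if not (y.size == x1.size == x2.size):
        raise ValueError("y, x1, x2 must have equal length")
    if y.size < 5:
        raise ValueError("need at least 5 observations")
    if not np.all(np.isfinite(np.concatenate([y, x1, x2]))):
        raise ValueError("inputs must be finite")
    if np.linalg.matrix_rank(
        np.column_stack([np.ones(y.size), x1, x2]), tol=1e-10
    ) < 3:
        raise ValueError("rank-deficient design: predictors are collinear")
    r2_full = _r2(y, np.column_stack([x1, x2]))
    r2_1 = _r2(y, x1[:, None])
    r2_2 = _r2(y, x2[:, None])
    td1 = (r2_full - r2_2 + r2_1) / 2.0
    td2 = (r2_full - r2_1 + r2_2) / 2.0
    return r2_full, td1, td2


def dominance_track(
    scores, var_tracks: list[MetricTrack], amp_tracks: list[MetricTrack]
) -> DominanceTrack:
    """Total dominance of ΔSD vs ΔAmplitude at every window center."""
    sids, times, V = _stack_tracks(var_tracks)
    asids, atimes, A = _stack_tracks(amp_tracks)
    if sids != asids or not np.allclose(times, atimes):
        raise ValueError("variability and amplitude tracks are misaligned")
    y = _align_scores(scores, sids)
    r2_full = np.empty(times.size)
    td_var = np.empty(times.size)
    td_amp = np.empty(times.size)
    for j in range(times.size):
        r2_full[j], td_var[j], td_amp[j] = total_dominance(y, V[:, j], A[:, j])
    return DominanceTrack(times=times, r2_full=r2_full, td_var=td_var, td_amp=td_amp)
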