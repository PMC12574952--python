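"""Per-subject sensory intensity discriminability from trial ratings.

The primary score is the rating difference ΔRating = mean(high) - mean(low),
which cancels any constant per-subject rating bias.  Signal-detection-theory
alternatives (AUC as probability of superiority, d') additionally normalise
for rating spread.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "delta_rating",
    "auc",
    "dprime",
    "discriminability_scores",
    "intensity_pairs",
]

DISCRIM_METRICS = ("delta_rating", "auc", "dprime")


def _check(r_high, r_low):
    h = np.asarray(r_high, dtype=float)
    l = np.asarray(r_low, dtype=float)
    if h.size == 0 or l.size == 0:
        raise ValueError("rating vectors must be nonempty")
    return h, l


def delta_rating(r_high, r_low) -> float:
    """ΔRating: trial-mean high rating minus trial-mean low rating."""
    h, l = _check(r_high, r_low)
    return float(h.mean() - l.mean())


def auc(r_high, r_low) -> float:
    """Area under the ROC curve as probability of superiority.

    Over all (high, low) trial pairs, the fraction with high > low, with
    ties counted 1/2 — the Mann-Whitney convention, computed from average
    ranks.  0.5 for identically distributed ratings, 1.0 for perfect
    separation.
    """
    h, l = _check(r_high, r_low)
    ranks = stats.rankdata(np.concatenate([h, l]))
    u = ranks[: h.size].sum() - h.size * (h.size + 1) / 2.0
    return float(u / (h.size * l.size))


def dprime(r_high, r_low) -> float:
    """d' = ΔRating / sqrt(0.5 (Var_high + Var_low)), sample variances (n-1)."""
    h, l = _check(r_high, r_low)
    if h.size < 2 or l.size < 2:
        raise ValueError("d' needs at least 2 trials per condition")
    pooled = 0.5 * (h.var(ddof=1) + l.var(ddof=1))
    if pooled <= 0:
        raise ValueError("zero pooled variance; d' undefined")
    return float((h.mean() - l.mean()) / np.sqrt(pooled))


_FUNCS = {"delta_rating": delta_rating, "auc": auc, "dprime": dprime}


def discriminability_scores(
    ratings: pd.DataFrame,
    metric: str = "delta_rating",
    high: str = "high",
    low: str = "low",
) -> pd.DataFrame:
    """Score every (subject, modality) in a ratings table.

    Returns a frame with columns subject_id, modality, metric, value.
    """
    if metric not in _FUNCS:
        raise ValueError(f"unknown metric {metric!r}; choose from {DISCRIM_METRICS}")
    fn = _FUNCS[metric]
    rows = []
    for (sid, mod), grp in ratings.groupby(["subject_id", "modality"], sort=True):
        r_high = grp.loc[grp["condition"] == high, "rating"].to_numpy()
        r_low = grp.loc[grp["condition"] == low, "rating"].to_numpy()
        rows.append((sid, mod, metric, fn(r_high, r_low)))
    return pd.DataFrame(rows, columns=["subject_id", "modality", "metric", "value"])


def intensity_pairs(levels) -> list[tuple]:
    """All (higher, lower) intensity pairs from an ordered level list.

    With L levels there are L(L-1)/2 pairs: 4 levels give 6, 6 levels 15.
    """
    levels = list(levels)
    if len(levels) < 2:
        raise ValueError("need at least two intensity levels")
    return [(b, a) for a, b in combinations(levels, 2)]
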