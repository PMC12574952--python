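"""Greedy cross-modality rating matching.

To compare pain against another modality without intensity-rating
confounds, each pain subject is paired with a subject of the other modality
whose per-condition mean ratings both lie within a tolerance (default 0.5
NRS units) of the pain subject's — so every returned pair has an absolute
matching error of at most the tolerance for both the high- and the
low-intensity condition.  Among eligible candidates the one with the
smallest summed absolute error is taken; exact ties are broken uniformly at
random with a seeded generator.  Pain subjects are visited in ascending
subject-id order (the greedy procedure is order-dependent), each candidate
can be used at most once, and pain subjects with no candidate are reported
unmatched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import bf_from_r, fisher_z_diff, partial_corr

__all__ = ["MatchResult", "match_ratings", "subject_condition_means", "matched_contrast"]


@dataclass
class MatchResult:
    """Injective pairing of pain subjects with other-modality subjects."""

    pairs: list[tuple[str, str]]
    errors: list[tuple[float, float]]        # (|Δhigh|, |Δlow|) per pair
    unmatched: list[str]
    modality_other: str = "other"
    tol: float = 0.5

    def __post_init__(self) -> None:
        for eh, el in self.errors:
            if eh > self.tol + 1e-12 or el > self.tol + 1e-12:
                raise ValueError("matching error exceeds tolerance")
        left = [a for a, _ in self.pairs]
        right = [b for _, b in self.pairs]
        if len(set(left)) != len(left) or len(set(right)) != len(right):
            raise ValueError("a subject appears in two pairs")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(a, b, eh, el) for (a, b), (eh, el) in zip(self.pairs, self.errors)],
            columns=["pain_id", "other_id", "err_high", "err_low"],
        )


def subject_condition_means(
    ratings: pd.DataFrame, modality: str, high: str = "high", low: str = "low"
) -> pd.DataFrame:
    """Per-subject (high, low) mean ratings for one modality."""
    sub = ratings[ratings["modality"] == modality]
    piv = sub.pivot_table(index="subject_id", columns="condition", values="rating")
    out = piv[[high, low]].rename(columns={high: "high", low: "low"}).reset_index()
    return out.sort_values("subject_id").reset_index(drop=True)


def match_ratings(
    pain_means: pd.DataFrame,
    other_means: pd.DataFrame,
    tol: float = 0.5,
    seed: int | None = 0,
    modality_other: str = "other",
) -> MatchResult:
    """Greedily pair pain subjects with rating-matched other-modality subjects.

    Both inputs need columns ``subject_id``, ``high``, ``low`` (per-subject
    mean ratings).  A pain subject with means (h, l) can be paired with any
    unused other subject whose means lie within ``tol`` of h and l
    respectively; among those, the candidates with the smallest
    |Δhigh| + |Δlow| are kept and one is chosen (seeded-uniformly on ties).
    """
    if tol <= 0:
        raise ValueError("tolerance must be positive")
    if len(pain_means) == 0 or len(other_means) == 0:
        raise ValueError("matching inputs must be nonempty")
    rng = np.random.default_rng(seed)
    other = other_means.sort_values("subject_id").reset_index(drop=True)
    o_ids = other["subject_id"].to_numpy()
    o_high = other["high"].to_numpy(dtype=float)
    o_low = other["low"].to_numpy(dtype=float)
    used = np.zeros(len(other), dtype=bool)
    pairs, errors, unmatched = [], [], []
    for _, row in pain_means.sort_values("subject_id").iterrows():
        eh = np.abs(o_high - float(row["high"]))
        el = np.abs(o_low - float(row["low"]))
        ok = (eh <= tol) & (el <= tol) & ~used
        if not ok.any():
            unmatched.append(row["subject_id"])
            continue
        total = eh + el
        best = np.min(total[ok])
        cand = np.flatnonzero(ok & (total <= best + 1e-12))
        pick = cand[0] if cand.size == 1 else rng.choice(cand)
        used[pick] = True
        pairs.append((row["subject_id"], o_ids[pick]))
        errors.append((float(eh[pick]), float(el[pick])))
    return MatchResult(
        pairs=pairs, errors=errors, unmatched=unmatched,
        modality_other=modality_other, tol=tol,
    )


def matched_contrast(
    match: MatchResult,
    pain_data: pd.DataFrame,
    other_data: pd.DataFrame,
    min_pairs: int = 10,
) -> dict:
    """ROI partial-correlation analysis within each matched subgroup.

    ``pain_data``/``other_data`` need columns ``subject_id``, ``dvar`` (ROI
    ΔSD), ``damp`` (ROI ΔAmplitude) and ``score`` (discriminability).  The
    partial correlation of dvar with score controlling damp is computed in
    the matched pain subset and the matched other-modality subset, with JZS
    Bayes factors, and the two coefficients are compared with the
    independent-groups Fisher-z test (the subgroups are disjoint subject
    sets).
    """
    if len(match.pairs) == 0:
        raise ValueError("empty match result")
    if len(match.pairs) < min_pairs:
        raise ValueError(f"need at least {min_pairs} matched pairs, got {len(match.pairs)}")

    def roi_partial(data: pd.DataFrame, ids: list[str]):
        sub = data.set_index("subject_id").loc[ids]
        r, p = partial_corr(
            sub["dvar"].to_numpy(), sub["score"].to_numpy(), sub["damp"].to_numpy()
        )
        return r, p, bf_from_r(r, len(ids))

    pain_ids = [a for a, _ in match.pairs]
    other_ids = [b for _, b in match.pairs]
    r_p, p_p, bf_p = roi_partial(pain_data, pain_ids)
    r_o, p_o, bf_o = roi_partial(other_data, other_ids)
    z, p_diff = fisher_z_diff(r_p, len(pain_ids), r_o, len(other_ids))
    return {
        "n_pairs": len(match.pairs),
        "r_pain": r_p, "p_pain": p_p, "bf_pain": bf_p,
        "r_other": r_o, "p_other": p_o, "bf_other": bf_o,
        "z_diff": z, "p_diff": p_diff,
    }
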