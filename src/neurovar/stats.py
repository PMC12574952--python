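"""Point-by-point between-subject inference linking tracks to discriminability.

Per-time-point Pearson/Spearman (or partial) correlations across subjects,
Benjamini-Hochberg FDR over the post-stimulus window, JZS Bayes factors with
Kass-Raftery evidence bins, Steiger's z for dependent correlations, and the
intra-individual (single-trial, Fisher-z + one-sample t) analysis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats
from statsmodels.stats.multitest import multipletests

from .variability import MetricTrack, TrackSet

__all__ = [
    "AssociationTrack",
    "pearson",
    "spearman",
    "partial_corr",
    "fdr_bh",
    "bf_jzs_corr",
    "bf_from_r",
    "bf_category",
    "steiger_z",
    "fisher_z_diff",
    "track_association",
    "intra_individual",
    "sensitivity_analysis",
    "association_frame",
]

logger = logging.getLogger(__name__)

JZS_RSCALE = math.sqrt(2) / 2  # unit-information scale of the g-prior


@dataclass
class AssociationTrack:
    """Per-time-point correlation results across subjects."""

    times: np.ndarray
    r: np.ndarray
    p: np.ndarray
    q_sig: np.ndarray                  # BH-FDR flags (post-stimulus family)
    bf: np.ndarray | None
    kind: str                          # pearson / spearman / partial
    n: int
    covariate_name: str | None = None

    def __post_init__(self) -> None:
        if not (self.times.size == self.r.size == self.p.size == self.q_sig.size):
            raise ValueError("track fields must have equal length")
        if np.any(np.abs(self.r[np.isfinite(self.r)]) > 1 + 1e-12):
            raise ValueError("|r| must be <= 1")


def _validate_xy(x, y, n_min: int):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < n_min:
        raise ValueError(f"need at least {n_min} observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    return x, y


def pearson(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-tailed t-distributed p."""
    x, y = _validate_xy(x, y, 3)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Rank correlation with a two-tailed p (used for small-N patient data)."""
    x, y = _validate_xy(x, y, 3)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def partial_corr(x, y, z) -> tuple[float, float]:
    """Correlation of x and y after removing the linear effect of z.

    Equals the correlation of the residuals of x~z and y~z; two-tailed p
    from a t statistic with n-3 degrees of freedom.
    """
    x, y = _validate_xy(x, y, 4)
    z = np.asarray(z, dtype=float)
    if z.size != x.size:
        raise ValueError("z must match x and y in length")
    if z.std() == 0:
        raise ValueError("covariate has zero variance")
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    denom_sq = (1 - rxz**2) * (1 - ryz**2)
    if denom_sq < 1e-24:
        # x or y is (numerically) collinear with z: nothing is left to
        # correlate after residualization
        return 0.0, 1.0
    r = (rxy - rxz * ryz) / math.sqrt(denom_sq)
    df = x.size - 3
    p = _r_to_p(np.array([r]), df)[0]
    return float(r), float(p)


def _r_to_p(r: np.ndarray, df: int) -> np.ndarray:
    """Two-tailed p for correlation(s) r on df degrees of freedom."""
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1 - r * r, np.finfo(float).tiny))
    return 2 * stats.t.sf(np.abs(t), df)


def fdr_bh(p, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags for a family of p values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    return reject


# ---------------------------------------------------------------------------
# JZS Bayes factor for a correlation
# ---------------------------------------------------------------------------

def _log_jzs_integrand(u: np.ndarray, r2: float, n: int, rscale: float) -> np.ndarray:
    """Log integrand of the one-predictor JZS regression BF after g = u/(1-u).

    Marginal likelihood ratio under a Zellner-Siow (inverse-gamma mixed
    g-) prior with scale ``rscale``; includes the Jacobian of the
    substitution mapping (0, inf) to (0, 1).
    """
    u = np.asarray(u, dtype=float)
    g = u / (1 - u)
    b = n * rscale**2 / 2.0
    with np.errstate(divide="ignore"):
        out = (
            0.5 * (n - 2) * np.log1p(g)
            - 0.5 * (n - 1) * np.log1p((1 - r2) * g)
            + 0.5 * math.log(b)
            - 0.5 * math.log(math.pi)
            - 1.5 * np.log(g)
            - b / g
            - 2.0 * np.log1p(-u)
        )
    return out


def bf_from_r(r: float, n: int, rscale: float = JZS_RSCALE) -> float:
    """JZS Bayes factor (alternative/null) for an observed correlation r at size n.

    Evaluated by adaptive quadrature of the g-prior integral; the integrand
    is computed in log space with a max-shift so large n |r| cannot
    overflow.  Raises if the quadrature does not converge.
    """
    if n < 5:
        raise ValueError("Bayes factor needs n >= 5")
    if not np.isfinite(r) or abs(r) >= 1:
        raise ValueError("r must lie strictly inside (-1, 1)")
    r2 = r * r
    grid = np.linspace(1e-9, 1 - 1e-9, 1024)
    lf = _log_jzs_integrand(grid, r2, n, rscale)
    shift = float(np.max(lf))
    val, err = integrate.quad(
        lambda u: math.exp(_log_jzs_integrand(np.array([u]), r2, n, rscale)[0] - shift),
        0.0,
        1.0,
        limit=200,
    )
    if not np.isfinite(val) or val <= 0 or err > 1e-4 * max(val, 1e-300):
        raise RuntimeError(
            f"JZS quadrature failed: integral={val!r}, abserr={err!r}, r={r}, n={n}"
        )
    return math.exp(shift + math.log(val))


def bf_jzs_corr(x, y, rscale: float = JZS_RSCALE) -> float:
    """JZS Bayes factor for the correlation between two samples."""
    x, y = _validate_xy(x, y, 5)
    r = np.corrcoef(x, y)[0, 1]
    return bf_from_r(float(r), x.size, rscale)


_BF_BINS = (
    (1.0, 3.3, "barely worth mentioning"),
    (3.3, 10.0, "substantial"),
    (10.0, 100.0, "strong"),
    (100.0, math.inf, "decisive"),
)


@dataclass
class BFCategory:
    label: str
    favors: str           # "alternative" or "null"
    evidence: float       # bf itself, or 1/bf when the null is favored


def bf_category(bf: float) -> BFCategory:
    """Kass-Raftery evidence bin for a Bayes factor.

    Boundaries belong to the upper bin (3.3 is "substantial").  Values
    below 1 favor the null; the reciprocal is binned and reported.
    """
    if not np.isfinite(bf) or bf <= 0:
        raise ValueError("Bayes factor must be positive")
    favors, value = ("alternative", bf) if bf >= 1 else ("null", 1.0 / bf)
    for lo, hi, label in _BF_BINS:
        if lo <= value < hi:
            return BFCategory(label=label, favors=favors, evidence=value)
    return BFCategory(label="decisive", favors=favors, evidence=value)


# ---------------------------------------------------------------------------
# Comparing correlations
# ---------------------------------------------------------------------------

def steiger_z(r_jk: float, r_jh: float, r_kh: float, n: int) -> tuple[float, float]:
    """Two-tailed test of two dependent correlations sharing variable j.

    Fisher-z form with the dependent-correlation covariance term (mean-r
    simplification).  ``r_jk`` and ``r_jh`` are the correlations being
    compared; ``r_kh`` is the correlation between the two non-shared
    variables.
    """
    for r in (r_jk, r_jh, r_kh):
        if abs(r) >= 1:
            raise ValueError("|r| = 1 input; test undefined")
    if n < 10:
        raise ValueError("Steiger's z needs n >= 10")
    z1, z2 = math.atanh(r_jk), math.atanh(r_jh)
    rm2 = (r_jk**2 + r_jh**2) / 2.0
    f = min((1 - r_kh) / (2 * (1 - rm2)), 1.0)
    h = (1 - f * rm2) / (1 - rm2)
    z = (z1 - z2) * math.sqrt((n - 3) / (2 * (1 - r_kh) * h))
    p = 2 * stats.norm.sf(abs(z))
    return float(z), float(p)


def fisher_z_diff(r1: float, n1: int, r2: float, n2: int) -> tuple[float, float]:
    """Two-tailed independent-groups test of two correlations (Fisher z).

    Used when the two correlations come from disjoint subject sets, e.g.
    rating-matched pain and non-pain subgroups.
    """
    for r in (r1, r2):
        if abs(r) >= 1:
            raise ValueError("|r| = 1 input; test undefined")
    if min(n1, n2) < 4:
        raise ValueError("need at least 4 subjects per group")
    z = (math.atanh(r1) - math.atanh(r2)) / math.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    return float(z), float(2 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# Track-level analyses
# ---------------------------------------------------------------------------

def _stack_tracks(tracks: list[MetricTrack]):
    sids = [t.subject_id for t in tracks]
    times = tracks[0].times
    for t in tracks[1:]:
        if t.times.size != times.size or not np.allclose(t.times, times):
            raise ValueError("tracks differ in window geometry")
    return sids, times, np.vstack([t.values for t in tracks])


def _align_scores(scores, sids: list[str]) -> np.ndarray:
    if isinstance(scores, pd.DataFrame):
        s = scores.set_index("subject_id")["value"]
    elif isinstance(scores, pd.Series):
        s = scores
    else:
        arr = np.asarray(scores, dtype=float)
        if arr.size != len(sids):
            raise ValueError("scores length does not match subjects")
        return arr
    missing = [sid for sid in sids if sid not in s.index]
    if missing:
        raise ValueError(f"scores missing subjects: {missing[:5]}")
    return s.loc[sids].to_numpy(dtype=float)


def _columnwise_r(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((Xc * Xc).sum(axis=0) * (yc * yc).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc * yc[:, None]).sum(axis=0) / denom
    return np.clip(r, -1.0, 1.0)


def track_association(
    tracks: list[MetricTrack],
    scores,
    covariate_tracks: list[MetricTrack] | None = None,
    method: str = "pearson",
    alpha: float = 0.05,
    compute_bf: bool = True,
    covariate_name: str | None = None,
) -> AssociationTrack:
    """Correlate a per-subject track with discriminability at every time point.

    ``tracks`` holds one (typically high-low difference) MetricTrack per
    subject; ``scores`` the per-subject discriminability values.  When
    ``covariate_tracks`` is given, the partial correlation controlling for
    the covariate at the same time point is computed instead.  FDR (BH) runs
    over the post-stimulus (t >= 0) window centers only; Bayes factors are
    evaluated per point from the observed (partial) r.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method {method!r}")
    sids, times, X = _stack_tracks(tracks)
    y = _align_scores(scores, sids)
    n = len(sids)
    if covariate_tracks is not None:
        csids, ctimes, Z = _stack_tracks(covariate_tracks)
        if csids != sids:
            raise ValueError("covariate tracks cover different subjects")
        if ctimes.size != times.size or not np.allclose(ctimes, times):
            raise ValueError("covariate tracks differ in geometry")
        kind = "partial"
        df = n - 3
    else:
        kind = method
        df = n - 2
    if method == "spearman":
        X = stats.rankdata(X, axis=0)
        y = stats.rankdata(y)
        if covariate_tracks is not None:
            Z = stats.rankdata(Z, axis=0)
    r_xy = _columnwise_r(X, y)
    if covariate_tracks is not None:
        r_xz = np.array(
            [_columnwise_r(X[:, [j]], Z[:, j])[0] for j in range(X.shape[1])]
        )
        r_yz = _columnwise_r(Z, y)
        denom_sq = (1 - r_xz**2) * (1 - r_yz**2)
        degenerate = denom_sq < 1e-24
        r = np.where(
            degenerate,
            0.0,
            np.clip((r_xy - r_xz * r_yz) / np.sqrt(np.maximum(denom_sq, 1e-300)), -1, 1),
        )
    else:
        r = r_xy
    p = _r_to_p(r, df)
    post = times >= 0
    q_sig = np.zeros(times.size, dtype=bool)
    q_sig[post] = fdr_bh(p[post], alpha=alpha)
    bf = None
    if compute_bf:
        bf = np.array([bf_from_r(float(v), n) for v in np.clip(r, -1 + 1e-12, 1 - 1e-12)])
    return AssociationTrack(
        times=times, r=r, p=p, q_sig=q_sig, bf=bf, kind=kind, n=n,
        covariate_name=covariate_name if covariate_tracks is not None else None,
    )


@dataclass
class IntraIndividualResult:
    """Group-level one-sample t of Fisher-z single-trial correlations."""

    times: np.ndarray
    t: np.ndarray
    p: np.ndarray
    q_sig: np.ndarray
    mean_z: np.ndarray
    n_subjects: int
    excluded: list[str] = field(default_factory=list)


def _trial_ratings_for(trackset: TrackSet, ratings: pd.DataFrame) -> np.ndarray:
    """Per-trial rating vector aligned with a TrackSet's trial rows."""
    sub = ratings[ratings["subject_id"] == trackset.subject_id]
    out = np.full(trackset.condition.size, np.nan)
    for cond in np.unique(trackset.condition):
        rows = np.flatnonzero(trackset.condition == cond)
        r = sub[sub["condition"] == cond].sort_values("trial_index")["rating"].to_numpy()
        if r.size != rows.size:
            raise ValueError(
                f"subject {trackset.subject_id}: {rows.size} trials in tracks but "
                f"{r.size} ratings for condition {cond!r}"
            )
        out[rows] = r
    return out


def intra_individual(
    tracksets: list[TrackSet], ratings: pd.DataFrame, alpha: float = 0.05
) -> IntraIndividualResult:
    """Single-trial metric-rating correlation per subject, tested at the group level.

    Per subject and time point, the single-trial metric values are
    correlated with the single-trial ratings (both conditions pooled); the
    Fisher-z transformed coefficients are compared against zero with a
    one-sample t test per time point, FDR-corrected over the post-stimulus
    window.  Subjects with zero rating variance are excluded and logged.
    """
    times = tracksets[0].times
    zs, excluded = [], []
    for ts in tracksets:
        if ts.condition.size < 5:
            raise ValueError(f"subject {ts.subject_id}: need >= 5 trials")
        y = _trial_ratings_for(ts, ratings)
        if np.std(y) == 0:
            excluded.append(ts.subject_id)
            logger.warning("subject %s excluded: zero rating variance", ts.subject_id)
            continue
        r = _columnwise_r(ts.values, y)
        zs.append(np.arctanh(np.clip(r, -1 + 1e-12, 1 - 1e-12)))
    if len(zs) < 3:
        raise ValueError("need at least 3 subjects with rating variance")
    Z = np.vstack(zs)
    tstat, p = stats.ttest_1samp(Z, 0.0, axis=0)
    post = times >= 0
    q_sig = np.zeros(times.size, dtype=bool)
    q_sig[post] = fdr_bh(p[post], alpha=alpha)
    return IntraIndividualResult(
        times=times, t=tstat, p=p, q_sig=q_sig, mean_z=Z.mean(axis=0),
        n_subjects=Z.shape[0], excluded=excluded,
    )


def sensitivity_analysis(
    var_tracksets: list[TrackSet],
    amp_tracksets: list[TrackSet],
    ratings: pd.DataFrame,
    alpha: float = 0.05,
    compute_bf: bool = True,
) -> AssociationTrack:
    """Between-subject sensitivity analysis on condition-pooled data.

    The per-subject temporal-SD track averaged over all trials regardless of
    intensity is partially correlated with the subject's mean rating
    ([high + low]/2), controlling for the pooled mean-amplitude track — the
    interindividual sensory-sensitivity analysis.
    """
    if len(var_tracksets) < 2:
        raise ValueError("sensitivity analysis needs more than one subject")

    def pooled(ts: TrackSet) -> MetricTrack:
        return MetricTrack(
            subject_id=ts.subject_id, metric=ts.metric, condition="pooled",
            window_ms=ts.window_ms, step_ms=ts.step_ms, times=ts.times,
            values=ts.values.mean(axis=0),
        )

    var_tracks = [pooled(ts) for ts in var_tracksets]
    amp_tracks = [pooled(ts) for ts in amp_tracksets]
    cond_means = ratings.groupby(["subject_id", "condition"])["rating"].mean()
    mean_rating = cond_means.groupby("subject_id").mean().rename("value").reset_index()
    return track_association(
        var_tracks, mean_rating, covariate_tracks=amp_tracks,
        alpha=alpha, compute_bf=compute_bf, covariate_name="pooled_amplitude",
    )


def association_frame(assoc: AssociationTrack) -> pd.DataFrame:
    """Long-format TSV-ready view of an AssociationTrack."""
    out = pd.DataFrame(
        {"time_ms": assoc.times, "r": assoc.r, "p": assoc.p, "fdr_sig": assoc.q_sig}
    )
    if assoc.bf is not None:
        out["bf"] = assoc.bf
    return out
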