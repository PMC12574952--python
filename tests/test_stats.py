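import math

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from neurovar.variability import MetricTrack, TrackSet
from neurovar.stats import (
    bf_category,
    bf_from_r,
    bf_jzs_corr,
    fdr_bh,
    fisher_z_diff,
    intra_individual,
    partial_corr,
    pearson,
    sensitivity_analysis,
    spearman,
    steiger_z,
    track_association,
)
from neurovar.simulate import GeneratorConfig, generate_cohort
from neurovar.cohort import cohort_tracksets, roi_partial_analysis


class TestCorrelations:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        r, p = pearson(x, x)
        assert r == pytest.approx(1.0)
        assert p < 1e-10

    def test_independent_permutation_is_null(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(1000)
        y = rng.permutation(x)
        r, _ = pearson(x, y)
        assert abs(r) < 0.1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson(np.ones(10), np.arange(10.0))

    def test_spearman_monotone_invariance(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(50), rng.standard_normal(50)
        r1, _ = spearman(x, y)
        r2, _ = spearman(np.exp(3 * x), y)
        assert r1 == pytest.approx(r2, abs=1e-12)


class TestPartialCorrelation:
    def test_orthogonal_covariate_leaves_r_unchanged(self):
        rng = np.random.default_rng(2)
        x, y = rng.standard_normal(100), rng.standard_normal(100)
        z = rng.standard_normal(100)
        # make z orthogonal to span{1, x, y} (joint projection, not sequential)
        basis = np.column_stack([np.ones(100), x, y])
        z = z - basis @ np.linalg.lstsq(basis, z, rcond=None)[0]
        r_simple, _ = pearson(x, y)
        r_part, _ = partial_corr(x, y, z)
        assert r_part == pytest.approx(r_simple, abs=1e-12)

    def test_covariate_equal_to_y_gives_zero(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        r, p = partial_corr(x, y, y)
        assert r == 0.0 and p == 1.0

    def test_matches_residualization_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            x, y, z = rng.standard_normal((3, 50))

            def residual(v, c):
                c1 = np.column_stack([np.ones(c.size), c])
                beta, *_ = np.linalg.lstsq(c1, v, rcond=None)
                return v - c1 @ beta

            expected = np.corrcoef(residual(x, z), residual(y, z))[0, 1]
            r, _ = partial_corr(x, y, z)
            assert r == pytest.approx(expected, abs=1e-10)

    def test_agrees_with_pingouin(self):
        rng = np.random.default_rng(5)
        x, y, z = rng.standard_normal((3, 40))
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pg.partial_corr(df, x="x", y="y", covar="z")
        r, p = partial_corr(x, y, z)
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_zero_variance_covariate_rejected(self):
        with pytest.raises(ValueError):
            partial_corr(np.arange(10.0), np.arange(10.0), np.ones(10))


def fdr_step_up_oracle(p, alpha):
    """Brute-force largest-k BH definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * alpha / m:
            k_max = k
    out = np.zeros(m, dtype=bool)
    out[order[:k_max]] = True
    return out


class TestFdrBH:
    def test_all_small_p_significant(self):
        assert fdr_bh([0.01, 0.02, 0.03, 0.04], alpha=0.05).all()

    def test_all_ones_none_significant(self):
        assert not fdr_bh(np.ones(10)).any()

    def test_single_p_threshold(self):
        assert fdr_bh([0.04]).all()
        assert not fdr_bh([0.06]).any()

    @given(
        hnp.arrays(np.float64, st.integers(1, 60),
                   elements=st.floats(0, 1, allow_nan=False))
    )
    def test_matches_step_up_oracle(self, p):
        np.testing.assert_array_equal(fdr_bh(p, 0.05), fdr_step_up_oracle(p, 0.05))

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])


def jzs_bf_grid_oracle(r, n, rscale=math.sqrt(2) / 2):
    """Independent fine-grid trapezoid integration of the g-prior integral."""
    g = np.exp(np.linspace(math.log(1e-8), math.log(1e8), 200_001))
    b = n * rscale**2 / 2.0
    logf = (
        0.5 * (n - 2) * np.log1p(g)
        - 0.5 * (n - 1) * np.log1p((1 - r * r) * g)
        + 0.5 * math.log(b)
        - 0.5 * math.log(math.pi)
        - 1.5 * np.log(g)
        - b / g
    )
    shift = logf.max()
    return math.exp(shift) * np.trapezoid(np.exp(logf - shift), g)


class TestJzsBayesFactor:
    def test_null_correlation_supports_null(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(50)
        y = rng.permutation(x)
        r = np.corrcoef(x, y)[0, 1]
        if abs(r) < 0.1:
            assert bf_jzs_corr(x, y) < 1.0

    def test_monotone_in_correlation_magnitude(self):
        bfs = [bf_from_r(r, 40) for r in (0.0, 0.2, 0.4, 0.6, 0.8)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    @pytest.mark.parametrize("r", [0.0, 0.3, 0.6, 0.9])
    @pytest.mark.parametrize("n", [10, 50, 200])
    def test_matches_grid_quadrature_oracle(self, r, n):
        assert bf_from_r(r, n) == pytest.approx(jzs_bf_grid_oracle(r, n), rel=0.01)

    def test_large_sample_strong_effect_does_not_overflow(self):
        assert np.isfinite(bf_from_r(0.95, 500))
        assert bf_from_r(0.95, 500) > 1e10

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bf_from_r(1.0, 50)
        with pytest.raises(ValueError):
            bf_from_r(0.5, 4)


class TestBfCategory:
    def test_null_favoring_reports_reciprocal(self):
        cat = bf_category(0.2)
        assert cat.favors == "null"
        assert cat.evidence == pytest.approx(5.0)
        assert cat.label == "substantial"

    def test_strong_evidence_bin(self):
        assert bf_category(56.16).label == "strong"

    def test_boundary_goes_to_upper_bin(self):
        assert bf_category(3.3).label == "substantial"
        assert bf_category(10.0).label == "strong"

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            bf_category(0.0)


class TestSteigerZ:
    def test_equal_correlations_give_zero(self):
        z, p = steiger_z(0.4, 0.4, 0.3, 100)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_monotone_in_gap(self):
        zs = [abs(steiger_z(0.1 + d, 0.1, 0.3, 100)[0]) for d in (0.1, 0.2, 0.3, 0.4)]
        assert all(b > a for a, b in zip(zs, zs[1:]))

    def test_degenerate_correlation_rejected(self):
        with pytest.raises(ValueError):
            steiger_z(1.0, 0.5, 0.3, 100)

    def test_agrees_with_bootstrap_of_correlation_difference(self):
        """Rejection decisions match a percentile bootstrap on synthetic triples."""
        rng = np.random.default_rng(7)
        n, n_boot, runs, agree = 200, 1000, 100, 0
        for run in range(runs):
            effect = 0.0 if run % 2 == 0 else 0.45
            base = rng.standard_normal(n)
            j = base + 0.8 * rng.standard_normal(n)
            k = effect * base + rng.standard_normal(n)
            h = rng.standard_normal(n)
            r_jk = np.corrcoef(j, k)[0, 1]
            r_jh = np.corrcoef(j, h)[0, 1]
            r_kh = np.corrcoef(k, h)[0, 1]
            _, p = steiger_z(r_jk, r_jh, r_kh, n)
            idx = rng.integers(0, n, size=(n_boot, n))
            J, K, H = j[idx], k[idx], h[idx]

            def rowwise_r(A, B):
                A = A - A.mean(axis=1, keepdims=True)
                B = B - B.mean(axis=1, keepdims=True)
                return (A * B).sum(1) / np.sqrt((A * A).sum(1) * (B * B).sum(1))

            d = rowwise_r(J, K) - rowwise_r(J, H)
            lo, hi = np.percentile(d, [2.5, 97.5])
            boot_reject = not (lo <= 0 <= hi)
            agree += (p < 0.05) == boot_reject
        assert agree >= 0.95 * runs


class TestFisherZDiff:
    def test_equal_correlations(self):
        z, p = fisher_z_diff(0.5, 100, 0.5, 80)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_detects_large_difference(self):
        _, p = fisher_z_diff(0.7, 200, 0.0, 200)
        assert p < 1e-6


def _toy_tracks(values, times=None):
    times = np.arange(-50.0, 200.0, 10.0) if times is None else times
    return [
        MetricTrack(f"S{i:03d}", "tempSD", "diff", 100, 10, times, v)
        for i, v in enumerate(values)
    ]


class TestTrackAssociation:
    def test_recovers_planted_correlation_at_roi(self, planted_tracks):
        """ROI partial r approaches the planted rho = 0.5 on the full cohort."""
        var_d, amp_d, scores, truth = planted_tracks
        res = roi_partial_analysis(var_d, amp_d, scores)
        assert abs(res.r - 0.5) < 0.15
        assert res.p < 1e-4

    def test_planted_effect_yields_fdr_cluster(self, planted_tracks):
        var_d, amp_d, scores, _ = planted_tracks
        assoc = track_association(
            var_d, scores, covariate_tracks=amp_d, compute_bf=False
        )
        sig_times = assoc.times[assoc.q_sig]
        assert sig_times.size > 50
        assert (sig_times > 100).any() and (sig_times < 600).any()
        assert not assoc.q_sig[assoc.times < 0].any()

    def test_shuffled_scores_rarely_significant(self, planted_tracks):
        var_d, amp_d, scores, _ = planted_tracks
        rng = np.random.default_rng(8)
        n_sig = 0
        for _ in range(20):
            shuffled = scores.copy()
            shuffled["value"] = rng.permutation(shuffled["value"].to_numpy())
            assoc = track_association(
                var_d, shuffled, covariate_tracks=amp_d, compute_bf=False
            )
            n_sig += assoc.q_sig.any()
        assert n_sig <= 2

    def test_covariate_equal_to_track_gives_zero_partial(self):
        rng = np.random.default_rng(9)
        tracks = _toy_tracks(rng.standard_normal((20, 25)))
        scores = pd.DataFrame(
            {"subject_id": [t.subject_id for t in tracks],
             "value": rng.standard_normal(20)}
        )
        assoc = track_association(
            tracks, scores, covariate_tracks=tracks, compute_bf=False
        )
        np.testing.assert_allclose(assoc.r, 0.0, atol=1e-12)

    def test_subject_mismatch_rejected(self):
        rng = np.random.default_rng(10)
        tracks = _toy_tracks(rng.standard_normal((8, 25)))
        scores = pd.DataFrame({"subject_id": ["X"] * 8, "value": np.arange(8.0)})
        with pytest.raises(ValueError, match="missing subjects"):
            track_association(tracks, scores, compute_bf=False)


def _intra_dataset(rng, coupled: bool, n_sub=25, n_tr=40):
    times = np.arange(-45.0, 150.0, 10.0)
    j0 = 12  # effect window index (positive time)
    tracksets, rows = [], []
    for i in range(n_sub):
        sid = f"S{i:03d}"
        vals = rng.standard_normal((n_tr, times.size))
        cond = np.array(["low", "high"] * (n_tr // 2), dtype=object)
        ratings = 5 + (1.2 * vals[:, j0] if coupled else 0.0) + 0.8 * rng.standard_normal(n_tr)
        ratings = np.clip(ratings, 0, 10)
        counters = {"low": 0, "high": 0}
        for k in range(n_tr):
            rows.append((sid, "pain", cond[k], counters[cond[k]], ratings[k]))
            counters[cond[k]] += 1
        tracksets.append(
            TrackSet(sid, "tempSD", 100, 10, times, vals, cond)
        )
    df = pd.DataFrame(
        rows, columns=["subject_id", "modality", "condition", "trial_index", "rating"]
    )
    return tracksets, df, times, j0


class TestIntraIndividual:
    def test_metric_coupled_ratings_detected(self):
        rng = np.random.default_rng(11)
        tracksets, ratings, times, j0 = _intra_dataset(rng, coupled=True)
        res = intra_individual(tracksets, ratings)
        assert res.q_sig[j0]
        assert res.t[j0] > 0

    def test_independent_ratings_stay_null(self):
        rng = np.random.default_rng(12)
        n_sig = 0
        for _ in range(10):
            tracksets, ratings, _, _ = _intra_dataset(rng, coupled=False, n_sub=15)
            res = intra_individual(tracksets, ratings)
            n_sig += res.q_sig.any()
        assert n_sig <= 1

    def test_zero_variance_subject_excluded(self):
        rng = np.random.default_rng(13)
        tracksets, ratings, _, _ = _intra_dataset(rng, coupled=True, n_sub=10)
        flat = ratings["subject_id"] == "S000"
        ratings.loc[flat, "rating"] = 5.0
        res = intra_individual(tracksets, ratings)
        assert res.excluded == ["S000"]
        assert res.n_subjects == 9


class TestSensitivityAnalysis:
    @staticmethod
    def _cohort(**kw):
        cfg = GeneratorConfig(n_subjects=50, n_trials_per_condition=8, seed=14, **kw)
        cohort, ratings, _ = generate_cohort(cfg)
        var_ts = cohort_tracksets(cohort, "tempSD", step_ms=10.0)
        amp_ts = cohort_tracksets(cohort, "amplitude", step_ms=10.0)
        return var_ts, amp_ts, ratings

    def test_uncoupled_generator_stays_null(self):
        # planted discriminability correlations off: otherwise Δσ ~ D leaks
        # into the condition-pooled means as a spurious sensitivity coupling
        var_ts, amp_ts, ratings = self._cohort(
            rho_var_discrim=0.0, rho_amp_discrim=0.0
        )
        assoc = sensitivity_analysis(var_ts, amp_ts, ratings, compute_bf=False)
        assert assoc.q_sig.sum() == 0

    def test_planted_base_rating_coupling_detected(self):
        var_ts, amp_ts, ratings = self._cohort(sigma_base_sd=0.4, rho_base_rating=0.9)
        assoc = sensitivity_analysis(var_ts, amp_ts, ratings, compute_bf=False)
        assert assoc.q_sig.sum() > 10

    def test_single_subject_rejected(self):
        var_ts, amp_ts, ratings = self._cohort()
        with pytest.raises(ValueError):
            sensitivity_analysis(var_ts[:1], amp_ts[:1], ratings)
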