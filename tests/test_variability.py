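import math
from itertools import permutations

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from neurovar.simulate import GeneratorConfig, erp_template
from neurovar.variability import (
    CV_SENTINEL,
    MetricTrack,
    coefficient_of_variation,
    condition_average,
    diff_track,
    induced_epochs,
    peak_roi,
    permutation_entropy,
    roi_value,
    sliding_track,
    temporal_sd,
    _ordinal_pattern_codes,
)

from conftest import make_epochs

finite_vectors = hnp.arrays(
    np.float64,
    st.integers(5, 40),
    elements=st.floats(-1e6, 1e6, allow_nan=False, width=64),
)


def two_pass_sd_oracle(x):
    """Independent reference: explicit two-pass population SD."""
    x = np.asarray(x, dtype=float)
    mu = sum(x) / len(x)
    return math.sqrt(sum((v - mu) ** 2 for v in x) / len(x))


def pe_oracle(x, m, tau):
    """Independent reference: exhaustive ordinal-pattern enumeration."""
    x = list(x)
    n_vec = len(x) - (m - 1) * tau
    counts = {}
    for i in range(n_vec):
        vec = [x[i + j * tau] for j in range(m)]
        # rank pattern with order-of-appearance tie-breaks
        order = sorted(range(m), key=lambda j: (vec[j], j))
        counts[tuple(order)] = counts.get(tuple(order), 0) + 1
    ps = [c / n_vec for c in counts.values()]
    return -sum(p * math.log(p) for p in ps)


class TestTemporalSD:
    def test_printed_formula_example(self):
        assert temporal_sd([0, 0, 0, 4]) == pytest.approx(math.sqrt(3), abs=1e-12)

    def test_constant_window_is_zero(self):
        assert temporal_sd(np.full(100, 2.7)) == pytest.approx(0.0, abs=1e-12)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            temporal_sd([1.0])

    @given(finite_vectors)
    def test_matches_two_pass_oracle(self, x):
        expected = two_pass_sd_oracle(x)
        # scale-aware tolerance: 1e-12 relative to the data magnitude
        tol = 1e-12 * max(1.0, float(np.max(np.abs(x))))
        assert abs(temporal_sd(x) - expected) <= tol

    @given(finite_vectors, st.floats(-100, 100, allow_nan=False))
    def test_homogeneity(self, x, a):
        assert temporal_sd(a * x) == pytest.approx(abs(a) * temporal_sd(x), rel=1e-9, abs=1e-9)


class TestPermutationEntropy:
    def test_embedding_count_for_standard_window(self):
        """A 100-point window with m=4, tau=1 yields exactly 97 vectors."""
        codes = _ordinal_pattern_codes(np.random.default_rng(0).standard_normal(100), 4, 1)
        assert codes.shape[-1] == 97

    def test_monotone_vector_has_zero_entropy(self):
        assert permutation_entropy(np.arange(50.0), m=4) == 0.0

    def test_small_vector_matches_enumeration(self):
        x = [3, 1, 2, 5, 4]
        assert permutation_entropy(x, m=3, tau=1) == pytest.approx(
            pe_oracle(x, 3, 1), abs=1e-12
        )

    @given(
        hnp.arrays(np.float64, st.integers(20, 60),
                   elements=st.floats(-100, 100, allow_nan=False)),
        st.integers(2, 4),
    )
    def test_matches_enumeration_oracle(self, x, m):
        assert permutation_entropy(x, m=m) == pytest.approx(pe_oracle(x, m, 1), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        assert permutation_entropy(np.exp(2 * x)) == pytest.approx(
            permutation_entropy(x), abs=1e-12
        )

    def test_bounded_and_saturates_for_iid_noise(self):
        rng = np.random.default_rng(4)
        pe = permutation_entropy(rng.standard_normal(10_000), m=4)
        assert 0 <= pe <= math.log(24) + 1e-12
        assert pe > 0.98 * math.log(24)

    def test_short_input_rejected(self):
        with pytest.raises(ValueError):
            permutation_entropy([1.0, 2.0], m=4)
        with pytest.raises(ValueError):
            permutation_entropy([1.0, 2.0, 3.0], m=1)


class TestCV:
    def test_zero_mean_gives_sentinel(self):
        assert coefficient_of_variation([-1.0, 1.0]) == CV_SENTINEL

    def test_constant_window(self):
        assert coefficient_of_variation([2.0, 2.0, 2.0, 2.0]) == 0.0

    def test_direct_evaluation(self):
        assert coefficient_of_variation([1.0, 3.0]) == pytest.approx(0.5, abs=1e-12)


class TestSlidingTrack:
    def test_constant_epoch_gives_zero_sd_track(self):
        e = make_epochs(np.full((2, 1500), 3.3))
        ts = sliding_track(e, "tempSD")
        np.testing.assert_allclose(ts.values, 0.0, atol=1e-6)

    def test_window_count_arithmetic(self):
        e = make_epochs(np.zeros((1, 1500)))
        ts = sliding_track(e, "tempSD", window_ms=100, step_ms=1)
        assert ts.times.size == 1401
        # centered timestamps: first window spans [-500, -401] ms
        assert ts.times[0] == pytest.approx((-500 - 401) / 2)

    def test_amplitude_track_peaks_near_template_peaks(self):
        cfg = GeneratorConfig()
        e = make_epochs(erp_template(cfg)[None, :])
        ts = sliding_track(e, "amplitude")
        assert abs(ts.times[np.argmax(ts.values[0])] - 400) <= 50
        assert abs(ts.times[np.argmin(ts.values[0])] - 200) <= 50

    def test_partition_consistency_with_scalar_metrics(self):
        """step=window tracks equal per-block scalar evaluations."""
        rng = np.random.default_rng(5)
        data = rng.standard_normal((2, 1500))
        e = make_epochs(data)
        for metric, fn in [
            ("tempSD", temporal_sd),
            ("PE", permutation_entropy),
            ("amplitude", np.mean),
            ("CV", coefficient_of_variation),
        ]:
            ts = sliding_track(e, metric, window_ms=100, step_ms=100)
            for k in range(2):
                blocks = [fn(data[k, i : i + 100]) for i in range(0, 1401, 100)]
                np.testing.assert_allclose(ts.values[k], blocks, rtol=1e-9, atol=1e-9)

    def test_pe_sliding_matches_scalar_path(self):
        rng = np.random.default_rng(6)
        data = rng.standard_normal((1, 300))
        e = make_epochs(data, t0=-100.0)
        ts = sliding_track(e, "PE", window_ms=100, step_ms=17)
        w = 100
        starts = np.arange(0, 300 - w + 1, 17)
        expected = [permutation_entropy(data[0, s : s + w], m=4) for s in starts]
        np.testing.assert_allclose(ts.values[0], expected, atol=1e-12)

    def test_unknown_metric_rejected(self):
        e = make_epochs(np.zeros((1, 1500)))
        with pytest.raises(ValueError, match="unknown metric"):
            sliding_track(e, "kurtosis")

    def test_trial_average_mode_one_row_per_condition(self):
        rng = np.random.default_rng(7)
        e = make_epochs(rng.standard_normal((4, 1500)),
                        condition=["low", "high", "low", "high"])
        ts = sliding_track(e, "tempSD", mode="trial-average", step_ms=50)
        assert ts.values.shape[0] == 2
        assert set(ts.condition) == {"low", "high"}


class TestConditionAverageAndDiff:
    def _tracks(self):
        rng = np.random.default_rng(8)
        e = make_epochs(rng.standard_normal((6, 1500)),
                        condition=["low"] * 3 + ["high"] * 3)
        return sliding_track(e, "tempSD", step_ms=10)

    def test_identical_conditions_give_zero_diff(self):
        ts = self._tracks()
        ts.values[3:] = ts.values[:3]
        d = diff_track(condition_average(ts, "high"), condition_average(ts, "low"))
        np.testing.assert_allclose(d.values, 0.0, atol=1e-12)
        assert d.condition == "diff"

    def test_single_trial_average_is_that_trial(self):
        rng = np.random.default_rng(9)
        e = make_epochs(rng.standard_normal((2, 1500)), condition=["low", "high"])
        ts = sliding_track(e, "tempSD", step_ms=10)
        avg = condition_average(ts, "high")
        np.testing.assert_array_equal(avg.values, ts.values[1])

    def test_geometry_mismatch_rejected(self):
        ts = self._tracks()
        a = condition_average(ts, "high")
        b = condition_average(ts, "low")
        b.times = b.times + 1.0
        with pytest.raises(ValueError):
            diff_track(a, b)


class TestInducedEpochs:
    def test_trial_average_is_zero(self):
        rng = np.random.default_rng(10)
        e = make_epochs(rng.standard_normal((6, 1500)),
                        condition=["low"] * 3 + ["high"] * 3)
        ind = induced_epochs(e)
        for cond in ("low", "high"):
            avg = ind.data[ind.condition == cond].mean(axis=0)
            np.testing.assert_allclose(avg, 0.0, atol=1e-9)

    def test_identical_trials_become_zero(self):
        row = np.random.default_rng(11).standard_normal(1500)
        e = make_epochs(np.vstack([row, row]), condition=["low", "low"])
        np.testing.assert_allclose(induced_epochs(e).data, 0.0, atol=1e-12)

    def test_single_trial_condition_rejected(self):
        e = make_epochs(np.zeros((3, 1500)), condition=["low", "low", "high"])
        with pytest.raises(ValueError, match="fewer than 2"):
            induced_epochs(e)

    def test_induced_data_retain_planted_variability_effect(self, small_cohort):
        """Removing the evoked average must not remove the induced ΔSD."""
        from neurovar.cohort import cohort_tracksets, delta_tracks, grand_average

        _, cohort, _, _ = small_cohort
        ind = [induced_epochs(e) for e in cohort]
        deltas = delta_tracks(cohort_tracksets(ind, "tempSD", step_ms=10.0))
        ga = grand_average(deltas)
        effect = (ga.times > 200) & (ga.times < 500)
        assert ga.values[effect].mean() > 0.1


class TestPeakRoi:
    def _track(self, values):
        values = np.asarray(values, dtype=float)
        times = np.linspace(-450, 950, values.size)
        return MetricTrack("S0", "tempSD", "diff", 100, 1, times, values)

    def test_interval_centered_on_known_peak(self):
        times = np.arange(-450.0, 950.0)
        values = np.exp(-0.5 * ((times - 300) / 40) ** 2)
        tr = MetricTrack("S0", "tempSD", "diff", 100, 1, times, values)
        lo, hi = peak_roi(tr, halfwidth_ms=10)
        assert (lo, hi) == (290.0, 310.0)
        # 21 window centers at 1 ms step
        assert np.sum((tr.times >= lo) & (tr.times <= hi)) == 21
        assert roi_value(tr, (lo, hi)) == pytest.approx(values.max(), rel=0.02)

    def test_trough_mode_for_pe(self):
        times = np.arange(-450.0, 950.0)
        values = -np.exp(-0.5 * ((times - 250) / 40) ** 2)
        tr = MetricTrack("S0", "PE", "diff", 100, 1, times, values)
        lo, hi = peak_roi(tr, halfwidth_ms=10, mode="min")
        assert (lo + hi) / 2 == 250.0

    def test_peak_search_ignores_prestimulus(self):
        times = np.arange(-450.0, 950.0)
        values = np.exp(-0.5 * ((times + 300) / 40) ** 2)  # peak before onset
        values += 0.5 * np.exp(-0.5 * ((times - 400) / 40) ** 2)
        tr = MetricTrack("S0", "tempSD", "diff", 100, 1, times, values)
        lo, hi = peak_roi(tr, halfwidth_ms=10)
        assert (lo + hi) / 2 == 400.0
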