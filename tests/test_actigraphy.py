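import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from actipain.actigraphy import (
    ActivityConfig,
    classify_windows,
    endurance_profile,
    median_intensity,
    normalize_counts,
    select_complete_days,
    summarize,
    time_active,
    window_means,
)
from actipain.synthdata import inject_nonwear

from conftest import make_series


# --- brute-force oracle: explicit loops over epochs and windows ------------

def brute_force_phenotypes(counts, device_max, n_days, threshold=2.5, window=5):
    """Naive recomputation of all three phenotypes by explicit iteration."""
    norm = [min(100.0, 100.0 * c / device_max) for c in counts]
    n_windows = len(norm) // window
    active = []
    for w in range(n_windows):
        mean = sum(norm[w * window : (w + 1) * window]) / window
        active.append(mean >= threshold)
    per_day = []
    wpd = 1440 // window
    for d in range(n_days):
        per_day.append(sum(active[d * wpd : (d + 1) * wpd]) * window)
    minutes = sum(per_day) / n_days
    active_epochs = []
    for w, a in enumerate(active):
        if a:
            active_epochs.extend(norm[w * window : (w + 1) * window])
    med = float(np.median(active_epochs)) if active_epochs else float("nan")
    imax = max(norm)
    bins = [0, 0, 0, 0, 0]
    for v in norm:
        if v == 0:
            bins[0] += 1
        elif imax and 100 * v / imax >= 75:
            bins[4] += 1
        elif imax and 100 * v / imax >= 50:
            bins[3] += 1
        elif imax and 100 * v / imax >= 25:
            bins[2] += 1
        else:
            bins[1] += 1
    return minutes, med, tuple(float(b) for b in bins)


def run_module(counts, device_max, n_days, threshold=2.5):
    series = normalize_counts(make_series(counts, device_max))
    config = ActivityConfig(analysis_days=n_days, inactive_threshold_pct=threshold)
    means = window_means(series)
    active = classify_windows(means, threshold)
    minutes = time_active(active, n_days)
    med, _ = median_intensity(series, active)
    bins = endurance_profile(series, config)
    return minutes, med, bins


class TestNormalization:
    def test_percentage_arithmetic(self):
        s = normalize_counts(make_series([250.0] * 1440, device_max=1000))
        assert s.counts[0] == 25.0

    def test_joint_rescaling_invariance(self):
        a = normalize_counts(make_series([30.0, 400.0] * 720, device_max=1000))
        b = normalize_counts(make_series([210.0, 2800.0] * 720, device_max=7000))
        np.testing.assert_allclose(a.counts, b.counts)

    def test_counts_above_max_clamped_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            s = normalize_counts(make_series([1500.0] + [0.0] * 1439, device_max=1000))
        assert s.counts[0] == 100.0
        assert "clamped" in caplog.text

    def test_nonpositive_max_rejected(self):
        with pytest.raises(ValueError):
            normalize_counts(make_series([1.0] * 1440, device_max=0))


class TestCompleteDays:
    def test_last_seven_of_fourteen_perfect_days(self):
        s = make_series(np.zeros(14 * 1440), start="2015-01-05")
        out = select_complete_days(s, 7)
        days = sorted(set(out.timestamps.date))
        assert [d.day for d in days] == list(range(12, 19))  # Jan 12..18

    def test_nonwear_gap_excludes_that_day_only(self):
        s = make_series(np.zeros(14 * 1440), start="2015-01-05")
        # 30-min removal on day 13 of wear (Jan 17)
        broken = inject_nonwear(s, [(12 * 1440 + 600, 30)])
        out = select_complete_days(broken, 7)
        days = sorted(d.day for d in set(out.timestamps.date))
        assert 17 not in days
        assert days == [11, 12, 13, 14, 15, 16, 18]

    def test_too_few_complete_days_raises_with_count(self):
        s = make_series(np.zeros(5 * 1440))
        with pytest.raises(ValueError, match="5 complete"):
            select_complete_days(s, 7)

    def test_episode_spanning_midnight_breaks_both_days(self):
        s = make_series(np.zeros(14 * 1440), start="2015-01-05")
        broken = inject_nonwear(s, [(10 * 1440 - 15, 30)])  # straddles Jan 14/15
        out = select_complete_days(broken, 7)
        days = sorted(d.day for d in set(out.timestamps.date))
        assert 14 not in days and 15 not in days


class TestWindows:
    def test_constant_trace_window_means(self, flat_week):
        means = window_means(normalize_counts(flat_week))
        assert len(means) == 7 * 288
        np.testing.assert_allclose(means, 3.0)

    def test_single_spike_window_mean(self):
        counts = np.zeros(1440)
        counts[4] = 250.0  # 25% of max; window mean = 5%
        means = window_means(normalize_counts(make_series(counts)))
        assert means[0] == pytest.approx(5.0)

    @pytest.mark.parametrize(
        "mean, expected_active",
        [(2.4999, False), (2.5, True), (0.0, False), (97.0, True)],
    )
    def test_threshold_is_strict_inequality(self, mean, expected_active):
        """Mean activity < 2.5% is inactive; exactly 2.5% counts as active."""
        assert classify_windows(np.array([mean]), 2.5)[0] == expected_active


class TestTimeActive:
    def test_extremes(self):
        assert time_active(np.ones(7 * 288, bool), 7) == 1440
        assert time_active(np.zeros(7 * 288, bool), 7) == 0

    def test_sixty_windows_per_day_is_300_minutes(self):
        labels = np.zeros((7, 288), bool)
        labels[:, :60] = True
        assert time_active(labels.ravel(), 7) == 300

    def test_monotone_when_count_increases(self):
        counts = np.zeros(7 * 1440)
        base = run_module(counts.copy(), 1000, 7)[0]
        counts[0] = 500.0
        assert run_module(counts, 1000, 7)[0] >= base


class TestMedianIntensity:
    def test_constant_trace(self, flat_week):
        s = normalize_counts(flat_week)
        active = classify_windows(window_means(s))
        med, defined = median_intensity(s, active)
        assert defined and med == 3.0

    def test_median_of_active_epochs_only(self):
        counts = np.zeros(1440)
        counts[0:5] = [100, 200, 300, 0, 0]  # one active window, values 10,20,30,0,0
        s = normalize_counts(make_series(counts))
        active = classify_windows(window_means(s))
        med, defined = median_intensity(s, active)
        assert defined and med == 10.0  # median of {10,20,30,0,0}

    def test_all_zero_trace_flagged_missing(self):
        s = normalize_counts(make_series(np.zeros(1440)))
        active = classify_windows(window_means(s))
        med, defined = median_intensity(s, active)
        assert not defined and np.isnan(med)


class TestEndurance:
    def test_all_zero_trace(self):
        s = normalize_counts(make_series(np.zeros(7 * 1440)))
        with pytest.warns(UserWarning, match="zero bin"):
            bins = endurance_profile(s)
        assert bins == (10080, 0, 0, 0, 0)

    def test_single_epoch_is_its_own_maximum(self):
        counts = np.zeros(7 * 1440)
        counts[100] = 800.0
        s = normalize_counts(make_series(counts))
        assert endurance_profile(s) == (10079, 0, 0, 0, 1)

    def test_quartiles_of_individual_max(self):
        counts = np.zeros(7 * 1440)
        counts[10] = 100.0  # 25% of the individual max of 400
        counts[20] = 400.0
        s = normalize_counts(make_series(counts))
        assert endurance_profile(s) == (10078, 0, 1, 0, 1)

    @given(
        seed=st.integers(0, 2**31 - 1),
        scale=st.floats(min_value=0.01, max_value=10.0),
    )
    def test_bins_partition_the_week(self, seed, scale):
        rng = np.random.default_rng(seed)
        counts = rng.choice([0.0, 5.0, 100.0, 700.0], size=7 * 1440) * scale
        s = normalize_counts(make_series(counts, device_max=1000 * scale))
        assert sum(endurance_profile(s)) == 7 * 1440


class TestOracleEquivalence:
    """Brute-force recomputation matches the module exactly on short traces."""

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_two_day_traces(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.choice(
            [0.0, 0.0, 10.0, 40.0, 200.0, 600.0, 990.0], size=2 * 1440
        )
        expected = brute_force_phenotypes(counts, 1000.0, 2)
        got = run_module(counts, 1000.0, 2)
        assert got[0] == pytest.approx(expected[0])
        assert got[1] == pytest.approx(expected[1])
        assert got[2] == pytest.approx(expected[2])

    def test_calibration_invariance_full_pipeline(self):
        rng = np.random.default_rng(3)
        counts = rng.gamma(1.0, 60.0, size=7 * 1440)
        a = run_module(counts, 1000.0, 7)
        b = run_module(counts * 7.0, 7000.0, 7)
        assert a[0] == pytest.approx(b[0], abs=1e-9)
        assert a[1] == pytest.approx(b[1], abs=1e-9)
        assert a[2] == pytest.approx(b[2])


class TestSummarize:
    def test_full_chain_on_constructed_trace(self):
        counts = np.tile(np.r_[np.full(300, 300.0), np.zeros(1140)], 14)
        summ = summarize(make_series(counts))
        assert summ.minutes_active_per_day == 300
        assert summ.median_active_intensity == 30.0
        assert sum(summ.endurance_minutes) == 10080
        assert len(summ.days_used) == 7
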