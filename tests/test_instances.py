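"""Night selection, feature extraction and labeling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from _helpers import make_trace
from nhpredict.io import SleepPeriod
from nhpredict.instances import (
    FEATURE_GROUPS,
    FEATURE_NAMES,
    N_FEATURES,
    WINDOW_POINTS,
    extract_features,
    format_class_count,
    hypo_episodes,
    label_night,
    select_nights,
    window_coverage,
)
from nhpredict.pipeline import patient_instances


def ts(s):
    return pd.Timestamp(s)


class TestCatalog:
    def test_29_features_in_11_groups_with_stated_breakdown(self):
        assert N_FEATURES == 29
        assert len(FEATURE_GROUPS) == 11
        assert sum(len(v) for v in FEATURE_GROUPS.values()) == 29
        assert len(FEATURE_GROUPS["iob"]) == 1
        assert len(FEATURE_GROUPS["cob"]) == 1
        assert len(FEATURE_GROUPS["activity"]) == 2


class TestSelectNights:
    def test_plain_night(self):
        periods = [SleepPeriod(ts("2019-01-01 23:10"), ts("2019-01-02 07:00"))]
        assert select_nights(periods) == [ts("2019-01-01 23:10")]

    def test_short_nap_is_skipped(self):
        periods = [
            SleepPeriod(ts("2019-01-01 22:00"), ts("2019-01-01 22:40")),
            SleepPeriod(ts("2019-01-01 23:30"), ts("2019-01-02 07:00")),
        ]
        assert select_nights(periods) == [ts("2019-01-01 23:30")]

    def test_no_periods_no_instances(self):
        assert select_nights([]) == []

    def test_after_midnight_onset_belongs_to_previous_night(self):
        periods = [
            SleepPeriod(ts("2019-01-01 23:30"), ts("2019-01-02 06:00")),
            SleepPeriod(ts("2019-01-03 01:30"), ts("2019-01-03 08:30")),
        ]
        onsets = select_nights(periods)
        assert onsets == [ts("2019-01-01 23:30"), ts("2019-01-03 01:30")]

    def test_daytime_sleep_ignored(self):
        periods = [SleepPeriod(ts("2019-01-01 13:00"), ts("2019-01-01 17:00"))]
        assert select_nights(periods) == []


def _constant_fixture(value=100.0, n=24 * 12 + 1):
    trace = make_trace([value] * n)
    zeros = np.zeros(n)
    return trace, zeros


class TestExtractFeatures:
    def test_constant_window_values(self):
        trace, zeros = _constant_fixture()
        onset = trace.grid[100]
        x = extract_features(trace, zeros, zeros, zeros, zeros, onset)
        named = dict(zip(FEATURE_NAMES, x))
        assert x.shape == (29,)
        for f in ("glucose_at_onset", "mean_last_30min", "mean_glucose", "median_glucose",
                  "mean_last_hour", "min_glucose", "max_glucose"):
            assert named[f] == 100.0
        for f in ("sd_glucose", "cv_glucose", "iqr_glucose", "range_glucose", "slope_mgdl_h",
                  "mean_abs_rate_mgdl_h", "max_fall_rate_mgdl_h", "max_rise_rate_mgdl_h",
                  "pct_below_70", "pct_above_180", "pct_above_250", "auc_below_70",
                  "hypo_episode_count", "any_hypo", "iob_at_onset", "cob_at_onset",
                  "aob_at_onset", "calories_in_window"):
            assert named[f] == pytest.approx(0.0, abs=1e-9)
        assert named["pct_70_180"] == 100.0
        assert named["minutes_since_hypo"] == 360.0

    def test_random_fixture_matches_per_feature_oracle(self):
        rng = np.random.default_rng(11)
        n = 2 * 288
        values = rng.uniform(50, 300, n)
        values[rng.random(n) < 0.1] = np.nan
        trace = make_trace(values)
        iob = rng.uniform(0, 6, n)
        cob = rng.uniform(0, 80, n)
        aob = rng.uniform(0, 500, n)
        cal = rng.uniform(5, 12, n)
        i = 400
        onset = trace.grid[i]
        x = dict(zip(FEATURE_NAMES, extract_features(trace, iob, cob, aob, cal, onset)))

        idx = np.arange(i - WINDOW_POINTS + 1, i + 1)
        glu = trace.glucose[idx]
        ok = ~np.isnan(glu)
        g = glu[ok]
        t_min = (np.arange(len(idx)) - (len(idx) - 1))[ok] * 5.0  # minutes relative to onset

        assert x["glucose_at_onset"] == g[-1]
        assert x["mean_last_30min"] == pytest.approx(g[t_min > -30].mean())
        assert x["mean_glucose"] == pytest.approx(g.mean())
        assert x["median_glucose"] == pytest.approx(np.median(g))
        assert x["mean_last_hour"] == pytest.approx(g[t_min > -60].mean())
        assert x["sd_glucose"] == pytest.approx(np.std(g, ddof=1))
        assert x["cv_glucose"] == pytest.approx(100 * np.std(g, ddof=1) / g.mean())
        assert x["iqr_glucose"] == pytest.approx(np.percentile(g, 75) - np.percentile(g, 25))
        assert x["min_glucose"] == g.min()
        assert x["max_glucose"] == g.max()
        assert x["range_glucose"] == pytest.approx(g.max() - g.min())
        lr = stats.linregress(t_min / 60.0, g)
        assert x["slope_mgdl_h"] == pytest.approx(lr.slope)
        rates = np.diff(g) / (np.diff(t_min) / 60.0)
        assert x["mean_abs_rate_mgdl_h"] == pytest.approx(np.abs(rates).mean())
        assert x["max_fall_rate_mgdl_h"] == pytest.approx(max(0, -rates.min()))
        assert x["max_rise_rate_mgdl_h"] == pytest.approx(max(0, rates.max()))
        assert x["pct_below_70"] == pytest.approx(100 * np.mean(g < 70))
        assert x["pct_70_180"] == pytest.approx(100 * np.mean((g >= 70) & (g <= 180)))
        assert x["pct_above_180"] == pytest.approx(100 * np.mean(g > 180))
        assert x["pct_above_250"] == pytest.approx(100 * np.mean(g > 250))
        f = 1.509 * (np.log(g) ** 1.084 - 5.381)
        assert x["lbgi"] == pytest.approx(np.mean(np.where(f < 0, 10 * f**2, 0)))
        assert x["hbgi"] == pytest.approx(np.mean(np.where(f > 0, 10 * f**2, 0)))
        assert x["auc_below_70"] == pytest.approx(np.trapezoid(np.maximum(0, 70 - g), t_min))
        assert x["iob_at_onset"] == iob[i]
        assert x["cob_at_onset"] == cob[i]
        assert x["aob_at_onset"] == aob[i]
        assert x["calories_in_window"] == pytest.approx(cal[idx].sum())
        assert x["any_hypo"] == float(bool((g < 70).any()))

    def test_translation_invariance_in_absolute_time(self):
        rng = np.random.default_rng(12)
        n = 288
        values = rng.uniform(60, 260, n)
        iob, cob, aob, cal = (rng.uniform(0, 5, n) for _ in range(4))
        t1 = make_trace(values, start="2019-01-01 00:00")
        t2 = make_trace(values, start="2019-01-02 00:00")
        x1 = extract_features(t1, iob, cob, aob, cal, t1.grid[200])
        x2 = extract_features(t2, iob, cob, aob, cal, t2.grid[200])
        np.testing.assert_array_equal(x1, x2)


class TestHypoEpisodes:
    def test_runs_separated_by_15_min_or_more_are_distinct(self):
        t = np.arange(-60, 1, 5.0)
        g = np.full(len(t), 100.0)
        g[0:2] = 65.0  # -60,-55
        g[6:8] = 60.0  # -30,-25  (20 min above threshold in between)
        assert len(hypo_episodes(t, g)) == 2

    def test_short_recovery_merges_runs(self):
        t = np.arange(-30, 1, 5.0)
        # sub-70 runs separated by a single above-threshold reading (10 min)
        g = np.array([65.0, 65.0, 75.0, 65.0, 100.0, 100.0, 100.0])
        assert len(hypo_episodes(t, g)) == 1


class TestLabel:
    def test_all_readings_at_or_above_70_is_class_0(self):
        trace, _ = _constant_fixture(100.0)
        assert label_night(trace, trace.grid[10]) == 0

    def test_single_69_reading_three_hours_in_is_class_1(self):
        values = [100.0] * 289
        values[10 + 36] = 69.0
        trace = make_trace(values)
        assert label_night(trace, trace.grid[10]) == 1

    def test_reading_outside_six_hour_window_does_not_count(self):
        values = [100.0] * 289
        values[10 + 73] = 69.0  # onset + 365 min
        trace = make_trace(values)
        assert label_night(trace, trace.grid[10]) == 0

    def test_boundary_70_is_not_hypoglycemia(self):
        values = [100.0] * 289
        values[20] = 70.0
        trace = make_trace(values)
        assert label_night(trace, trace.grid[10]) == 0

    def test_lowering_a_reading_never_flips_positive_to_negative(self):
        rng = np.random.default_rng(13)
        values = rng.uniform(65, 200, 289)
        trace = make_trace(values)
        assert label_night(trace, trace.grid[10]) == 1
        values2 = values.copy()
        values2[30] = min(values2[30], 50.0)
        assert label_night(make_trace(values2), trace.grid[10]) == 1


class TestBuildDataset:
    def test_instance_count_and_summary_format(self, demo_instances):
        assert len(demo_instances) > 0
        for ni in demo_instances:
            assert ni.x.shape == (29,)
            assert np.isfinite(ni.x).all()
            assert ni.y in (0, 1)
            assert ni.coverage_pre >= 0.8 and ni.coverage_post >= 0.8

    def test_class_count_rendering(self):
        assert format_class_count(24, 104) == "24 (23%)"
        assert format_class_count(80, 104) == "80 (77%)"

    def test_class_percentages_sum_to_100_within_rounding(self, demo_instances):
        pos = sum(ni.y for ni in demo_instances)
        total = len(demo_instances)
        p1 = int(np.floor(100 * pos / total + 0.5))
        p0 = int(np.floor(100 * (total - pos) / total + 0.5))
        assert abs(p1 + p0 - 100) <= 1

    def test_low_coverage_night_is_discarded(self, demo_prepared):
        import dataclasses

        prep = demo_prepared
        glucose = prep.trace.glucose.copy()
        provenance = prep.trace.provenance.copy()
        # blank out the label window of the first night
        onset = select_nights(prep.sleep)[0]
        i = np.searchsorted(prep.trace.grid.asi8, onset.value, side="right") - 1
        glucose[i:i + WINDOW_POINTS] = np.nan
        provenance[i:i + WINDOW_POINTS] = "missing"
        trace2 = dataclasses.replace(prep.trace, glucose=glucose, provenance=provenance)
        prep2 = dataclasses.replace(prep, trace=trace2)
        kept = {ni.sleep_onset for ni in patient_instances(prep2)}
        assert onset not in kept
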