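import json

import numpy as np
import pandas as pd
import pytest

from neodot.event_analysis import (
    EVENT_TABLE_COLUMNS,
    DegenerateTestError,
    RecoveryCriterion,
    analyze_events,
    build_report,
    event_baseline,
    hemispheric_power_test,
    response_metrics,
    summarize_events,
)
from neodot.reconstruction import HaemoImageSeries
from neodot.synthetic_scene import biphasic_shape, make_hemispheric_power

FS = 10.0


def biphasic_trace(onset_s, duration_s=700.0, amp=2.7, u=1.5,
                   tr=12.5, tf=116.0, trec=123.0):
    t = np.arange(0, duration_s, 1 / FS)
    return t, amp * biphasic_shape(t, onset_s, tr, tf, trec, u)


def annotation_table(onsets, durations=None):
    onsets = np.asarray(onsets, float)
    durations = np.full(len(onsets), 60.0) if durations is None else durations
    return pd.DataFrame(
        {
            "event_id": np.arange(1, len(onsets) + 1),
            "am_onset_s": onsets,
            "dh_onset_s": onsets,
            "eeg_duration_s": durations,
            "label": ["seizure"] * len(onsets),
        }
    )


class TestEventBaseline:
    def test_constant(self):
        y = np.full(2000, 3.7)
        assert event_baseline(y, FS, 100.0) == pytest.approx(3.7)

    def test_linear(self):
        a = 0.02
        t = np.arange(2000) / FS
        # window is [onset-60, onset-30): mean of a*t is ~ a*(onset-45)
        assert event_baseline(a * t, FS, 100.0) == pytest.approx(
            a * (100.0 - 45.0), abs=a * 0.1
        )

    def test_inverted_window(self):
        with pytest.raises(ValueError, match="inverted"):
            event_baseline(np.zeros(2000), FS, 100.0, window=(-30.0, -60.0))

    def test_out_of_range_names_event(self):
        with pytest.raises(ValueError, match="event 4"):
            event_baseline(np.zeros(100), FS, 20.0, event_id=4)


class TestResponseMetrics:
    def test_pure_template_exact(self):
        t, y = biphasic_trace(onset_s=150.0)
        row = response_metrics(y, FS, 150.0, hbo_trace=1.7 / 2.7 * y,
                               hbr_trace=1.0 / 2.7 * y, event_id=1)
        assert row["responsive"]
        assert row["max_to_min_estimable"] and row["recovery_estimable"]
        assert row["time_to_hbt_max_s"] == pytest.approx(12.5, abs=0.1)
        assert row["time_max_to_min_s"] == pytest.approx(116.0, abs=0.1)
        assert row["time_min_to_recovery_s"] == pytest.approx(123.0, abs=0.1)
        assert row["dot_event_duration_s"] == pytest.approx(251.5, abs=0.3)
        assert row["peak_hbt_uM"] == pytest.approx(2.7, abs=1e-3)
        assert row["peak_hbo_uM"] == pytest.approx(1.7, abs=1e-3)
        assert row["peak_hbr_uM"] == pytest.approx(1.0, abs=1e-3)
        # the undershoot exceeds the initial increase
        assert -y.min() > y.max()

    def test_flat_trace_unresponsive(self):
        row = response_metrics(np.zeros(7000), FS, 150.0)
        assert not row["responsive"]
        assert np.isnan(row["time_to_hbt_max_s"])
        assert np.isnan(row["peak_hbt_uM"])

    def test_negative_deflection_unresponsive(self):
        t, y = biphasic_trace(onset_s=150.0)
        row = response_metrics(-y, FS, 150.0)
        assert not row["responsive"]

    def test_min_censored_by_next_onset(self):
        # next event starts while the trace is still falling (trough at 278.5)
        t, y = biphasic_trace(onset_s=150.0)
        row = response_metrics(y, FS, 150.0, next_onset_s=250.0)
        assert row["responsive"]
        assert not row["max_to_min_estimable"]
        assert not row["recovery_estimable"]
        assert np.isnan(row["time_max_to_min_s"])
        assert row["dot_event_duration_s"] == pytest.approx(
            row["time_to_hbt_max_s"]
        )

    def test_recovery_censored_by_next_onset(self):
        # next event after the trough (278.5 s) but before recovery (401.5 s)
        t, y = biphasic_trace(onset_s=150.0)
        row = response_metrics(y, FS, 150.0, next_onset_s=310.0)
        assert row["max_to_min_estimable"]
        assert not row["recovery_estimable"]
        assert row["time_max_to_min_s"] == pytest.approx(116.0, abs=0.2)
        assert np.isnan(row["time_min_to_recovery_s"])
        assert row["dot_event_duration_s"] == pytest.approx(
            row["time_to_hbt_max_s"] + row["time_max_to_min_s"]
        )

    def test_time_shift_invariance(self):
        t1, y1 = biphasic_trace(onset_s=150.0)
        t2, y2 = biphasic_trace(onset_s=157.3)
        r1 = response_metrics(y1, FS, 150.0)
        r2 = response_metrics(y2, FS, 157.3)
        for col in ("time_to_hbt_max_s", "time_max_to_min_s",
                    "time_min_to_recovery_s"):
            assert r1[col] == pytest.approx(r2[col], abs=0.15)

    def test_amplitude_scale_invariance_of_timing(self):
        t, y = biphasic_trace(onset_s=150.0)
        r1 = response_metrics(y, FS, 150.0)
        r2 = response_metrics(10.0 * y, FS, 150.0)
        for col in ("time_to_hbt_max_s", "time_max_to_min_s",
                    "time_min_to_recovery_s"):
            assert r1[col] == pytest.approx(r2[col], abs=1e-6)
        assert r2["peak_hbt_uM"] == pytest.approx(10 * r1["peak_hbt_uM"])

    def test_raw_rules_without_refinement(self):
        t, y = biphasic_trace(onset_s=150.0)
        crit = RecoveryCriterion(refine=False)
        row = response_metrics(y, FS, 150.0, recovery_criterion=crit)
        # raw argmax/argmin land on the knots; the slope gate fires a little
        # before the true end of recovery
        assert row["time_to_hbt_max_s"] == pytest.approx(12.5, abs=0.1)
        assert row["time_max_to_min_s"] == pytest.approx(116.0, abs=0.1)
        assert row["time_min_to_recovery_s"] == pytest.approx(123.0, abs=5.0)


class TestAnalyzeEvents:
    def test_two_events_with_trend(self):
        t = np.arange(0, 1400, 1 / FS)
        y = 2.7 * (
            biphasic_shape(t, 150.0, 12.5, 116.0, 123.0, 1.5)
            + biphasic_shape(t, 750.0, 12.5, 116.0, 123.0, 1.5)
        )
        y = y + 5.0 + 0.002 * t  # offset + slow drift, removed by detrend
        tab = analyze_events({"hbt": y}, FS, annotation_table([150.0, 750.0]))
        assert list(tab.columns) == EVENT_TABLE_COLUMNS
        assert len(tab) == 2
        for _, row in tab.iterrows():
            assert row["responsive"]
            assert row["time_to_hbt_max_s"] == pytest.approx(12.5, abs=0.5)
            assert row["time_max_to_min_s"] == pytest.approx(116.0, abs=1.0)
            assert row["time_min_to_recovery_s"] == pytest.approx(123.0, abs=2.0)

    def test_unsorted_annotations(self):
        t = np.arange(0, 1400, 1 / FS)
        y = 2.7 * (
            biphasic_shape(t, 150.0, 12.5, 116.0, 123.0, 1.5)
            + biphasic_shape(t, 750.0, 12.5, 116.0, 123.0, 1.5)
        )
        tab = analyze_events({"hbt": y}, FS, annotation_table([750.0, 150.0]))
        # rows come back in temporal order regardless of table order
        assert tab["consensus_onset_s"].is_monotonic_increasing

    def test_missing_hbt_trace(self):
        with pytest.raises(KeyError):
            analyze_events({"hbo": np.zeros(7000)}, FS, annotation_table([150.0]))


class TestHemisphericPowerTest:
    def test_brute_force_three_pairs(self):
        left = np.array([11.0, 12.0, 13.0])
        right = np.array([10.0, 10.0, 10.0])
        tstat, p = hemispheric_power_test(left, right)
        # d = [1, 2, 3]: t = mean / (sd / sqrt(3)) = 2 * sqrt(3)
        assert tstat == pytest.approx(2 * np.sqrt(3.0), rel=1e-12)
        # closed-form two-sided p for t with 2 dof: 1 - t/sqrt(t^2 + 2)
        t0 = 2 * np.sqrt(3.0)
        assert p == pytest.approx(1.0 - t0 / np.sqrt(t0**2 + 2.0), rel=1e-9)

    def test_degenerate(self):
        left = np.array([1.0, 2.0, 3.0])
        with pytest.raises(DegenerateTestError):
            hemispheric_power_test(left, left + 5.0)

    def test_validation(self):
        with pytest.raises(ValueError):
            hemispheric_power_test(np.ones(3), np.ones(4))
        with pytest.raises(ValueError):
            hemispheric_power_test(np.ones(1), np.ones(1))

    def test_fixture_integration(self):
        left, right = make_hemispheric_power(effect=0.0, seed=1)
        tstat, p = hemispheric_power_test(left, right)
        assert np.isfinite(tstat) and 0.0 < p <= 1.0


class TestSummarize:
    def make_table(self):
        t, y = biphasic_trace(onset_s=150.0)
        return analyze_events({"hbt": y}, FS, annotation_table([150.0]),
                              detrend=False)

    def test_single_event(self):
        tab = self.make_table()
        s = summarize_events(tab)
        assert s["n_events"] == 1 and s["n_responsive"] == 1
        assert s["time_to_hbt_max_s"]["mean"] == pytest.approx(
            tab["time_to_hbt_max_s"].iloc[0]
        )
        assert s["time_to_hbt_max_s"]["sd"] == 0.0

    def test_channel_amplitudes(self):
        tab = self.make_table()
        amps = np.array([[1.0, 2.0, 3.0]])
        s = summarize_events(tab, channel_amplitudes={"hbt": amps})
        assert s["channel_hbt"]["max"] == 3.0
        assert s["channel_hbt"]["max"] >= s["channel_hbt"]["mean"]

    def test_empty_table(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_events(pd.DataFrame(columns=EVENT_TABLE_COLUMNS))


class TestBuildReport:
    def test_artifacts_and_roundtrip(self, tmp_path):
        t, y = biphasic_trace(onset_s=150.0)
        tab = analyze_events({"hbt": y}, FS, annotation_table([150.0]),
                             detrend=False)
        out = tmp_path / "report"
        summary = build_report(tab, out, global_traces={"hbt": y},
                               sample_rate_hz=FS)
        assert (out / "events.csv").exists()
        assert (out / "global_traces.png").exists()
        with open(out / "summary.json") as f:
            loaded = json.load(f)
        assert loaded["summary"]["n_events"] == summary["summary"]["n_events"]
        back = pd.read_csv(out / "events.csv")
        assert back["time_to_hbt_max_s"].iloc[0] == pytest.approx(
            tab["time_to_hbt_max_s"].iloc[0]
        )

    def test_image_grid(self, tmp_path, rng):
        t, y = biphasic_trace(onset_s=150.0)
        tab = analyze_events({"hbt": y}, FS, annotation_table([150.0]),
                             detrend=False)
        times = np.arange(0.0, 700.0, 1.0)
        n_nodes = 40
        series = HaemoImageSeries(
            rng.standard_normal((len(times), n_nodes)),
            rng.standard_normal((len(times), n_nodes)),
            times, 0.1,
        )
        out = tmp_path / "report"
        build_report(tab, out, images=series, sample_rate_hz=FS)
        assert (out / "event_1_images.png").exists()

    def test_empty_image_series_warns(self, tmp_path):
        t, y = biphasic_trace(onset_s=150.0)
        tab = analyze_events({"hbt": y}, FS, annotation_table([150.0]),
                             detrend=False)
        empty = HaemoImageSeries(np.zeros((0, 5)), np.zeros((0, 5)),
                                 np.zeros(0), 0.1)
        with pytest.warns(UserWarning, match="empty image series"):
            build_report(tab, tmp_path / "r2", images=empty, sample_rate_hz=FS)
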