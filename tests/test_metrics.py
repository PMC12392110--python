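"""Spike detection, the four SLE metrics, pause counting and aggregation."""

import numpy as np
import pandas as pd
import pytest

from sleseg.io import Event, EventList, Recording
from sleseg.metrics import (
    aggregate,
    detect_pauses,
    detect_spikes,
    mean_sle_duration,
    metrics_for_unit,
    metrics_table,
    sle_fraction,
    sle_rate,
    spike_frequency,
)

FS = 2000.0


def rec_with_troughs(trough_specs, n=8000):
    """Flat signal with V-shaped troughs at (index, depth)."""
    x = np.zeros(n)
    for idx, depth in trough_specs:
        x[idx] = -depth
        x[idx - 1] = -depth / 2
        x[idx + 1] = -depth / 2
    return Recording(x, FS, "r")


class TestDetectSpikes:
    def test_isolated_troughs_all_found(self):
        specs = [(1000, 2.0), (1900, 3.0), (2800, 1.5)]  # >=0.4 s apart
        rec = rec_with_troughs(specs)
        events = EventList([Event(0, 4000)], FS, 4.0)
        spikes = detect_spikes(rec, events)
        assert list(spikes.indices) == [1000, 1900, 2800]

    def test_competition_within_window(self):
        # troughs 0.1 s apart: only the deeper survives the +-0.165-s rule
        rec = rec_with_troughs([(1000, 2.0), (1200, 1.0)])
        events = EventList([Event(0, 4000)], FS, 4.0)
        spikes = detect_spikes(rec, events)
        assert list(spikes.indices) == [1000]

    def test_constant_signal_no_spikes(self):
        rec = Recording(np.zeros(4000) + 1.0, FS, "r")
        events = EventList([Event(0, 4000)], FS, 2.0)
        assert len(detect_spikes(rec, events)) == 0

    def test_spikes_outside_events_ignored(self):
        rec = rec_with_troughs([(1000, 2.0), (3000, 2.0)])
        events = EventList([Event(500, 1500)], FS, 4.0)
        spikes = detect_spikes(rec, events)
        assert list(spikes.indices) == [1000]
        assert list(spikes.event_index) == [0]

    def test_invalid_window(self):
        rec = rec_with_troughs([(1000, 2.0)])
        with pytest.raises(ValueError):
            detect_spikes(rec, EventList([Event(0, 100)], FS, 4.0), window_s=0)

    def test_matches_brute_force_scan(self):
        """Oracle equivalence on random signals: O(n*w) strict-window scan."""
        rng = np.random.default_rng(3)
        fs = 200.0
        w = int(round(0.165 * fs))
        for trial in range(10):
            x = rng.standard_normal(600)
            rec = Recording(x, fs, "r")
            events = EventList([Event(0, 600)], fs, 3.0)
            got = list(detect_spikes(rec, events).indices)
            # clip convention: out-of-range comparisons clamp to the boundary
            # sample, so the first/last samples compare to themselves and are
            # never minima
            brute = [
                i
                for i in range(600)
                if all(
                    x[i] < x[min(max(i - s, 0), 599)] and x[i] < x[min(i + s, 599)]
                    for s in range(1, w + 1)
                )
            ]
            assert got == brute


class TestMetricValues:
    def test_fraction_quarter(self):
        events = EventList([Event(0, 600 * 2000)], FS, 2400.0)
        assert sle_fraction(events) == pytest.approx(0.25)

    def test_fraction_empty_and_full(self):
        assert sle_fraction(EventList([], FS, 100.0)) == 0.0
        full = EventList([Event(0, int(100 * FS))], FS, 100.0)
        assert sle_fraction(full) == pytest.approx(1.0)

    def test_rate_288_events_in_40min(self):
        events = EventList([Event(i * 16000, i * 16000 + 800) for i in range(288)], FS, 2400.0)
        assert sle_rate(events) == pytest.approx(7.2)

    def test_spike_frequency_pooled(self):
        events = EventList([Event(0, int(10 * FS))], FS, 60.0)

        class _Fake:
            def __len__(self):
                return 50

        assert spike_frequency(_Fake(), events) == pytest.approx(5.0)

    def test_no_events_missing_not_zero(self):
        events = EventList([], FS, 60.0)
        assert sle_rate(events) == 0.0
        assert np.isnan(mean_sle_duration(events))
        assert np.isnan(spike_frequency(None, events))

    def test_identity_fraction_rate_duration(self):
        rng = np.random.default_rng(0)
        onsets = np.sort(rng.choice(200_000, 40, replace=False)) * 10
        events = EventList(
            [Event(int(o), int(o) + int(rng.integers(400, 8000))) for o in onsets[::4]],
            FS,
            2400.0,
        )
        f = sle_fraction(events)
        assert f == pytest.approx(sle_rate(events) * mean_sle_duration(events) / 60.0)


class TestPauses:
    def test_single_long_gap(self):
        events = EventList([Event(0, int(10 * FS)), Event(int(140 * FS), int(150 * FS))], FS, 160.0)
        assert detect_pauses(events) == 1

    def test_no_events_whole_window_is_pause(self):
        assert detect_pauses(EventList([], FS, 2400.0)) == 1

    def test_regular_events_no_pause(self):
        events = EventList(
            [Event(int(i * 60 * FS), int((i * 60 + 2) * FS)) for i in range(40)], FS, 2400.0
        )
        assert detect_pauses(events) == 0

    def test_boundary_strictly_greater(self):
        # exactly 120-s leading gap does not count
        events = EventList([Event(int(120 * FS), int(130 * FS))], FS, 130.0)
        assert detect_pauses(events) == 0


def table_from(rows):
    return pd.DataFrame.from_records(rows)


class TestAggregate:
    def base_row(self, unit, group, animal, fraction, analyzed, n_events, n_spikes=0):
        return {
            "unit_id": unit,
            "group": group,
            "animal_id": animal,
            "slice_id": unit,
            "fraction": fraction,
            "mean_duration_s": fraction * analyzed / n_events if n_events else float("nan"),
            "rate_per_min": n_events / (analyzed / 60.0),
            "spike_freq_hz": float("nan"),
            "analyzed_s": analyzed,
            "n_events": n_events,
            "n_spikes": n_spikes,
        }

    def test_slice_level_identity(self):
        t = table_from([self.base_row("s1", "ctrl", "a1", 0.2, 1200.0, 10)])
        pd.testing.assert_frame_equal(aggregate(t, "slice"), t)

    def test_identical_slices_pool_to_same_metrics(self):
        r = self.base_row("s1", "ctrl", "a1", 0.25, 1200.0, 12)
        t = table_from([r, {**r, "unit_id": "s2", "slice_id": "s2"}])
        out = aggregate(t, "animal")
        assert len(out) == 1
        assert out.iloc[0]["fraction"] == pytest.approx(0.25)
        assert out.iloc[0]["rate_per_min"] == pytest.approx(r["rate_per_min"])

    def test_time_weighted_fraction(self):
        t = table_from(
            [
                self.base_row("s1", "ctrl", "a1", 0.2, 1200.0, 10),
                self.base_row("s2", "ctrl", "a1", 0.4, 1200.0, 10),
            ]
        )
        out = aggregate(t, "animal")
        assert out.iloc[0]["fraction"] == pytest.approx(0.3)

    def test_order_invariance(self):
        rows = [
            self.base_row("s1", "ctrl", "a1", 0.2, 1200.0, 10),
            self.base_row("s2", "ctrl", "a1", 0.4, 600.0, 4),
            self.base_row("s3", "cnb", "a2", 0.1, 1200.0, 7),
        ]
        out1 = aggregate(table_from(rows), "animal")
        out2 = aggregate(table_from(rows[::-1]), "animal")
        pd.testing.assert_frame_equal(
            out1.sort_values("unit_id").reset_index(drop=True),
            out2.sort_values("unit_id").reset_index(drop=True),
        )

    def test_missing_animal_id_rejected(self):
        t = table_from([self.base_row("s1", "ctrl", "", 0.2, 1200.0, 10)])
        with pytest.raises(ValueError):
            aggregate(t, "animal")


class TestOnSyntheticRecording:
    def test_ground_truth_rate_recovered(self, short_recording):
        rec, truth = short_recording
        row = metrics_for_unit(truth, detect_spikes(rec, truth), "short")
        assert row["rate_per_min"] == pytest.approx(12.0, rel=0.4)
        assert row["fraction"] == pytest.approx(
            row["rate_per_min"] * row["mean_duration_s"] / 60.0
        )
        assert row["spike_freq_hz"] > 0

    def test_metrics_table_carries_metadata(self, short_recording):
        rec, truth = short_recording
        rec.meta.update({"group": "naive", "animal_id": "a1", "slice_id": "s1"})
        t = metrics_table([(rec, truth)])
        assert t.iloc[0]["group"] == "naive"
        assert t.iloc[0]["n_events"] == len(truth)
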