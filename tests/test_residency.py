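"""Monitoring windows, visit segmentation, SFI, co-detection, summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sharkmove import residency as res
from sharkmove.simulate.acoustics import ReceiverStation, TransmitterSpec

from conftest import random_detection_log

T0 = pd.Timestamp("2014-06-01")


def brute_force_visits(detections: pd.DataFrame, gap_min=30.0, single_min=7.7):
    """Independent interval-splitting oracle for visit segmentation."""
    out = []
    d = detections.sort_values(["transmitter_id", "time", "receiver_id"], kind="stable")
    for tx, sub in d.groupby("transmitter_id"):
        recs = list(sub.itertuples(index=False))
        group = [recs[0]]
        for prev, cur in zip(recs, recs[1:]):
            boundary = (cur.receiver_id != prev.receiver_id) or (
                (cur.time - prev.time) >= pd.Timedelta(minutes=gap_min)
            )
            if boundary:
                out.append((tx, group))
                group = []
            group.append(cur)
        out.append((tx, group))
    rows = []
    for tx, group in out:
        start, end = group[0].time, group[-1].time
        dur = single_min if len(group) == 1 else (end - start).total_seconds() / 60.0
        rows.append((tx, group[0].receiver_id, start, end, dur, len(group)))
    return pd.DataFrame(
        rows, columns=["transmitter_id", "receiver_id", "start", "end", "duration_min", "n_detections"]
    )


def make_detections(entries):
    """entries: (minutes_from_t0, receiver_id[, transmitter_id])"""
    if not entries:
        return pd.DataFrame(columns=["time", "transmitter_id", "receiver_id"])
    rows = []
    for e in entries:
        t, rx = e[0], e[1]
        tx = e[2] if len(e) > 2 else "T1"
        rows.append({"time": T0 + pd.Timedelta(minutes=t), "transmitter_id": tx, "receiver_id": rx})
    return pd.DataFrame(rows)


class TestSingleDetectionDuration:
    def test_buffer_convention(self):
        """Longest train (3.6 s) + two maximum silences (230 s) -> 7.7 min."""
        assert res.single_detection_duration_min() == 7.7

    def test_unrounded_value(self):
        assert res.single_detection_duration_min(decimals=3) == pytest.approx(463.6 / 60, abs=5e-4)


class TestMonitoringWindows:
    def _rx(self, start, end, rid="R1"):
        return ReceiverStation(rid, (20.7, -156.5), 15.0, "Maui", [(pd.Timestamp(start), pd.Timestamp(end))])

    def _tx(self, activation, days, tid="T1"):
        return TransmitterSpec(tid, "S" + tid, pd.Timestamp(activation), days)

    def test_calendar_day_intersection(self):
        # receiver deployed all of 2014, tag active Mar 2014 - Mar 2016
        rx = self._rx("2014-01-01", "2015-01-01")
        tx = self._tx("2014-03-01", 731.0)
        (w,) = res.monitoring_windows([rx], [tx], tz_offset_h=0.0)
        assert w.monitored_days == 306

    def test_disjoint_gives_zero_days(self):
        rx = self._rx("2015-01-01", "2015-06-01")
        tx = self._tx("2014-01-01", 30.0)
        (w,) = res.monitoring_windows([rx], [tx])
        assert w.monitored_days == 0

    def test_potential_detection_days_sum(self):
        rxs = [self._rx("2014-06-01", "2014-09-09", f"R{k}") for k in range(2)]
        txs = [self._tx("2014-06-01", 100.0, f"T{k}") for k in range(2)]
        ws = res.monitoring_windows(rxs, txs, tz_offset_h=0.0)
        assert res.potential_detection_days(ws) == 400


class TestSegmentVisits:
    def test_continuous_detections_one_visit(self):
        v = res.segment_visits(make_detections([(0, "A"), (10, "A"), (20, "A")]))
        assert len(v) == 1
        assert v["duration_min"].iloc[0] == 20.0 and v["n_detections"].iloc[0] == 3

    def test_single_detections_get_nominal_duration(self):
        v = res.segment_visits(make_detections([(0, "A"), (40, "A")]))
        assert v["duration_min"].tolist() == [7.7, 7.7]

    def test_location_change_closes_visit(self):
        v = res.segment_visits(make_detections([(0, "A"), (5, "B"), (10, "A")]))
        assert len(v) == 3
        assert v["receiver_id"].tolist() == ["A", "B", "A"]

    def test_exact_30_min_gap_closes(self):
        v = res.segment_visits(make_detections([(0, "A"), (30, "A")]))
        assert len(v) == 2

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        log = random_detection_log(rng, 500)
        got = res.segment_visits(log).reset_index(drop=True)
        want = brute_force_visits(log).reset_index(drop=True)
        pd.testing.assert_frame_equal(got, want, check_dtype=False)

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        log = random_detection_log(rng, 400)
        v = res.segment_visits(log)
        assert v["n_detections"].sum() == len(log)
        assert (v["duration_min"] > 0).all()


class TestSFI:
    def _window(self, days=100, tid="T1", rid="R1"):
        rx = ReceiverStation(rid, (20.7, -156.5), 15.0, "Maui",
                             [(T0, T0 + pd.Timedelta(days=days))])
        tx = TransmitterSpec(tid, "S1", T0, float(days))
        return res.monitoring_windows([rx], [tx], tz_offset_h=0.0)

    def test_formula(self):
        ws = self._window(100)
        det = make_detections([(1440.0 * k + 60, "R1") for k in range(10)])
        sfi = res.compute_sfi(det, ws, tz_offset_h=0.0)
        assert sfi["sfi_pct"].iloc[0] == pytest.approx(10.0)

    def test_zero_detections_zero_sfi(self):
        ws = self._window(50)
        sfi = res.compute_sfi(make_detections([]), ws, tz_offset_h=0.0)
        assert sfi["sfi_pct"].iloc[0] == 0.0 and sfi["monitored_days"].iloc[0] == 50

    def test_detections_without_window_raise(self):
        ws = self._window(100)
        det = make_detections([(60, "R9")])  # receiver with no window
        with pytest.raises(ValueError, match="no monitored days"):
            res.compute_sfi(det, ws, tz_offset_h=0.0)

    def test_binomial_visiting_probability_recovered(self):
        """Daily visiting probability 0.3 over 400 days -> SFI within 3 sigma."""
        rng = np.random.default_rng(100)
        days = 400
        ws = self._window(days)
        visit_days = np.flatnonzero(rng.random(days) < 0.3)
        det = make_detections([(1440.0 * d + 720, "R1") for d in visit_days])
        sfi = res.compute_sfi(det, ws, tz_offset_h=0.0)
        sigma = 100 * np.sqrt(0.3 * 0.7 / days)
        assert abs(sfi["sfi_pct"].iloc[0] - 30.0) < 3 * sigma

    def test_sfi_monotone_in_detection_days(self):
        ws = self._window(100)
        vals = []
        for nd in (5, 10, 20):
            det = make_detections([(1440.0 * k + 60, "R1") for k in range(nd)])
            vals.append(res.compute_sfi(det, ws, tz_offset_h=0.0)["sfi_pct"].iloc[0])
        assert vals == sorted(vals)


class TestRevisitInterval:
    @pytest.mark.parametrize("sfi,days", [(20.0, 5.0), (10.0, 10.0), (100.0, 1.0)])
    def test_equivalences(self, sfi, days):
        assert res.sfi_equivalent_revisit_interval(sfi) == days

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            res.sfi_equivalent_revisit_interval(0.0)


class TestDetectionDayFrequency:
    def _dates(self, n):
        return {(T0 + pd.Timedelta(days=k)).date() for k in range(n)}

    def test_every_day(self):
        det = make_detections([(1440.0 * k + 60, "R1") for k in range(10)])
        assert res.detection_day_frequency(det, "R1", self._dates(10), tz_offset_h=0.0) == 100.0

    def test_none(self):
        assert res.detection_day_frequency(make_detections([]), "R1", self._dates(10)) == 0.0

    def test_partial(self):
        det = make_detections([(1440.0 * k + 60, "R1") for k in range(62)])
        assert res.detection_day_frequency(det, "R1", self._dates(100), tz_offset_h=0.0) == 62.0


class TestCodetection:
    def test_max_sharks_single_day(self):
        det = make_detections([(k, "R1", f"T{k}") for k in range(8)])
        s = res.codetection_summary(det, "R1", tz_offset_h=0.0)
        assert s.max_sharks_per_day == 8

    def test_single_shark_no_multi_days(self):
        det = make_detections([(1440.0 * k, "R1") for k in range(5)])
        s = res.codetection_summary(det, "R1", tz_offset_h=0.0)
        assert s.pct_days_multi == 0.0

    def test_multi_fraction_of_monitored_days(self):
        entries = []
        for day in range(25):  # two sharks on 25 days
            entries += [(1440.0 * day + 60, "R1", "T1"), (1440.0 * day + 70, "R1", "T2")]
        s = res.codetection_summary(
            make_detections(entries), "R1",
            monitored_dates={(T0 + pd.Timedelta(days=k)).date() for k in range(100)},
            tz_offset_h=0.0,
        )
        assert s.pct_days_multi == 25.0

    def test_codetection_bounded_by_active_transmitters(self):
        rng = np.random.default_rng(7)
        entries = [
            (float(rng.integers(0, 14400)), "R1", f"T{rng.integers(0, 5)}") for _ in range(200)
        ]
        s = res.codetection_summary(make_detections(entries), "R1", tz_offset_h=0.0)
        assert s.max_sharks_per_day <= 5


class TestSharkSummaries:
    def test_mean_excluding_zeros_and_max(self):
        sfi = pd.DataFrame(
            {
                "transmitter_id": ["T1"] * 3,
                "receiver_id": ["R1", "R2", "R3"],
                "days_detected": [0, 10, 20],
                "monitored_days": [100] * 3,
                "sfi_pct": [0.0, 10.0, 20.0],
            }
        )
        visits = res.segment_visits(make_detections([(0, "R2"), (100, "R3")]))
        out = res.shark_summaries(visits, sfi)
        row = out.iloc[0]
        assert row["mean_sfi_excl_zero_pct"] == 15.0 and row["max_sfi_pct"] == 20.0

    def test_visit_duration_stats_include_all_visits(self):
        visits = pd.DataFrame(
            {
                "transmitter_id": "T1",
                "receiver_id": "R1",
                "start": [T0, T0 + pd.Timedelta(hours=2), T0 + pd.Timedelta(hours=30)],
                "end": [T0, T0 + pd.Timedelta(hours=2), T0 + pd.Timedelta(hours=30)],
                "duration_min": [5.0, 7.7, 700.7],
                "n_detections": [2, 1, 50],
            }
        )
        sfi = pd.DataFrame(
            {"transmitter_id": ["T1"], "receiver_id": ["R1"], "days_detected": [2],
             "monitored_days": [10], "sfi_pct": [20.0]}
        )
        out = res.shark_summaries(visits, sfi)
        assert out["max_visit_min"].iloc[0] == 700.7
        assert out["mean_visit_min"].iloc[0] == pytest.approx(np.mean([5.0, 7.7, 700.7]))

    def test_single_visit_absence_flagged(self):
        visits = res.segment_visits(make_detections([(0, "R1")]))
        sfi = pd.DataFrame(
            {"transmitter_id": ["T1"], "receiver_id": ["R1"], "days_detected": [1],
             "monitored_days": [10], "sfi_pct": [10.0]}
        )
        out = res.shark_summaries(visits, sfi)
        assert bool(out["absence_undefined"].iloc[0])
        assert np.isnan(out["mean_absence_h"].iloc[0])


class TestEndToEndResidency:
    def test_resident_outranks_transient(self, grid, shark_spec):
        """A core-attracted shark at its home receiver accrues higher SFI
        than a shark whose core lies ~20 km away (seeded simulator run)."""
        from sharkmove.simulate.movement import MovementParams, SharkSpec, simulate_shark_track
        from sharkmove.simulate.acoustics import simulate_acoustic_detections
        from conftest import CORE_CENTER

        home = ReceiverStation(
            "HOME", CORE_CENTER, 15.0, "Maui",
            [(pd.Timestamp("2014-01-01"), pd.Timestamp("2015-01-01"))],
        )
        far_center = (20.55, -156.25)
        days = 12.0
        specs = {
            "RES": MovementParams(attraction_center=CORE_CENTER, excursion_rate_per_day=0.0),
            "TRA": MovementParams(attraction_center=far_center, excursion_rate_per_day=0.0),
        }
        sfis = {}
        for sid, params in specs.items():
            spec = SharkSpec(sid, "F", 300.0, "Maui", CORE_CENTER, pd.Timestamp("2014-03-01"))
            path = simulate_shark_track(spec, params, grid, duration_days=days, seed=55)
            tx = TransmitterSpec("T" + sid, sid, pd.Timestamp("2014-03-01"), 3650.0)
            det = simulate_acoustic_detections(path, tx, [home], seed=56)
            ws = res.monitoring_windows([home], [tx], period=(path.times[0], path.times[-1]))
            sfis[sid] = res.compute_sfi(det, ws)["sfi_pct"].iloc[0]
        assert sfis["RES"] > sfis["TRA"]
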