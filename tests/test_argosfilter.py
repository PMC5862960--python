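"""Argos cleaning: class-Z removal, outlier radius, speed filter, thinning,
and UTM projection properties."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from sharkmove.argosfilter import (
    as_track,
    drop_class_z,
    filter_pipeline,
    project_to_planar,
    remove_distant_outliers,
    retained,
    speed_filter,
    thin_temporal_clusters,
)
from sharkmove.geo import haversine_km
from sharkmove.projection import lonlat_to_utm, utm_to_lonlat
from sharkmove.simulate.argos import simulate_argos_fixes
from sharkmove.simulate.movement import MovementParams, simulate_shark_track

from conftest import CORE_CENTER

T0 = pd.Timestamp("2014-01-01")


def track_from(rows):
    """rows: (hours_from_t0, lat, lon, lc)"""
    return as_track(
        pd.DataFrame(
            [
                {"time": T0 + pd.Timedelta(hours=h), "lat": la, "lon": lo, "lc": lc}
                for h, la, lo, lc in rows
            ]
        )
    )


class TestDropClassZ:
    def test_z_fixes_flagged(self):
        tr = track_from([(i, 20.7, -156.5, c) for i, c in enumerate("321ZB")])
        out = drop_class_z(tr)
        assert retained(out)["lc"].tolist() == ["3", "2", "1", "B"]
        assert out.loc[~out["retained"], "reason"].tolist() == ["class_z"]

    def test_no_z_is_identity(self):
        tr = track_from([(i, 20.7, -156.5, c) for i, c in enumerate("32A")])
        assert drop_class_z(tr)["retained"].all()

    def test_all_z_empty_but_no_error(self):
        tr = track_from([(i, 20.7, -156.5, "Z") for i in range(3)])
        assert retained(drop_class_z(tr)).empty


class TestDistantOutliers:
    def test_far_fix_removed(self):
        tr = track_from([(0, 20.7, -156.5, "2"), (1, 60.0, -156.5, "B")])
        out = remove_distant_outliers(tr, CORE_CENTER, max_km=2000.0)
        assert out["reason"].tolist() == ["", "distant_outlier"]

    def test_all_near_identity(self):
        tr = track_from([(i, 20.7 + 0.01 * i, -156.5, "2") for i in range(4)])
        assert remove_distant_outliers(tr, CORE_CENTER, 2000.0)["retained"].all()

    def test_default_radius_retains_longest_excursion(self):
        """A 1,460 km offshore excursion must survive the default radius."""
        lat_far = CORE_CENTER[0] + 1460.0 / 111.195
        tr = track_from([(0, *CORE_CENTER, "2"), (400, lat_far, CORE_CENTER[1], "1")])
        assert remove_distant_outliers(tr, CORE_CENTER)["retained"].all()


class TestSpeedFilter:
    def test_b_fix_beyond_buffer_removed(self):
        # 10 km in 1 h from an LC-2 anchor > 4.2 km/h
        tr = track_from([(0, 20.7, -156.5, "2"), (1, 20.7 + 10 / 111.195, -156.5, "B")])
        out = speed_filter(tr)
        assert out["reason"].tolist() == ["", "speed"]

    def test_a_fix_within_buffer_retained(self):
        tr = track_from([(0, 20.7, -156.5, "2"), (1, 20.7 + 2 / 111.195, -156.5, "A")])
        assert speed_filter(tr)["retained"].all()

    def test_land_fix_removed_at_any_speed(self, grid):
        from conftest import ISLAND_CENTER

        tr = track_from([(0, *CORE_CENTER, "2"), (1000, *ISLAND_CENTER, "0")])
        out = speed_filter(tr, grid=grid)
        assert out["reason"].tolist() == ["", "land"]

    def test_anchor_exempt_even_at_high_speed(self):
        tr = track_from([(0, 20.7, -156.5, "2"), (1, 20.7 + 50 / 111.195, -156.5, "3")])
        assert speed_filter(tr)["retained"].all()

    def test_pre_anchor_fix_uses_first_subsequent_anchor(self):
        tr = track_from(
            [(0, 20.7 + 2 / 111.195, -156.5, "B"), (1, 20.7, -156.5, "2")]
        )
        assert speed_filter(tr)["retained"].all()

    def test_no_anchors_removes_all_with_warning(self):
        tr = track_from([(i, 20.7, -156.5, c) for i, c in enumerate("0AB")])
        with pytest.warns(UserWarning, match="no anchor"):
            out = speed_filter(tr)
        assert not out["retained"].any()

    def test_idempotent(self):
        rng = np.random.default_rng(4)
        rows = [
            (float(h), 20.7 + rng.normal(0, 0.05), -156.5 + rng.normal(0, 0.05),
             rng.choice(list("321AB0")))
            for h in range(60)
        ]
        tr = track_from(rows)
        once = speed_filter(tr)
        twice = speed_filter(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_no_retained_fix_exceeds_vmax_from_anchor(self):
        """Direct assertion of the filter's defining invariant on outputs."""
        rng = np.random.default_rng(9)
        rows = [
            (float(h) * 2, 20.7 + rng.normal(0, 0.08), -156.5 + rng.normal(0, 0.08),
             rng.choice(list("21AB0")))
            for h in range(80)
        ]
        out = speed_filter(track_from(rows))
        kept = retained(out)
        anchors = kept[kept["lc"].isin(["1", "2", "3", "G"])]
        for _, fx in kept[kept["lc"].isin(["0", "A", "B"])].iterrows():
            prev = anchors[anchors["time"] <= fx["time"]]
            anchor = prev.iloc[-1] if len(prev) else anchors.iloc[0]
            d = haversine_km(fx["lat"], fx["lon"], anchor["lat"], anchor["lon"])
            hrs = abs((fx["time"] - anchor["time"]).total_seconds()) / 3600.0
            assert d <= 4.2 * max(hrs, 1e-9) + 1e-9

    def test_lc3_only_low_error_retention(self, shark_spec, grid):
        """>=99% of fixes survive when programmed speeds stay below vmax."""
        params = MovementParams(
            attraction_center=CORE_CENTER, surfacing_prob=1.0, excursion_rate_per_day=0.0
        )
        path = simulate_shark_track(shark_spec, params, grid, duration_days=10.0, seed=21)
        fixes = simulate_argos_fixes(path, lc_distribution={"3": 1.0}, seed=3)
        out = filter_pipeline(fixes, CORE_CENTER, grid, thin=False)
        assert out["retained"].mean() >= 0.99


class TestThinning:
    def test_cluster_collapses_to_single_fix(self):
        # burst at 0/2/4 min within a track sampled every 6 h: the burst
        # gaps fall below the median interval and collapse to one fix
        rows = [(0.0, 20.7, -156.5, "A"), (2 / 60, 20.7, -156.5, "A"), (4 / 60, 20.7, -156.5, "A")]
        rows += [(6.0 * k, 20.7, -156.5, "A") for k in range(1, 5)]
        out = thin_temporal_clusters(track_from(rows))
        kept = retained(out)
        # the 2-min burst collapses (only its earliest fix survives) and the
        # regularly spaced tail is untouched apart from the fix adjacent to
        # the burst, whose lead gap falls just under the median interval
        assert kept["time"].tolist() == [
            T0,
            T0 + pd.Timedelta(hours=12),
            T0 + pd.Timedelta(hours=18),
            T0 + pd.Timedelta(hours=24),
        ]

    def test_evenly_spaced_identity(self):
        tr = track_from([(float(h), 20.7, -156.5, "A") for h in range(6)])
        assert thin_temporal_clusters(tr)["retained"].all()

    def test_highest_quality_kept_in_cluster(self):
        tr = track_from(
            [(0.0, 20.7, -156.5, "A"), (2 / 60, 20.71, -156.5, "3"),
             (4 / 60, 20.7, -156.5, "A"), (6.0, 20.7, -156.5, "A")]
        )
        out = thin_temporal_clusters(tr)
        kept = retained(out)
        assert "3" in kept["lc"].tolist()

    def test_single_fix_identity(self):
        tr = track_from([(0, 20.7, -156.5, "B")])
        assert thin_temporal_clusters(tr)["retained"].all()


class TestProjection:
    def test_round_trip_within_one_meter(self):
        rng = np.random.default_rng(0)
        lat = rng.uniform(18.5, 23.0, 200)
        lon = rng.uniform(-161.0, -157.0, 200)
        x, y = lonlat_to_utm(lat, lon, zone=4)
        la2, lo2 = utm_to_lonlat(x, y, zone=4)
        assert np.max(haversine_km(lat, lon, la2, lo2)) * 1000 < 1.0

    def test_planar_distance_matches_haversine(self):
        """~1 km great-circle pair -> planar distance within 0.5%."""
        lat = np.array([20.7, 20.7 + 1.0 / 111.195])
        lon = np.array([-158.9, -158.9])
        gc = haversine_km(lat[0], lon[0], lat[1], lon[1]) * 1000
        x, y = lonlat_to_utm(lat, lon, zone=4)
        planar = float(np.hypot(np.diff(x), np.diff(y))[0])
        assert planar == pytest.approx(gc, rel=0.005)

    def test_zone_mismatch_warns(self):
        with pytest.warns(UserWarning, match="central meridian"):
            lonlat_to_utm(20.7, -140.0, zone=4)

    def test_polar_latitude_rejected(self):
        with pytest.raises(ValueError, match="84"):
            lonlat_to_utm(85.0, -158.0, zone=4)

    def test_project_to_planar_uses_retained_only(self):
        tr = track_from([(0, 20.7, -158.9, "2"), (1, 20.8, -158.9, "Z")])
        tr = drop_class_z(tr)
        assert project_to_planar(tr).shape == (1, 2)


class TestPipelineProperties:
    def test_retained_is_subsequence_and_reasons_valid(self, shark_spec, grid):
        params = MovementParams(attraction_center=CORE_CENTER, excursion_rate_per_day=0.0)
        path = simulate_shark_track(shark_spec, params, grid, duration_days=6.0, seed=31)
        fixes = simulate_argos_fixes(path, seed=5)
        out = filter_pipeline(fixes, CORE_CENTER, grid)
        kept = retained(out)
        assert kept["time"].is_monotonic_increasing
        assert set(out.loc[~out["retained"], "reason"]) <= {
            "distant_outlier", "class_z", "speed", "land", "cluster_thinned"
        }
        # retained rows are exactly a subset of the input rows, order preserved
        merged = fixes.sort_values("time").reset_index(drop=True)
        assert len(kept) <= len(merged)

    def test_class_b_large_error_mostly_removed(self, shark_spec, grid):
        """5-km RMS LC-B noise around a slow track: filter removes a fraction."""
        params = MovementParams(
            attraction_center=CORE_CENTER, surfacing_prob=1.0, excursion_rate_per_day=0.0
        )
        path = simulate_shark_track(shark_spec, params, grid, duration_days=5.0, seed=41)
        fixes = simulate_argos_fixes(
            path,
            lc_distribution={"2": 0.2, "B": 0.8},
            lc_error_rms_m={"2": 300.0, "B": 5000.0},
            seed=6,
        )
        out = filter_pipeline(fixes, CORE_CENTER, grid, thin=False)
        b = out[out["lc"] == "B"]
        assert (~b["retained"]).mean() > 0
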