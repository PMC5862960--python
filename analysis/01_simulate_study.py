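#!/usr/bin/env python
"""Simulate the synthetic multi-island study.

Two islands ~45 km apart, six sharks (four resident to the first island,
two to the second, one of which makes offshore excursions), eight receivers
spanning shallow recreation and deep shelf sites. Writes the full file set
(bathymetry grid, metadata CSVs, detections, per-shark Argos tables) under
results/synthetic/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from sharkmove import io as smio
from sharkmove.grid import depth_at, write_ascii_grid
from sharkmove.simulate.acoustics import (
    ReceiverStation,
    TransmitterSpec,
    simulate_acoustic_detections,
)
from sharkmove.simulate.argos import simulate_argos_fixes
from sharkmove.simulate.movement import MovementParams, SharkSpec, simulate_shark_track
from sharkmove.simulate.seascape import Island, generate_seascape

SEED = 2014
OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"
T0 = pd.Timestamp("2014-01-01")
DAYS = 30.0

ISLANDS = [
    Island(center=(20.80, -156.60), land_radius_km=10.0, shelf_width_km=18.0),
    Island(center=(21.10, -157.00), land_radius_km=7.0, shelf_width_km=8.0),
]
# attraction cores sit on the shelf near the first shallow receiver of
# each island, so resident sharks accrue realistic detection logs
CORE_A: tuple[float, float]
CORE_B: tuple[float, float]


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    grid = generate_seascape(ISLANDS, origin=(20.3, -157.6), n_rows=140, n_cols=160, cell_deg=0.012)
    write_ascii_grid(grid, OUT / "bathymetry.asc")
    print(f"seascape: {grid.n_rows}x{grid.n_cols} cells, "
          f"depth range {np.nanmin(grid.depth):.0f}..{np.nanmax(grid.depth):.0f} m")

    deployments = [(T0, T0 + pd.Timedelta(days=DAYS))]

    def site(island_idx, bearing_deg, dist_km):
        from sharkmove.geo import local_frame_to_lonlat

        cy, cx = ISLANDS[island_idx].center
        th = np.radians(bearing_deg)
        la, lo = local_frame_to_lonlat(dist_km * np.sin(th), dist_km * np.cos(th), cy, cx)
        return float(la), float(lo)

    # shallow sites just off each coastline, deep sites near the shelf break
    layout = [
        ("A-SH1", 0, 120.0, 10.8, "shallow-recreation"), ("A-SH2", 0, 160.0, 11.2, "shallow-recreation"),
        ("A-DP1", 0, 130.0, 22.0, "deep"), ("A-DP2", 0, 90.0, 23.0, "deep"),
        ("B-SH1", 1, 140.0, 7.5, "shallow-recreation"), ("B-SH2", 1, 180.0, 7.6, "shallow-recreation"),
        ("B-DP1", 1, 120.0, 13.0, "deep"), ("B-DP2", 1, 90.0, 13.4, "deep"),
    ]
    receivers = []
    for rid, isl, bearing, dist, use in layout:
        pos = site(isl, bearing, dist)
        d = float(depth_at(grid, *pos))
        assert d > 0, rid
        receivers.append(ReceiverStation(rid, pos, d, "AB"[isl], deployments, use))

    global CORE_A, CORE_B
    CORE_A = site(0, 125.0, 12.5)
    CORE_B = site(1, 150.0, 8.5)

    rng = np.random.default_rng(SEED)
    sharks, txs, detections = [], [], []
    configs = [
        ("S1", "F", CORE_A, 0.0), ("S2", "F", CORE_A, 0.0), ("S3", "M", CORE_A, 0.0),
        ("S4", "F", CORE_A, 0.0), ("S5", "F", CORE_B, 0.0), ("S6", "M", CORE_B, 0.15),
    ]
    for sid, sex, core, excur in configs:
        spec = SharkSpec(sid, sex, float(rng.uniform(220, 440)), "A" if core == CORE_A else "B",
                         core, T0)
        params = MovementParams(attraction_center=core, excursion_rate_per_day=excur)
        path = simulate_shark_track(spec, params, grid, duration_days=DAYS, seed=SEED)
        tx = TransmitterSpec("T" + sid, sid, T0, 3650.0)
        det = simulate_acoustic_detections(path, tx, receivers, seed=SEED)
        argos = simulate_argos_fixes(path, seed=SEED)
        smio.write_argos_csv(argos, OUT / f"argos_{sid}.csv")
        sharks.append(spec)
        txs.append(tx)
        detections.append(det)
        print(f"{sid} ({sex}, core {spec.island}): {len(det)} detections, {len(argos)} Argos fixes")

    det_all = pd.concat(detections, ignore_index=True).sort_values("time")
    smio.write_detections_csv(det_all, OUT / "detections.csv")
    smio.write_receivers_csv(receivers, OUT / "receivers.csv")
    smio.write_transmitters_csv(txs, OUT / "transmitters.csv")
    smio.write_sharks_csv(sharks, OUT / "sharks.csv")
    print(f"total detections: {len(det_all)} -> {OUT}")


if __name__ == "__main__":
    main()
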