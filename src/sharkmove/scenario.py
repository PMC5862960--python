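"""Scenario-driven simulation: one config file -> a full synthetic study.

A scenario is a YAML document (key/value with nested sections) defining the
seascape (islands, grid), the sharks (with per-shark movement parameters),
the receiver array, and the master seed. ``run_scenario`` writes the
standard file set: bathymetry ASCII grid, sharks/receivers/transmitters
CSVs, a pooled detections CSV, and per-shark Argos CSVs.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from sharkmove import io as smio
from sharkmove.grid import write_ascii_grid
from sharkmove.simulate.acoustics import (
    ReceiverStation,
    TransmitterSpec,
    simulate_acoustic_detections,
)
from sharkmove.simulate.argos import simulate_argos_fixes
from sharkmove.simulate.movement import MovementParams, SharkSpec, simulate_shark_track
from sharkmove.simulate.seascape import Island, generate_seascape


def load_scenario(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def build_seascape(cfg: dict):
    g = cfg["grid"]
    islands = [
        Island(
            center=tuple(i["center"]),
            land_radius_km=i.get("land_radius_km", 8.0),
            shelf_width_km=i.get("shelf_width_km", 15.0),
            peak_elevation_m=i.get("peak_elevation_m", 1000.0),
            slope_m_per_km=i.get("slope_m_per_km", 200.0),
        )
        for i in cfg["islands"]
    ]
    return generate_seascape(
        islands,
        origin=tuple(g["origin"]),
        n_rows=g["n_rows"],
        n_cols=g["n_cols"],
        cell_deg=g["cell_deg"],
    )


def run_scenario(cfg: dict, outdir) -> dict:
    """Simulate a scenario and write its file set; returns the objects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg.get("seed", 0))
    grid = build_seascape(cfg)
    write_ascii_grid(grid, outdir / "bathymetry.asc")

    receivers = [
        ReceiverStation(
            receiver_id=r["id"],
            position=tuple(r["position"]),
            depth_m=r["depth_m"],
            island=r.get("island", ""),
            deployments=[(pd.Timestamp(s), pd.Timestamp(e)) for s, e in r["deployments"]],
            use_class=r.get("use_class", "other"),
        )
        for r in cfg.get("receivers", [])
    ]

    sharks, transmitters, paths = [], [], {}
    detections = []
    for s in cfg.get("sharks", []):
        spec = SharkSpec(
            shark_id=s["id"],
            sex=s.get("sex", "F"),
            total_length_cm=s.get("total_length_cm", 350.0),
            island=s.get("island", ""),
            tagging_position=tuple(s.get("tagging_position", s["movement"]["attraction_center"])),
            tagged_at=pd.Timestamp(s["tagged_at"]),
            mature=s.get("mature", True),
        )
        mv = dict(s["movement"])
        mv["attraction_center"] = tuple(mv["attraction_center"])
        params = MovementParams(**mv)
        path = simulate_shark_track(
            spec, params, grid,
            duration_days=s.get("duration_days", cfg.get("duration_days", 30)),
            step_min=cfg.get("step_min", 1.0),
            seed=seed,
        )
        tx = TransmitterSpec(
            transmitter_id=s.get("transmitter_id", "T" + s["id"]),
            shark_id=s["id"],
            activation=pd.Timestamp(s["tagged_at"]),
            battery_days=s.get("battery_days", 3650.0),
        )
        sharks.append(spec)
        transmitters.append(tx)
        paths[s["id"]] = path
        det = simulate_acoustic_detections(
            path, tx, receivers, range_m=cfg.get("range_m", 900.0), seed=seed
        )
        detections.append(det)
        argos = simulate_argos_fixes(path, seed=seed)
        smio.write_argos_csv(argos, outdir / f"argos_{s['id']}.csv")

    det_all = (
        pd.concat(detections, ignore_index=True)
        if detections
        else pd.DataFrame(columns=["time", "transmitter_id", "receiver_id"])
    )
    smio.write_detections_csv(det_all, outdir / "detections.csv")
    smio.write_receivers_csv(receivers, outdir / "receivers.csv")
    smio.write_transmitters_csv(transmitters, outdir / "transmitters.csv")
    smio.write_sharks_csv(sharks, outdir / "sharks.csv")
    return {
        "grid": grid,
        "sharks": sharks,
        "transmitters": transmitters,
        "receivers": receivers,
        "paths": paths,
        "detections": det_all,
    }
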