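"""Tabular and geometry I/O.

CSV schemas follow receiver-array export conventions: detections as
(time, transmitter_id, receiver_id) with ISO-8601 UTC timestamps; Argos
fixes as (time, lat, lon, lc[, retained, reason]); receiver metadata with
deployment intervals serialized as ``start/end`` pairs joined by ``;``.
Isopleths and tracks export as GeoJSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from shapely.geometry import mapping

from sharkmove.simulate.acoustics import ReceiverStation, TransmitterSpec
from sharkmove.simulate.movement import SharkSpec


def write_detections_csv(detections: pd.DataFrame, path) -> None:
    out = detections.copy()
    out["time"] = pd.to_datetime(out["time"]).dt.strftime("%Y-%m-%dT%H:%M:%S.%f")
    out.to_csv(path, index=False)


def read_detections_csv(path) -> pd.DataFrame:
    d = pd.read_csv(path)
    d["time"] = pd.to_datetime(d["time"])
    return d


def write_argos_csv(track: pd.DataFrame, path) -> None:
    track.to_csv(path, index=False, date_format="%Y-%m-%dT%H:%M:%S")


def read_argos_csv(path) -> pd.DataFrame:
    d = pd.read_csv(path, dtype={"lc": str})
    d["time"] = pd.to_datetime(d["time"])
    return d


def write_receivers_csv(receivers: list[ReceiverStation], path) -> None:
    rows = []
    for r in receivers:
        rows.append(
            {
                "receiver_id": r.receiver_id,
                "lat": r.position[0],
                "lon": r.position[1],
                "depth_m": r.depth_m,
                "island": r.island,
                "use_class": r.use_class,
                "deployments": ";".join(
                    f"{s.isoformat()}/{e.isoformat()}" for s, e in r.deployments
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_receivers_csv(path) -> list[ReceiverStation]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        deps = []
        if isinstance(row["deployments"], str) and row["deployments"]:
            for iv in row["deployments"].split(";"):
                s, e = iv.split("/")
                deps.append((pd.Timestamp(s), pd.Timestamp(e)))
        out.append(
            ReceiverStation(
                receiver_id=str(row["receiver_id"]),
                position=(row["lat"], row["lon"]),
                depth_m=row["depth_m"],
                island=row["island"],
                deployments=deps,
                use_class=row.get("use_class", "other"),
            )
        )
    return out


def write_transmitters_csv(transmitters: list[TransmitterSpec], path) -> None:
    rows = [
        {
            "transmitter_id": t.transmitter_id,
            "shark_id": t.shark_id,
            "activation": t.activation.isoformat(),
            "battery_days": t.battery_days,
            "train_s_min": t.train_s[0],
            "train_s_max": t.train_s[1],
            "off_s_min": t.off_s[0],
            "off_s_max": t.off_s[1],
        }
        for t in transmitters
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_transmitters_csv(path) -> list[TransmitterSpec]:
    df = pd.read_csv(path)
    return [
        TransmitterSpec(
            transmitter_id=str(r["transmitter_id"]),
            shark_id=str(r["shark_id"]),
            activation=pd.Timestamp(r["activation"]),
            battery_days=r["battery_days"],
            train_s=(r["train_s_min"], r["train_s_max"]),
            off_s=(r["off_s_min"], r["off_s_max"]),
        )
        for _, r in df.iterrows()
    ]


def write_sharks_csv(sharks: list[SharkSpec], path) -> None:
    rows = [
        {
            "shark_id": s.shark_id,
            "sex": s.sex,
            "total_length_cm": s.total_length_cm,
            "island": s.island,
            "lat": s.tagging_position[0],
            "lon": s.tagging_position[1],
            "tagged_at": pd.Timestamp(s.tagged_at).isoformat(),
            "mature": s.mature,
        }
        for s in sharks
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sharks_csv(path) -> list[SharkSpec]:
    df = pd.read_csv(path)
    return [
        SharkSpec(
            shark_id=str(r["shark_id"]),
            sex=r["sex"],
            total_length_cm=r["total_length_cm"],
            island=r["island"],
            tagging_position=(r["lat"], r["lon"]),
            tagged_at=pd.Timestamp(r["tagged_at"]),
            mature=bool(r.get("mature", True)),
        )
        for _, r in df.iterrows()
    ]


def isopleths_to_geojson(isopleths, path=None) -> dict:
    """Isopleths as a GeoJSON FeatureCollection (level, area_km2, fraction)."""
    features = []
    for lv, geom, area, frac in zip(
        isopleths.levels, isopleths.geometries, isopleths.areas_km2, isopleths.fractions
    ):
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {
                    "level": lv,
                    "area_km2": float(area),
                    "fraction_enclosed": float(frac),
                },
            }
        )
    fc = {"type": "FeatureCollection", "features": features}
    if path is not None:
        Path(path).write_text(json.dumps(fc))
    return fc


def track_to_geojson(track: pd.DataFrame, path=None, as_line: bool = True) -> dict:
    """Retained fixes as GeoJSON LineString or MultiPoint."""
    r = track[track["retained"]] if "retained" in track.columns else track
    coords = [[float(lo), float(la)] for la, lo in zip(r["lat"], r["lon"])]
    geom = {"type": "LineString" if as_line else "MultiPoint", "coordinates": coords}
    fc = {
        "type": "FeatureCollection",
        "features": [{"type": "Feature", "geometry": geom, "properties": {}}],
    }
    if path is not None:
        Path(path).write_text(json.dumps(fc))
    return fc
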