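"""Acoustic-array residency metrics.

From a raw detection log (timestamp, transmitter, receiver) this module
derives monitoring-window-adjusted residency metrics:

- **Monitoring windows** — the denominator of every rate: the intersection
  of a receiver's deployment intervals, a transmitter's battery window
  (nominal life, zero-failure assumption), and the analysis period, counted
  in *local* calendar days (study default UTC-10).
- **Visits** — contiguous presence bouts: a visit ends when the animal is
  next detected at a different receiver or is silent for >= 30 min; a
  single-detection visit is assigned a fixed nominal duration (7.7 min:
  the longest pulse train, 3.6 s, bracketed by two maximum silent periods
  of 230 s), applied uniformly to all transmitters to avoid duty-cycle bias.
- **Site Fidelity Index (SFI)** — percentage of monitored days on which the
  animal was detected at a receiver; SFI x% is equivalent to one visit per
  100/x days under uniform spacing.
- **Detection-day frequency and co-detection** — site-level presence of any
  tagged animal, and daily counts of distinct individuals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd

from sharkmove.simulate.acoustics import ReceiverStation, TransmitterSpec

#: Study-region local time (Hawaii, no DST).
LOCAL_UTC_OFFSET_H = -10.0

VISIT_GAP_MIN = 30.0


def single_detection_duration_min(
    train_s: float = 3.6, max_off_s: float = 230.0, decimals: int = 1
) -> float:
    """Nominal duration assigned to a one-detection visit (minutes).

    The longest pulse train preceded and followed by listening periods equal
    to the maximum random off time: (train + 2 x off) seconds, rounded to
    one decimal (3.6 + 460 s = 463.6 s -> 7.7 min).
    """
    return round((train_s + 2.0 * max_off_s) / 60.0, decimals)


SINGLE_DETECTION_MIN = single_detection_duration_min()


def local_dates(times, tz_offset_h: float = LOCAL_UTC_OFFSET_H):
    """Local calendar date for each UTC timestamp."""
    t = pd.to_datetime(times) + pd.Timedelta(hours=tz_offset_h)
    return t.dt.date if hasattr(t, "dt") else t.date()


def _interval_dates(start, end, tz_offset_h: float) -> set[date]:
    """Local dates touched by the half-open interval [start, end)."""
    start, end = pd.Timestamp(start), pd.Timestamp(end)
    if end <= start:
        return set()
    s = (start + pd.Timedelta(hours=tz_offset_h)).date()
    e = (end + pd.Timedelta(hours=tz_offset_h) - pd.Timedelta(nanoseconds=1)).date()
    return {s + timedelta(days=k) for k in range((e - s).days + 1)}


@dataclass
class MonitoringWindow:
    """Adjusted monitoring period for one transmitter-receiver pair."""

    transmitter_id: str
    receiver_id: str
    intervals: list[tuple[pd.Timestamp, pd.Timestamp]]
    dates: frozenset
    tz_offset_h: float = LOCAL_UTC_OFFSET_H

    @property
    def monitored_days(self) -> int:
        return len(self.dates)

    def contains(self, when) -> bool:
        t = pd.Timestamp(when)
        return any(s <= t < e for s, e in self.intervals)


def monitoring_windows(
    receivers: list[ReceiverStation],
    transmitters: list[TransmitterSpec],
    period: tuple | None = None,
    tz_offset_h: float = LOCAL_UTC_OFFSET_H,
) -> list[MonitoringWindow]:
    """Per-pair monitoring windows: deployment ∩ battery life ∩ period.

    Intervals are half-open; monitored days are counted as distinct local
    calendar days the intersection touches. Receivers deployed after a
    shark was tagged (and vice versa) are thereby adjusted automatically.
    """
    out = []
    for tx in transmitters:
        t0, t1 = pd.Timestamp(tx.activation), tx.battery_end
        if period is not None:
            t0 = max(t0, pd.Timestamp(period[0]))
            t1 = min(t1, pd.Timestamp(period[1]))
        for rx in receivers:
            ivs, dates = [], set()
            for s, e in rx.deployments:
                lo, hi = max(s, t0), min(e, t1)
                if lo < hi:
                    ivs.append((lo, hi))
                    dates |= _interval_dates(lo, hi, tz_offset_h)
            out.append(MonitoringWindow(tx.transmitter_id, rx.receiver_id, ivs, frozenset(dates), tz_offset_h))
    return out


def potential_detection_days(windows: list[MonitoringWindow]) -> int:
    """Total monitored days summed over all transmitter-receiver pairs."""
    return int(sum(w.monitored_days for w in windows))


def segment_visits(
    detections: pd.DataFrame,
    gap_min: float = VISIT_GAP_MIN,
    single_detection_min: float = SINGLE_DETECTION_MIN,
) -> pd.DataFrame:
    """Partition a detection log into visits.

    Per transmitter, detections are scanned chronologically (exact time ties
    broken by receiver id); the open visit closes when the next detection is
    at a different receiver or ``gap_min`` minutes or more later. Visit
    duration is last-minus-first detection in minutes, or
    ``single_detection_min`` for one-detection visits. Every detection
    belongs to exactly one visit.
    """
    cols = ["transmitter_id", "receiver_id", "start", "end", "duration_min", "n_detections"]
    if detections.empty:
        return pd.DataFrame(columns=cols)
    d = detections.sort_values(
        ["transmitter_id", "time", "receiver_id"], kind="stable"
    ).reset_index(drop=True)
    gap = pd.Timedelta(minutes=gap_min)

    rows = []
    for tx, sub in d.groupby("transmitter_id", sort=True):
        times = sub["time"].to_numpy()
        recs = sub["receiver_id"].to_numpy()
        start = 0
        for i in range(1, len(sub) + 1):
            if (
                i == len(sub)
                or recs[i] != recs[i - 1]
                or (times[i] - times[i - 1]) >= gap
            ):
                n = i - start
                dur = (
                    single_detection_min
                    if n == 1
                    else (times[i - 1] - times[start]) / np.timedelta64(1, "m")
                )
                rows.append((tx, recs[start], times[start], times[i - 1], float(dur), n))
                start = i
    return pd.DataFrame(rows, columns=cols)


def compute_sfi(
    detections: pd.DataFrame,
    windows: list[MonitoringWindow],
    tz_offset_h: float = LOCAL_UTC_OFFSET_H,
) -> pd.DataFrame:
    """Site Fidelity Index per transmitter-receiver pair.

    SFI = 100 x (distinct local detection days) / (monitored days). Pairs
    with zero detections are kept (SFI 0). Detections on days outside the
    pair's monitoring window are flagged with a warning and not counted;
    detections at a pair with zero monitored days raise (data inconsistency).
    """
    wmap = {(w.transmitter_id, w.receiver_id): w for w in windows}
    counts: dict[tuple[str, str], int] = {}
    if not detections.empty:
        d = detections.copy()
        d["date"] = local_dates(d["time"], tz_offset_h)
        for (tx, rx), sub in d.groupby(["transmitter_id", "receiver_id"], sort=True):
            w = wmap.get((tx, rx))
            days = set(sub["date"])
            if w is None or w.monitored_days == 0:
                raise ValueError(
                    f"detections present for pair ({tx}, {rx}) with no monitored days"
                )
            outside = days - set(w.dates)
            if outside:
                warnings.warn(
                    f"{len(outside)} detection day(s) outside monitoring window for ({tx}, {rx})",
                    stacklevel=2,
                )
            counts[(tx, rx)] = len(days & set(w.dates))

    rows = []
    for w in windows:
        nd = counts.get((w.transmitter_id, w.receiver_id), 0)
        sfi = 100.0 * nd / w.monitored_days if w.monitored_days else np.nan
        rows.append(
            {
                "transmitter_id": w.transmitter_id,
                "receiver_id": w.receiver_id,
                "days_detected": nd,
                "monitored_days": w.monitored_days,
                "sfi_pct": sfi,
            }
        )
    return pd.DataFrame(rows)


def sfi_equivalent_revisit_interval(sfi_percent: float) -> float:
    """Mean days between detection days implied by an SFI percentage.

    SFI 20% -> one visit per 5 days; 10% -> per 10 days; 100% -> daily.
    """
    if sfi_percent <= 0 or sfi_percent > 100:
        raise ValueError("SFI must lie in (0, 100]")
    return 100.0 / sfi_percent


def detection_day_frequency(
    detections: pd.DataFrame,
    receiver_id: str,
    monitored_dates,
    tz_offset_h: float = LOCAL_UTC_OFFSET_H,
) -> float:
    """% of a receiver's monitored days with >=1 tagged animal detected."""
    monitored = set(monitored_dates)
    if not monitored:
        return float("nan")
    d = detections[detections["receiver_id"] == receiver_id]
    if d.empty:
        return 0.0
    days = set(local_dates(d["time"], tz_offset_h))
    return 100.0 * len(days & monitored) / len(monitored)


@dataclass
class CodetectionSummary:
    """Daily distinct-individual counts at one receiver."""

    receiver_id: str
    daily_counts: pd.Series
    pct_days_multi: float
    max_sharks_per_day: int


def codetection_summary(
    detections: pd.DataFrame,
    receiver_id: str,
    monitored_dates=None,
    tz_offset_h: float = LOCAL_UTC_OFFSET_H,
) -> CodetectionSummary:
    """Distinct sharks per local day at a receiver, and multi-shark-day rate.

    ``pct_days_multi`` is the share of monitored days (detection days if
    ``monitored_dates`` is None) with >=2 distinct individuals.
    """
    d = detections[detections["receiver_id"] == receiver_id].copy()
    if d.empty:
        counts = pd.Series(dtype=int)
    else:
        d["date"] = local_dates(d["time"], tz_offset_h)
        counts = d.groupby("date")["transmitter_id"].nunique().sort_index()
    denom = len(set(monitored_dates)) if monitored_dates is not None else len(counts)
    multi = int((counts >= 2).sum())
    return CodetectionSummary(
        receiver_id=receiver_id,
        daily_counts=counts,
        pct_days_multi=(100.0 * multi / denom) if denom else float("nan"),
        max_sharks_per_day=int(counts.max()) if len(counts) else 0,
    )


def shark_summaries(
    visits: pd.DataFrame,
    sfi: pd.DataFrame,
    tz_offset_h: float = LOCAL_UTC_OFFSET_H,
) -> pd.DataFrame:
    """Per-shark residency summary table.

    Columns: mean (excluding zeros) and max SFI; mean and max visit duration
    (all visits); mean (over days with >=1 visit) and max visits per day;
    most-visited receiver (ties broken by highest SFI there); mean and max
    absence from that receiver (hours between consecutive visits, NaN and
    flagged when the shark has fewer than two visits there).
    """
    rows = []
    for tx in sorted(set(sfi["transmitter_id"]) | set(visits.get("transmitter_id", []))):
        s = sfi[sfi["transmitter_id"] == tx]
        v = visits[visits["transmitter_id"] == tx] if not visits.empty else visits
        nz = s[s["sfi_pct"] > 0]["sfi_pct"]
        row = {
            "transmitter_id": tx,
            "mean_sfi_excl_zero_pct": nz.mean() if len(nz) else np.nan,
            "max_sfi_pct": s["sfi_pct"].max() if len(s) else np.nan,
            "mean_visit_min": v["duration_min"].mean() if len(v) else np.nan,
            "max_visit_min": v["duration_min"].max() if len(v) else np.nan,
        }
        if len(v):
            per_day = v.assign(date=local_dates(v["start"], tz_offset_h)).groupby("date").size()
            row["mean_visits_per_day_excl_zero"] = per_day.mean()
            row["max_visits_per_day"] = int(per_day.max())
            by_rx = v.groupby("receiver_id").size()
            top = by_rx[by_rx == by_rx.max()].index
            if len(top) > 1 and len(s):
                cand = s[s["receiver_id"].isin(top)]
                fav = cand.sort_values("sfi_pct", ascending=False)["receiver_id"].iloc[0]
            else:
                fav = top[0]
            row["most_visited_receiver"] = fav
            fv = v[v["receiver_id"] == fav].sort_values("start")
            gaps_h = (
                (fv["start"].iloc[1:].to_numpy() - fv["end"].iloc[:-1].to_numpy())
                / np.timedelta64(1, "h")
            )
            row["n_visits_most_visited"] = len(fv)
            row["mean_absence_h"] = float(np.mean(gaps_h)) if gaps_h.size else np.nan
            row["max_absence_h"] = float(np.max(gaps_h)) if gaps_h.size else np.nan
            row["absence_undefined"] = gaps_h.size == 0
        else:
            row.update(
                mean_visits_per_day_excl_zero=np.nan,
                max_visits_per_day=0,
                most_visited_receiver=None,
                n_visits_most_visited=0,
                mean_absence_h=np.nan,
                max_absence_h=np.nan,
                absence_undefined=True,
            )
        rows.append(row)
    return pd.DataFrame(rows)
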