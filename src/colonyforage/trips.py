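"""Foraging-trip segmentation and trip-level movement metrics.

Raw GPS fixes of a central-place forager are filtered and cut into foraging
trips: fixes in the overnight logger-off window (23:00-03:00 local time) are
removed, fixes within 500 m of the colony are excluded, and maximal runs of the
remaining fixes form candidate trips, retained when their duration exceeds
14 minutes (short colony departures are treated as disturbance, not foraging).
Trips that span the night window are kept as single trips.

Distances are great-circle (haversine, R = 6371 km); trip duration is the time
from the first to the last retained fix of the trip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import geo
from .errors import UndefinedMetricError

logger = logging.getLogger(__name__)

#: fix classification labels
NIGHT, COLONY, TRIP, SHORT = "night", "colony", "trip", "short"


@dataclass
class Trip:
    """One foraging trip: its retained fixes plus summary metrics."""

    bird_id: str
    trip_id: str
    fixes: pd.DataFrame
    colony_id: str = ""

    def __post_init__(self):
        if len(self.fixes) < 2:
            raise UndefinedMetricError(f"trip {self.trip_id} has fewer than 2 fixes")

    @property
    def start(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[0]

    @property
    def end(self) -> pd.Timestamp:
        return self.fixes["timestamp"].iloc[-1]

    @property
    def duration_hr(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0

    @property
    def total_km(self) -> float:
        lat = self.fixes["lat"].to_numpy()
        lon = self.fixes["lon"].to_numpy()
        return float(np.sum(geo.haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:])))

    @property
    def max_km(self) -> float:
        return float(self.fixes["dist_colony_km"].max())

    @property
    def year(self) -> int:
        return int(self.start.year)


def mask_night(fixes: pd.DataFrame, window=(23, 3), tz: str = "Europe/London") -> pd.DataFrame:
    """Drop fixes whose local clock time falls in the half-open night window.

    The default window [23:00, 03:00) matches the logger battery-saving
    schedule: a fix stamped exactly 23:00:00 is removed, one at 03:00:00 is
    retained.  Times are evaluated in the colony's civil time zone.
    """
    if fixes.empty:
        return fixes
    local = fixes["timestamp"].dt.tz_convert(tz)
    minutes = local.dt.hour * 60 + local.dt.minute + local.dt.second / 60.0
    start, end = window[0] * 60, window[1] * 60
    if start <= end:
        night = (minutes >= start) & (minutes < end)
    else:  # window wraps midnight
        night = (minutes >= start) | (minutes < end)
    n = int(night.sum())
    if n:
        logger.info("night mask removed %d of %d fixes", n, len(fixes))
    return fixes.loc[~night].copy()


def classify_fixes(fixes: pd.DataFrame, colony_latlon, buffer_m: float = 500.0,
                   min_duration_min: float = 14.0, window=(23, 3),
                   tz: str = "Europe/London") -> pd.Series:
    """Classify every fix of one bird exactly once.

    Returns a Series of labels aligned with ``fixes``: ``night`` (in the
    masked window), ``colony`` (within the colony buffer), ``trip`` (member of
    a retained trip) or ``short`` (member of a candidate run not exceeding the
    minimum duration).
    """
    labels = pd.Series(TRIP, index=fixes.index, dtype=object)
    local = fixes["timestamp"].dt.tz_convert(tz)
    minutes = local.dt.hour * 60 + local.dt.minute + local.dt.second / 60.0
    start, end = window[0] * 60, window[1] * 60
    night = (minutes >= start) & (minutes < end) if start <= end else \
        (minutes >= start) | (minutes < end)
    dist = geo.haversine_km(fixes["lat"].to_numpy(), fixes["lon"].to_numpy(),
                            colony_latlon[0], colony_latlon[1])
    colony_prox = (~night) & (np.atleast_1d(dist) <= buffer_m / 1000.0)
    labels[night.to_numpy()] = NIGHT
    labels[colony_prox.to_numpy()] = COLONY
    # runs of candidate (at-sea, day-retained) fixes
    candidate = (labels == TRIP).to_numpy()
    idx = np.flatnonzero(candidate)
    if idx.size:
        # positions among *surviving* (non-night, non-colony) sequence: runs break
        # wherever a colony fix intervenes; night-masked fixes do not break runs
        keep_order = fixes.index[~night.to_numpy()]
        keep_labels = labels.loc[keep_order].to_numpy()
        run_start = None
        runs = []
        for pos, lab in enumerate(keep_labels):
            if lab == TRIP and run_start is None:
                run_start = pos
            elif lab != TRIP and run_start is not None:
                runs.append((run_start, pos))
                run_start = None
        if run_start is not None:
            runs.append((run_start, len(keep_labels)))
        ts = fixes["timestamp"].loc[keep_order].to_numpy()
        for a, b in runs:
            dur_min = (ts[b - 1] - ts[a]) / np.timedelta64(60, "s")
            if not dur_min > min_duration_min:
                labels.loc[keep_order[a:b]] = SHORT
    return labels


def segment_trips(fixes: pd.DataFrame, colony_latlon, buffer_m: float = 500.0,
                  min_duration_min: float = 14.0, night_window=(23, 3),
                  tz: str = "Europe/London", apply_night_mask: bool = True) -> list:
    """Cut one bird's fixes into foraging trips.

    Fixes must be sorted in time and belong to a single bird.  Night-window
    fixes are removed first (set ``apply_night_mask=False`` if the table was
    already masked), colony-buffer fixes are excluded, and maximal runs of the
    remaining fixes whose span exceeds ``min_duration_min`` become trips.  A
    fix at exactly the buffer distance counts as at the colony.
    """
    if fixes.empty:
        return []
    bird = str(fixes["bird_id"].iloc[0])
    colony_id = str(fixes["colony_id"].iloc[0]) if "colony_id" in fixes else ""
    work = fixes
    # when the table was pre-masked, pass an empty window that matches nothing
    labels = classify_fixes(work, colony_latlon, buffer_m=buffer_m,
                            min_duration_min=min_duration_min,
                            window=night_window if apply_night_mask else (0, 0), tz=tz)
    member = work.loc[labels == TRIP].copy()
    if member.empty:
        logger.info("bird %s: no qualifying trips", bird)
        return []
    member["dist_colony_km"] = geo.haversine_km(
        member["lat"].to_numpy(), member["lon"].to_numpy(),
        colony_latlon[0], colony_latlon[1])
    # rebuild run boundaries among retained trip fixes: a new trip starts after
    # any intervening colony fix (night fixes do not split trips)
    non_night = labels.loc[labels != NIGHT]
    run_ids = np.full(len(non_night), -1, dtype=int)
    run = -1
    prev_trip = False
    for pos, lab in enumerate(non_night.to_numpy()):
        if lab == TRIP:
            if not prev_trip:
                run += 1
            run_ids[pos] = run
            prev_trip = True
        else:
            prev_trip = False
    member_runs = pd.Series(run_ids, index=non_night.index).loc[member.index]
    trips = []
    for k in range(run + 1):
        grp = member.loc[member_runs == k]
        if len(grp) < 2:
            continue
        trips.append(Trip(bird_id=bird, trip_id=f"{bird}_t{len(trips):03d}",
                          fixes=grp.reset_index(drop=True), colony_id=colony_id))
    return trips


def trip_metrics(trip: Trip):
    """Duration (hr), total path length (km) and maximum colony distance (km)."""
    if len(trip.fixes) < 2:
        raise UndefinedMetricError(f"trip {trip.trip_id} has fewer than 2 fixes")
    return trip.duration_hr, trip.total_km, trip.max_km


def trips_to_frame(trips) -> pd.DataFrame:
    """One row per trip with its summary metrics."""
    rows = []
    for tr in trips:
        rows.append({
            "bird_id": tr.bird_id, "trip_id": tr.trip_id, "colony_id": tr.colony_id,
            "year": tr.year, "start": tr.start, "end": tr.end, "n_fixes": len(tr.fixes),
            "duration_hr": tr.duration_hr, "total_km": tr.total_km, "max_km": tr.max_km,
        })
    return pd.DataFrame(rows)


def colony_year_summary(trips, level: str = "trip") -> pd.DataFrame:
    """Mean trip metrics per colony-year.

    ``level='trip'`` averages over trips (the default); ``level='bird'`` first
    averages within bird, then across birds, as a sensitivity option.
    """
    frame = trips if isinstance(trips, pd.DataFrame) else trips_to_frame(trips)
    if frame.empty:
        return pd.DataFrame(columns=["colony_id", "year", "n_trips",
                                     "mean_duration_hr", "mean_total_km", "mean_max_km"])
    cols = ["duration_hr", "total_km", "max_km"]
    if level == "bird":
        per_bird = frame.groupby(["colony_id", "year", "bird_id"])[cols].mean().reset_index()
        agg = per_bird.groupby(["colony_id", "year"])[cols].mean()
    elif level == "trip":
        agg = frame.groupby(["colony_id", "year"])[cols].mean()
    else:
        raise ValueError(f"unknown averaging level {level!r}")
    n = frame.groupby(["colony_id", "year"]).size().rename("n_trips")
    out = agg.rename(columns={"duration_hr": "mean_duration_hr",
                              "total_km": "mean_total_km",
                              "max_km": "mean_max_km"}).join(n).reset_index()
    return out


def colony_radius(trips) -> pd.Series:
    """Maximum observed foraging distance per colony across all years (km)."""
    frame = trips if isinstance(trips, pd.DataFrame) else trips_to_frame(trips)
    return frame.groupby("colony_id")["max_km"].max()
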