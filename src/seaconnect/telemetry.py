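"""Adult-movement summaries from acoustic/PSAT detection records.

Positions are consumed as given (no geolocation modelling). Distances are
great-circle legs on a spherical Earth; zone-to-zone connectivity events are
transitions between named, non-overlapping coastal polygons.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, shape
from shapely.prepared import prep

from .geo import haversine_km

__all__ = [
    "TelemetryTrack",
    "track_distances",
    "zone_transitions",
    "annual_distance_km",
    "read_tracks_csv",
    "write_tracks_csv",
    "read_zones_geojson",
]

SOURCES = ("acoustic", "psat")


@dataclass
class TelemetryTrack:
    """One fish's time-ordered detection/position records."""

    fish_id: str
    times: np.ndarray  # datetime64[ns], strictly increasing
    lons: np.ndarray
    lats: np.ndarray
    sources: np.ndarray | None = None
    deployment_days: float | None = None
    position_sd_km: np.ndarray | None = None  # optional per-record uncertainty

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.lons = np.asarray(self.lons, dtype=float)
        self.lats = np.asarray(self.lats, dtype=float)
        n = self.times.size
        if not (self.lons.size == self.lats.size == n):
            raise ValueError("times, lons, lats must have equal length")
        if n > 1 and not np.all(np.diff(self.times) > np.timedelta64(0, "ns")):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(np.abs(self.lats) > 90) or np.any(np.abs(self.lons) > 360):
            raise ValueError("positions outside plausible lon/lat bounds")
        if self.sources is not None:
            self.sources = np.asarray(self.sources, dtype=object)
            bad = set(self.sources) - set(SOURCES)
            if bad:
                raise ValueError(f"unknown sources {bad}")

    def __len__(self):
        return self.times.size


def track_distances(track: TelemetryTrack) -> dict:
    """Cumulative path length, maximum pairwise displacement, and legs (km)."""
    n = len(track)
    if n == 0:
        raise ValueError("track has no records")
    if n == 1:
        return {"cumulative_km": 0.0, "max_displacement_km": 0.0, "legs_km": np.array([])}
    legs = haversine_km(track.lons[:-1], track.lats[:-1], track.lons[1:], track.lats[1:])
    lon = track.lons
    lat = track.lats
    # max displacement over all record pairs
    dmax = 0.0
    for i in range(n - 1):
        d = haversine_km(lon[i], lat[i], lon[i + 1 :], lat[i + 1 :])
        m = float(np.max(d))
        if m > dmax:
            dmax = m
    return {
        "cumulative_km": float(np.sum(legs)),
        "max_displacement_km": dmax,
        "legs_km": np.asarray(legs),
    }


def annual_distance_km(track: TelemetryTrack, window_days: float = 365.0) -> float:
    """Maximum cumulative distance within any sliding window of ``window_days``."""
    n = len(track)
    if n < 2:
        return 0.0
    legs = haversine_km(track.lons[:-1], track.lats[:-1], track.lons[1:], track.lats[1:])
    cum = np.concatenate([[0.0], np.cumsum(legs)])
    t = track.times
    win = np.timedelta64(int(window_days * 86400), "s")
    best = 0.0
    j = 0
    for i in range(n):
        while t[i] - t[j] > win:
            j += 1
        best = max(best, float(cum[i] - cum[j]))
    return best


def zone_transitions(track: TelemetryTrack, zones: dict) -> dict:
    """Classify records by zone and list zone-entry transitions.

    ``zones`` maps name → shapely polygon; zones must not overlap. Records in
    no zone are classified ``offshore``. Transitions are consecutive records
    in different zones; returns the per-record classification, the ordered
    event list, and counts per ordered zone pair.
    """
    names = sorted(zones)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            inter = zones[a].intersection(zones[b])
            if not inter.is_empty and inter.area > 0:
                raise ValueError(f"zones {a!r} and {b!r} overlap")
    prepared = [(n, prep(zones[n])) for n in names]
    labels = []
    for lo, la in zip(track.lons, track.lats):
        z = "offshore"
        pt = Point(lo, la)
        for n, poly in prepared:
            if poly.contains(pt):
                z = n
                break
        labels.append(z)
    events = []
    counts: dict = {}
    for i in range(1, len(labels)):
        if labels[i] != labels[i - 1]:
            ev = (labels[i - 1], labels[i])
            events.append({"time": track.times[i], "from": ev[0], "to": ev[1]})
            counts[ev] = counts.get(ev, 0) + 1
    return {"labels": labels, "events": events, "counts": counts}


# ---- CSV / GeoJSON I/O (fixtures dialect) ----

def write_tracks_csv(tracks, path) -> None:
    rows = []
    for tr in tracks:
        src = tr.sources if tr.sources is not None else ["acoustic"] * len(tr)
        for t, lo, la, s in zip(tr.times, tr.lons, tr.lats, src):
            rows.append({"id": tr.fish_id, "timestamp": pd.Timestamp(t).isoformat(), "lon": lo, "lat": la, "source": s})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks_csv(path) -> list:
    df = pd.read_csv(path, parse_dates=["timestamp"])
    tracks = []
    for fid, sub in df.groupby("id", sort=True):
        sub = sub.sort_values("timestamp")
        tracks.append(
            TelemetryTrack(
                fish_id=str(fid),
                times=sub["timestamp"].to_numpy(),
                lons=sub["lon"].to_numpy(float),
                lats=sub["lat"].to_numpy(float),
                sources=sub["source"].to_numpy(object) if "source" in sub else None,
            )
        )
    return tracks


def read_zones_geojson(path) -> dict:
    with open(path) as fh:
        gj = json.load(fh)
    return {f["properties"]["name"]: shape(f["geometry"]) for f in gj["features"]}


def summarise_tracks(tracks, zones: dict | None = None) -> pd.DataFrame:
    """Per-fish distance summary table (the telemetry stage's main output)."""
    rows = []
    for tr in tracks:
        d = track_distances(tr)
        row = {
            "fish_id": tr.fish_id,
            "n_records": len(tr),
            "cumulative_km": d["cumulative_km"],
            "max_displacement_km": d["max_displacement_km"],
            "annual_km": annual_distance_km(tr),
        }
        if zones:
            row["n_transitions"] = len(zone_transitions(tr, zones)["events"])
        rows.append(row)
    return pd.DataFrame(rows).set_index("fish_id")
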