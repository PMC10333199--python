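"""Rule-based stopover detection and the stopover heat map.

A stopover is a pause for rest or refueling, read off the detection record:
considering only stations more than 50 km from the tagging location, either
(a) detections at a single station spanning strictly more than 4 h with no
intervening detections elsewhere, or (b) detections spanning strictly more
than 6 h among multiple stations all within 30 km of one another (max
pairwise distance — a clique, not a chain). Overlapping qualifying runs are
merged; durations are closed intervals, last minus first detection.
"""

from __future__ import annotations

from datetime import date

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .geo import gc_distance
from .model import Dataset, DetectionBout, Region, Stopover
from .routes import distance_to_region_km


def detect_stopovers(bouts: list[DetectionBout], deployment: pd.Series,
                     station_coords: dict,
                     config: AnalysisConfig | None = None) -> list[Stopover]:
    """Stopovers for one bird from its time-sorted bouts.

    Candidate runs are maximal contiguous bout windows that satisfy either
    the single-station or the clustered multi-station rule; overlapping
    candidates are merged into one stopover. Each bout contributes to at
    most one stopover.
    """
    config = config or AnalysisConfig()
    starts = [b.start for b in bouts]
    if starts != sorted(starts):
        raise ValueError("bouts must be time-sorted")
    dep_lat = float(deployment["deploy_lat"])
    dep_lon = float(deployment["deploy_lon"])

    # eligibility: only far-from-capture bouts are considered at all
    elig = [b for b in bouts
            if gc_distance(dep_lat, dep_lon, *station_coords[b.station_id])
            > config.stopover_min_dist_from_capture_km]
    if not elig:
        return []

    n = len(elig)
    sid = [b.station_id for b in elig]
    pair_km: dict[tuple[str, str], float] = {}

    def st_dist(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in pair_km:
            pair_km[key] = gc_distance(*station_coords[key[0]], *station_coords[key[1]])
        return pair_km[key]

    def span_h(i: int, j: int) -> float:
        return (elig[j].end - elig[i].start).total_seconds() / 3600.0

    qualifying: list[tuple[int, int]] = []  # inclusive index windows

    # single-station rule: maximal same-station runs, span > 4 h
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sid[j + 1] == sid[i]:
            j += 1
        if span_h(i, j) > config.stopover_single_station_h:
            qualifying.append((i, j))
        i = j + 1

    # multi-station rule: from every start, the maximal window whose
    # stations form a <= 30 km clique; qualifies with >= 2 distinct
    # stations and span > 6 h (overlapping windows are merged below)
    for i in range(n):
        stations = {sid[i]}
        j = i
        while j + 1 < n and all(st_dist(sid[j + 1], s) <= config.stopover_station_cluster_km
                                for s in stations):
            j += 1
            stations.add(sid[j])
        if len(stations) >= 2 and span_h(i, j) > config.stopover_multi_station_h:
            qualifying.append((i, j))

    if not qualifying:
        return []

    # merge overlapping index windows
    qualifying.sort()
    merged = [list(qualifying[0])]
    for a, b in qualifying[1:]:
        if a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])

    out = []
    for a, b in merged:
        members = elig[a:b + 1]
        st = frozenset(m.station_id for m in members)
        lats = [station_coords[s][0] for s in sorted(st)]
        lons = [station_coords[s][1] for s in sorted(st)]
        out.append(Stopover(tag_id=members[0].tag_id, stations=st,
                            start=min(m.start for m in members),
                            end=max(m.end for m in members),
                            centroid_lat=float(np.mean(lats)),
                            centroid_lon=float(np.mean(lons))))
    return out


def delaware_stopover_durations(detections: pd.DataFrame, stations: pd.DataFrame,
                                bay: Region,
                                config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per-bird Delaware Bay presence duration.

    Duration in days = (last bay detection - first bay detection) / 86400 s,
    over detections at stations within the bay buffer. Birds with fewer than
    two bay detections are excluded (column ``excluded`` in the companion
    list of skipped tags is not produced; they simply do not appear).
    Returns columns tag_id, first_bay, last_bay, duration_d.
    """
    config = config or AnalysisConfig()
    in_bay = {r.station_id: distance_to_region_km(r.lat, r.lon, bay) <= config.bay_buffer_km
              for r in stations.itertuples(index=False)}
    det = detections[detections["station_id"].map(in_bay).fillna(False)]
    rows = []
    for tag, grp in det.groupby("tag_id", sort=True):
        if len(grp) < 2:
            continue
        first, last = grp["time_utc"].min(), grp["time_utc"].max()
        rows.append({"tag_id": tag, "first_bay": first, "last_bay": last,
                     "duration_d": (last - first).total_seconds() / 86400.0})
    return pd.DataFrame(rows, columns=["tag_id", "first_bay", "last_bay", "duration_d"])


def stopover_heatmap(stopovers: list[Stopover], station_coords: dict,
                     lat_range: tuple[float, float], lon_range: tuple[float, float],
                     cell_deg: float = 0.25, buffer_km: float = 50.0) -> dict:
    """Individual-count stopover grid.

    Cell value = number of distinct individuals with at least one stopover
    station within ``buffer_km`` of the cell center; an individual counts at
    most once per cell however many stopovers it has there. Returns a dict
    with 1-D ``lat_centers``/``lon_centers`` axes and a 2-D ``counts``
    array, plus a ``to_geojson`` -ready feature list under ``features``
    (cells with nonzero counts only).
    """
    lat_centers = np.arange(lat_range[0] + cell_deg / 2, lat_range[1], cell_deg)
    lon_centers = np.arange(lon_range[0] + cell_deg / 2, lon_range[1], cell_deg)
    if len(lat_centers) == 0 or len(lon_centers) == 0:
        raise ValueError("degenerate heat-map grid: zero cells")
    glat, glon = np.meshgrid(lat_centers, lon_centers, indexing="ij")
    counts = np.zeros(glat.shape, dtype=int)

    by_bird: dict[str, set] = {}
    for s in stopovers:
        by_bird.setdefault(s.tag_id, set()).update(s.stations)
    for _tag, st_ids in sorted(by_bird.items()):
        covered = np.zeros(glat.shape, dtype=bool)
        for s in sorted(st_ids):
            lat, lon = station_coords[s]
            covered |= gc_distance(lat, lon, glat, glon) <= buffer_km
        counts += covered

    features = []
    half = cell_deg / 2
    for i, j in zip(*np.nonzero(counts)):
        clat, clon = float(lat_centers[i]), float(lon_centers[j])
        ring = [[clon - half, clat - half], [clon + half, clat - half],
                [clon + half, clat + half], [clon - half, clat + half],
                [clon - half, clat - half]]
        features.append({"type": "Feature",
                         "properties": {"count": int(counts[i, j])},
                         "geometry": {"type": "Polygon", "coordinates": [ring]}})
    return {"lat_centers": lat_centers, "lon_centers": lon_centers,
            "counts": counts,
            "geojson": {"type": "FeatureCollection", "features": features}}


def stopovers_to_frame(stopovers: list[Stopover]) -> pd.DataFrame:
    rows = [{"tag_id": s.tag_id, "stations": ";".join(sorted(s.stations)),
             "start": s.start, "end": s.end, "duration_h": s.duration_h,
             "centroid_lat": s.centroid_lat, "centroid_lon": s.centroid_lon}
            for s in stopovers]
    return pd.DataFrame(rows, columns=["tag_id", "stations", "start", "end",
                                       "duration_h", "centroid_lat", "centroid_lon"])
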