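"""Departure-date estimation under sparse receiver coverage.

With no receiving station near the capture site, most birds' departures
cannot be dated exactly. A bird first detected at a station *inland* within
the Carolinas gets a known departure date (the date of that first away
detection). Every other bird detected away from the capture site gets an
inclusive day-window from its tag-deployment date to its first away
detection, with uniform per-day weights (a 5-day window contributes 0.2 to
each day). Summing weights across birds yields an uncertainty-aware
departure timeline whose total mass equals the number of birds.
"""

from __future__ import annotations

from datetime import date, timedelta
from fractions import Fraction

import pandas as pd

from .config import AnalysisConfig
from .geo import gc_distance
from .model import Dataset, DepartureEstimate, DetectionBout, Region


def _bout_station_coords(bout: DetectionBout, coords: dict) -> tuple[float, float]:
    try:
        return coords[bout.station_id]
    except KeyError:
        raise KeyError(f"bout references unknown station {bout.station_id!r}")


def estimate_departure(bouts: list[DetectionBout], deployment: pd.Series,
                       regions: list[Region],
                       config: AnalysisConfig | None = None,
                       station_coords: dict | None = None) -> DepartureEstimate | None:
    """Departure estimate for one bird, or None if it was never detected
    away from the capture site.

    ``bouts`` must be this bird's QC'd bouts in time order; ``deployment``
    a row of the deployments table. "Away from the capture site" means a
    station more than ``stopover_min_dist_from_capture_km`` from the
    deployment coordinates. If the first away bout is inside an
    ``inland_carolinas`` region the departure date is known (that bout's
    start date); otherwise the bird gets a uniform window from deployment
    date to first-away date, both inclusive.
    """
    config = config or AnalysisConfig()
    if station_coords is None:
        raise ValueError("station_coords (station_id -> (lat, lon)) is required")
    starts = [b.start for b in bouts]
    if starts != sorted(starts):
        raise ValueError("bouts must be time-sorted")

    inland = next((r for r in regions if r.role == "inland_carolinas"), None)
    dep_lat, dep_lon = float(deployment["deploy_lat"]), float(deployment["deploy_lon"])
    deploy_date = pd.Timestamp(deployment["deploy_time_utc"]).date()

    first_away = None
    for b in bouts:
        if b.start < pd.Timestamp(deployment["deploy_time_utc"]):
            continue
        lat, lon = _bout_station_coords(b, station_coords)
        if gc_distance(dep_lat, dep_lon, lat, lon) > config.stopover_min_dist_from_capture_km:
            first_away = (b, lat, lon)
            break
    if first_away is None:
        return None

    bout, lat, lon = first_away
    away_date = bout.start.date()
    if inland is not None:
        from shapely.geometry import Point
        if inland.geometry.covers(Point(lon, lat)):
            return DepartureEstimate(tag_id=bout.tag_id, kind="known",
                                     known_date=away_date,
                                     weights={away_date: 1.0})
    n_days = (away_date - deploy_date).days + 1  # both endpoints inclusive
    if n_days == 1:
        return DepartureEstimate(tag_id=bout.tag_id, kind="known",
                                 known_date=away_date, weights={away_date: 1.0})
    w = Fraction(1, n_days)
    weights = {deploy_date + timedelta(days=i): float(w) for i in range(n_days)}
    # uniform weights as floats can miss 1.0 by an ulp; renormalize exactly
    total = sum(weights.values())
    weights = {d: v / total for d, v in weights.items()}
    return DepartureEstimate(tag_id=bout.tag_id, kind="window",
                             window_start=deploy_date, window_end=away_date,
                             weights=weights)


def departure_timeline(estimates: list[DepartureEstimate]) -> dict[date, float]:
    """Sum per-day departure weights across birds.

    The returned mapping (sorted by date) has total mass equal to the number
    of contributing birds; days in nobody's window are absent (weight 0).
    """
    if not estimates:
        raise ValueError("need at least one departure estimate")
    timeline: dict[date, float] = {}
    for est in estimates:
        for d, w in est.weights.items():
            timeline[d] = timeline.get(d, 0.0) + w
    return dict(sorted(timeline.items()))


def weighted_median_date(timeline: dict[date, float]) -> date:
    """Smallest date at which cumulative normalized timeline mass >= 0.5."""
    total = sum(timeline.values())
    if total <= 0:
        raise ValueError("timeline has no mass")
    acc = 0.0
    for d in sorted(timeline):
        acc += timeline[d] / total
        if acc >= 0.5 - 1e-12:
            return d
    return max(timeline)  # pragma: no cover (float safety net)


def estimates_to_frame(estimates: list[DepartureEstimate]) -> pd.DataFrame:
    rows = []
    for e in estimates:
        rows.append({
            "tag_id": e.tag_id, "kind": e.kind,
            "known_date": e.known_date.isoformat() if e.known_date else "",
            "window_start": e.window_start.isoformat() if e.window_start else "",
            "window_end": e.window_end.isoformat() if e.window_end else "",
        })
    return pd.DataFrame(rows, columns=["tag_id", "kind", "known_date",
                                       "window_start", "window_end"])


def timeline_to_frame(timeline: dict[date, float]) -> pd.DataFrame:
    return pd.DataFrame({"date": [d.isoformat() for d in sorted(timeline)],
                         "weight_sum": [timeline[d] for d in sorted(timeline)]})
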