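"""Delaware Bay use classification: stopped / skipped spectrum.

Each bird's post-deployment detection history is scored by an ordered,
total decision tree:

1. *stopped* — at least two bay-region bouts whose detections span more
   than ``min_stop_days``;
2. *likely_stopped* — at least two bouts just outside the bay buffer
   (within ``likely_buffer_km`` beyond it) spanning two or more calendar
   days;
3. *skipped* — detected north of the bay with too little slack time for a
   stop: elapsed time between the last detection at/below the bay's
   maximum latitude and the first detection above it, minus the minimum
   transit time at ``assumed_transit_speed_ms``, is under ``min_stop_days``;
4. *likely_skipped* — the same northern evidence with enough slack, but an
   inland trajectory (intermediate detections in the Great Lakes Basin or
   far west of the Atlantic coastline) inconsistent with a mid-Atlantic
   coastal stop;
5. *unknown* — anything else.

Stations "in the bay" are those within ``bay_buffer_km`` of the Delaware
Bay watershed polygon.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from shapely.geometry import Point

from .config import AnalysisConfig
from .geo import distance_to_ring_km, gc_distance
from .model import Dataset, DetectionBout, Region, StrategyCall


def _boundary_rings(geometry):
    geoms = getattr(geometry, "geoms", [geometry])
    for g in geoms:
        if g.geom_type == "Polygon":
            yield list(g.exterior.coords)
            for hole in g.interiors:
                yield list(hole.coords)
        else:  # LineString boundary
            yield list(g.coords)


def distance_to_region_km(lat: float, lon: float, region: Region) -> float:
    """Great-circle distance (km) from a point to a region; 0 inside it."""
    if region.geometry.is_empty:
        raise ValueError(f"region {region.name!r} is empty")
    if region.geometry.geom_type in ("Polygon", "MultiPolygon") and \
            region.geometry.covers(Point(lon, lat)):
        return 0.0
    return min(distance_to_ring_km(lat, lon, ring)
               for ring in _boundary_rings(region.geometry))


def region_membership(lat: float, lon: float, region: Region,
                      buffer_km: float = 0.0) -> bool:
    """True iff the point is inside the region or within ``buffer_km`` of it."""
    return distance_to_region_km(lat, lon, region) <= buffer_km


def classify_delaware_strategy(bouts: list[DetectionBout], deployment: pd.Series,
                               regions: list[Region], station_coords: dict,
                               config: AnalysisConfig | None = None) -> StrategyCall:
    """Score one bird's Delaware Bay use. See module docstring for the tree.

    Only bouts between deployment and the end of the migration season
    (``migration_season_end``, same year as deployment) are considered.
    Raises ValueError when the bird has no post-deployment bouts.
    """
    config = config or AnalysisConfig()
    bay = next((r for r in regions if r.role == "delaware_bay"), None)
    lakes = next((r for r in regions if r.role == "great_lakes"), None)
    coast = next((r for r in regions if r.name == "atlantic_coast"), None)
    if bay is None:
        raise ValueError("no delaware_bay region supplied")

    deploy_time = pd.Timestamp(deployment["deploy_time_utc"])
    mm, dd = (int(x) for x in config.migration_season_end.split("-"))
    season_end = pd.Timestamp(year=deploy_time.year, month=mm, day=dd,
                              tz="UTC") + pd.Timedelta(days=1)
    bouts = [b for b in bouts if deploy_time <= b.start < season_end]
    if not bouts:
        raise ValueError(f"tag {deployment['tag_id']}: no post-deployment bouts in season")
    bouts = sorted(bouts, key=lambda b: (b.start, b.station_id))
    tag = bouts[0].tag_id

    # per-station geometry, computed once
    st_ids = sorted({b.station_id for b in bouts})
    dist_bay = {s: distance_to_region_km(*station_coords[s], bay) for s in st_ids}
    lat_of = {s: station_coords[s][0] for s in st_ids}
    bay_max_lat = bay.max_lat

    bay_bouts = [b for b in bouts if dist_bay[b.station_id] <= config.bay_buffer_km]
    annulus_bouts = [b for b in bouts
                     if config.bay_buffer_km < dist_bay[b.station_id]
                     <= config.bay_buffer_km + config.likely_buffer_km]

    evidence: dict = {"n_bay_bouts": len(bay_bouts), "n_annulus_bouts": len(annulus_bouts)}

    # (1) stopped: >= 2 bay bouts spanning > min_stop_days
    if len(bay_bouts) >= 2:
        span_d = (max(b.end for b in bay_bouts)
                  - min(b.start for b in bay_bouts)).total_seconds() / 86400.0
        evidence["bay_span_days"] = span_d
        if span_d > config.min_stop_days:
            return StrategyCall(tag_id=tag, strategy="stopped", evidence=evidence)

    # (2) likely_stopped: >= 2 bouts just outside the bay over >= 2 calendar days
    if len(annulus_bouts) >= 2:
        days = {b.start.date() for b in annulus_bouts} | {b.end.date() for b in annulus_bouts}
        evidence["annulus_calendar_days"] = len(days)
        if len(days) >= 2:
            return StrategyCall(tag_id=tag, strategy="likely_stopped", evidence=evidence)

    # northern evidence: last detection at/below the bay's max latitude and
    # first detection above it
    north_idx = next((i for i, b in enumerate(bouts) if lat_of[b.station_id] > bay_max_lat), None)
    if north_idx is not None and north_idx > 0:
        south = bouts[north_idx - 1]
        north = bouts[north_idx]
        elapsed_s = (north.start - south.end).total_seconds()
        dist_km = gc_distance(*station_coords[south.station_id],
                              *station_coords[north.station_id])
        min_transit_s = dist_km * 1000.0 / config.assumed_transit_speed_ms
        slack_d = (elapsed_s - min_transit_s) / 86400.0
        evidence.update({"south_station": south.station_id, "north_station": north.station_id,
                         "slack_days": slack_d})
        # any bay presence must look like a fly-through: all bay detections
        # within min_stop_days (rule 1 already caught multi-bout long spans,
        # but a single bout can span days under continuous coverage)
        if bay_bouts:
            bay_span_d = (max(b.end for b in bay_bouts)
                          - min(b.start for b in bay_bouts)).total_seconds() / 86400.0
            bay_flythrough_ok = bay_span_d <= config.min_stop_days
        else:
            bay_flythrough_ok = True
        # (3) skipped: no time for a bay stop
        if slack_d < config.min_stop_days and bay_flythrough_ok:
            return StrategyCall(tag_id=tag, strategy="skipped", evidence=evidence)
        # (4) likely_skipped: slack exists but the route ran inland
        if slack_d >= config.min_stop_days and bay_flythrough_ok:
            inter = bouts[:north_idx]  # detections before crossing north
            inland = []
            for b in inter:
                lat, lon = station_coords[b.station_id]
                in_lakes = lakes is not None and region_membership(lat, lon, lakes)
                west_of_coast = (coast is not None and
                                 _west_of_coastline(lat, lon, coast, config.inland_offset_km))
                inland.append(in_lakes or west_of_coast)
            evidence["all_intermediate_inland"] = bool(inland) and all(inland)
            if evidence["all_intermediate_inland"]:
                return StrategyCall(tag_id=tag, strategy="likely_skipped", evidence=evidence)

    return StrategyCall(tag_id=tag, strategy="unknown", evidence=evidence)


def _west_of_coastline(lat: float, lon: float, coast: Region, offset_km: float) -> bool:
    """True when the point sits more than offset_km west of the coastline."""
    if distance_to_region_km(lat, lon, coast) <= offset_km:
        return False
    # west test: coastline longitude at the nearest vertex latitude
    coords = np.concatenate([np.asarray(ring) for ring in _boundary_rings(coast.geometry)])
    nearest = coords[np.argmin(np.abs(coords[:, 1] - lat))]
    return lon < nearest[0]


def summarize_strategies(calls: list[StrategyCall]) -> dict:
    """Counts of the five classes plus pooled proportions.

    Proportions pool stopped+likely_stopped and skipped+likely_skipped and
    use only classifiable (non-unknown) birds as the denominator. With no
    classifiable birds the proportions are None and ``undefined`` is set.
    """
    if not calls:
        raise ValueError("need at least one strategy call")
    counts = {s: 0 for s in ("stopped", "likely_stopped", "skipped", "likely_skipped", "unknown")}
    for c in calls:
        counts[c.strategy] += 1
    n_stop = counts["stopped"] + counts["likely_stopped"]
    n_skip = counts["skipped"] + counts["likely_skipped"]
    n_class = n_stop + n_skip
    out = {"counts": counts, "n_birds": len(calls), "n_classifiable": n_class,
           "n_stopped_pooled": n_stop, "n_skipped_pooled": n_skip}
    if n_class == 0:
        out.update({"prop_stopped_pooled": None, "prop_skipped_pooled": None,
                    "undefined": True})
    else:
        out.update({"prop_stopped_pooled": n_stop / n_class,
                    "prop_skipped_pooled": n_skip / n_class, "undefined": False})
    return out


def oneway_anova(groups: list[np.ndarray]) -> dict:
    """Classical one-way fixed-effects ANOVA from sums of squares.

    Returns F, df, p (upper tail of the F distribution) and R^2 = SSB/SST.
    Raises ValueError when every group is constant (F undefined).
    """
    from scipy.stats import f as f_dist
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    n_i = np.array([len(g) for g in groups])
    means = np.array([g.mean() for g in groups])
    grand = np.concatenate(groups).mean()
    ssb = float(np.sum(n_i * (means - grand) ** 2))
    ssw = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b, df_w = len(groups) - 1, int(n_i.sum()) - len(groups)
    if ssw == 0.0:
        if ssb == 0.0:
            raise ValueError("all observations identical: F undefined")
        return {"F": np.inf, "df": (df_b, df_w), "p": 0.0, "r2": 1.0,
                "group_means": means.tolist(), "group_n": n_i.tolist()}
    F = (ssb / df_b) / (ssw / df_w)
    return {"F": F, "df": (df_b, df_w), "p": float(f_dist.sf(F, df_b, df_w)),
            "r2": ssb / (ssb + ssw),
            "group_means": means.tolist(), "group_n": n_i.tolist()}


def mass_by_strategy(deployments: pd.DataFrame, calls: list[StrategyCall]) -> dict:
    """Body mass at capture vs pooled migration strategy.

    Groups birds into stopped-pooled / skipped-pooled / unknown, drops birds
    without a recorded mass, and runs a one-way ANOVA. Also reports pairwise
    mean differences between groups.
    """
    mass = deployments.set_index("tag_id")["body_mass_g"]
    by_group: dict[str, list[float]] = {}
    for c in calls:
        m = mass.get(c.tag_id, np.nan)
        if pd.notna(m):
            by_group.setdefault(c.pooled, []).append(float(m))
    usable = {k: np.array(v) for k, v in sorted(by_group.items()) if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError("need >= 2 strategy groups with >= 2 massed birds each")
    res = oneway_anova(list(usable.values()))
    res["groups"] = list(usable.keys())
    names = list(usable.keys())
    res["mean_differences"] = {
        f"{a}-{b}": float(usable[a].mean() - usable[b].mean())
        for i, a in enumerate(names) for b in names[i + 1:]}
    return res


def calls_to_frame(calls: list[StrategyCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append({"tag_id": c.tag_id, "strategy": c.strategy, "pooled": c.pooled,
                     "n_bay_bouts": c.evidence.get("n_bay_bouts", 0),
                     "bay_span_days": c.evidence.get("bay_span_days", np.nan),
                     "slack_days": c.evidence.get("slack_days", np.nan)})
    return pd.DataFrame(rows, columns=["tag_id", "strategy", "pooled", "n_bay_bouts",
                                       "bay_span_days", "slack_days"])
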