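"""End-to-end pipeline runner and study report assembly.

``run_pipeline`` chains detection QC, bout grouping, departure timing,
Delaware Bay strategy classification, stopover detection, flight extraction
and wind support on a loaded :class:`~rufatrack.model.Dataset`;
``build_report`` condenses the results into one JSON-serializable summary
whose every number is reproducible from the per-stage tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .departure import (departure_timeline, estimate_departure, estimates_to_frame,
                        timeline_to_frame, weighted_median_date)
from .kinematics import extract_flights, flights_to_frame
from .model import Dataset
from .qc import bout_detections, bouts_to_frame, filter_detections
from .routes import (calls_to_frame, classify_delaware_strategy, mass_by_strategy,
                     summarize_strategies)
from .stopover import (delaware_stopover_durations, detect_stopovers,
                       stopover_heatmap, stopovers_to_frame)
from .wind import speed_wind_association, supports_to_frame, wind_support_for_flights


def simple_ols(x, y) -> dict:
    """Closed-form simple least squares of y on x.

    Returns slope, intercept, the t statistic for the slope (slope / SE),
    df = n - 2, two-sided p, and R^2. Raises on constant x or n < 3.
    """
    from scipy.stats import t as t_dist
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    sxx = float((xc ** 2).sum())
    if sxx == 0.0:
        raise ValueError("constant x: slope undefined")
    slope = float((xc * (y - y.mean())).sum() / sxx)
    intercept = float(y.mean() - slope * x.mean())
    resid = y - (intercept + slope * x)
    sse = float((resid ** 2).sum())
    sst = float(((y - y.mean()) ** 2).sum())
    df = n - 2
    if sse == 0.0:
        return {"slope": slope, "intercept": intercept, "t": np.inf if slope != 0 else 0.0,
                "df": df, "p": 0.0 if slope != 0 else 1.0, "r2": 1.0 if sst > 0 else 0.0}
    se = np.sqrt(sse / df / sxx)
    t = slope / se
    return {"slope": slope, "intercept": intercept, "t": float(t), "df": df,
            "p": float(2 * t_dist.sf(abs(t), df)), "r2": (1.0 - sse / sst) if sst > 0 else 0.0}


@dataclass
class PipelineResult:
    """All per-stage outputs of one pipeline run."""

    qc_report: object
    valid_detections: pd.DataFrame
    bouts_by_tag: dict
    departures: list
    timeline: dict
    calls: list
    stopovers: list
    bay_durations: pd.DataFrame
    heatmap: Optional[dict]
    flights: list
    supports: list
    excluded_tags: dict = field(default_factory=dict)   # tag -> reason

    def tables(self) -> dict[str, pd.DataFrame]:
        from .qc import bouts_to_frame
        all_bouts = [b for bs in self.bouts_by_tag.values() for b in bs]
        return {
            "bouts": bouts_to_frame(all_bouts),
            "departures": estimates_to_frame(self.departures),
            "timeline": timeline_to_frame(self.timeline) if self.timeline
            else pd.DataFrame(columns=["date", "weight_sum"]),
            "strategies": calls_to_frame(self.calls),
            "stopovers": stopovers_to_frame(self.stopovers),
            "delaware_durations": self.bay_durations,
            "flights": flights_to_frame(self.flights),
            "wind_support": supports_to_frame(self.supports),
        }


def run_pipeline(ds: Dataset, config: AnalysisConfig | None = None,
                 heatmap_bounds: tuple | None = None) -> PipelineResult:
    """Run every analysis stage on a validated dataset.

    ``heatmap_bounds`` is ((lat0, lat1), (lon0, lon1)); when None it is
    taken from the station extent padded by 1 degree.
    """
    config = config or AnalysisConfig()
    coords = ds.station_coords()
    valid, qc_rep = filter_detections(ds.detections, ds.deployments, config)
    bouts = bout_detections(valid, config)
    by_tag: dict[str, list] = {}
    for b in bouts:
        by_tag.setdefault(b.tag_id, []).append(b)
    for tag in by_tag:
        by_tag[tag].sort(key=lambda b: (b.start, b.station_id))

    bay = ds.region("delaware_bay")
    departures, calls, stopovers = [], [], []
    excluded: dict[str, str] = {}
    for row in ds.deployments.sort_values("tag_id").itertuples(index=False):
        tag = row.tag_id
        dep = pd.Series(row._asdict())
        tag_bouts = by_tag.get(tag, [])
        if not tag_bouts:
            excluded[tag] = "never detected"
            continue
        est = estimate_departure(tag_bouts, dep, ds.regions, config, station_coords=coords)
        if est is None:
            excluded[tag] = "never detected away from capture site"
        else:
            departures.append(est)
        if bay is not None:
            try:
                calls.append(classify_delaware_strategy(tag_bouts, dep, ds.regions,
                                                        coords, config))
            except ValueError:
                excluded.setdefault(tag, "no in-season bouts")
        stopovers.extend(detect_stopovers(tag_bouts, dep, coords, config))

    timeline = departure_timeline(departures) if departures else {}
    bay_dur = (delaware_stopover_durations(valid, ds.stations, bay, config)
               if bay is not None else pd.DataFrame(columns=["tag_id", "first_bay",
                                                             "last_bay", "duration_d"]))
    heat = None
    if stopovers:
        if heatmap_bounds is None:
            lat0, lat1 = ds.stations["lat"].min() - 1, ds.stations["lat"].max() + 1
            lon0, lon1 = ds.stations["lon"].min() - 1, ds.stations["lon"].max() + 1
        else:
            (lat0, lat1), (lon0, lon1) = heatmap_bounds
        heat = stopover_heatmap(stopovers, coords, (lat0, lat1), (lon0, lon1),
                                cell_deg=config.heatmap_cell_deg,
                                buffer_km=config.heatmap_buffer_km)

    flights = []
    for tag in sorted(by_tag):
        flights.extend(extract_flights(by_tag[tag], coords, config))
    supports = (wind_support_for_flights(flights, ds.wind, coords)
                if ds.wind is not None and flights else [])

    return PipelineResult(qc_report=qc_rep, valid_detections=valid, bouts_by_tag=by_tag,
                          departures=departures, timeline=timeline, calls=calls,
                          stopovers=stopovers, bay_durations=bay_dur, heatmap=heat,
                          flights=flights, supports=supports, excluded_tags=excluded)


def build_report(res: PipelineResult, deployments: pd.DataFrame) -> dict:
    """Assemble the study summary from a pipeline result.

    Sections with too little data are marked ``{"insufficient_data": true}``
    rather than omitted, so report structure is stable. Deterministic:
    identical inputs produce identical output.
    """
    report: dict = {
        "qc": {"n_input": res.qc_report.n_input, "n_valid": res.qc_report.n_valid,
               "rejected": dict(sorted(res.qc_report.n_rejected_by_rule.items()))},
        "metadata": {"weighted_median_rule": "smallest date with cumulative mass >= 0.5"},
        "excluded": dict(sorted(res.excluded_tags.items())),
    }

    # strategies and per-strategy departure timelines
    if res.calls:
        report["strategies"] = summarize_strategies(res.calls)
        pooled_of = {c.tag_id: c.pooled for c in res.calls}
        panels = {}
        for pool in ("stopped", "unknown", "skipped"):
            ests = [e for e in res.departures if pooled_of.get(e.tag_id) == pool]
            if ests:
                tl = departure_timeline(ests)
                panels[pool] = {"n_birds": len(ests),
                                "weighted_median": weighted_median_date(tl).isoformat()}
        report["departure_panels"] = panels
    else:
        report["strategies"] = {"insufficient_data": True}

    if res.timeline:
        report["departures"] = {
            "n_birds": len(res.departures),
            "n_known": sum(1 for e in res.departures if e.kind == "known"),
            "total_mass": float(sum(res.timeline.values())),
            "weighted_median": weighted_median_date(res.timeline).isoformat(),
        }
    else:
        report["departures"] = {"insufficient_data": True}

    # Delaware Bay stopover durations and duration-vs-arrival regression
    d = res.bay_durations
    if len(d) >= 1:
        dur = d["duration_d"].to_numpy(float)
        report["delaware_stopover"] = {
            "n": int(len(dur)), "mean_d": float(dur.mean()),
            "sd_d": float(dur.std(ddof=1)) if len(dur) > 1 else None,
            "median_d": float(np.median(dur)),
            "range_d": [float(dur.min()), float(dur.max())],
        }
        if len(dur) >= 3:
            arrival_doy = d["first_bay"].dt.dayofyear.to_numpy(float)
            if np.ptp(arrival_doy) > 0:
                report["delaware_stopover"]["duration_vs_arrival_ols"] = \
                    simple_ols(arrival_doy, dur)
    else:
        report["delaware_stopover"] = {"insufficient_data": True}

    report["stopovers"] = {
        "n_events": len(res.stopovers),
        "n_birds": len({s.tag_id for s in res.stopovers}),
    }

    if res.flights:
        tot = np.array([f.total_length_km for f in res.flights])
        disp = np.array([f.displacement_km for f in res.flights])
        spd = np.array([f.net_ground_speed_ms for f in res.flights])
        report["flights"] = {
            "n_flights": len(res.flights),
            "n_birds": len({f.tag_id for f in res.flights}),
            "total_length_km": {"median": float(np.median(tot)),
                                "range": [float(tot.min()), float(tot.max())]},
            "displacement_km": {"median": float(np.median(disp)),
                                "range": [float(disp.min()), float(disp.max())]},
            "ground_speed_ms": {"mean": float(spd.mean()), "median": float(np.median(spd))},
        }
    else:
        report["flights"] = {"insufficient_data": True}

    if len(res.supports) >= 3:
        report["wind"] = speed_wind_association(res.flights, res.supports)
    else:
        report["wind"] = {"insufficient_data": True}

    # body mass vs pooled strategy
    try:
        report["mass_by_strategy"] = mass_by_strategy(deployments, res.calls)
    except ValueError as err:
        report["mass_by_strategy"] = {"insufficient_data": True, "reason": str(err)}
    return report
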