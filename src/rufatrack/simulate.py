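"""Synthetic study generator with known ground truth.

Emulates the study design end to end: a sparse automated-telemetry network
(no receiving station near the capture site, a Delaware Bay cluster, a Great
Lakes corridor, an Atlantic coastal corridor and subarctic end stations),
birds following strategy-specific great-circle routes whose per-leg ground
speed is airspeed plus a tailwind coupling plus noise, probabilistic
detection within receiver range on the tag's exact burst-interval lattice,
Poisson false-positive detections with aperiodic times, and a smooth
6-hourly gridded wind field.

Every quantity the pipeline estimates is recorded as truth: strategy,
departure time, stopovers, and per-leg speeds with the tailwind used to
generate them. Tracks are piecewise great-circle segments with constant
per-leg speed, matching the pipeline's own kinematic assumptions so truth is
computable in closed form. Fixing the seed fixes every output byte; each
bird draws from its own substream, so adding a bird never perturbs another's
trajectory.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Polygon

from .config import AnalysisConfig
from .geo import gc_distance, gc_interpolate, initial_bearing
from .model import Dataset, Region, WindField
from .wind import sample_wind, tailwind_support

CAPTURE_LAT, CAPTURE_LON = 32.54, -80.17  # nearshore island, coastal South Carolina

# id -> (lat, lon); the base network leaves a > 150 km gap around the capture
# site, mirroring the near-total absence of coastal receivers there
BASE_STATIONS = {
    "SC_INLAND": (33.95, -81.12),     # inland South Carolina
    "NC_COAST": (34.70, -76.70),
    "VA_COAST": (37.10, -75.90),
    "CHESAPEAKE": (37.80, -76.20),
    "DB_1": (39.05, -75.40),          # Delaware Bay cluster
    "DB_2": (39.20, -75.10),
    "DB_3": (38.95, -74.95),
    "NJ_COAST": (40.20, -74.00),
    "NY_BAY": (40.55, -73.95),
    "CAPE_COD": (41.70, -70.10),
    "LAKE_ERIE": (42.20, -80.10),     # Great Lakes corridor
    "LAKE_ONT": (43.30, -77.60),
    "LAKE_HURON": (44.50, -81.30),
    "JAMES_BAY": (52.20, -80.60),
    "HUDSON_BAY": (55.30, -82.30),
}

# strategy routes as waypoint names; "CAPTURE" is the deployment location,
# "(stop)" suffix marks a stopover waypoint
ROUTES = {
    "stopped": ["CAPTURE", "VA_COAST", "DB_1(stop)", "NJ_COAST", "CAPE_COD"],
    "skipped": ["CAPTURE", "SC_INLAND", "LAKE_ERIE", "LAKE_HURON", "JAMES_BAY"],
    "atlantic_chesapeake": ["CAPTURE", "NC_COAST", "CHESAPEAKE(stop)", "NY_BAY", "CAPE_COD"],
    "atlantic_nybay": ["CAPTURE", "NC_COAST", "NY_BAY(stop)", "CAPE_COD"],
}

# legs whose midpoints get an extra station under dense coverage
DENSE_MIDPOINT_LEGS = [("SC_INLAND", "LAKE_ERIE"), ("LAKE_HURON", "JAMES_BAY"),
                       ("NC_COAST", "CHESAPEAKE"), ("VA_COAST", "DB_1")]

SPARSE_DROP = {"SC_INLAND", "VA_COAST", "CHESAPEAKE", "LAKE_ERIE", "DB_3"}


@dataclass
class SimScenario:
    """Generator configuration; defaults encode the study conditions."""

    seed: int = 0
    n_stopped: int = 12
    n_skipped: int = 20
    n_atlantic: int = 8
    coverage: str = "default"            # sparse | default | dense
    detection_range_km: float = 15.0
    p_detect: float = 0.8                # per transmitted burst in range
    false_positive_rate: float = 1.0     # Poisson mean per station-day
    airspeed_mean_ms: float = 16.0
    airspeed_sd_ms: float = 1.0
    wind_coupling: float = 1.0
    speed_noise_ms: float = 2.0
    u_mean_ms: float = 2.0               # background southwesterly flow
    v_mean_ms: float = 3.0
    wind_perturb_ms: float = 4.0
    wind_max_ms: float = 25.0
    year: int = 2019
    stationary_cluster_period_s: float = 3600.0
    stationary_cluster_len: int = 6
    freq_offset_sd_khz: float = 1.0

    def __post_init__(self):
        for p in (self.p_detect,):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.false_positive_rate < 0:
            raise ValueError("false_positive_rate must be >= 0")
        if self.coverage not in ("sparse", "default", "dense"):
            raise ValueError(f"unknown coverage level {self.coverage!r}")

    @property
    def n_birds(self) -> int:
        return self.n_stopped + self.n_skipped + self.n_atlantic


@dataclass
class SimResult:
    """In-memory generator output: a loadable Dataset plus ground truth."""

    dataset: Dataset
    truth: list[dict]
    is_true_detection: np.ndarray     # parallels dataset.detections rows

    def truth_by_tag(self) -> dict[str, dict]:
        return {t["tag_id"]: t for t in self.truth}


def station_table(coverage: str = "default") -> pd.DataFrame:
    st = dict(BASE_STATIONS)
    if coverage == "dense":
        for a, b in DENSE_MIDPOINT_LEGS:
            lat, lon = gc_interpolate(*BASE_STATIONS[a], *BASE_STATIONS[b], 0.5)
            st[f"MID_{a}_{b}"] = (float(lat), float(lon))
    elif coverage == "sparse":
        st = {k: v for k, v in st.items() if k not in SPARSE_DROP}
    rows = [{"station_id": k, "lat": v[0], "lon": v[1],
             "active_from": pd.NaT, "active_to": pd.NaT}
            for k, v in sorted(st.items())]
    return pd.DataFrame(rows)


def make_regions() -> list[Region]:
    """Synthetic stand-ins for the analysis regions (idealized rectangles
    and a simplified coastline polyline; not survey-accurate geometries)."""

    def box(lat0, lat1, lon0, lon1):
        return Polygon([(lon0, lat0), (lon1, lat0), (lon1, lat1), (lon0, lat1)])

    coast = LineString([(-80.8, 32.0), (-78.0, 33.8), (-75.5, 35.2), (-76.0, 36.9),
                        (-74.9, 38.9), (-74.0, 40.5), (-70.0, 41.3)])
    return [
        Region("delaware_bay_watershed", "delaware_bay", box(38.8, 39.8, -75.8, -74.8)),
        Region("great_lakes_basin", "great_lakes", box(41.5, 49.0, -93.0, -76.0)),
        Region("inland_carolinas", "inland_carolinas", box(33.5, 36.5, -83.5, -79.5)),
        Region("capture_zone", "capture_zone",
               box(CAPTURE_LAT - 0.4, CAPTURE_LAT + 0.4, CAPTURE_LON - 0.4, CAPTURE_LON + 0.4)),
        Region("atlantic_coast", "other", coast),
    ]


def simulate_wind(seed: int, scenario: SimScenario | None = None,
                  lat_range=(25.0, 60.0), lon_range=(-95.0, -60.0),
                  step_deg: float = 2.5) -> WindField:
    """Smooth 6-hourly synthetic wind grid: mean flow plus low-order
    spatial-temporal harmonics with random phases, bounded by wind_max_ms."""
    sc = scenario or SimScenario()
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 7]))
    lats = np.arange(lat_range[0], lat_range[1] + step_deg / 2, step_deg)
    lons = np.arange(lon_range[0], lon_range[1] + step_deg / 2, step_deg)
    t0 = pd.Timestamp(f"{sc.year}-04-20T00:00:00Z")
    t1 = pd.Timestamp(f"{sc.year}-06-16T00:00:00Z")
    times = pd.date_range(t0, t1, freq="6h").tz_localize(None).values
    th = (times - times[0]) / np.timedelta64(1, "h")
    LA, LO = np.meshgrid(lats, lons, indexing="ij")

    def harmonics():
        """Sum of traveling waves (synoptic systems crossing the grid every
        few days), rescaled so the field's pointwise sd = wind_perturb_ms."""
        f = np.zeros((len(times), len(lats), len(lons)))
        TH = th[:, None, None]
        for amp, period_h, llat, llon in ((1.0, 96.0, 25.0, 30.0),
                                          (0.6, 42.0, 12.0, 15.0),
                                          (0.4, 18.0, 6.0, 8.0)):
            p = rng.uniform(0, 2 * np.pi, size=2)
            f += amp * np.sin(2 * np.pi * (LA[None] / llat + TH / period_h) + p[0]) \
                * np.cos(2 * np.pi * (LO[None] / llon - TH / (1.7 * period_h)) + p[1])
        sd = f.std()
        if sd > 0 and sc.wind_perturb_ms > 0:
            f *= sc.wind_perturb_ms / sd
        return f if sc.wind_perturb_ms > 0 else np.zeros_like(f)

    u = np.clip(sc.u_mean_ms + harmonics(), -sc.wind_max_ms, sc.wind_max_ms)
    v = np.clip(sc.v_mean_ms + harmonics(), -sc.wind_max_ms, sc.wind_max_ms)
    return WindField(times=times, lats=lats, lons=lons, u=u, v=v)


def _ts(epoch_s: float) -> pd.Timestamp:
    return pd.Timestamp(epoch_s, unit="s", tz="UTC")


def _epoch(ts: pd.Timestamp) -> float:
    return ts.value / 1e9


@dataclass
class _Segment:
    t0: float
    t1: float
    lat0: float
    lon0: float
    lat1: float
    lon1: float
    moving: bool

    def position(self, t):
        """Position at epoch time(s) t (clipped to the segment)."""
        if not self.moving or self.t1 <= self.t0:
            f = np.zeros_like(np.asarray(t, float))
        else:
            f = np.clip((np.asarray(t, float) - self.t0) / (self.t1 - self.t0), 0, 1)
        return gc_interpolate(self.lat0, self.lon0, self.lat1, self.lon1, f)


def _build_track(strategy: str, route: list[str], t_depart: float,
                 wind: WindField, rng: np.random.Generator, sc: SimScenario,
                 deploy_t: float, stop_days_fn) -> tuple[list[_Segment], dict]:
    """Piecewise great-circle track plus the bird's truth record."""
    airspeed = rng.normal(sc.airspeed_mean_ms, sc.airspeed_sd_ms)
    waypoints = []
    for name in route:
        stop = name.endswith("(stop)")
        base = name.removesuffix("(stop)")
        # waypoints are fixed geography: birds fly the same route whether or
        # not a receiving station is operating there (sparse coverage)
        lat, lon = (CAPTURE_LAT, CAPTURE_LON) if base == "CAPTURE" else BASE_STATIONS[base]
        waypoints.append({"name": base, "lat": lat, "lon": lon, "stop": stop})

    segments = [_Segment(deploy_t, t_depart, CAPTURE_LAT, CAPTURE_LON,
                         CAPTURE_LAT, CAPTURE_LON, moving=False)]
    truth = {"strategy": strategy, "departure_time": _ts(t_depart).isoformat(),
             "departure_date": _ts(t_depart).date().isoformat(),
             "stopovers": [], "legs": []}
    t = t_depart
    for a, b in zip(waypoints, waypoints[1:]):
        dist_km = gc_distance(a["lat"], a["lon"], b["lat"], b["lon"])
        bearing = initial_bearing(a["lat"], a["lon"], b["lat"], b["lon"])
        u, w = sample_wind(wind, _ts(t), a["lat"], a["lon"])
        tail = tailwind_support(u, w, bearing)
        speed = max(6.0, airspeed + sc.wind_coupling * tail + rng.normal(0, sc.speed_noise_ms))
        t_end = t + dist_km * 1000.0 / speed
        segments.append(_Segment(t, t_end, a["lat"], a["lon"], b["lat"], b["lon"], moving=True))
        truth["legs"].append({"from": a["name"], "to": b["name"],
                              "t_start": _ts(t).isoformat(), "t_end": _ts(t_end).isoformat(),
                              "distance_km": float(dist_km), "speed_ms": float(speed),
                              "tailwind_ms": float(tail), "bearing_deg": float(bearing),
                              "airspeed_ms": float(airspeed)})
        t = t_end
        if b["stop"]:
            stop_s = stop_days_fn(t) * 86400.0
            segments.append(_Segment(t, t + stop_s, b["lat"], b["lon"],
                                     b["lat"], b["lon"], moving=False))
            truth["stopovers"].append({"station": b["name"], "start": _ts(t).isoformat(),
                                       "end": _ts(t + stop_s).isoformat(),
                                       "duration_d": stop_s / 86400.0})
            t += stop_s
    return segments, truth


def _emit_detections(tag_id: str, segments: list[_Segment], st_df: pd.DataFrame,
                     burst_interval: float, phase: float, rng: np.random.Generator,
                     sc: SimScenario) -> list[dict]:
    """Detections of one bird: bursts on the tag's interval lattice, kept
    with probability p_detect while the true position is within range."""
    out = []
    st_ids = st_df["station_id"].to_numpy()
    st_lat = st_df["lat"].to_numpy()
    st_lon = st_df["lon"].to_numpy()

    def lattice(lo: float, hi: float) -> np.ndarray:
        k0 = int(np.ceil((lo - phase) / burst_interval))
        k1 = int(np.floor((hi - phase) / burst_interval))
        if k1 < k0:
            return np.empty(0)
        return phase + np.arange(k0, k1 + 1) * burst_interval

    def record(times: np.ndarray, lats: np.ndarray, lons: np.ndarray) -> None:
        """Exact range check + detection draw for candidate burst times."""
        d = gc_distance(lats[:, None], lons[:, None], st_lat[None, :], st_lon[None, :])
        hit_t, hit_s = np.nonzero(d <= sc.detection_range_km)
        for ti, si in zip(hit_t, hit_s):
            if rng.random() > sc.p_detect:
                continue
            out.append({"tag_id": tag_id, "station_id": st_ids[si],
                        "time_utc": _ts(times[ti]),
                        "n_pulses": 3,
                        "freq_offset_khz": float(rng.normal(0, sc.freq_offset_sd_khz)),
                        "signal": float(-60.0 - 1.5 * d[ti, si] + rng.normal(0, 3.0))})

    for seg in segments:
        if not seg.moving:
            dist0 = gc_distance(seg.lat0, seg.lon0, st_lat, st_lon)
            if not np.any(dist0 <= sc.detection_range_km):
                continue
            # stationary: sparse duty-cycled clusters of consecutive bursts
            for c0 in np.arange(seg.t0, seg.t1, sc.stationary_cluster_period_s):
                t = lattice(c0, min(c0 + sc.stationary_cluster_len * burst_interval, seg.t1))
                if len(t):
                    lat, lon = seg.position(t)
                    record(t, np.atleast_1d(lat), np.atleast_1d(lon))
        else:
            # coarse 60 s scan to find in-range windows, then exact bursts
            n = max(2, int((seg.t1 - seg.t0) / 60.0) + 1)
            ts = np.linspace(seg.t0, seg.t1, n)
            lat, lon = seg.position(ts)
            d = gc_distance(np.asarray(lat)[:, None], np.asarray(lon)[:, None],
                            st_lat[None, :], st_lon[None, :])
            near_any = (d <= sc.detection_range_km + 2.0).any(axis=1)
            if not near_any.any():
                continue
            idx = np.nonzero(near_any)[0]
            # contiguous index windows
            brk = np.nonzero(np.diff(idx) > 1)[0]
            for w in np.split(idx, brk + 1):
                lo = max(seg.t0, ts[w[0]] - 120.0)
                hi = min(seg.t1, ts[w[-1]] + 120.0)
                t = lattice(lo, hi)
                if len(t):
                    plat, plon = seg.position(t)
                    record(t, np.atleast_1d(plat), np.atleast_1d(plon))
    return out


def _false_positives(st_df: pd.DataFrame, tag_ids: list[str], t0: float, t1: float,
                     rng: np.random.Generator, sc: SimScenario) -> list[dict]:
    """Spurious decodes: Poisson per station-day, random tag id, 1-3 pulses,
    continuous (aperiodic) times, broad frequency offsets."""
    out = []
    n_days = int(np.ceil((t1 - t0) / 86400.0))
    for row in st_df.itertuples(index=False):
        n = rng.poisson(sc.false_positive_rate * n_days)
        times = np.sort(rng.uniform(t0, t1, size=n))
        for t in times:
            out.append({"tag_id": tag_ids[rng.integers(len(tag_ids))],
                        "station_id": row.station_id,
                        "time_utc": _ts(float(t)),
                        "n_pulses": int(rng.choice([1, 2, 3], p=[0.4, 0.3, 0.3])),
                        "freq_offset_khz": float(rng.normal(0, 8.0)),
                        "signal": float(rng.normal(-95.0, 5.0))})
    return out


def simulate_scenario(scenario: SimScenario | None = None,
                      seed: int | None = None) -> SimResult:
    """Generate a full synthetic study: stations, deployments, regions,
    wind, detections (true + false positives) and per-bird ground truth."""
    sc = scenario or SimScenario()
    if seed is not None:
        sc = dataclasses.replace(sc, seed=int(seed))
    st_df = station_table(sc.coverage)
    stations = {r.station_id: (r.lat, r.lon) for r in st_df.itertuples(index=False)}
    regions = make_regions()
    wind = simulate_wind(sc.seed, sc)

    strategies = (["stopped"] * sc.n_stopped + ["skipped"] * sc.n_skipped
                  + ["atlantic"] * sc.n_atlantic)
    deployments, truth, det_rows, true_flags = [], [], [], []

    for i, strat in enumerate(strategies):
        rng = np.random.default_rng(np.random.SeedSequence([int(sc.seed), 1000 + i]))
        tag = f"T{i + 1:03d}"
        bi = round(float(rng.uniform(4.7, 11.3)), 1)
        deploy_day = int(rng.integers(0, 14))  # Apr 25 .. May 8
        deploy = _epoch(pd.Timestamp(f"{sc.year}-04-25T14:00:00Z")) + deploy_day * 86400.0
        depart = deploy + rng.uniform(1.0, 5.0) * 86400.0
        # morning departures keep the first inland detection on the true date
        dd = _ts(depart)
        depart = _epoch(pd.Timestamp(dd.date().isoformat() + "T00:00:00Z")) \
            + rng.uniform(6.0, 10.0) * 3600.0
        if depart <= deploy:
            depart += 86400.0

        if strat == "stopped":
            route = ROUTES["stopped"]
            mass = rng.normal(131.0, 12.0)

            def stop_days(t_arr, _rng=rng):
                doy = _ts(t_arr).dayofyear
                return float(np.clip(_rng.normal(14.0 - 0.7 * (doy - 125), 2.5), 1.5, 17.0))
        elif strat == "skipped":
            route = ROUTES["skipped"]
            mass = rng.normal(140.0, 12.0)
            stop_days = None
        else:
            route = ROUTES["atlantic_chesapeake" if i % 2 == 0 else "atlantic_nybay"]
            mass = rng.normal(133.0, 12.0)

            def stop_days(t_arr, _rng=rng):
                return float(_rng.uniform(2.0, 10.0))

        segments, t_rec = _build_track(strat, route, depart, wind, rng, sc,
                                       deploy, stop_days)
        t_rec["tag_id"] = tag
        t_rec["pooled"] = "stopped" if strat == "stopped" else "skipped"
        t_rec["unambiguous"] = strat in ("stopped", "skipped")
        truth.append(t_rec)
        deployments.append({"tag_id": tag, "burst_interval_s": bi,
                            "nominal_freq_mhz": 166.38, "deploy_time_utc": _ts(deploy),
                            "deploy_lat": CAPTURE_LAT, "deploy_lon": CAPTURE_LON,
                            "body_mass_g": round(float(max(95.0, mass)), 1),
                            "age_class": "adult", "site": "capture_island"})
        phase = deploy + float(rng.uniform(0, bi))
        dets = _emit_detections(tag, segments, st_df, bi, phase, rng, sc)
        det_rows.extend(dets)
        true_flags.extend([True] * len(dets))

    if sc.false_positive_rate > 0 and deployments:
        rng_fp = np.random.default_rng(np.random.SeedSequence([int(sc.seed), 13]))
        t0 = _epoch(pd.Timestamp(f"{sc.year}-04-25T00:00:00Z"))
        t1 = _epoch(pd.Timestamp(f"{sc.year}-06-15T00:00:00Z"))
        fps = _false_positives(st_df, [d["tag_id"] for d in deployments], t0, t1, rng_fp, sc)
        det_rows.extend(fps)
        true_flags.extend([False] * len(fps))

    det = pd.DataFrame(det_rows, columns=["tag_id", "station_id", "time_utc",
                                          "n_pulses", "freq_offset_khz", "signal"])
    flags = np.asarray(true_flags, dtype=bool)
    if len(det):
        order = np.lexsort((det["station_id"].to_numpy(), det["time_utc"].to_numpy(),
                            det["tag_id"].to_numpy()))
        det = det.iloc[order].reset_index(drop=True)
        flags = flags[order]

    dep_df = pd.DataFrame(deployments, columns=["tag_id", "burst_interval_s",
                                                "nominal_freq_mhz", "deploy_time_utc",
                                                "deploy_lat", "deploy_lon", "body_mass_g",
                                                "age_class", "site"])
    ds = Dataset(stations=st_df, deployments=dep_df, detections=det,
                 regions=regions, wind=wind)
    return SimResult(dataset=ds, truth=truth, is_true_detection=flags)


def write_scenario(result: SimResult, out_dir: str | Path,
                   wind_format: str = "nc") -> dict[str, Path]:
    """Write the generated study to disk in the pipeline's input formats."""
    from . import io as rio
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"stations": out / "stations.csv", "deployments": out / "deployments.csv",
             "detections": out / "detections.csv", "regions": out / "regions.geojson",
             "wind": out / ("wind.nc" if wind_format == "nc" else "wind.csv"),
             "truth": out / "truth.json"}
    rio.write_stations(result.dataset.stations, paths["stations"])
    rio.write_deployments(result.dataset.deployments, paths["deployments"])
    rio.write_detections(result.dataset.detections, paths["detections"])
    rio.write_regions(result.dataset.regions, paths["regions"])
    rio.write_wind(result.dataset.wind, paths["wind"])
    with open(paths["truth"], "w") as fh:
        json.dump(result.truth, fh, indent=1)
    return paths
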