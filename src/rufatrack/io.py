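"""Readers, writers and dataset validation.

File formats: plain CSV for the three tabular inputs, GeoJSON for regions,
CF-style NetCDF (or a long-format CSV fallback) for the wind grid. All
timestamps are ISO-8601 UTC in files and timezone-aware ``datetime64`` in
memory; no local-time arithmetic happens anywhere in the package.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import shape, mapping

from .config import AnalysisConfig
from .model import (DEPLOYMENT_COLUMNS, DETECTION_COLUMNS, STATION_COLUMNS,
                    AGE_CLASSES, Dataset, Region, ReferentialIntegrityError,
                    SchemaError, WindField)


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {missing}")


def _parse_utc(series: pd.Series, what: str, allow_na: bool = False) -> pd.Series:
    out = pd.to_datetime(series, utc=True, format="ISO8601", errors="coerce")
    bad = out.isna() & series.notna() & (series.astype(str).str.strip() != "")
    if bad.any():
        raise SchemaError(f"{what}: unparseable timestamp(s) at rows {list(series.index[bad])[:5]}")
    if not allow_na and out.isna().any():
        raise SchemaError(f"{what}: missing timestamp(s)")
    return out


def read_stations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"station_id": str})
    _require_columns(df, ["station_id", "lat", "lon"], "stations.csv")
    for c in ("active_from", "active_to"):
        if c not in df.columns:
            df[c] = pd.NaT
        else:
            df[c] = _parse_utc(df[c], f"stations.csv {c}", allow_na=True)
    df["lat"] = pd.to_numeric(df["lat"])
    df["lon"] = pd.to_numeric(df["lon"])
    return df[STATION_COLUMNS]


def read_deployments(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tag_id": str, "site": str})
    _require_columns(df, ["tag_id", "burst_interval_s", "deploy_time_utc",
                          "deploy_lat", "deploy_lon"], "deployments.csv")
    df["deploy_time_utc"] = _parse_utc(df["deploy_time_utc"], "deployments.csv deploy_time_utc")
    for c, default in (("nominal_freq_mhz", np.nan), ("body_mass_g", np.nan),
                       ("age_class", "unknown"), ("site", "")):
        if c not in df.columns:
            df[c] = default
    df["age_class"] = df["age_class"].fillna("unknown")
    bad_age = ~df["age_class"].isin(AGE_CLASSES)
    if bad_age.any():
        raise SchemaError(f"deployments.csv: invalid age_class {df.loc[bad_age, 'age_class'].unique()}")
    if (df["burst_interval_s"] <= 0).any():
        raise SchemaError("deployments.csv: burst_interval_s must be > 0")
    if (df["body_mass_g"].dropna() <= 0).any():
        raise SchemaError("deployments.csv: body_mass_g must be > 0 when present")
    return df[DEPLOYMENT_COLUMNS]


def read_detections(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"tag_id": str, "station_id": str})
    _require_columns(df, ["tag_id", "station_id", "time_utc", "n_pulses"], "detections.csv")
    df["time_utc"] = _parse_utc(df["time_utc"], "detections.csv time_utc")
    df["n_pulses"] = pd.to_numeric(df["n_pulses"], downcast=None).astype(int)
    if (df["n_pulses"] < 1).any():
        raise SchemaError("detections.csv: n_pulses must be >= 1")
    for c in ("freq_offset_khz", "signal"):
        if c not in df.columns:
            df[c] = np.nan
        else:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    return df[DETECTION_COLUMNS]


def read_regions(path: str | Path) -> list[Region]:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise SchemaError("regions.geojson: expected a FeatureCollection")
    regions = []
    for feat in gj["features"]:
        props = feat.get("properties") or {}
        if "name" not in props or "role" not in props:
            raise SchemaError("regions.geojson: every feature needs properties.name and .role")
        regions.append(Region(name=props["name"], role=props["role"],
                              geometry=shape(feat["geometry"])))
    return regions


def read_wind(path: str | Path) -> WindField:
    """Read a wind grid from NetCDF (variables u, v on time/lat/lon) or
    from a long-format CSV with columns time, lat, lon, u, v."""
    path = Path(path)
    if path.suffix == ".nc":
        import xarray as xr
        with xr.open_dataset(path, engine="scipy") as ds:
            ds.load()
        return WindField(times=ds["time"].values, lats=ds["lat"].values,
                         lons=ds["lon"].values, u=ds["u"].values, v=ds["v"].values,
                         pressure_level_hpa=float(ds.attrs.get("pressure_level_hpa", 1000.0)))
    df = pd.read_csv(path)
    _require_columns(df, ["time", "lat", "lon", "u", "v"], "wind csv")
    df["time"] = _parse_utc(df["time"], "wind csv time")
    times = np.sort(df["time"].unique())
    lats = np.sort(df["lat"].unique())
    lons = np.sort(df["lon"].unique())
    if len(df) != len(times) * len(lats) * len(lons):
        raise SchemaError("wind csv: not a complete regular time x lat x lon grid")
    df = df.sort_values(["time", "lat", "lon"])
    shape3 = (len(times), len(lats), len(lons))
    times = pd.DatetimeIndex(times).tz_convert("UTC").tz_localize(None).values
    return WindField(times=times, lats=lats, lons=lons,
                     u=df["u"].to_numpy().reshape(shape3),
                     v=df["v"].to_numpy().reshape(shape3))


def write_wind(wind: WindField, path: str | Path) -> None:
    path = Path(path)
    if path.suffix == ".nc":
        import xarray as xr
        ds = xr.Dataset(
            {"u": (("time", "lat", "lon"), wind.u), "v": (("time", "lat", "lon"), wind.v)},
            coords={"time": wind.times, "lat": wind.lats, "lon": wind.lons},
            attrs={"pressure_level_hpa": wind.pressure_level_hpa},
        )
        ds.to_netcdf(path, engine="scipy")  # NETCDF3 classic
        return
    t, la, lo = np.meshgrid(wind.times, wind.lats, wind.lons, indexing="ij")
    pd.DataFrame({
        "time": pd.to_datetime(t.ravel()).tz_localize("UTC").strftime("%Y-%m-%dT%H:%M:%SZ"),
        "lat": la.ravel(), "lon": lo.ravel(),
        "u": wind.u.ravel(), "v": wind.v.ravel(),
    }).to_csv(path, index=False)


def load_dataset(detections_path: str | Path,
                 stations_path: str | Path,
                 deployments_path: str | Path,
                 regions_path: Optional[str | Path] = None,
                 wind_path: Optional[str | Path] = None) -> Dataset:
    """Load and cross-validate all inputs.

    Raises :class:`SchemaError` for missing columns or uncoercible values and
    :class:`ReferentialIntegrityError` when detections reference a station or
    tag absent from the master tables.
    """
    stations = read_stations(stations_path)
    deployments = read_deployments(deployments_path)
    detections = read_detections(detections_path)
    regions = read_regions(regions_path) if regions_path else []
    wind = read_wind(wind_path) if wind_path else None

    unknown_st = set(detections["station_id"]) - set(stations["station_id"])
    if unknown_st:
        raise ReferentialIntegrityError(
            f"detections reference unknown station(s): {sorted(unknown_st)}")
    unknown_tag = set(detections["tag_id"]) - set(deployments["tag_id"])
    if unknown_tag:
        raise ReferentialIntegrityError(
            f"detections reference unknown tag(s): {sorted(unknown_tag)}")
    return Dataset(stations=stations, deployments=deployments,
                   detections=detections, regions=regions, wind=wind)


def validate_dataset(ds: Dataset) -> pd.DataFrame:
    """Non-fatal consistency report.

    Returns a DataFrame with columns (severity, code, message, tag_id,
    station_id); empty when everything is consistent. Flags coordinates out
    of range, detections before tag deployment, and detections outside a
    station's activity period (validated but, by default, never filtered on).
    """
    rows = []

    def add(severity, code, message, tag_id="", station_id=""):
        rows.append({"severity": severity, "code": code, "message": message,
                     "tag_id": tag_id, "station_id": station_id})

    for r in ds.stations.itertuples(index=False):
        if not (-90 <= r.lat <= 90) or not (-180 <= r.lon < 180):
            add("error", "coord_out_of_range",
                f"station {r.station_id} at ({r.lat}, {r.lon})", station_id=r.station_id)
        if pd.notna(r.active_from) and pd.notna(r.active_to) and r.active_from > r.active_to:
            add("error", "activity_period_inverted",
                f"station {r.station_id} active_from after active_to", station_id=r.station_id)
    for r in ds.deployments.itertuples(index=False):
        if not (-90 <= r.deploy_lat <= 90) or not (-180 <= r.deploy_lon < 180):
            add("error", "coord_out_of_range",
                f"deployment {r.tag_id} at ({r.deploy_lat}, {r.deploy_lon})", tag_id=r.tag_id)

    deploy_time = ds.deployments.set_index("tag_id")["deploy_time_utc"]
    det = ds.detections.merge(ds.stations[["station_id", "active_from", "active_to"]],
                              on="station_id", how="left")
    det["deploy_time"] = det["tag_id"].map(deploy_time)
    pre = det["time_utc"] < det["deploy_time"]
    for r in det[pre].itertuples(index=False):
        add("warning", "pre_deployment_detection",
            f"tag {r.tag_id} detected at {r.time_utc} before deployment {r.deploy_time}",
            tag_id=r.tag_id, station_id=r.station_id)
    inactive = (det["active_from"].notna() & (det["time_utc"] < det["active_from"])) | \
               (det["active_to"].notna() & (det["time_utc"] > det["active_to"]))
    for r in det[inactive].itertuples(index=False):
        add("warning", "detection_outside_station_activity",
            f"tag {r.tag_id} detected at inactive station {r.station_id} at {r.time_utc}",
            tag_id=r.tag_id, station_id=r.station_id)
    return pd.DataFrame(rows, columns=["severity", "code", "message", "tag_id", "station_id"])


def _iso(ts) -> str:
    if ts is None or (isinstance(ts, float) and np.isnan(ts)) or pd.isna(ts):
        return ""
    return pd.Timestamp(ts).tz_convert("UTC").strftime("%Y-%m-%dT%H:%M:%SZ")


def write_stations(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    for c in ("active_from", "active_to"):
        out[c] = out[c].map(_iso)
    out.sort_values("station_id").to_csv(path, index=False)


def write_deployments(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["deploy_time_utc"] = out["deploy_time_utc"].map(_iso)
    out.sort_values("tag_id").to_csv(path, index=False)


def write_detections(df: pd.DataFrame, path: str | Path) -> None:
    out = df.copy()
    out["time_utc"] = out["time_utc"].map(_iso)
    out.sort_values(["tag_id", "time_utc", "station_id"]).to_csv(path, index=False)


def write_regions(regions: list[Region], path: str | Path) -> None:
    gj = {"type": "FeatureCollection",
          "features": [{"type": "Feature",
                        "properties": {"name": r.name, "role": r.role},
                        "geometry": mapping(r.geometry)} for r in regions]}
    with open(path, "w") as fh:
        json.dump(gj, fh, indent=1)


def write_results(out_dir: str | Path, *, tables: dict[str, pd.DataFrame] | None = None,
                  summary: dict | None = None,
                  heatmap_geojson: dict | None = None) -> list[Path]:
    """Write analysis outputs deterministically.

    ``tables`` maps file stem -> DataFrame (written as <stem>.csv with rows
    ordered by tag_id then time where those columns exist); ``summary`` is
    dumped to summary.json with sorted keys; ``heatmap_geojson`` to
    heatmap.geojson. Returns the list of written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for stem, df in (tables or {}).items():
        df = df.copy()
        order = [c for c in ("tag_id", "time_utc", "start", "depart_time", "station_id")
                 if c in df.columns]
        if order:
            df = df.sort_values(order, kind="mergesort")
        for c in df.columns:
            if pd.api.types.is_datetime64_any_dtype(df[c]):
                df[c] = df[c].map(_iso)
        p = out_dir / f"{stem}.csv"
        df.to_csv(p, index=False)
        written.append(p)
    if summary is not None:
        p = out_dir / "summary.json"
        with open(p, "w") as fh:
            json.dump(summary, fh, indent=1, sort_keys=True, default=_json_default)
        written.append(p)
    if heatmap_geojson is not None:
        p = out_dir / "heatmap.geojson"
        with open(p, "w") as fh:
            json.dump(heatmap_geojson, fh, indent=1)
        written.append(p)
    return written


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, pd.Timestamp):
        return _iso(o)
    if isinstance(o, (set, frozenset, tuple)):
        return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
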