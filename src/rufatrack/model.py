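"""Core domain types.

Tabular inputs (stations, tag deployments, detections) are held as pandas
DataFrames with UTC ``datetime64`` timestamps and validated schemas; the
geographic and meteorological objects get small dataclasses. A ``Dataset``
bundles everything one analysis run needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from shapely.geometry import MultiPolygon, Polygon
from shapely.geometry.base import BaseGeometry

REGION_ROLES = ("delaware_bay", "great_lakes", "inland_carolinas", "capture_zone", "other")
AGE_CLASSES = ("adult", "second_year", "unknown")
STRATEGIES = ("stopped", "likely_stopped", "skipped", "likely_skipped", "unknown")

STATION_COLUMNS = ["station_id", "lat", "lon", "active_from", "active_to"]
DEPLOYMENT_COLUMNS = ["tag_id", "burst_interval_s", "nominal_freq_mhz", "deploy_time_utc",
                      "deploy_lat", "deploy_lon", "body_mass_g", "age_class", "site"]
DETECTION_COLUMNS = ["tag_id", "station_id", "time_utc", "n_pulses", "freq_offset_khz", "signal"]


class SchemaError(ValueError):
    """A required column is missing or a value fails type coercion."""


class ReferentialIntegrityError(ValueError):
    """A record references an entity absent from its master table."""


@dataclass
class Region:
    """Named lat/lon polygon with an analysis role.

    ``geometry`` is a shapely (Multi)Polygon in GeoJSON axis order
    (x = lon, y = lat); LineString geometries are allowed for role
    ``other`` (e.g. a coastline used in route classification).
    """

    name: str
    role: str
    geometry: BaseGeometry

    def __post_init__(self):
        if self.role not in REGION_ROLES:
            raise ValueError(f"unknown region role {self.role!r}")
        if self.geometry.is_empty:
            raise ValueError(f"region {self.name!r} has empty geometry")
        if isinstance(self.geometry, (Polygon, MultiPolygon)) and not self.geometry.is_valid:
            raise ValueError(f"region {self.name!r} polygon is invalid (self-intersecting?)")

    @property
    def max_lat(self) -> float:
        return float(self.geometry.bounds[3])


@dataclass
class WindField:
    """Gridded u/v surface wind (m/s) on a regular lat/lon/time grid.

    u is the eastward and v the northward wind component (the vector points
    where the air moves TO, reanalysis convention), by default at the
    1000 hPa pressure level.
    """

    times: np.ndarray          # datetime64[ns], strictly increasing
    lats: np.ndarray           # strictly monotone
    lons: np.ndarray           # strictly monotone
    u: np.ndarray              # (time, lat, lon)
    v: np.ndarray
    pressure_level_hpa: float = 1000.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype="datetime64[ns]")
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        expected = (len(self.times), len(self.lats), len(self.lons))
        if self.u.shape != expected or self.v.shape != expected:
            raise ValueError(f"wind array shape {self.u.shape} != axes {expected}")
        for name, ax in (("times", self.times.astype("int64")),
                         ("lats", self.lats), ("lons", self.lons)):
            d = np.diff(ax)
            if not (np.all(d > 0) or np.all(d < 0)):
                raise ValueError(f"wind axis {name} must be strictly monotone")


@dataclass
class Dataset:
    """All validated inputs for one analysis run."""

    stations: pd.DataFrame
    deployments: pd.DataFrame
    detections: pd.DataFrame
    regions: list[Region] = field(default_factory=list)
    wind: Optional[WindField] = None

    def region(self, role: str) -> Optional[Region]:
        """First region with the given role, or None."""
        for r in self.regions:
            if r.role == role:
                return r
        return None

    def region_by_name(self, name: str) -> Optional[Region]:
        for r in self.regions:
            if r.name == name:
                return r
        return None

    def station_coords(self) -> dict[str, tuple[float, float]]:
        """Map station_id -> (lat, lon)."""
        return {row.station_id: (row.lat, row.lon)
                for row in self.stations.itertuples(index=False)}


@dataclass(frozen=True)
class DetectionBout:
    """Contiguous run of valid detections of one tag at one station."""

    tag_id: str
    station_id: str
    start: pd.Timestamp
    end: pd.Timestamp
    n_detections: int

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("bout start after end")
        if self.n_detections < 1:
            raise ValueError("bout needs at least one detection")

    @property
    def span_s(self) -> float:
        return (self.end - self.start).total_seconds()


@dataclass
class QCReport:
    """Accounting of the detection-filter pipeline."""

    n_input: int
    n_rejected_by_rule: dict[str, int]
    n_valid: int

    def __post_init__(self):
        if self.n_input != self.n_valid + sum(self.n_rejected_by_rule.values()):
            raise ValueError("QC counts do not conserve detections")


@dataclass
class DepartureEstimate:
    """Known departure date or an inclusive day-window with uniform weights."""

    tag_id: str
    kind: str                      # "known" | "window"
    known_date: Optional[pd.Timestamp] = None       # normalized to date
    window_start: Optional[pd.Timestamp] = None
    window_end: Optional[pd.Timestamp] = None
    weights: dict = field(default_factory=dict)     # date -> fraction

    def __post_init__(self):
        if self.kind not in ("known", "window"):
            raise ValueError(f"bad departure kind {self.kind!r}")
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"departure weights sum to {total}, not 1")
        if self.kind == "known" and len(self.weights) != 1:
            raise ValueError("known departure must carry a single unit weight")


@dataclass
class StrategyCall:
    """Delaware Bay use classification for one bird, with evidence."""

    tag_id: str
    strategy: str
    evidence: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")

    @property
    def pooled(self) -> str:
        """stopped/likely_stopped -> 'stopped'; skipped/likely_skipped -> 'skipped'."""
        if self.strategy in ("stopped", "likely_stopped"):
            return "stopped"
        if self.strategy in ("skipped", "likely_skipped"):
            return "skipped"
        return "unknown"


@dataclass
class Stopover:
    """A detected stopover: one or more clustered stations, a time span."""

    tag_id: str
    stations: frozenset
    start: pd.Timestamp
    end: pd.Timestamp
    centroid_lat: float
    centroid_lon: float

    @property
    def duration_h(self) -> float:
        return (self.end - self.start).total_seconds() / 3600.0


@dataclass
class FlightTrajectory:
    """A migratory flight between two receiving stations >= 150 km apart.

    Departure is the LAST detection at the beginning station; arrival the
    FIRST detection at the ending station. Displacement is the orthodrome
    between the two end stations; total length sums great-circle legs over
    every station passed.
    """

    tag_id: str
    station_sequence: tuple
    depart_time: pd.Timestamp
    arrive_time: pd.Timestamp
    total_length_km: float
    displacement_km: float

    def __post_init__(self):
        if self.arrive_time <= self.depart_time:
            raise ValueError("flight must have positive duration")
        if self.displacement_km > self.total_length_km + 1e-6:
            raise ValueError("displacement exceeds total path length")

    @property
    def duration_h(self) -> float:
        return (self.arrive_time - self.depart_time).total_seconds() / 3600.0

    @property
    def net_ground_speed_ms(self) -> float:
        return self.displacement_km * 1000.0 / (self.duration_h * 3600.0)


@dataclass
class WindSupportResult:
    """Wind sampled at flight departure, projected on the preferred bearing."""

    tag_id: str
    flight_index: int
    u_ms: float
    v_ms: float
    preferred_bearing_deg: float
    tailwind_ms: float

    @property
    def is_tailwind(self) -> bool:
        return self.tailwind_ms > 0.0
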