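"""Wind sampling and tailwind support.

For each migratory flight, surface wind (u eastward, v northward, m/s, by
default the 1000 hPa level) is sampled at the departure station at the grid
time closest to departure, then projected onto the preferred direction of
movement — the great-circle bearing to the ending station:

    tailwind = u * sin(beta) + v * cos(beta)

Positive values support the flight; any wind within 90 degrees of the
direction of movement is a tailwind (winds from just south of east through
just south of west all assist a due-north flight).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .kinematics import flight_bearing
from .model import FlightTrajectory, WindField, WindSupportResult


class OutOfDomainError(ValueError):
    """Query point or time outside the wind grid."""


def _nearest_time_index(times: np.ndarray, when: pd.Timestamp) -> int:
    t64 = np.datetime64(pd.Timestamp(when).tz_convert("UTC").tz_localize(None), "ns")
    diffs = np.abs((times - t64).astype("timedelta64[ns]").astype(np.int64))
    # ties -> earlier slice
    step = np.diff(times).min().astype("timedelta64[ns]").astype(np.int64) if len(times) > 1 else 0
    lo, hi = times.min() - step, times.max() + step
    if t64 < lo or t64 > hi:
        raise OutOfDomainError(f"time {when} outside wind grid range +/- one step")
    best = int(np.argmin(diffs))  # argmin returns the first (earlier) index on ties
    return best


def sample_wind(wind: WindField, when: pd.Timestamp, lat: float, lon: float,
                mode: str = "bilinear") -> tuple[float, float]:
    """Sample (u, v) m/s at a point and time.

    Nearest time slice (ties resolve to the earlier slice); spatial
    interpolation bilinear by default, or ``mode='nearest'`` for the
    nearest grid node. Raises :class:`OutOfDomainError` outside the grid.
    """
    ti = _nearest_time_index(wind.times, when)
    lats, lons = wind.lats, wind.lons
    sl = slice(None) if lats[0] <= lats[-1] else slice(None, None, -1)
    sn = slice(None) if lons[0] <= lons[-1] else slice(None, None, -1)
    la, lo = lats[sl], lons[sn]
    u2, v2 = wind.u[ti][sl, :][:, sn], wind.v[ti][sl, :][:, sn]
    if not (la[0] <= lat <= la[-1]) or not (lo[0] <= lon <= lo[-1]):
        raise OutOfDomainError(f"point ({lat}, {lon}) outside wind grid extent")
    if mode == "nearest":
        i = int(np.argmin(np.abs(la - lat)))
        j = int(np.argmin(np.abs(lo - lon)))
        return float(u2[i, j]), float(v2[i, j])
    if mode != "bilinear":
        raise ValueError(f"unknown sampling mode {mode!r}")
    i = int(np.clip(np.searchsorted(la, lat) - 1, 0, len(la) - 2))
    j = int(np.clip(np.searchsorted(lo, lon) - 1, 0, len(lo) - 2))
    fy = (lat - la[i]) / (la[i + 1] - la[i])
    fx = (lon - lo[j]) / (lo[j + 1] - lo[j])

    def bilin(g):
        return float((1 - fy) * (1 - fx) * g[i, j] + (1 - fy) * fx * g[i, j + 1]
                     + fy * (1 - fx) * g[i + 1, j] + fy * fx * g[i + 1, j + 1])

    return bilin(u2), bilin(v2)


def tailwind_support(u: float, v: float, preferred_bearing_deg: float) -> float:
    """Signed wind component (m/s) along the preferred bearing.

    ``u`` eastward, ``v`` northward (vector points where air moves TO);
    positive result = tailwind, negative = headwind.
    """
    if not (np.isfinite(u) and np.isfinite(v)):
        raise ValueError("wind components must be finite")
    b = np.radians(preferred_bearing_deg)
    return float(u * np.sin(b) + v * np.cos(b))


def wind_support_for_flights(flights: list[FlightTrajectory], wind: WindField,
                             station_coords: dict,
                             mode: str = "bilinear") -> list[WindSupportResult]:
    """Tailwind support at departure for each flight.

    Wind is sampled at the departure station's coordinates at the grid time
    closest to the departure (last detection at the beginning station).
    """
    out = []
    for k, f in enumerate(flights):
        lat, lon = station_coords[f.station_sequence[0]]
        u, v = sample_wind(wind, f.depart_time, lat, lon, mode=mode)
        beta = flight_bearing(f, station_coords)
        out.append(WindSupportResult(tag_id=f.tag_id, flight_index=k, u_ms=u, v_ms=v,
                                     preferred_bearing_deg=beta,
                                     tailwind_ms=tailwind_support(u, v, beta)))
    return out


def pearson_r(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson correlation from centered cross-moments, with a two-sided p
    from the t transform on n - 2 df. Raises on zero variance."""
    from scipy.stats import t as t_dist
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 paired observations")
    xc, yc = x - x.mean(), y - y.mean()
    sx = float(np.sqrt((xc ** 2).sum()))
    sy = float(np.sqrt((yc ** 2).sum()))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero variance: correlation undefined")
    r = float((xc * yc).sum() / (sx * sy))
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return r, float(2.0 * t_dist.sf(abs(t), n - 2))


def speed_wind_association(flights: list[FlightTrajectory],
                           supports: list[WindSupportResult]) -> dict:
    """Ground speed vs tailwind across flights.

    Returns Pearson r, its two-sided p, the number of flights, and the
    fraction of flights departing with a tailwind (tailwind_ms > 0).
    """
    if len(flights) != len(supports):
        raise ValueError("flights and wind supports must align")
    speeds = np.array([f.net_ground_speed_ms for f in flights])
    tails = np.array([s.tailwind_ms for s in supports])
    finite = np.isfinite(speeds) & np.isfinite(tails)
    speeds, tails = speeds[finite], tails[finite]
    r, p = pearson_r(tails, speeds)
    return {"pearson_r": r, "p_value": p, "n_flights": int(len(speeds)),
            "tailwind_fraction": float(np.mean(tails > 0.0))}


def supports_to_frame(supports: list[WindSupportResult]) -> pd.DataFrame:
    rows = [{"tag_id": s.tag_id, "flight_index": s.flight_index, "u_ms": s.u_ms,
             "v_ms": s.v_ms, "bearing_deg": s.preferred_bearing_deg,
             "tailwind_ms": s.tailwind_ms, "is_tailwind": s.is_tailwind}
            for s in supports]
    return pd.DataFrame(rows, columns=["tag_id", "flight_index", "u_ms", "v_ms",
                                       "bearing_deg", "tailwind_ms", "is_tailwind"])
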