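"""Migratory-flight extraction and trajectory kinematics.

A flight is a passage between two receiving stations at least 150 km apart
(excluding local movements) completed in 18 h or less. Departure time is the
last detection at the beginning station and arrival the first detection at
the ending station, so the net ground speed — orthodrome displacement over
elapsed time — is a lower bound on the true transit speed. Total trajectory
length chains great-circle legs over every station passed en route.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .geo import gc_distance, initial_bearing
from .model import DetectionBout, FlightTrajectory


def _station_visits(bouts: list[DetectionBout]) -> list[dict]:
    """Collapse consecutive same-station bouts into visits with first/last times."""
    visits: list[dict] = []
    for b in bouts:
        if visits and visits[-1]["station_id"] == b.station_id:
            visits[-1]["last"] = max(visits[-1]["last"], b.end)
        else:
            visits.append({"station_id": b.station_id, "first": b.start, "last": b.end})
    return visits


def extract_flights(bouts: list[DetectionBout], station_coords: dict,
                    config: AnalysisConfig | None = None) -> list[FlightTrajectory]:
    """Extract non-overlapping migratory flights from one bird's bouts.

    Candidate flights are windows of consecutive station visits whose end
    stations are >= ``flight_min_displacement_km`` apart and whose elapsed
    time (last detection at the first station to first detection at the
    last) is positive and <= ``flight_max_duration_h``. When candidates
    share a station, the one with the larger displacement wins (ties: the
    earlier departure), so one bird contributes multiple flights only when
    their station sequences are disjoint.
    """
    config = config or AnalysisConfig()
    starts = [b.start for b in bouts]
    if starts != sorted(starts):
        raise ValueError("bouts must be time-sorted")
    visits = _station_visits(bouts)
    nv = len(visits)
    candidates: list[FlightTrajectory] = []
    for i in range(nv):
        for j in range(i + 1, nv):
            si, sj = visits[i]["station_id"], visits[j]["station_id"]
            if si == sj:
                continue
            disp = gc_distance(*station_coords[si], *station_coords[sj])
            if disp < config.flight_min_displacement_km:
                continue
            depart, arrive = visits[i]["last"], visits[j]["first"]
            if arrive <= depart:
                continue
            duration_h = (arrive - depart).total_seconds() / 3600.0
            if duration_h > config.flight_max_duration_h:
                continue
            seq = tuple(v["station_id"] for v in visits[i:j + 1])
            total = float(sum(gc_distance(*station_coords[a], *station_coords[b])
                              for a, b in zip(seq, seq[1:])))
            candidates.append(FlightTrajectory(
                tag_id=bouts[0].tag_id, station_sequence=seq,
                depart_time=depart, arrive_time=arrive,
                total_length_km=float(total), displacement_km=float(disp)))

    # greedy selection: largest displacement first, earlier departure on ties
    candidates.sort(key=lambda f: (-f.displacement_km, f.depart_time, f.station_sequence))
    chosen: list[FlightTrajectory] = []
    used: set = set()
    for c in candidates:
        if used.isdisjoint(c.station_sequence):
            chosen.append(c)
            used.update(c.station_sequence)
    chosen.sort(key=lambda f: f.depart_time)
    return chosen


def flight_bearing(flight: FlightTrajectory, station_coords: dict) -> float:
    """Preferred direction of movement: great-circle initial bearing from the
    beginning to the ending receiving station, degrees from true north."""
    a = station_coords[flight.station_sequence[0]]
    b = station_coords[flight.station_sequence[-1]]
    return initial_bearing(a[0], a[1], b[0], b[1])


def flights_to_frame(flights: list[FlightTrajectory]) -> pd.DataFrame:
    rows = [{"tag_id": f.tag_id, "stations": ";".join(f.station_sequence),
             "depart_time": f.depart_time, "arrive_time": f.arrive_time,
             "total_length_km": f.total_length_km, "displacement_km": f.displacement_km,
             "duration_h": f.duration_h, "ground_speed_ms": f.net_ground_speed_ms}
            for f in flights]
    return pd.DataFrame(rows, columns=["tag_id", "stations", "depart_time", "arrive_time",
                                       "total_length_km", "displacement_km",
                                       "duration_h", "ground_speed_ms"])
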