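"""Analysis configuration.

Every numeric decision rule in the pipeline lives here so the whole analysis
is reproducible from one record: the Delaware Bay membership buffer, stopover
span and clustering thresholds, flight filters, the assumed transit speed
used to decide whether a bird had time to stop, and the detection-QC
parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable thresholds for the migration-analysis pipeline.

    Distances are km, durations in the unit named by the suffix. Defaults
    encode the study's decision rules: stations within 30 km of the Delaware
    Bay watershed count as "in the bay"; a stopover is a detection span
    > 4 h at one station or > 6 h across stations within 30 km of each
    other, considering only stations > 50 km from the tagging site; flights
    need >= 150 km displacement and <= 18 h duration; a bay stop requires
    more than ``min_stop_days`` between bay detections.
    """

    bay_buffer_km: float = 30.0
    likely_buffer_km: float = 60.0       # annulus beyond the bay buffer
    min_stop_days: float = 1.0
    stopover_single_station_h: float = 4.0
    stopover_multi_station_h: float = 6.0
    stopover_station_cluster_km: float = 30.0
    stopover_min_dist_from_capture_km: float = 50.0
    flight_min_displacement_km: float = 150.0
    flight_max_duration_h: float = 18.0
    heatmap_buffer_km: float = 50.0
    heatmap_cell_deg: float = 0.25
    assumed_transit_speed_ms: float = 20.0
    inland_offset_km: float = 150.0      # "inland" = this far west of the coastline
    bout_max_gap_min: float = 30.0
    # detection QC
    min_pulses: int = 3
    min_run_bursts: int = 3
    burst_interval_tol_s: float = 0.1
    k_max_missed_bursts: int = 10
    freq_tol_khz: float = 4.0
    # season window: detections after this month-day (any year) are ignored
    migration_season_end: str = "06-15"

    def __post_init__(self):
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"config field {f.name} must be strictly positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from JSON, TOML or YAML; every field optional."""
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            data = json.loads(text)
        elif path.suffix == ".toml":
            import tomllib
            data = tomllib.loads(text)
        elif path.suffix in (".yaml", ".yml"):
            import yaml
            data = yaml.safe_load(text)
        else:
            raise ValueError(f"unsupported config format: {path.suffix}")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
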