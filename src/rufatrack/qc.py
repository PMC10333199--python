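"""False-positive filtering of coded-tag detections, and bout grouping.

Coded VHF tags are identified by pulse pattern plus a fixed burst interval,
so a station's random radio noise occasionally decodes as a valid tag id.
Three ordered rules remove such false positives, each rejection attributed
to exactly one rule:

R1  fewer than ``min_pulses`` consecutive pulses in the burst;
R2  burst-interval consistency: within a tag-at-station sequence, the gap to
    the previous detection must be within ``burst_interval_tol_s`` of an
    integer multiple (1..k_max) of the tag's burst interval — consecutive
    consistent detections form a *run*, and runs shorter than
    ``min_run_bursts`` are rejected (isolated or aperiodic hits cannot be
    distinguished from noise);
R3  receiver frequency offset beyond ``freq_tol_khz`` (when recorded).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .model import DetectionBout, QCReport

RULES = ("R1_min_pulses", "R2_burst_interval", "R3_freq_offset")


def _interval_consistent(gaps_s: np.ndarray, burst_interval_s: float,
                         tol_s: float, k_max: int) -> np.ndarray:
    """True where a gap is within tol of k * burst_interval for k in 1..k_max."""
    k = np.rint(gaps_s / burst_interval_s)
    near = np.abs(gaps_s - k * burst_interval_s) <= tol_s
    return near & (k >= 1) & (k <= k_max)


def filter_detections(detections: pd.DataFrame, deployments: pd.DataFrame,
                      config: AnalysisConfig | None = None
                      ) -> tuple[pd.DataFrame, QCReport]:
    """Apply the R1 -> R2 -> R3 rule pipeline.

    Returns the surviving detections (original row order preserved) and a
    :class:`QCReport`; every input row lands in the valid set or in exactly
    one rule's rejection count. Detections of a tag with no deployment
    record raise, because R2 needs the tag's burst interval.
    """
    config = config or AnalysisConfig()
    unknown = set(detections["tag_id"]) - set(deployments["tag_id"])
    if unknown:
        raise KeyError(f"detections of tag(s) with no deployment record: {sorted(unknown)}")

    rejected = {r: 0 for r in RULES}
    df = detections.copy()
    df["_order"] = np.arange(len(df))

    # R1: pulse count
    r1 = df["n_pulses"] < config.min_pulses
    rejected["R1_min_pulses"] = int(r1.sum())
    df = df[~r1]

    # R2: burst-interval runs, per tag x station, on R1 survivors
    bi = deployments.set_index("tag_id")["burst_interval_s"]
    keep_mask = pd.Series(True, index=df.index)
    for (tag, _st), grp in df.groupby(["tag_id", "station_id"], sort=False):
        grp = grp.sort_values("time_utc", kind="mergesort")
        t = grp["time_utc"].astype("int64").to_numpy() / 1e9
        if len(t) == 1:
            ok = np.array([False])
        else:
            consistent = _interval_consistent(np.diff(t), float(bi[tag]),
                                              config.burst_interval_tol_s,
                                              config.k_max_missed_bursts)
            # run ids: a new run starts where the gap to the previous
            # detection is inconsistent
            run_id = np.concatenate([[0], np.cumsum(~consistent)])
            _, counts = np.unique(run_id, return_counts=True)
            ok = counts[run_id] >= config.min_run_bursts
        keep_mask.loc[grp.index] = ok
    rejected["R2_burst_interval"] = int((~keep_mask).sum())
    df = df[keep_mask]

    # R3: frequency offset, only where the field is present
    if "freq_offset_khz" in df.columns:
        r3 = df["freq_offset_khz"].abs() > config.freq_tol_khz
        r3 = r3.fillna(False)
        rejected["R3_freq_offset"] = int(r3.sum())
        df = df[~r3]

    valid = df.sort_values("_order").drop(columns="_order")
    report = QCReport(n_input=len(detections), n_rejected_by_rule=rejected,
                      n_valid=len(valid))
    return valid, report


def bout_detections(valid: pd.DataFrame,
                    config: AnalysisConfig | None = None) -> list[DetectionBout]:
    """Group valid detections into station bouts.

    Within each tag's time-sorted history a new bout starts when the station
    changes or when the gap at the same station exceeds
    ``bout_max_gap_min``. Deterministic: ties broken by station id.
    """
    config = config or AnalysisConfig()
    max_gap_s = config.bout_max_gap_min * 60.0
    bouts: list[DetectionBout] = []
    for tag, grp in valid.groupby("tag_id", sort=True):
        grp = grp.sort_values(["time_utc", "station_id"], kind="mergesort")
        times = list(grp["time_utc"])
        stations = grp["station_id"].to_numpy()
        start_idx = 0
        for i in range(1, len(grp) + 1):
            boundary = (i == len(grp)
                        or stations[i] != stations[i - 1]
                        or (times[i] - times[i - 1]).total_seconds() > max_gap_s)
            if boundary:
                bouts.append(DetectionBout(
                    tag_id=tag, station_id=stations[start_idx],
                    start=times[start_idx], end=times[i - 1],
                    n_detections=i - start_idx))
                start_idx = i
    return bouts


def bouts_to_frame(bouts: list[DetectionBout]) -> pd.DataFrame:
    """Tabular view of bouts (one row per bout, sorted by tag then start)."""
    df = pd.DataFrame([{"tag_id": b.tag_id, "station_id": b.station_id,
                        "start": b.start, "end": b.end,
                        "n_detections": b.n_detections} for b in bouts],
                      columns=["tag_id", "station_id", "start", "end", "n_detections"])
    return df.sort_values(["tag_id", "start", "station_id"], kind="mergesort",
                          ignore_index=True)
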