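"""Detection filtering rules and bout grouping."""

import numpy as np
import pandas as pd
import pytest

from rufatrack import AnalysisConfig, bout_detections, filter_detections
from rufatrack.evaluate import qc_retention


def det_frame(times_s, tag="T1", station="S1", n_pulses=3, freq=0.0):
    t0 = pd.Timestamp("2019-05-10T00:00:00Z")
    return pd.DataFrame({
        "tag_id": tag, "station_id": station,
        "time_utc": [t0 + pd.Timedelta(seconds=float(s)) for s in times_s],
        "n_pulses": n_pulses, "freq_offset_khz": freq, "signal": -70.0,
    })


def deployments(tag="T1", bi=5.0):
    return pd.DataFrame({"tag_id": [tag], "burst_interval_s": [bi],
                         "nominal_freq_mhz": [166.38],
                         "deploy_time_utc": [pd.Timestamp("2019-05-01T00:00:00Z")],
                         "deploy_lat": [32.5], "deploy_lon": [-80.2],
                         "body_mass_g": [137.0], "age_class": ["adult"], "site": ["x"]})


def brute_force_multiple_ok(gap_s, bi, tol=0.1, k_max=10):
    """Independent oracle for the interval rule."""
    return any(abs(gap_s - k * bi) <= tol for k in range(1, k_max + 1))


def test_low_pulse_count_rejected_under_r1():
    det = det_frame([0, 5, 10], n_pulses=2)
    valid, rep = filter_detections(det, deployments())
    assert len(valid) == 0
    assert rep.n_rejected_by_rule["R1_min_pulses"] == 3


def test_perfectly_periodic_run_retained():
    det = det_frame([0, 5, 10, 15, 20])
    valid, rep = filter_detections(det, deployments(bi=5.0))
    assert len(valid) == 5 and rep.n_valid == 5


def test_aperiodic_gaps_rejected_under_r2():
    # gaps 7.3 s and 13.1 s for a 5.0 s tag: no multiple 1..10 within 0.1 s
    gaps = [7.3, 13.1]
    assert not any(brute_force_multiple_ok(g, 5.0) for g in gaps)
    det = det_frame([0.0, 7.3, 20.4])
    valid, rep = filter_detections(det, deployments(bi=5.0))
    assert len(valid) == 0
    assert rep.n_rejected_by_rule["R2_burst_interval"] == 3


def test_missed_bursts_tolerated_up_to_k_max():
    # gaps of 2x and 10x the interval stay in one run; 11x breaks it
    det = det_frame([0, 10, 60, 65, 70])          # gaps 10 (2x), 50 (10x), 5, 5
    valid, _ = filter_detections(det, deployments(bi=5.0))
    assert len(valid) == 5
    det2 = det_frame([0, 55.0, 110.0])            # gaps 55 = 11x -> three singletons
    valid2, rep2 = filter_detections(det2, deployments(bi=5.0))
    assert len(valid2) == 0
    assert rep2.n_rejected_by_rule["R2_burst_interval"] == 3


def test_frequency_offset_rule():
    det = det_frame([0, 5, 10], freq=6.0)   # beyond default 4 kHz tolerance
    valid, rep = filter_detections(det, deployments())
    assert len(valid) == 0
    assert rep.n_rejected_by_rule["R3_freq_offset"] == 3


def test_unknown_tag_raises():
    det = det_frame([0, 5], tag="GHOST")
    with pytest.raises(KeyError, match="GHOST"):
        filter_detections(det, deployments(tag="T1"))


def test_conservation_and_idempotence(default_result):
    det = default_result.dataset.detections
    dep = default_result.dataset.deployments
    valid, rep = filter_detections(det, dep)
    assert rep.n_input == rep.n_valid + sum(rep.n_rejected_by_rule.values())
    assert rep.n_input == len(det)
    again, rep2 = filter_detections(valid, dep)
    assert len(again) == len(valid)
    assert sum(rep2.n_rejected_by_rule.values()) == 0


def test_retention_on_labeled_synthetic_data(default_result):
    valid, _ = filter_detections(default_result.dataset.detections,
                                 default_result.dataset.deployments)
    ret = qc_retention(valid, default_result)
    assert ret["tp_retention"] >= 0.95
    assert ret["fp_retention"] <= 0.05


def test_single_station_small_gaps_one_bout():
    # bout grouping acts on already-validated detections
    det = det_frame(np.arange(10) * 240.0)  # 4-min gaps
    bouts = bout_detections(det)
    assert len(bouts) == 1 and bouts[0].n_detections == 10


def test_station_change_splits_bouts():
    a = det_frame([0, 5, 10], station="A")
    b = det_frame([60, 65, 70], station="B")
    c = det_frame([120, 125, 130], station="A")
    det = pd.concat([a, b, c], ignore_index=True)
    valid, _ = filter_detections(det, deployments())
    bouts = bout_detections(valid)
    assert [bt.station_id for bt in bouts] == ["A", "B", "A"]


def test_same_station_gap_beyond_threshold_splits():
    det = det_frame([0, 5, 10, 7200, 7205, 7210])  # clusters 2 h apart
    valid, _ = filter_detections(det, deployments())
    bouts = bout_detections(valid)
    assert len(bouts) == 2
    assert all(b.n_detections == 3 for b in bouts)


def test_every_valid_detection_in_exactly_one_bout(default_pipeline):
    pr = default_pipeline
    n_in_bouts = sum(b.n_detections for bs in pr.bouts_by_tag.values() for b in bs)
    assert n_in_bouts == len(pr.valid_detections) == pr.qc_report.n_valid
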