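import numpy as np
import pandas as pd
import pytest

from rufatrack import AnalysisConfig, SimScenario, run_pipeline, simulate_scenario
from rufatrack.model import DetectionBout


def mk_bout(tag, station, start, end=None, n=5):
    start = pd.Timestamp(start, tz="UTC") if pd.Timestamp(start).tz is None else pd.Timestamp(start)
    end = start if end is None else pd.Timestamp(end, tz="UTC")
    return DetectionBout(tag_id=tag, station_id=station, start=start, end=end, n_detections=n)


def mk_deployment(tag="B1", lat=32.54, lon=-80.17, when="2019-05-01T14:00:00Z",
                  mass=137.0):
    return pd.Series({"tag_id": tag, "burst_interval_s": 5.0, "nominal_freq_mhz": 166.38,
                      "deploy_time_utc": pd.Timestamp(when),
                      "deploy_lat": lat, "deploy_lon": lon,
                      "body_mass_g": mass, "age_class": "adult", "site": "capture"})


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def noiseless_result():
    """Dense coverage, perfect detection, no false positives."""
    return simulate_scenario(SimScenario(seed=7, coverage="dense",
                                         p_detect=1.0, false_positive_rate=0.0))


@pytest.fixture(scope="session")
def noiseless_pipeline(noiseless_result):
    return run_pipeline(noiseless_result.dataset)


@pytest.fixture(scope="session")
def default_result():
    """The default study conditions: 40 birds, p_detect 0.8, false positives."""
    return simulate_scenario(SimScenario(seed=7))


@pytest.fixture(scope="session")
def default_pipeline(default_result):
    return run_pipeline(default_result.dataset)
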