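"""Region membership geometry, the strategy decision tree, and ANOVA."""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Polygon

from rufatrack import (classify_delaware_strategy, mass_by_strategy, oneway_anova,
                       region_membership, summarize_strategies)
from rufatrack.geo import gc_distance
from rufatrack.model import Region, StrategyCall
from rufatrack.routes import distance_to_region_km
from rufatrack.simulate import BASE_STATIONS, make_regions

from conftest import mk_bout, mk_deployment

REGIONS = make_regions()
BAY = next(r for r in REGIONS if r.role == "delaware_bay")
SQUARE = Region("box", "other", Polygon([(-75.5, 39.0), (-74.5, 39.0),
                                         (-74.5, 40.0), (-75.5, 40.0)]))


def west_point(km):
    """A point ``km`` west of the square's western edge at mid-latitude."""
    lat = 39.5
    dlon = km / (111.19492664455873 * np.cos(np.radians(lat)))
    return lat, -75.5 - dlon


def test_point_inside_is_member_at_zero_buffer():
    assert region_membership(39.5, -75.0, SQUARE, buffer_km=0.0)


def test_point_outside_not_member_at_zero_buffer():
    assert not region_membership(39.5, -76.0, SQUARE, buffer_km=0.0)


def test_buffer_boundary_29_vs_31_km():
    lat29, lon29 = west_point(29.0)
    lat31, lon31 = west_point(31.0)
    # sanity: the constructed points sit where intended (within meters)
    assert distance_to_region_km(lat29, lon29, SQUARE) == pytest.approx(29.0, abs=0.1)
    assert region_membership(lat29, lon29, SQUARE, buffer_km=30.0)
    assert not region_membership(lat31, lon31, SQUARE, buffer_km=30.0)


def classify(bouts, deployment=None, coords=None):
    return classify_delaware_strategy(bouts, deployment or mk_deployment(),
                                      REGIONS, coords or dict(BASE_STATIONS))


def test_two_bay_bouts_spanning_over_a_day_is_stopped():
    bouts = [mk_bout("B1", "DB_1", "2019-05-10T02:00:00", "2019-05-10T03:00:00"),
             mk_bout("B1", "DB_2", "2019-05-12T09:00:00", "2019-05-12T10:00:00")]
    assert classify(bouts).strategy == "stopped"


def test_fast_northern_transit_is_skipped():
    # last inland-SC detection, then a station ~900 km north of the bay 16 h
    # later: minimum transit 12.6 h at 20 m/s leaves ~3.4 h of slack (< 1 d)
    d = gc_distance(*BASE_STATIONS["SC_INLAND"], *BASE_STATIONS["LAKE_ERIE"])
    bouts = [mk_bout("B1", "SC_INLAND", "2019-05-15T18:00:00"),
             mk_bout("B1", "LAKE_ERIE", "2019-05-16T10:00:00", "2019-05-16T10:10:00")]
    call = classify(bouts)
    assert call.strategy == "skipped"
    expected_slack_d = (16.0 * 3600 - d * 1000 / 20.0) / 86400.0
    assert call.evidence["slack_days"] == pytest.approx(expected_slack_d, rel=1e-3)


def test_slow_inland_transit_is_likely_skipped():
    # 3 days elapsed to the Lakes with an inland intermediate detection
    bouts = [mk_bout("B1", "SC_INLAND", "2019-05-10T08:00:00", "2019-05-10T08:10:00"),
             mk_bout("B1", "LAKE_ERIE", "2019-05-13T10:00:00", "2019-05-13T10:10:00"),
             mk_bout("B1", "LAKE_HURON", "2019-05-13T20:00:00", "2019-05-13T20:10:00")]
    assert classify(bouts).strategy == "likely_skipped"


def test_single_ambiguous_coastal_detection_is_unknown():
    bouts = [mk_bout("B1", "NC_COAST", "2019-05-12T08:00:00")]
    assert classify(bouts).strategy == "unknown"


def test_annulus_bouts_over_two_days_is_likely_stopped():
    # NJ_COAST sits between 30 and 90 km from the bay polygon
    d = distance_to_region_km(*BASE_STATIONS["NJ_COAST"], BAY)
    assert 30.0 < d <= 90.0
    bouts = [mk_bout("B1", "NJ_COAST", "2019-05-10T08:00:00", "2019-05-10T09:00:00"),
             mk_bout("B1", "NJ_COAST", "2019-05-11T15:00:00", "2019-05-11T16:00:00")]
    assert classify(bouts).strategy == "likely_stopped"


def test_adding_bay_stop_moves_skipped_bird_to_stopped():
    fast = [mk_bout("B1", "SC_INLAND", "2019-05-15T18:00:00", "2019-05-15T18:10:00"),
            mk_bout("B1", "LAKE_ERIE", "2019-05-16T10:00:00", "2019-05-16T10:10:00")]
    assert classify(fast).strategy == "skipped"
    with_stop = sorted(fast + [
        mk_bout("B1", "DB_1", "2019-05-17T02:00:00", "2019-05-17T03:00:00"),
        mk_bout("B1", "DB_2", "2019-05-19T09:00:00", "2019-05-19T10:00:00")],
        key=lambda b: b.start)
    assert classify(with_stop).strategy == "stopped"


def test_no_post_deployment_bouts_raises():
    bouts = [mk_bout("B1", "NC_COAST", "2019-04-01T08:00:00")]
    with pytest.raises(ValueError):
        classify(bouts)


def test_summary_pools_and_excludes_unknowns():
    calls = ([StrategyCall("a%d" % i, "skipped") for i in range(20)]
             + [StrategyCall("b%d" % i, "likely_skipped") for i in range(4)]
             + [StrategyCall("c%d" % i, "stopped") for i in range(7)]
             + [StrategyCall("d%d" % i, "likely_stopped") for i in range(2)]
             + [StrategyCall("e%d" % i, "unknown") for i in range(9)])
    s = summarize_strategies(calls)
    assert s["n_classifiable"] == 33
    assert s["n_skipped_pooled"] == 24
    assert s["prop_skipped_pooled"] == pytest.approx(24 / 33)
    assert round(100 * s["prop_skipped_pooled"]) == 73


def test_summary_all_unknown_flagged():
    s = summarize_strategies([StrategyCall("x", "unknown")])
    assert s["undefined"] and s["prop_skipped_pooled"] is None


def test_summary_even_split():
    s = summarize_strategies([StrategyCall("x", "stopped"), StrategyCall("y", "skipped")])
    assert s["prop_stopped_pooled"] == 0.5 == s["prop_skipped_pooled"]


def test_anova_identical_groups_f_zero():
    res = oneway_anova([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
    assert res["F"] == pytest.approx(0.0)


def test_anova_hand_computed_example():
    # groups {1,2,3}, {4,5,6}: SSB = 13.5, SSW = 4, F = 13.5/(4/4) = 13.5
    res = oneway_anova([np.array([1.0, 2, 3]), np.array([4.0, 5, 6])])
    assert res["F"] == pytest.approx(13.5)
    assert res["df"] == (1, 4)


def test_anova_matches_scipy():
    from scipy.stats import f_oneway
    rng = np.random.default_rng(5)
    groups = [rng.normal(size=n) for n in (8, 12, 9)]
    res = oneway_anova(groups)
    ref = f_oneway(*groups)
    assert res["F"] == pytest.approx(ref.statistic, rel=1e-12)
    assert res["p"] == pytest.approx(ref.pvalue, rel=1e-9)


def test_anova_all_constant_raises():
    with pytest.raises(ValueError):
        oneway_anova([np.array([2.0, 2.0]), np.array([2.0, 2.0])])


def test_mass_by_strategy_groups_and_differences():
    dep = pd.DataFrame({"tag_id": [f"T{i}" for i in range(6)],
                        "body_mass_g": [130.0, 132, 128, 140, 141, 142]})
    calls = [StrategyCall(f"T{i}", "stopped") for i in range(3)] + \
            [StrategyCall(f"T{i}", "skipped") for i in range(3, 6)]
    res = mass_by_strategy(dep, calls)
    assert res["groups"] == ["skipped", "stopped"]
    assert res["mean_differences"]["skipped-stopped"] == pytest.approx(11.0)
    assert res["df"] == (1, 4)
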