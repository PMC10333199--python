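"""Stopover rules (strict 4 h / 6 h thresholds, 30 km clique, 50 km
exclusion), durations, heat map, and a brute-force oracle equivalence."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rufatrack import AnalysisConfig, delaware_stopover_durations, detect_stopovers, stopover_heatmap
from rufatrack.geo import gc_distance
from rufatrack.simulate import BASE_STATIONS, make_regions

from conftest import mk_bout, mk_deployment

BAY = next(r for r in make_regions() if r.role == "delaware_bay")

# a dedicated local layout: capture at origin-ish, stations at known ranges
CAP_LAT, CAP_LON = 32.54, -80.17


def station_at_km(km, lat=None):
    """Station due north of the capture site at a given distance."""
    lat0 = CAP_LAT + km / 111.19492664455873
    return (lat0 if lat is None else lat, CAP_LON)


COORDS = {
    "FAR_A": station_at_km(200.0),
    "FAR_B": (CAP_LAT + 200.0 / 111.19492664455873 + 25.0 / 111.19492664455873, CAP_LON),
    "NEAR_40": station_at_km(40.0),
    "FAR_60": station_at_km(60.0),
}


def hours(h):
    return pd.Timedelta(hours=h)


T0 = pd.Timestamp("2019-05-20T06:00:00Z")


def bout_at(station, start_h, end_h, tag="B1"):
    return mk_bout(tag, station, (T0 + hours(start_h)).isoformat(),
                   (T0 + hours(end_h)).isoformat())


def detect(bouts, coords=None, config=None):
    return detect_stopovers(sorted(bouts, key=lambda b: b.start), mk_deployment(),
                            coords or COORDS, config or AnalysisConfig())


def test_single_station_span_over_4h_is_stopover():
    st = detect([bout_at("FAR_A", 0.0, 4.5)])
    assert len(st) == 1
    assert st[0].duration_h == pytest.approx(4.5)
    assert st[0].stations == frozenset({"FAR_A"})


def test_single_station_span_exactly_4h_is_not():
    assert detect([bout_at("FAR_A", 0.0, 4.0)]) == []


def test_multi_station_cluster_over_6h():
    assert gc_distance(*COORDS["FAR_A"], *COORDS["FAR_B"]) == pytest.approx(25.0, abs=0.1)
    bouts = [bout_at("FAR_A", 0.0, 2.0), bout_at("FAR_B", 3.0, 4.0),
             bout_at("FAR_A", 5.0, 6.5)]
    st = detect(bouts)
    assert len(st) == 1
    assert st[0].stations == frozenset({"FAR_A", "FAR_B"})
    assert st[0].duration_h == pytest.approx(6.5)


def test_multi_station_exactly_6h_is_not():
    bouts = [bout_at("FAR_A", 0.0, 2.0), bout_at("FAR_B", 3.0, 6.0)]
    assert detect(bouts) == []


def test_stations_beyond_30km_do_not_cluster():
    far_c = (CAP_LAT + (200.0 + 32.0) / 111.19492664455873, CAP_LON)
    coords = {**COORDS, "FAR_C": far_c}
    assert gc_distance(*COORDS["FAR_A"], *far_c) > 30.0
    bouts = [bout_at("FAR_A", 0.0, 2.0), bout_at("FAR_C", 3.0, 6.5)]
    assert detect(bouts, coords=coords) == []


def test_within_50km_of_capture_excluded():
    # 10 h of detections at a station only 40 km from the tagging site
    assert detect([bout_at("NEAR_40", 0.0, 10.0)]) == []
    # the same span at 60 km qualifies
    assert len(detect([bout_at("FAR_60", 0.0, 10.0)])) == 1


def test_intervening_station_breaks_single_station_run():
    far_c = (CAP_LAT + 500.0 / 111.19492664455873, CAP_LON)  # far from A
    coords = {**COORDS, "FAR_C": far_c}
    bouts = [bout_at("FAR_A", 0.0, 2.0), bout_at("FAR_C", 2.5, 3.0),
             bout_at("FAR_A", 3.5, 5.0)]
    # neither A-run spans > 4 h on its own, and A/C are 300 km apart
    assert detect(bouts, coords=coords) == []


def brute_force_stopovers(bouts, coords, config):
    """Independent oracle: enumerate all contiguous windows, keep qualifying
    ones, take maximal windows, merge overlaps."""
    dep_lat, dep_lon = CAP_LAT, CAP_LON
    elig = [b for b in bouts
            if gc_distance(dep_lat, dep_lon, *coords[b.station_id])
            > config.stopover_min_dist_from_capture_km]
    n = len(elig)
    quals = []
    for i in range(n):
        for j in range(i, n):
            w = elig[i:j + 1]
            span = (w[-1].end - w[0].start).total_seconds() / 3600.0
            stations = {b.station_id for b in w}
            single = len(stations) == 1 and span > config.stopover_single_station_h
            clique = all(gc_distance(*coords[a], *coords[b]) <= config.stopover_station_cluster_km
                         for a, b in itertools.combinations(stations, 2))
            multi = len(stations) >= 2 and clique and span > config.stopover_multi_station_h
            if single or multi:
                quals.append((i, j))
    maximal = [q for q in quals
               if not any(o != q and o[0] <= q[0] and q[1] <= o[1] for o in quals)]
    merged = []
    for a, b in sorted(maximal):
        if merged and a <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [(elig[a].start, elig[b].end,
             frozenset(x.station_id for x in elig[a:b + 1])) for a, b in merged]


def test_matches_brute_force_oracle_on_random_bout_sets():
    config = AnalysisConfig()
    rng = np.random.default_rng(2024)
    # small station pool: two clusterable, one distant, one near capture
    coords = dict(COORDS)
    names = list(coords)
    for trial in range(60):
        n = rng.integers(1, 9)
        t = 0.0
        bouts = []
        for _ in range(n):
            t += float(rng.uniform(0.2, 3.0))
            dur = float(rng.uniform(0.1, 4.0))
            bouts.append(bout_at(names[rng.integers(len(names))], t, t + dur))
            t += dur
        ours = detect(bouts, coords=coords, config=config)
        oracle = brute_force_stopovers(sorted(bouts, key=lambda b: b.start),
                                       coords, config)
        assert len(ours) == len(oracle), f"trial {trial}"
        for s, (start, end, stations) in zip(ours, oracle):
            assert (s.start, s.end, s.stations) == (start, end, stations)


def test_lengthening_span_never_removes_stopover():
    base = [bout_at("FAR_A", 0.0, 4.5)]
    longer = [bout_at("FAR_A", 0.0, 7.5)]
    assert len(detect(base)) == 1 and len(detect(longer)) == 1


def test_bay_durations_first_to_last():
    det = pd.DataFrame({
        "tag_id": ["K1", "K1", "K2"],
        "station_id": ["DB_1", "DB_2", "DB_1"],
        "time_utc": pd.to_datetime(["2019-05-10T06:00:00Z", "2019-05-15T20:24:00Z",
                                    "2019-05-11T00:00:00Z"], utc=True),
        "n_pulses": 3, "freq_offset_khz": 0.0, "signal": -70.0,
    })
    stations = pd.DataFrame({"station_id": ["DB_1", "DB_2"],
                             "lat": [BASE_STATIONS["DB_1"][0], BASE_STATIONS["DB_2"][0]],
                             "lon": [BASE_STATIONS["DB_1"][1], BASE_STATIONS["DB_2"][1]],
                             "active_from": pd.NaT, "active_to": pd.NaT})
    out = delaware_stopover_durations(det, stations, BAY)
    assert list(out["tag_id"]) == ["K1"]  # K2 has a single bay detection
    assert out["duration_d"].iloc[0] == pytest.approx(5.6)


def test_bay_duration_zero_when_first_equals_last():
    det = pd.DataFrame({
        "tag_id": ["K1", "K1"], "station_id": ["DB_1", "DB_1"],
        "time_utc": pd.to_datetime(["2019-05-10T06:00:00Z"] * 2, utc=True),
        "n_pulses": 3, "freq_offset_khz": 0.0, "signal": -70.0})
    stations = pd.DataFrame({"station_id": ["DB_1"], "lat": [BASE_STATIONS["DB_1"][0]],
                             "lon": [BASE_STATIONS["DB_1"][1]],
                             "active_from": pd.NaT, "active_to": pd.NaT})
    out = delaware_stopover_durations(det, stations, BAY)
    assert out["duration_d"].iloc[0] == 0.0


def grid_counts(stopovers, coords):
    return stopover_heatmap(stopovers, coords, (33.0, 36.0), (-81.5, -78.5),
                            cell_deg=0.25, buffer_km=50.0)


def test_heatmap_single_individual_single_station():
    st = detect([bout_at("FAR_A", 0.0, 5.0)])
    h = grid_counts(st, COORDS)
    glat, glon = np.meshgrid(h["lat_centers"], h["lon_centers"], indexing="ij")
    d = gc_distance(COORDS["FAR_A"][0], COORDS["FAR_A"][1], glat, glon)
    assert (h["counts"][d <= 50.0] == 1).all()
    assert (h["counts"][d > 50.0] == 0).all()


def test_heatmap_counts_individuals_not_events():
    same_bird = detect([bout_at("FAR_A", 0.0, 5.0), bout_at("FAR_B", 6.0, 7.0),
                        bout_at("FAR_A", 30.0, 35.0)])
    h1 = grid_counts(same_bird, COORDS)
    assert h1["counts"].max() == 1
    two_birds = detect([bout_at("FAR_A", 0.0, 5.0)]) + \
        detect([bout_at("FAR_A", 0.0, 5.0, tag="B2")])
    h2 = grid_counts(two_birds, COORDS)
    assert h2["counts"].max() == 2


def test_heatmap_bounded_by_individuals_with_stopovers(noiseless_pipeline):
    pr = noiseless_pipeline
    if pr.heatmap is not None:
        n_birds = len({s.tag_id for s in pr.stopovers})
        assert pr.heatmap["counts"].max() <= n_birds


def test_heatmap_degenerate_grid_raises():
    with pytest.raises(ValueError):
        stopover_heatmap([], {}, (33.0, 33.0), (-81.0, -78.0))
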