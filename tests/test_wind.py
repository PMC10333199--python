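"""Wind grid sampling, tailwind projection, and the Pearson estimator."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rufatrack import WindField, pearson_r, sample_wind, tailwind_support
from rufatrack.wind import OutOfDomainError


@pytest.fixture(scope="module")
def grid():
    times = pd.date_range("2019-05-01", periods=8, freq="6h").values
    lats = np.array([38.0, 39.0, 40.0])
    lons = np.array([-76.0, -75.0, -74.0])
    u = np.arange(8 * 3 * 3, dtype=float).reshape(8, 3, 3)
    v = -u / 2.0
    return WindField(times=times, lats=lats, lons=lons, u=u, v=v)


def test_sample_at_node_is_identity(grid):
    u, v = sample_wind(grid, pd.Timestamp("2019-05-01T06:00:00Z"), 39.0, -75.0)
    assert (u, v) == (grid.u[1, 1, 1], grid.v[1, 1, 1])


def test_bilinear_midpoint_averages_four_nodes():
    times = np.array([np.datetime64("2019-05-01T00:00")])
    wf = WindField(times=times, lats=np.array([0.0, 1.0]), lons=np.array([0.0, 1.0]),
                   u=np.array([[[0.0, 0.0], [10.0, 10.0]]]),
                   v=np.zeros((1, 2, 2)))
    u, v = sample_wind(wf, pd.Timestamp("2019-05-01T00:00:00Z"), 0.5, 0.5)
    assert u == pytest.approx(5.0)


def test_nearest_time_rounds_and_breaks_ties_early(grid):
    # 2.9 h after slice 0 on a 6-h grid -> slice 0
    u0, _ = sample_wind(grid, pd.Timestamp("2019-05-01T02:54:00Z"), 38.0, -76.0)
    assert u0 == grid.u[0, 0, 0]
    # exactly halfway -> the earlier slice
    uh, _ = sample_wind(grid, pd.Timestamp("2019-05-01T03:00:00Z"), 38.0, -76.0)
    assert uh == grid.u[0, 0, 0]


def test_nearest_node_mode(grid):
    u, _ = sample_wind(grid, pd.Timestamp("2019-05-01T00:00:00Z"), 38.4, -75.9,
                       mode="nearest")
    assert u == grid.u[0, 0, 0]


def test_out_of_domain_raises(grid):
    with pytest.raises(OutOfDomainError):
        sample_wind(grid, pd.Timestamp("2019-05-01T00:00:00Z"), 50.0, -75.0)
    with pytest.raises(OutOfDomainError):
        sample_wind(grid, pd.Timestamp("2019-06-15T00:00:00Z"), 39.0, -75.0)


@pytest.mark.parametrize("u,v,beta,expected", [
    (0.0, 8.0, 0.0, 8.0),        # pure north wind, due-north flight
    (10.0, 0.0, 0.0, 0.0),       # pure crosswind
    (3.0, 4.0, 36.87, 5.0),      # 3-4-5 projection
    (0.0, -8.0, 0.0, -8.0),      # headwind
])
def test_tailwind_projection_examples(u, v, beta, expected):
    assert tailwind_support(u, v, beta) == pytest.approx(expected, abs=2e-4)


def test_wind_from_just_south_of_east_assists_due_north_flight():
    # wind FROM the east-southeast blows toward the west-northwest: small
    # positive v component -> still a (weak) tailwind for a due-north flight
    assert tailwind_support(-8.0, 0.3, 0.0) > 0.0


finite = st.floats(-50.0, 50.0, allow_nan=False)


@settings(deadline=None, derandomize=True, max_examples=300)
@given(finite, finite, st.floats(0.0, 360.0, exclude_max=True))
def test_tailwind_bounded_by_wind_speed_and_antisymmetric(u, v, beta):
    tw = tailwind_support(u, v, beta)
    speed = np.hypot(u, v)
    assert abs(tw) <= speed + 1e-9
    assert tw == pytest.approx(-tailwind_support(u, v, beta + 180.0), abs=1e-9)


def test_tailwind_equality_iff_aligned():
    # wind exactly along the bearing: |tailwind| == wind speed
    beta = 30.0
    u, v = 6 * np.sin(np.radians(beta)), 6 * np.cos(np.radians(beta))
    assert tailwind_support(u, v, beta) == pytest.approx(6.0, abs=1e-12)
    # any misalignment strictly reduces it
    assert tailwind_support(u, v, beta + 10.0) < 6.0


def test_pearson_exact_linear():
    x = np.arange(10.0)
    r, p = pearson_r(x, 2 * x + 1)
    assert r == pytest.approx(1.0)
    assert p == 0.0


def test_pearson_hand_computed():
    r, _ = pearson_r(np.array([1.0, 2, 3]), np.array([1.0, 3, 2]))
    assert r == pytest.approx(0.5, abs=1e-12)


def test_pearson_matches_definition_brute_force():
    rng = np.random.default_rng(77)
    for _ in range(50):
        n = rng.integers(3, 40)
        x, y = rng.normal(size=n), rng.normal(size=n)
        r, p = pearson_r(x, y)
        brute = np.mean((x - x.mean()) * (y - y.mean())) / (x.std() * y.std())
        assert r == pytest.approx(brute, abs=1e-12)
        from scipy.stats import pearsonr
        ref = pearsonr(x, y)
        assert r == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)


def test_pearson_zero_variance_raises():
    with pytest.raises(ValueError):
        pearson_r(np.ones(5), np.arange(5.0))
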