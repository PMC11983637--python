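"""Layout geometry: angular allocation, radial banding, coordinate maps.

Expected values come from independent closed-form oracles:
width_i = (360 - sum(gaps)) * range_i / sum(ranges) for sectors,
cumulative subtraction for bands, and plain linear/trig formulas for the
coordinate transforms.
"""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import circogram as cg
from circogram.errors import DegenerateRange, GapOverflow, RadiusExhausted
from circogram.grammar import GlobalParams
from circogram.layout import point_in_cell, with_ylim


def _params(**kw):
    return GlobalParams(**kw)


def test_single_sector_no_gap_covers_full_circle():
    [s] = cg.allocate_sectors({"a": (0.0, 1.0)}, _params(gap_degrees=0.0))
    assert abs(s.sweep) == pytest.approx(360.0, abs=1e-12)


def test_equal_sectors_share_the_non_gap_circle():
    xlims = {c: (0.0, 5.0) for c in "abcd"}
    secs = cg.allocate_sectors(xlims, _params(gap_degrees=1.0))
    for s in secs:
        assert abs(s.sweep) == pytest.approx((360 - 4) / 4, abs=1e-12)


def test_sweeps_proportional_to_ranges():
    secs = cg.allocate_sectors({"a": (0.0, 10.0), "b": (0.0, 30.0)},
                               _params(gap_degrees=2.0))
    assert abs(secs[0].sweep) == pytest.approx(89.0, abs=1e-12)
    assert abs(secs[1].sweep) == pytest.approx(267.0, abs=1e-12)


def test_explicit_weights_override_ranges():
    secs = cg.allocate_sectors({"a": (0.0, 10.0), "b": (0.0, 30.0)},
                               _params(gap_degrees=0.0),
                               weights={"a": 1.0, "b": 1.0})
    assert abs(secs[0].sweep) == pytest.approx(180.0)


def test_degenerate_xlim_and_gap_overflow():
    with pytest.raises(DegenerateRange):
        cg.allocate_sectors({"a": (1.0, 1.0)}, _params())
    with pytest.raises(GapOverflow):
        cg.allocate_sectors({"a": (0.0, 1.0), "b": (0.0, 1.0)},
                            _params(gap_degrees=180.0))


@given(
    st.integers(1, 8),
    st.floats(0.0, 20.0),
    st.floats(-180.0, 180.0),
    st.booleans(),
)
def test_conservation_and_disjointness(n, gap, start, clockwise):
    xlims = {f"s{i}": (0.0, float(i + 1)) for i in range(n)}
    params = _params(gap_degrees=gap, start_degree=start, clockwise=clockwise)
    secs = cg.allocate_sectors(xlims, params)
    total = sum(abs(s.sweep) for s in secs) + n * gap
    assert total == pytest.approx(360.0, abs=1e-9)
    # spans are consecutive and disjoint along the traversal direction
    for a, b in zip(secs, secs[1:]):
        if clockwise:
            assert b.start_angle <= a.end_angle + 1e-12
        else:
            assert b.start_angle >= a.end_angle - 1e-12


def test_single_band_arithmetic():
    [b] = cg.allocate_tracks([0.2], margins=0.0)
    assert (b.r_outer, b.r_inner) == (1.0, pytest.approx(0.8))


def test_cumulative_band_subtraction():
    b0, b1 = cg.allocate_tracks([0.2, 0.1], margins=0.02)
    assert (b0.r_outer, b0.r_inner) == (1.0, pytest.approx(0.8))
    assert b1.r_outer == pytest.approx(0.78)
    assert b1.r_inner == pytest.approx(0.68)


def test_exact_radius_exhaustion_rejected():
    # 3 * 0.3 + 2 * 0.05 = 1.0: the last band would close at r_inner = 0
    with pytest.raises(RadiusExhausted):
        cg.allocate_tracks([0.3, 0.3, 0.3], margins=0.05)


def test_bands_disjoint_and_inside_unit_radius():
    bands = cg.allocate_tracks([0.15, 0.2, 0.1], margins=(0.01, 0.01))
    for b in bands:
        assert 0.0 < b.r_inner < b.r_outer <= 1.0
    for a, b in zip(bands, bands[1:]):
        assert b.r_outer < a.r_inner


def test_cell_to_polar_endpoints_and_midpoint():
    [sec] = cg.allocate_sectors({"a": (0.0, 10.0)}, _params(gap_degrees=0.0))
    band = with_ylim(cg.allocate_tracks([0.2], margins=0.0)[0], (0.0, 1.0))
    p = cg.cell_to_polar(sec, band, 0.0, 1.0)
    assert p.theta == pytest.approx(sec.start_angle)
    assert p.r == pytest.approx(band.r_outer)
    # midpoint x maps to the mid angle regardless of direction
    for cw in (True, False):
        [s] = cg.allocate_sectors({"a": (-5.0, 5.0)},
                                  _params(gap_degrees=0.0, clockwise=cw))
        mid = cg.cell_to_polar(s, band, 0.0, 0.5)
        assert mid.theta == pytest.approx((s.start_angle + s.end_angle) / 2)


def test_clockwise_interpolation_example():
    sec = cg.SectorLayout("a", (0.0, 10.0), 0.0, -89.0)
    band = with_ylim(cg.TrackBand(0, 1.0, 0.8), (0.0, 1.0))
    p = cg.cell_to_polar(sec, band, 5.0, 0.5)
    assert p.theta == pytest.approx(-44.5, abs=1e-12)
    assert p.r == pytest.approx(0.9, abs=1e-12)


@pytest.mark.parametrize("theta,r,expected", [
    (0.0, 1.0, (1.0, 0.0)),
    (90.0, 1.0, (0.0, 1.0)),
    (45.0, 0.5, (0.35355, 0.35355)),
])
def test_polar_to_canvas_trig_oracle(theta, r, expected):
    cx, cy = cg.polar_to_canvas(cg.PolarPoint(theta, r))
    assert cx == pytest.approx(expected[0], abs=5e-6)
    assert cy == pytest.approx(expected[1], abs=5e-6)


def test_round_trip_against_analytic_inverse():
    rng = np.random.default_rng(7)
    for _ in range(100):
        x0, x1 = sorted(rng.uniform(-100, 100, 2))
        if x1 - x0 < 1e-6:
            continue
        y0, y1 = sorted(rng.uniform(-10, 10, 2))
        if y1 - y0 < 1e-6:
            continue
        sec = cg.SectorLayout("s", (x0, x1),
                              rng.uniform(-360, 360), rng.uniform(-360, 360))
        if abs(sec.sweep) < 1e-6:
            continue
        band = with_ylim(cg.TrackBand(0, 0.9, 0.5), (y0, y1))
        x = rng.uniform(x0, x1)
        y = rng.uniform(y0, y1)
        p = cg.cell_to_polar(sec, band, x, y)
        # analytic inverse of the two linear maps
        x_back = x0 + (p.theta - sec.start_angle) / sec.sweep * (x1 - x0)
        y_back = y0 + (p.r - band.r_inner) / (band.r_outer - band.r_inner) * (y1 - y0)
        assert x_back == pytest.approx(x, abs=1e-9 * max(1, abs(x)))
        assert y_back == pytest.approx(y, abs=1e-9 * max(1, abs(y)))


def test_monotonicity_of_theta_in_x_and_r_in_y():
    sec = cg.SectorLayout("s", (0.0, 1.0), 30.0, -60.0)
    band = with_ylim(cg.TrackBand(0, 0.9, 0.4), (0.0, 1.0))
    xs = np.linspace(0, 1, 11)
    thetas = [cg.cell_to_polar(sec, band, x, 0.5).theta for x in xs]
    assert all(b < a for a, b in zip(thetas, thetas[1:]))  # clockwise sector
    rs = [cg.cell_to_polar(sec, band, 0.5, y).r for y in xs]
    assert all(b > a for a, b in zip(rs, rs[1:]))


def test_out_of_range_points_clip_to_cell_boundary():
    sec = cg.SectorLayout("s", (0.0, 1.0), 0.0, -90.0)
    band = with_ylim(cg.TrackBand(0, 1.0, 0.8), (0.0, 1.0))
    p = cg.cell_to_polar(sec, band, 2.0, -1.0)
    assert p.theta == pytest.approx(-90.0)
    assert p.r == pytest.approx(0.8)
    assert not point_in_cell(sec, band, 2.0, -1.0)
    assert point_in_cell(sec, band, 0.5, 0.5)
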