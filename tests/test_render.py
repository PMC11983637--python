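"""Deferred evaluation: show(), link drawing, scene statistics, SVG output."""

import math

import numpy as np
import pandas as pd
import pytest

import circogram as cg
from circogram.errors import EmptyInterval, UnknownSector
from circogram.grammar import GlobalParams
from circogram.render import draw_link
from circogram.scene import (
    ArcBandPrim,
    PointPrim,
    PolygonPrim,
    PolylinePrim,
    RibbonPrim,
    Scene,
)


def _sectors_two():
    return cg.allocate_sectors({"a": (0.0, 1.0), "b": (0.0, 1.0)},
                               GlobalParams(gap_degrees=1.0))


def test_empty_plot_renders_empty_scene():
    plot = cg.make_plot("initialize", {"categories": ["a", "b"],
                                       "xlims": [(0, 1), (0, 1)]})
    scene = cg.show(plot)
    assert scene.primitives == ()


def test_panel_point_count_matches_fixture(simple_plot):
    stats = cg.scene_stats(cg.show(simple_plot))
    # 5 data rows drawn as points + one border arc-band per (sector, track)
    assert stats.by_kind["point"] == 5
    assert stats.by_kind["arc_band"] == 2
    assert stats.by_sector["a"] == 1 + 3
    assert stats.by_sector["b"] == 1 + 2


def test_show_is_pure(simple_plot):
    a = cg.scene_to_svg(cg.show(simple_plot))
    b = cg.scene_to_svg(cg.show(simple_plot))
    assert a == b


def test_track_order_determines_radial_bands(track_with_data):
    other = cg.make_track(
        pd.DataFrame({"category": ["a", "b"], "x": [0.5, 0.5], "y": [1.0, 1.0]}),
        ylim=(0, 2))

    def bands(plot):
        scene = cg.show(plot)
        out = {}
        for p in scene.primitives:
            style = dict(p.style)
            if style.get("role") == "border":
                out.setdefault(style["track"], p.r_outer)
        return out

    base = cg.make_plot("initialize", {"categories": ["a", "b"],
                                       "xlims": [(0, 4), (0, 2)]})
    b12 = bands(base + track_with_data + other)
    b21 = bands(base + other + track_with_data)
    assert b12[0] == b21[0] > b12[1]  # outermost radius goes to first added


def test_geom_order_is_paint_order_only(track_with_data):
    g1 = cg.make_track_geom("points", aesthetics={"color": "red"})
    g2 = cg.make_track_geom("points", aesthetics={"color": "blue"})
    base = cg.make_plot("initialize", {"categories": ["a", "b"],
                                       "xlims": [(0, 4), (0, 2)]})

    def colors(plot):
        return [dict(p.style)["fill"] for p in cg.show(plot).primitives
                if isinstance(p, PointPrim)]

    c12 = colors(base + (track_with_data + g1 + g2))
    c21 = colors(base + (track_with_data + g2 + g1))
    assert c12 == c21[::-1] or sorted(c12) == sorted(c21)
    assert c12.index("red") < c12.index("blue")
    assert c21.index("blue") < c21.index("red")


def test_clip_warnings_counted():
    df = pd.DataFrame({"category": ["a"] * 3, "x": [0.5, 2.0, 0.7],
                       "y": [0.5, 0.5, 9.0]})
    plot = cg.make_plot("initialize", {"categories": ["a"], "xlims": [(0, 1)]})
    plot = plot + cg.make_track(df, ylim=(0, 1))
    scene = cg.show(plot)
    assert scene.clip_warnings == 2


def test_all_primitives_inside_unit_viewport(genome):
    scene = cg.show(cg.build_example2(genome=genome))
    for p in scene.primitives:
        if isinstance(p, (PolylinePrim, PolygonPrim)):
            assert all(math.hypot(x, y) <= 1.0 + 1e-9 for x, y in p.points)
        elif isinstance(p, PointPrim):
            assert math.hypot(p.cx, p.cy) <= 1.0 + 1e-9
        elif isinstance(p, ArcBandPrim):
            assert p.r_outer <= 1.0 + 1e-9
        elif isinstance(p, RibbonPrim):
            assert p.radius <= 1.0 + 1e-9


# --- links -----------------------------------------------------------------

def test_point_link_with_zero_curvature_is_straight_chord():
    secs = _sectors_two()
    link = cg.make_link("a", 0.5, "b", 0.5, aesthetics={"h": 0.0})
    [prim] = draw_link(link, secs, anchor_radius=1.0)
    pts = np.asarray(prim.points)
    # all sampled points lie on the straight segment between the endpoints
    p0, p1 = pts[0], pts[-1]
    d = p1 - p0
    rel = pts - p0
    cross = np.abs(rel[:, 0] * d[1] - rel[:, 1] * d[0]) / np.linalg.norm(d)
    assert cross.max() < 1e-9


def test_scaled_link_moves_anchor_not_angles():
    secs = _sectors_two()
    full = draw_link(cg.make_link("a", 0.5, "b", 0.5), secs, 1.0)[0]
    scaled = draw_link(cg.make_link("a", 0.5, "b", 0.5, scale=0.8), secs, 1.0)[0]
    r_full = math.hypot(*full.points[0])
    r_scaled = math.hypot(*scaled.points[0])
    assert r_scaled == pytest.approx(0.8 * r_full)
    # endpoint angles unchanged
    ang = lambda p: math.atan2(p[1], p[0])
    assert ang(full.points[0]) == pytest.approx(ang(scaled.points[0]))
    assert ang(full.points[-1]) == pytest.approx(ang(scaled.points[-1]))


def test_self_loop_point_link_allowed_ribbon_rejected():
    secs = _sectors_two()
    stub = draw_link(cg.make_link("a", 0.5, "a", 0.5), secs, 1.0)
    assert len(stub) == 1
    with pytest.raises(EmptyInterval):
        draw_link(cg.make_link("a", (0.5, 0.5), "b", (0.2, 0.4)), secs, 1.0)


def test_unknown_sector_in_link_rejected():
    with pytest.raises(UnknownSector):
        draw_link(cg.make_link("a", 0.5, "zz", 0.5), _sectors_two(), 1.0)


def test_links_paint_after_tracks(simple_plot):
    plot = simple_plot + cg.make_link("a", 0.5, "b", 0.5)
    roles = [dict(p.style).get("role") for p in cg.show(plot).primitives]
    assert roles[-1] == "link"


def test_zoomed_records_render_in_both_sectors(genome):
    regions = cg.generate_random_regions(genome, 60, seed=5)
    plot = cg.make_plot("initializeWithIdeogram", {
        "cytoband": genome.cytobands,
        "zoom": ([genome.chroms[0]], 0.4),
    })
    track = cg.make_genomic_track(regions, panel_kind="points", ylim=(0, 1))
    scene = cg.show(plot + track)
    n_chr1 = int((regions.df["chrom"] == genome.chroms[0]).sum())
    pts = [p for p in scene.primitives if isinstance(p, PointPrim)]
    by_sector = {}
    for p in pts:
        by_sector.setdefault(dict(p.style)["sector"], 0)
        by_sector[dict(p.style)["sector"]] += 1
    assert by_sector[genome.chroms[0]] == n_chr1
    assert by_sector[genome.chroms[0] + "_zoom"] == n_chr1
    assert len(pts) == len(regions) + n_chr1


# --- svg -------------------------------------------------------------------

def test_empty_scene_serializes_to_valid_svg():
    import xml.etree.ElementTree as ET
    doc = cg.scene_to_svg(Scene())
    root = ET.fromstring(doc)
    assert root.tag.endswith("svg")


def test_scene_stats_totals_consistent(simple_plot):
    scene = cg.show(simple_plot)
    stats = cg.scene_stats(scene)
    assert stats.total == len(scene.primitives) == sum(stats.by_kind.values())


def test_svg_serialization_is_deterministic(genome):
    scene = cg.show(cg.build_example1(genome, seed=4))
    assert cg.scene_to_svg(scene) == cg.scene_to_svg(cg.show(
        cg.build_example1(genome, seed=4)))


def test_render_error_carries_component_path(track_with_data):
    plot = cg.make_plot("initialize", {"categories": ["a", "b"],
                                       "xlims": [(0, 4), (0, 2)]})
    empty = cg.make_track(panel_kind="region-only")
    bad = empty + (cg.CellSpec(sector_id="a") + cg.make_cell_geom("points"))
    with pytest.raises(cg.CircogramError, match=r"\[track 1\]"):
        cg.show(plot + track_with_data + bad)
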