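"""Composition algebra: the six legal addition rules, immutability,
and global-parameter resolution."""

import pytest
from hypothesis import given, strategies as st

import circogram as cg
from circogram.errors import (
    IllegalComposition,
    InvalidParameterValue,
    MissingInitArgument,
    UnknownInitArgument,
    UnknownInitMode,
)
from circogram.grammar import (
    CellGeomSpec,
    CellSpec,
    ParSpec,
    PlotSpec,
    TrackGeomSpec,
    TrackSpec,
    combine,
)


def _plot():
    return cg.make_plot("initialize",
                        {"categories": ["a"], "xlims": [(0.0, 1.0)]})


def _link():
    return cg.make_link("a", 0.2, "a", 0.8)


# (container factory, component factory, list attribute)
RULES = [
    (_plot, lambda: ParSpec({"gap.degree": 2}), "pars"),
    (_plot, TrackSpec, "tracks"),
    (_plot, _link, "links"),
    (TrackSpec, lambda: TrackGeomSpec(kind="points"), "track_geoms"),
    (TrackSpec, lambda: CellSpec(sector_id="a"), "cells"),
    (lambda: CellSpec(sector_id="a"), lambda: CellGeomSpec(kind="points"),
     "cell_geoms"),
]


@pytest.mark.parametrize("container_f,component_f,attr", RULES,
                         ids=[r[2] for r in RULES])
@pytest.mark.parametrize("n", range(6))
def test_each_rule_appends_exactly_one_component(container_f, component_f,
                                                 attr, n):
    c = container_f()
    for _ in range(n):
        c = combine(c, component_f())
    assert len(getattr(c, attr)) == n
    comp = component_f()
    out = combine(c, comp)
    assert len(getattr(out, attr)) == n + 1
    assert getattr(out, attr)[-1] is comp          # appended last
    assert len(getattr(c, attr)) == n              # input unchanged
    # the other component lists are untouched
    for _, _, other in RULES:
        if other != attr and hasattr(out, other):
            assert getattr(out, other) == getattr(c, other)


ILLEGAL = [
    (TrackSpec(), CellGeomSpec(kind="points")),   # cell geom straight into track
    (_plot(), TrackGeomSpec(kind="points")),
    (_plot(), CellGeomSpec(kind="points")),
    (_plot(), CellSpec(sector_id="a")),
    (TrackSpec(), ParSpec({})),
    (TrackSpec(), TrackSpec()),
    (CellSpec(sector_id="a"), TrackGeomSpec(kind="points")),
    (CellSpec(sector_id="a"), CellSpec(sector_id="b")),
    (ParSpec({}), ParSpec({})),
]


@pytest.mark.parametrize("container,component", ILLEGAL,
                         ids=lambda v: type(v).__name__)
def test_illegal_pairs_raise(container, component):
    with pytest.raises(IllegalComposition):
        combine(container, component)


def test_plus_operator_matches_combine():
    p = _plot()
    t = TrackSpec()
    assert (p + t).tracks == combine(p, t).tracks


def test_container_reuse_gives_independent_chains():
    base = TrackSpec() + TrackGeomSpec(kind="points")
    left = base + CellSpec(sector_id="a")
    right = base + CellSpec(sector_id="b") + CellSpec(sector_id="c")
    assert len(base.cells) == 0
    assert [c.sector_id for c in left.cells] == ["a"]
    assert [c.sector_id for c in right.cells] == ["b", "c"]
    assert left.track_geoms == right.track_geoms == base.track_geoms


@given(st.lists(st.sampled_from(["par", "track", "link"]), max_size=12))
def test_random_plot_chains_count_components(seq):
    plot = _plot()
    for name in seq:
        plot = plot + {"par": ParSpec({}), "track": TrackSpec(),
                       "link": _link()}[name]
    assert len(plot.pars) == seq.count("par")
    assert len(plot.tracks) == seq.count("track")
    assert len(plot.links) == seq.count("link")
    # addition order preserved for tracks
    assert all(isinstance(t, TrackSpec) for t in plot.tracks)


@given(st.lists(st.sampled_from(["geom", "cell"]), max_size=12))
def test_random_track_chains_count_components(seq):
    track = TrackSpec()
    for name in seq:
        track = track + ({"geom": TrackGeomSpec(kind="points"),
                          "cell": CellSpec(sector_id="a")}[name])
    assert len(track.track_geoms) == seq.count("geom")
    assert len(track.cells) == seq.count("cell")


# --- make_plot -------------------------------------------------------------

@pytest.mark.parametrize("mode,args", [
    ("initialize", {"categories": ["a", "b"],
                    "xlims": [(0, 1), (0, 1)]}),
    ("heatmap.initialize", {"matrix": [[1.0, 2.0], [3.0, 4.0]]}),
    ("initializeWithIdeogram", {}),
    ("genomicInitialize", {"data": {"chr1": 100, "chr2": 50}}),
])
def test_each_init_mode_constructs(mode, args):
    plot = cg.make_plot(mode, args)
    assert plot.init_mode == mode
    assert (len(plot.pars), len(plot.tracks), len(plot.links)) == (0, 0, 0)


def test_unknown_init_mode_rejected():
    with pytest.raises(UnknownInitMode):
        cg.make_plot("spiral", {})


def test_missing_and_unknown_init_arguments():
    with pytest.raises(MissingInitArgument):
        cg.make_plot("initialize", {"categories": ["a"]})
    with pytest.raises(MissingInitArgument):
        cg.make_plot("genomicInitialize", {})
    with pytest.raises(UnknownInitArgument):
        cg.make_plot("initialize", {"categories": ["a"], "xlims": [(0, 1)],
                                    "cytoband": None})


def test_init_mode_registry_has_exactly_four_modes():
    assert len(cg.INIT_MODES) == 4


# --- resolve_pars ----------------------------------------------------------

def test_empty_par_list_gives_documented_defaults():
    params = cg.resolve_pars([])
    assert params.start_degree == 0.0
    assert params.gap_degrees == 1.0
    assert params.clockwise is True
    assert params.default_track_height == 0.2


def test_last_par_wins_on_key_collision():
    params = cg.resolve_pars([ParSpec({"gap.degree": 5}),
                              ParSpec({"gap.degree": 2})])
    assert params.gap_degrees == 2.0


def test_disjoint_pars_commute():
    a = ParSpec({"start.degree": 90.0})
    b = ParSpec({"track.height": 0.1})
    c = ParSpec({"clock.wise": False})
    assert cg.resolve_pars([a, b, c]) == cg.resolve_pars([c, a, b])


def test_gap_list_totalling_360_rejected():
    with pytest.raises(InvalidParameterValue):
        cg.resolve_pars([ParSpec({"gap.degree": [1, 1, 358]})], n_sectors=3)


def test_invalid_parameter_values_rejected_at_construction():
    with pytest.raises(InvalidParameterValue):
        ParSpec({"track.height": 1.5})
    with pytest.raises(InvalidParameterValue):
        ParSpec({"no.such.key": 1})
    with pytest.raises(InvalidParameterValue):
        ParSpec({"gap.degree": -1})


def test_scalar_gap_broadcast_to_sector_count():
    params = cg.resolve_pars([ParSpec({"gap.degree": 3})], n_sectors=4)
    assert params.gap_degrees == (3.0, 3.0, 3.0, 3.0)
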