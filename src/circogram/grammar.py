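"""Component types and the addition-composition algebra.

A circular plot is assembled from immutable components: a :class:`PlotSpec`
container accumulates global-parameter bundles (:class:`ParSpec`), tracks
(:class:`TrackSpec`) and sector-to-sector links (:class:`LinkSpec`); a track
accumulates track-wide geometry (:class:`TrackGeomSpec`) and per-cell
containers (:class:`CellSpec`); a cell accumulates cell-local geometry
(:class:`CellGeomSpec`).  Exactly six (container, component) pairs are
legal; everything else — notably adding cell-local geometry directly to a
track — raises :class:`~circogram.errors.IllegalComposition`.

Composition never mutates: ``combine`` (also exposed as the overloaded
``+``) returns a new container with the component appended, so intermediate
plots and tracks can be reused across several composition chains.
Everything here is declarative; no data is touched until the plot is
rendered by :func:`circogram.render.show`.
"""

from __future__ import annotations

import numbers
from dataclasses import dataclass, field, replace
from typing import Any, Callable, Mapping, Sequence

from .errors import (
    IllegalComposition,
    InvalidParameterValue,
    MissingInitArgument,
    UnknownInitArgument,
    UnknownInitMode,
)

__all__ = [
    "INIT_MODES",
    "PRIMARY_COMPONENTS",
    "PAR_DEFAULTS",
    "ABSENT",
    "PlotSpec",
    "ParSpec",
    "TrackSpec",
    "CellSpec",
    "LinkSpec",
    "TrackGeomSpec",
    "CellGeomSpec",
    "GlobalParams",
    "combine",
    "make_plot",
    "make_link",
    "resolve_pars",
]


class _Absent:
    """Singleton marking a deliberately missing coordinate or data slot."""

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return "ABSENT"


#: Sentinel for "coordinate not given, default from the owning track".
ABSENT = _Absent()


#: The four plot-initialization modes.
INIT_MODES = (
    "initialize",
    "heatmap.initialize",
    "initializeWithIdeogram",
    "genomicInitialize",
)

_INIT_REQUIRED: dict[str, tuple[str, ...]] = {
    "initialize": ("categories", "xlims"),
    "heatmap.initialize": ("matrix",),
    "initializeWithIdeogram": (),
    "genomicInitialize": ("data",),
}

_INIT_ALLOWED: dict[str, frozenset[str]] = {
    "initialize": frozenset({"categories", "xlims"}),
    "heatmap.initialize": frozenset({"matrix", "split"}),
    "initializeWithIdeogram": frozenset({"cytoband", "plot_type", "zoom"}),
    "genomicInitialize": frozenset({"data", "plot_type", "zoom"}),
}


# ---------------------------------------------------------------------------
# Global parameters
# ---------------------------------------------------------------------------

#: Registry of recognised Par keys and their defaults (circos-style names).
PAR_DEFAULTS: dict[str, Any] = {
    "start.degree": 0.0,
    "gap.degree": 1.0,          # scalar broadcast to every sector, or a list
    "clock.wise": True,
    "track.height": 0.2,        # fraction of the canvas radius
    "track.margin": (0.01, 0.01),
    "cell.padding": (0.0, 0.0, 0.0, 0.0),
}


def _check_par(key: str, value: Any) -> Any:
    if key not in PAR_DEFAULTS:
        raise InvalidParameterValue(
            f"unknown parameter {key!r}; known keys: {sorted(PAR_DEFAULTS)}"
        )
    if key == "start.degree":
        if not isinstance(value, numbers.Real):
            raise InvalidParameterValue("start.degree must be a number")
        return float(value)
    if key == "gap.degree":
        if isinstance(value, numbers.Real):
            if value < 0:
                raise InvalidParameterValue("gap.degree must be >= 0")
            return float(value)
        if isinstance(value, Sequence):
            gaps = tuple(float(g) for g in value)
            if any(g < 0 for g in gaps):
                raise InvalidParameterValue("gap.degree entries must be >= 0")
            if sum(gaps) >= 360.0:
                raise InvalidParameterValue(
                    f"gap.degree total {sum(gaps)} must be < 360"
                )
            return gaps
        raise InvalidParameterValue("gap.degree must be a number or sequence")
    if key == "clock.wise":
        if not isinstance(value, bool):
            raise InvalidParameterValue("clock.wise must be a boolean")
        return value
    if key == "track.height":
        if not isinstance(value, numbers.Real) or not 0.0 < value <= 1.0:
            raise InvalidParameterValue("track.height must be in (0, 1]")
        return float(value)
    if key in ("track.margin", "cell.padding"):
        vals = tuple(float(v) for v in value)
        if any(v < 0 for v in vals):
            raise InvalidParameterValue(f"{key} entries must be >= 0")
        return vals
    raise AssertionError("unreachable")


@dataclass(frozen=True)
class ParSpec:
    """A bundle of global plotting parameters.

    Keys are validated eagerly against :data:`PAR_DEFAULTS`; merging of
    several ParSpecs happens in :func:`resolve_pars` (last wins).
    """

    settings: Mapping[str, Any]

    def __post_init__(self) -> None:
        checked = {k: _check_par(k, v) for k, v in dict(self.settings).items()}
        object.__setattr__(self, "settings", checked)


@dataclass(frozen=True)
class GlobalParams:
    """Fully-resolved global plotting parameters.

    ``gap_degrees`` may still be a scalar if the sector count was unknown at
    resolution time; :func:`circogram.layout.allocate_sectors` broadcasts it.
    The canvas radius is fixed at 1.0.
    """

    start_degree: float = 0.0
    gap_degrees: float | tuple[float, ...] = 1.0
    clockwise: bool = True
    default_track_height: float = 0.2
    track_margin: tuple[float, float] = (0.01, 0.01)
    cell_padding: tuple[float, ...] = (0.0, 0.0, 0.0, 0.0)
    canvas_radius: float = 1.0

    def gaps_for(self, n_sectors: int) -> tuple[float, ...]:
        """Per-sector gap list, broadcasting a scalar gap."""
        if isinstance(self.gap_degrees, tuple):
            if len(self.gap_degrees) != n_sectors:
                raise InvalidParameterValue(
                    f"gap.degree list has {len(self.gap_degrees)} entries "
                    f"for {n_sectors} sectors"
                )
            return self.gap_degrees
        return (float(self.gap_degrees),) * n_sectors


def resolve_pars(
    pars: Sequence[ParSpec], n_sectors: int | None = None
) -> GlobalParams:
    """Merge ParSpecs onto the documented defaults, last-wins per key.

    Parameters with disjoint keys therefore commute; colliding keys are
    order-sensitive in addition order.  When ``n_sectors`` is given, a
    scalar gap is broadcast and the total-gap bound (< 360 degrees) is
    enforced here; otherwise the check is deferred to sector allocation.
    """
    merged = dict(PAR_DEFAULTS)
    for p in pars:
        if not isinstance(p, ParSpec):
            raise InvalidParameterValue(f"expected ParSpec, got {type(p).__name__}")
        merged.update(p.settings)

    gaps = merged["gap.degree"]
    if n_sectors is not None:
        if isinstance(gaps, tuple):
            if len(gaps) != n_sectors:
                raise InvalidParameterValue(
                    f"gap.degree list has {len(gaps)} entries for "
                    f"{n_sectors} sectors"
                )
        else:
            gaps = (float(gaps),) * n_sectors
        if sum(gaps) >= 360.0:
            raise InvalidParameterValue(
                f"total gap {sum(gaps)} degrees must be < 360"
            )

    return GlobalParams(
        start_degree=merged["start.degree"],
        gap_degrees=gaps,
        clockwise=merged["clock.wise"],
        default_track_height=merged["track.height"],
        track_margin=tuple(merged["track.margin"]),
        cell_padding=tuple(merged["cell.padding"]),
    )


# ---------------------------------------------------------------------------
# Geometry component shells (constructors and resolution live in geoms.py;
# the types are defined here because the addition rules dispatch on them)
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class TrackGeomSpec:
    """Track-wide geometry: drawn in every sector of the owning track."""

    kind: str
    data: Any = None  # optional per-sector coordinate table (DataFrame)
    aesthetics: Mapping[str, Any] = field(default_factory=dict)


@dataclass(frozen=True, eq=False)
class CellGeomSpec:
    """Cell-local geometry: drawn in a single (sector, track) cell.

    ``x`` and ``y`` may each be :data:`ABSENT` (default from the owning
    track's per-sector data at render time), a concrete vector, or a
    callable of ``(x_default, y_default)`` whose return value is used.
    """

    kind: str
    x: Any = ABSENT
    y: Any = ABSENT
    aesthetics: Mapping[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class CellSpec:
    """The cell container: cell-local geoms targeted at one sector."""

    sector_id: str
    cell_geoms: tuple[CellGeomSpec, ...] = ()

    def __add__(self, component: Any) -> "CellSpec":
        return combine(self, component)


@dataclass(frozen=True, eq=False)
class TrackSpec:
    """One concentric track: optional per-sector data, a drawing panel,
    plus accumulated track-wide geoms and cells."""

    sector_data: Any = None          # DataFrame with category/x[/y] or None
    ylim: tuple[float, float] | None = None
    height: float | None = None      # fraction of canvas radius
    panel_kind: str = "points"
    track_geoms: tuple[TrackGeomSpec, ...] = ()
    cells: tuple[CellSpec, ...] = ()

    def __add__(self, component: Any) -> "TrackSpec":
        return combine(self, component)

    def sector_ids(self) -> tuple[str, ...]:
        if self.sector_data is None:
            return ()
        seen: dict[str, None] = {}
        for c in self.sector_data["category"]:
            seen.setdefault(str(c))
        return tuple(seen)


@dataclass(frozen=True, eq=False)
class LinkSpec:
    """A curve (point endpoints) or ribbon (interval endpoints) joining two
    sectors across the circle's interior.

    Endpoints are ``(sector_id, position)`` or ``(sector_id, (start, end))``.
    ``scale`` shrinks the radial anchor of the link (1.0 anchors at the
    innermost free radius).
    """

    endpoint_1: tuple[str, Any]
    endpoint_2: tuple[str, Any]
    aesthetics: Mapping[str, Any] = field(default_factory=dict)
    scale: float = 1.0

    def __post_init__(self) -> None:
        for ep in (self.endpoint_1, self.endpoint_2):
            sector, pos = ep
            if not isinstance(sector, str):
                raise InvalidParameterValue("link endpoint sector must be a label")
            if isinstance(pos, (tuple, list)):
                lo, hi = pos
                if lo > hi:
                    raise InvalidParameterValue(
                        f"link interval ({lo}, {hi}) must have start <= end"
                    )
        if not 0.0 < self.scale <= 1.0:
            raise InvalidParameterValue("link scale must be in (0, 1]")
        object.__setattr__(self, "aesthetics", dict(self.aesthetics))

    @property
    def kind(self) -> str:
        a = isinstance(self.endpoint_1[1], (tuple, list))
        b = isinstance(self.endpoint_2[1], (tuple, list))
        return "interval-ribbon" if (a or b) else "point"


@dataclass(frozen=True, eq=False)
class PlotSpec:
    """The root container: initialization mode/arguments plus ordered
    pars, tracks and links accumulated by addition."""

    init_mode: str
    init_args: Mapping[str, Any] = field(default_factory=dict)
    pars: tuple[ParSpec, ...] = ()
    tracks: tuple[TrackSpec, ...] = ()
    links: tuple[LinkSpec, ...] = ()

    def __add__(self, component: Any) -> "PlotSpec":
        return combine(self, component)


#: The seven primary component categories of the grammar.
PRIMARY_COMPONENTS: tuple[type, ...] = (
    PlotSpec,
    ParSpec,
    TrackSpec,
    TrackGeomSpec,
    LinkSpec,
    CellSpec,
    CellGeomSpec,
)

# The six legal addition rules: (container type, component type, list field).
_RULES: tuple[tuple[type, type, str], ...] = (
    (PlotSpec, ParSpec, "pars"),
    (PlotSpec, TrackSpec, "tracks"),
    (PlotSpec, LinkSpec, "links"),
    (TrackSpec, TrackGeomSpec, "track_geoms"),
    (TrackSpec, CellSpec, "cells"),
    (CellSpec, CellGeomSpec, "cell_geoms"),
)

COMPOSITION_RULES = tuple((c.__name__, k.__name__) for c, k, _ in _RULES)


def combine(container: Any, component: Any) -> Any:
    """Append ``component`` to the matching list of ``container``.

    Returns a new container of the same kind with the component appended
    last; the input container is left untouched.  Raises
    :class:`IllegalComposition` for any (container, component) pair outside
    the six rules — in particular cell-local geometry can never be added
    directly to a track: it must go through a :class:`CellSpec`.
    """
    for ctype, ktype, attr in _RULES:
        if isinstance(container, ctype) and isinstance(component, ktype):
            # CellGeomSpec is not a TrackGeomSpec, so Track + CellGeom falls
            # through every rule and is rejected below.
            current = getattr(container, attr)
            return replace(container, **{attr: current + (component,)})
    raise IllegalComposition(
        f"cannot add {type(component).__name__} to {type(container).__name__}; "
        f"legal rules: {COMPOSITION_RULES}"
    )


# ---------------------------------------------------------------------------
# Constructors
# ---------------------------------------------------------------------------

def make_plot(init_mode: str, init_args: Mapping[str, Any] | None = None) -> PlotSpec:
    """Create an empty plot container with validated init parameters.

    ``initialize`` needs explicit sector ``categories`` and per-sector
    ``xlims``; ``heatmap.initialize`` needs a ``matrix``;
    ``initializeWithIdeogram`` falls back to the packaged synthetic genome
    when no ``cytoband`` is given; ``genomicInitialize`` needs genomic
    ``data`` (an interval table or a chromosome-length mapping).
    """
    if init_mode not in INIT_MODES:
        raise UnknownInitMode(
            f"initMode {init_mode!r} is not one of {list(INIT_MODES)}"
        )
    args = dict(init_args or {})
    for key in args:
        if key not in _INIT_ALLOWED[init_mode]:
            raise UnknownInitArgument(
                f"init argument {key!r} not valid for mode {init_mode!r}; "
                f"allowed: {sorted(_INIT_ALLOWED[init_mode])}"
            )
    for key in _INIT_REQUIRED[init_mode]:
        if key not in args:
            raise MissingInitArgument(
                f"mode {init_mode!r} requires init argument {key!r}"
            )
    if init_mode == "initialize":
        cats = list(args["categories"])
        xlims = [tuple(map(float, xl)) for xl in args["xlims"]]
        if len(cats) != len(xlims):
            raise MissingInitArgument(
                f"{len(cats)} categories but {len(xlims)} xlims"
            )
        if len(cats) != len(set(cats)):
            raise MissingInitArgument("sector categories must be unique")
        args["categories"], args["xlims"] = cats, xlims
    return PlotSpec(init_mode=init_mode, init_args=args)


def make_link(
    sector_1: str,
    pos_1: Any,
    sector_2: str,
    pos_2: Any,
    aesthetics: Mapping[str, Any] | None = None,
    scale: float = 1.0,
) -> LinkSpec:
    """Build a link between two sector positions or intervals."""
    return LinkSpec(
        endpoint_1=(sector_1, tuple(pos_1) if isinstance(pos_1, (tuple, list)) else pos_1),
        endpoint_2=(sector_2, tuple(pos_2) if isinstance(pos_2, (tuple, list)) else pos_2),
        aesthetics=dict(aesthetics or {}),
        scale=scale,
    )
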