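"""Geometry constructors and track-to-geometry data mapping.

The grammar defers all data resolution to render time.  A cell-local geom
may omit its coordinates entirely: when the plot is shown, the owning
track's data for the corresponding sector is extracted and used as the
default.  A coordinate may also be a callable ``f(x_default, y_default)``
whose return value becomes the actual coordinate vector — the layered
analogue of remapping an aesthetic against the parent data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CallableResultInvalid,
    MalformedGeomData,
    MalformedTrackData,
    NoDefaultAvailable,
    UnknownAesthetic,
    UnknownGeomKind,
)
from .grammar import ABSENT, CellGeomSpec, TrackGeomSpec, TrackSpec

__all__ = [
    "TRACK_GEOM_KINDS",
    "CELL_GEOM_KINDS",
    "TrackGeomSpec",
    "CellGeomSpec",
    "ResolvedGeom",
    "make_track",
    "make_track_geom",
    "make_cell_geom",
    "resolve_geom_data",
    "resolve_track_geom",
    "classify_cn_color",
    "classify_cn_colors",
]

TRACK_GEOM_KINDS = ("points", "lines", "text", "axis", "rect", "heatmap-cells")
CELL_GEOM_KINDS = ("points", "lines", "text", "axis", "rect")

_COMMON_AES = {"color", "alpha", "z"}
_AES_BY_KIND: dict[str, frozenset[str]] = {
    "points": frozenset(_COMMON_AES | {"size", "marker"}),
    "lines": frozenset(_COMMON_AES | {"width", "dash"}),
    "text": frozenset(_COMMON_AES | {"labels", "font_size", "facing"}),
    "axis": frozenset(_COMMON_AES | {"ticks", "side", "font_size"}),
    "rect": frozenset(_COMMON_AES | {"fill", "border", "bar_width"}),
    "heatmap-cells": frozenset(_COMMON_AES | {"palette", "value_column", "border"}),
}

DEFAULT_AES: dict[str, dict[str, Any]] = {
    "points": {"color": "black", "size": 1.0, "marker": "circle", "alpha": 1.0},
    "lines": {"color": "black", "width": 1.0, "dash": None, "alpha": 1.0},
    "text": {"color": "black", "font_size": 8.0, "facing": "tangential", "alpha": 1.0},
    "axis": {"color": "black", "ticks": 5, "side": "top", "font_size": 6.0, "alpha": 1.0},
    "rect": {"fill": "grey", "border": "black", "bar_width": None, "alpha": 1.0},
    "heatmap-cells": {"palette": "greys", "value_column": "value", "border": None,
                      "alpha": 1.0},
}


def _check_kind(kind: str, registry: Sequence[str]) -> None:
    if kind not in registry:
        raise UnknownGeomKind(
            f"geom kind {kind!r} not in registry {list(registry)}"
        )


def _check_aes(kind: str, aesthetics: Mapping[str, Any]) -> dict[str, Any]:
    allowed = _AES_BY_KIND[kind]
    for key in aesthetics:
        if key not in allowed:
            raise UnknownAesthetic(
                f"aesthetic {key!r} not valid for kind {kind!r}; "
                f"allowed: {sorted(allowed)}"
            )
    return dict(aesthetics)


@dataclass(frozen=True, eq=False)
class ResolvedGeom:
    """A geometry after data mapping: concrete coordinate vectors only."""

    kind: str
    sector_id: str
    x_values: np.ndarray
    y_values: np.ndarray
    aesthetics: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Constructors
# ---------------------------------------------------------------------------

def _as_frame(data: Any) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    try:
        return pd.DataFrame(dict(data))
    except ValueError as exc:  # ragged columns
        raise MalformedTrackData(f"ragged or unalignable track data: {exc}") from exc


def make_track(
    data: Any = None,
    ylim: tuple[float, float] | None = None,
    height: float | None = None,
    panel_kind: str = "points",
) -> TrackSpec:
    """Build a track component.

    ``data``, when present, must carry ``category`` and ``x`` columns
    (``y`` optional).  A track without data and with ``panel_kind``
    "region-only" is a drawable empty band — useful as a scaffold that
    cell geoms fill in later.
    """
    if panel_kind not in ("points", "lines", "region-only", "heatmap", "ideogram"):
        raise UnknownGeomKind(f"unknown panel kind {panel_kind!r}")
    frame = None
    if data is not None:
        frame = _as_frame(data)
        if "category" not in frame.columns:
            raise MalformedTrackData("track data must have a 'category' column")
        if "x" not in frame.columns:
            raise MalformedTrackData("track data must have an 'x' column")
        if frame["category"].isna().any():
            raise MalformedTrackData("track data 'category' contains missing values")
        frame = frame.reset_index(drop=True)
    return TrackSpec(
        sector_data=frame,
        ylim=None if ylim is None else (float(ylim[0]), float(ylim[1])),
        height=None if height is None else float(height),
        panel_kind=panel_kind,
    )


def make_track_geom(
    kind: str,
    data: Any = None,
    aesthetics: Mapping[str, Any] | None = None,
) -> TrackGeomSpec:
    """Build track-wide geometry; ``data`` absent defaults from the track."""
    _check_kind(kind, TRACK_GEOM_KINDS)
    aes = _check_aes(kind, aesthetics or {})
    frame = None if data is None else _as_frame(data)
    if frame is not None and "category" not in frame.columns:
        raise MalformedTrackData("track-geom data must have a 'category' column")
    return TrackGeomSpec(kind=kind, data=frame, aesthetics=aes)


def make_cell_geom(
    kind: str,
    x: Any = ABSENT,
    y: Any = ABSENT,
    aesthetics: Mapping[str, Any] | None = None,
) -> CellGeomSpec:
    """Build cell-local geometry with possibly deferred coordinates.

    Each of ``x``/``y`` may be :data:`~circogram.grammar.ABSENT`, a concrete
    vector, or a callable of the per-sector default vectors.  Callables are
    stored unevaluated; nothing touches track data until render time.
    """
    _check_kind(kind, CELL_GEOM_KINDS)
    aes = _check_aes(kind, aesthetics or {})

    def norm(v: Any) -> Any:
        if v is ABSENT or callable(v):
            return v
        arr = np.asarray(v, dtype=float)
        if arr.ndim != 1:
            raise MalformedGeomData(f"coordinate vector must be 1-D, got shape {arr.shape}")
        return arr

    xv, yv = norm(x), norm(y)
    if isinstance(xv, np.ndarray) and isinstance(yv, np.ndarray) and len(xv) != len(yv):
        raise MalformedGeomData(
            f"x has length {len(xv)} but y has length {len(yv)}"
        )
    return CellGeomSpec(kind=kind, x=xv, y=yv, aesthetics=aes)


# ---------------------------------------------------------------------------
# Resolution (render-time data mapping)
# ---------------------------------------------------------------------------

def sector_defaults(
    track: TrackSpec, sector_id: str
) -> tuple[np.ndarray | None, np.ndarray | None]:
    """The track's default (x, y) vectors for one sector, or (None, None)."""
    if track.sector_data is None:
        return None, None
    sub = track.sector_data[track.sector_data["category"].astype(str) == sector_id]
    if sub.empty:
        return None, None
    x = sub["x"].to_numpy(dtype=float)
    y = sub["y"].to_numpy(dtype=float) if "y" in sub.columns else None
    return x, y


def _resolve_coord(
    value: Any,
    default: np.ndarray | None,
    x_default: np.ndarray | None,
    y_default: np.ndarray | None,
    which: str,
    sector_id: str,
) -> np.ndarray:
    if value is ABSENT:
        if default is None:
            raise NoDefaultAvailable(
                f"{which} is absent and the track has no data for sector "
                f"{sector_id!r} to default from"
            )
        return np.asarray(default, dtype=float)
    if callable(value):
        if x_default is None:
            raise NoDefaultAvailable(
                f"{which} callable needs track defaults, but the track has no "
                f"data for sector {sector_id!r}"
            )
        result = value(x_default, y_default)
        try:
            arr = np.asarray(result, dtype=float)
        except (TypeError, ValueError) as exc:
            raise CallableResultInvalid(
                f"{which} callable returned non-numeric result: {exc}"
            ) from exc
        if arr.ndim != 1:
            raise CallableResultInvalid(
                f"{which} callable returned array of shape {arr.shape}; expected 1-D"
            )
        return arr
    return np.asarray(value, dtype=float)


def resolve_geom_data(
    geom: CellGeomSpec, track: TrackSpec, sector_id: str
) -> ResolvedGeom:
    """Resolve a cell geom's coordinates against its owning track.

    Absent coordinates take the track's per-sector data; callables are
    invoked with ``(x_default, y_default)``; concrete vectors pass through.
    The result is validated to equal-length vectors.
    """
    x_def, y_def = sector_defaults(track, sector_id)
    x = _resolve_coord(geom.x, x_def, x_def, y_def, "x", sector_id)
    y = _resolve_coord(geom.y, y_def, x_def, y_def, "y", sector_id)
    if len(x) != len(y):
        raise CallableResultInvalid(
            f"resolved x has length {len(x)} but y has length {len(y)} "
            f"in sector {sector_id!r}"
        )
    aes = {**DEFAULT_AES[geom.kind], **geom.aesthetics}
    return ResolvedGeom(kind=geom.kind, sector_id=sector_id,
                        x_values=x, y_values=y, aesthetics=aes)


def resolve_track_geom(
    geom: TrackGeomSpec, track: TrackSpec, sector_id: str
) -> ResolvedGeom:
    """Resolve track-wide geometry for one sector.

    Symmetric with the cell rule: a geom without its own data defaults
    from the owning track's table restricted to the sector.
    """
    if geom.data is not None:
        sub = geom.data[geom.data["category"].astype(str) == sector_id]
        x = sub["x"].to_numpy(dtype=float)
        y = (sub["y"].to_numpy(dtype=float) if "y" in sub.columns
             else np.zeros(len(sub)))
    else:
        x, y = sector_defaults(track, sector_id)
        if x is None:
            raise NoDefaultAvailable(
                f"track geom {geom.kind!r} has no data and the track has none "
                f"for sector {sector_id!r}"
            )
        if y is None:
            y = np.zeros(len(x))
    aes = {**DEFAULT_AES[geom.kind], **geom.aesthetics}
    return ResolvedGeom(kind=geom.kind, sector_id=sector_id,
                        x_values=np.asarray(x, dtype=float),
                        y_values=np.asarray(y, dtype=float),
                        aesthetics=aes)


# ---------------------------------------------------------------------------
# Copy-number color rule
# ---------------------------------------------------------------------------

def classify_cn_color(value: float) -> str:
    """Classify a copy-number ratio in [-1, 1] into a dot color.

    Gains (>= +0.15) are red, losses (<= -0.15) are green, the band in
    between is grey.  The thresholds belong to the colored extremes.
    """
    if not np.isfinite(value):
        raise ValueError(f"copy-number value must be finite, got {value}")
    if value >= 0.15:
        return "red"
    if value <= -0.15:
        return "green"
    return "grey"


def classify_cn_colors(values: Sequence[float]) -> list[str]:
    """Vectorized :func:`classify_cn_color`."""
    return [classify_cn_color(float(v)) for v in np.asarray(values, dtype=float)]
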