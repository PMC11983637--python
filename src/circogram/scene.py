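"""Canvas primitives and render statistics.

A :class:`Scene` is the output of deferred evaluation: an ordered list of
low-level primitives (order = paint order) on a unit-radius canvas centered
on the origin.  Scenes are plain data — serializing one to SVG twice gives
byte-identical files, which is what makes golden-file testing possible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Any, Mapping

__all__ = [
    "PointPrim",
    "PolylinePrim",
    "PolygonPrim",
    "ArcBandPrim",
    "RibbonPrim",
    "TextPrim",
    "Scene",
    "RenderStats",
    "scene_stats",
]


def _freeze_style(style: Mapping[str, Any]) -> tuple[tuple[str, Any], ...]:
    return tuple(sorted(style.items()))


@dataclass(frozen=True)
class PointPrim:
    kind = "point"
    cx: float
    cy: float
    size: float
    style: tuple[tuple[str, Any], ...] = ()


@dataclass(frozen=True)
class PolylinePrim:
    kind = "polyline"
    points: tuple[tuple[float, float], ...]
    style: tuple[tuple[str, Any], ...] = ()


@dataclass(frozen=True)
class PolygonPrim:
    kind = "polygon"
    points: tuple[tuple[float, float], ...]
    style: tuple[tuple[str, Any], ...] = ()


@dataclass(frozen=True)
class ArcBandPrim:
    """Annular wedge between two angles and two radii."""

    kind = "arc_band"
    theta1: float
    theta2: float
    r_inner: float
    r_outer: float
    style: tuple[tuple[str, Any], ...] = ()


@dataclass(frozen=True)
class RibbonPrim:
    """Two anchor arcs at ``radius`` joined by cubic Bezier flanks whose
    control points sit at radius ``h`` (pulled toward the origin)."""

    kind = "ribbon"
    theta_1a: float
    theta_1b: float
    theta_2a: float
    theta_2b: float
    radius: float
    h: float
    style: tuple[tuple[str, Any], ...] = ()


@dataclass(frozen=True)
class TextPrim:
    kind = "text"
    cx: float
    cy: float
    angle: float
    content: str
    style: tuple[tuple[str, Any], ...] = ()


@dataclass(frozen=True)
class Scene:
    """Ordered primitives plus a count of clipped (out-of-range) points."""

    primitives: tuple[Any, ...] = ()
    clip_warnings: int = 0


@dataclass(frozen=True)
class RenderStats:
    """Primitive counts by kind / track / sector, plus clip warnings."""

    by_kind: dict[str, int]
    by_track: dict[Any, int]
    by_sector: dict[str, int]
    clip_warnings: int
    total: int


def scene_stats(scene: Scene) -> RenderStats:
    """Tally a scene; totals are consistent with its primitive list."""
    by_kind: Counter = Counter()
    by_track: Counter = Counter()
    by_sector: Counter = Counter()
    for prim in scene.primitives:
        by_kind[prim.kind] += 1
        style = dict(prim.style)
        if "track" in style:
            by_track[style["track"]] += 1
        if "sector" in style:
            by_sector[style["sector"]] += 1
    return RenderStats(
        by_kind=dict(by_kind),
        by_track=dict(by_track),
        by_sector=dict(by_sector),
        clip_warnings=scene.clip_warnings,
        total=len(scene.primitives),
    )
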