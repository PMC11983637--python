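"""Deterministic SVG 1.1 serialization of scenes.

Element order follows scene paint order; attributes are emitted in a fixed
(sorted) order; every coordinate is formatted to 6 decimal places.  Two
identical scenes therefore serialize to byte-identical files.  Canvas
coordinates use the math convention (y up); the writer flips y for SVG.

Arcs (annular wedges and ribbon anchors) are flattened to path segments at
a fixed angular step of 2 degrees so the output contains no arc commands
whose rendering could vary between viewers.
"""

from __future__ import annotations

import math
from typing import Any, Iterable
from xml.sax.saxutils import escape, quoteattr

from .scene import (
    ArcBandPrim,
    PointPrim,
    PolygonPrim,
    PolylinePrim,
    RibbonPrim,
    Scene,
    TextPrim,
)

__all__ = ["scene_to_svg", "write_svg"]

_ARC_STEP_DEG = 2.0
_POINT_BASE_RADIUS = 0.008

#: style keys passed through as SVG presentation attributes
_PRESENTATION = ("fill", "stroke", "stroke-width", "opacity", "font-size")


def _fmt(v: float) -> str:
    s = f"{v:.6f}"
    return "0.000000" if s == "-0.000000" else s


def _xy(cx: float, cy: float) -> tuple[str, str]:
    return _fmt(cx), _fmt(-cy)  # flip y for SVG's downward axis


def _polar_xy(theta_deg: float, r: float) -> tuple[float, float]:
    t = math.radians(theta_deg)
    return r * math.cos(t), r * math.sin(t)


def _sample_arc(theta1: float, theta2: float, r: float) -> list[tuple[float, float]]:
    sweep = theta2 - theta1
    n = max(1, int(math.ceil(abs(sweep) / _ARC_STEP_DEG)))
    return [_polar_xy(theta1 + sweep * i / n, r) for i in range(n + 1)]


def _style_attrs(style: tuple[tuple[str, Any], ...]) -> str:
    parts = []
    meta = []
    st = dict(style)
    for key in _PRESENTATION:
        if key in st and st[key] is not None:
            parts.append(f"{key}={quoteattr(str(st[key]))}")
    for key in sorted(st):
        if key not in _PRESENTATION and st[key] is not None:
            meta.append(f"data-{key}={quoteattr(str(st[key]))}")
    return " ".join(parts + meta)


def _path(d: str, style: tuple[tuple[str, Any], ...]) -> str:
    attrs = _style_attrs(style)
    return f'<path d="{d}"' + (f" {attrs}" if attrs else "") + " />"


def _points_attr(pts: Iterable[tuple[float, float]]) -> str:
    return " ".join(",".join(_xy(x, y)) for x, y in pts)


def _emit(prim: Any) -> str:
    if isinstance(prim, PointPrim):
        x, y = _xy(prim.cx, prim.cy)
        attrs = _style_attrs(prim.style)
        r = _fmt(_POINT_BASE_RADIUS * prim.size)
        return f'<circle cx="{x}" cy="{y}" r="{r}"' + (f" {attrs}" if attrs else "") + " />"
    if isinstance(prim, PolylinePrim):
        attrs = _style_attrs(prim.style)
        return (f'<polyline points="{_points_attr(prim.points)}"'
                + (f" {attrs}" if attrs else "") + " />")
    if isinstance(prim, PolygonPrim):
        attrs = _style_attrs(prim.style)
        return (f'<polygon points="{_points_attr(prim.points)}"'
                + (f" {attrs}" if attrs else "") + " />")
    if isinstance(prim, ArcBandPrim):
        outer = _sample_arc(prim.theta1, prim.theta2, prim.r_outer)
        inner = _sample_arc(prim.theta2, prim.theta1, prim.r_inner)
        cmds = []
        x, y = _xy(*outer[0])
        cmds.append(f"M {x} {y}")
        for pt in outer[1:] + inner:
            x, y = _xy(*pt)
            cmds.append(f"L {x} {y}")
        cmds.append("Z")
        return _path(" ".join(cmds), prim.style)
    if isinstance(prim, RibbonPrim):
        arc1 = _sample_arc(prim.theta_1a, prim.theta_1b, prim.radius)
        arc2 = _sample_arc(prim.theta_2a, prim.theta_2b, prim.radius)
        c1 = _polar_xy(prim.theta_1b, prim.h)
        c2 = _polar_xy(prim.theta_2a, prim.h)
        c3 = _polar_xy(prim.theta_2b, prim.h)
        c4 = _polar_xy(prim.theta_1a, prim.h)
        cmds = []
        x, y = _xy(*arc1[0])
        cmds.append(f"M {x} {y}")
        for pt in arc1[1:]:
            x, y = _xy(*pt)
            cmds.append(f"L {x} {y}")
        cx1, cy1 = _xy(*c1)
        cx2, cy2 = _xy(*c2)
        x, y = _xy(*arc2[0])
        cmds.append(f"C {cx1} {cy1} {cx2} {cy2} {x} {y}")
        for pt in arc2[1:]:
            x, y = _xy(*pt)
            cmds.append(f"L {x} {y}")
        cx3, cy3 = _xy(*c3)
        cx4, cy4 = _xy(*c4)
        x, y = _xy(*arc1[0])
        cmds.append(f"C {cx3} {cy3} {cx4} {cy4} {x} {y}")
        cmds.append("Z")
        return _path(" ".join(cmds), prim.style)
    if isinstance(prim, TextPrim):
        x, y = _xy(prim.cx, prim.cy)
        attrs = _style_attrs(prim.style)
        rot = ""
        if prim.angle != 0.0:
            rot = f' transform="rotate({_fmt(-prim.angle)} {x} {y})"'
        return (f'<text x="{x}" y="{y}"{rot}'
                + (f" {attrs}" if attrs else "")
                + f">{escape(prim.content)}</text>")
    raise TypeError(f"unknown primitive {type(prim).__name__}")


def scene_to_svg(scene: Scene, size: int = 600) -> str:
    """Serialize a scene to an SVG 1.1 document string."""
    lines = [
        '<?xml version="1.0" encoding="UTF-8"?>',
        (f'<svg xmlns="http://www.w3.org/2000/svg" version="1.1" '
         f'width="{size}" height="{size}" viewBox="-1.1 -1.1 2.2 2.2">'),
        '<g stroke-width="0.002">',
    ]
    lines.extend(_emit(p) for p in scene.primitives)
    lines.append("</g>")
    lines.append("</svg>")
    return "\n".join(lines) + "\n"


def write_svg(scene: Scene, destination: Any, size: int = 600) -> None:
    """Write a scene to ``destination`` (path or text stream)."""
    doc = scene_to_svg(scene, size=size)
    if hasattr(destination, "write"):
        destination.write(doc)
    else:
        with open(destination, "w", encoding="utf-8") as fh:
            fh.write(doc)
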