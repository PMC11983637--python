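"""Deferred evaluation: turn a completed plot description into a Scene.

Nothing is computed while components are being composed; :func:`show`
performs the whole pipeline in a fixed order:

1. resolve global parameters from the accumulated Par components;
2. initialize sectors from the init mode (ideogram tracks are prepended
   for genomic modes);
3. lay out and draw tracks in addition order — for each track its panel,
   then track-wide geoms, then each cell's geoms in addition order;
4. draw links last, anchored at the innermost free radius.

``show`` is pure: re-invoking it on the same plot yields an identical
scene, so serialized output is byte-for-byte reproducible.
"""

from __future__ import annotations

import math
from typing import Any, Mapping

import numpy as np
import pandas as pd

from . import synth as _synth_mod  # deferred default genome (imported lazily below)
from .errors import (
    CircogramError,
    EmptyInterval,
    MissingInitArgument,
    UnknownSector,
)
from .geoms import (
    DEFAULT_AES,
    resolve_geom_data,
    resolve_track_geom,
)
from .genomic import (
    CytobandTable,
    GenomicCellGeomSpec,
    GenomicLinkSpec,
    GenomicTable,
    GenomicTrackSpec,
    HeatmapLinkSpec,
    STAIN_FILL,
    base_sector,
    genomic_initialize,
    read_cytoband,
)
from .grammar import ABSENT, GlobalParams, LinkSpec, PlotSpec, TrackSpec, resolve_pars
from .layout import (
    PolarPoint,
    SectorLayout,
    TrackBand,
    allocate_sectors,
    allocate_tracks,
    cell_to_polar,
    point_in_cell,
    polar_to_canvas,
    with_ylim,
)
from .scene import (
    ArcBandPrim,
    PointPrim,
    PolygonPrim,
    PolylinePrim,
    RibbonPrim,
    Scene,
    TextPrim,
)

__all__ = ["show", "draw_link"]

_BEZIER_SEGMENTS = 32


# ---------------------------------------------------------------------------
# Initialization dispatch
# ---------------------------------------------------------------------------

def _init_sectors(
    plot: PlotSpec,
) -> tuple[dict[str, tuple[float, float]], dict[str, float] | None,
           tuple[TrackSpec, ...]]:
    mode = plot.init_mode
    args = dict(plot.init_args)
    if mode == "initialize":
        cats, xlims = args["categories"], args["xlims"]
        return {str(c): (float(a), float(b)) for c, (a, b) in zip(cats, xlims)}, None, ()
    if mode == "heatmap.initialize":
        mat = np.asarray(args["matrix"], dtype=float)
        if mat.ndim != 2:
            raise MissingInitArgument("heatmap matrix must be 2-D")
        split = args.get("split")
        if split is None:
            return {"mat": (0.0, float(mat.shape[1]))}, None, ()
        out: dict[str, tuple[float, float]] = {}
        labels = [str(s) for s in split]
        if len(labels) != mat.shape[1]:
            raise MissingInitArgument(
                f"split has {len(labels)} labels for {mat.shape[1]} columns"
            )
        for lab in dict.fromkeys(labels):
            out[lab] = (0.0, float(labels.count(lab)))
        return out, None, ()
    # genomic modes
    zoom = args.get("zoom")
    if zoom is not None:
        zoom = (list(zoom[0]), float(zoom[1]))
    if mode == "initializeWithIdeogram":
        cyto = args.get("cytoband")
        if cyto is None:
            cyto = _synth_mod.default_genome().cytobands
        elif isinstance(cyto, (str, bytes)) or hasattr(cyto, "read"):
            cyto = read_cytoband(cyto)
        init = genomic_initialize(cyto, plot_type=args.get("plot_type", ("ideogram",)),
                                  zoom=zoom)
        return init.xlims, init.weights, init.tracks
    # genomicInitialize: data is a GenomicTable or a chrom-length mapping
    data = args["data"]
    if isinstance(data, GenomicTable):
        lengths = {c: int(data.for_chrom(c)["end"].max()) for c in data.chroms}
    elif isinstance(data, CytobandTable):
        lengths = data.chrom_lengths
    else:
        lengths = {str(k): int(v) for k, v in dict(data).items()}
    init = genomic_initialize(lengths, plot_type=args.get("plot_type", ()), zoom=zoom)
    return init.xlims, init.weights, init.tracks


# ---------------------------------------------------------------------------
# Primitive emission helpers
# ---------------------------------------------------------------------------

class _Emitter:
    """Accumulates primitives and the clip-warning count."""

    def __init__(self) -> None:
        self.prims: list[Any] = []
        self.clips = 0

    def point(self, sector: SectorLayout, band: TrackBand, x: float, y: float,
              size: float, style: dict[str, Any]) -> None:
        if not point_in_cell(sector, band, x, y):
            self.clips += 1
        cx, cy = polar_to_canvas(cell_to_polar(sector, band, x, y))
        self.prims.append(PointPrim(cx=cx, cy=cy, size=size,
                                    style=tuple(sorted(style.items()))))

    def mapped(self, sector: SectorLayout, band: TrackBand, x: float, y: float,
               ) -> tuple[float, float]:
        if not point_in_cell(sector, band, x, y):
            self.clips += 1
        return polar_to_canvas(cell_to_polar(sector, band, x, y))


def _arc_band(sector: SectorLayout, band: TrackBand, x0: float, x1: float,
              y0: float, y1: float, style: dict[str, Any]) -> ArcBandPrim:
    x0 = min(max(x0, sector.xlim[0]), sector.xlim[1])
    x1 = min(max(x1, sector.xlim[0]), sector.xlim[1])
    y0 = min(max(y0, band.ylim[0]), band.ylim[1])
    y1 = min(max(y1, band.ylim[0]), band.ylim[1])
    return ArcBandPrim(
        theta1=sector.x_to_theta(x0),
        theta2=sector.x_to_theta(x1),
        r_inner=band.y_to_r(min(y0, y1)),
        r_outer=band.y_to_r(max(y0, y1)),
        style=tuple(sorted(style.items())),
    )


def _grey_ramp(frac: float) -> str:
    v = int(round(255 * (1.0 - min(max(frac, 0.0), 1.0))))
    return f"#{v:02x}{v:02x}{v:02x}"


def _text_angle(theta: float, facing: str) -> float:
    if facing == "upright":
        return 0.0
    ang = theta % 360.0
    # tangential with an upright flip so labels on the lower half read
    # left-to-right
    if 90.0 < ang <= 270.0:
        return theta + 90.0
    return theta - 90.0


def _per_point(aes_value: Any, i: int) -> Any:
    if isinstance(aes_value, (list, tuple, np.ndarray)):
        return aes_value[i]
    return aes_value


def _emit_resolved(em: _Emitter, kind: str, x: np.ndarray, y: np.ndarray,
                   aes: Mapping[str, Any], sector: SectorLayout, band: TrackBand,
                   meta: dict[str, Any]) -> None:
    if kind == "points":
        for i in range(len(x)):
            style = {"fill": _per_point(aes["color"], i), "stroke": None,
                     "opacity": aes["alpha"], **meta}
            em.point(sector, band, float(x[i]), float(y[i]),
                     size=float(aes["size"]), style=style)
    elif kind == "lines":
        pts = tuple(em.mapped(sector, band, float(xi), float(yi))
                    for xi, yi in zip(x, y))
        if len(pts) >= 2:
            style = {"fill": "none", "stroke": aes["color"],
                     "stroke-width": 0.002 * float(aes["width"]),
                     "opacity": aes["alpha"], **meta}
            em.prims.append(PolylinePrim(points=pts,
                                         style=tuple(sorted(style.items()))))
    elif kind == "text":
        labels = aes.get("labels")
        if labels is None:
            labels = [""] * len(x)
        for i in range(len(x)):
            p = cell_to_polar(sector, band, float(x[i]), float(y[i]))
            cx, cy = polar_to_canvas(p)
            style = {"fill": _per_point(aes["color"], i),
                     "font-size": 0.004 * float(aes["font_size"]),
                     "opacity": aes["alpha"], **meta}
            em.prims.append(TextPrim(cx=cx, cy=cy,
                                     angle=_text_angle(p.theta, aes["facing"]),
                                     content=str(_per_point(labels, i)),
                                     style=tuple(sorted(style.items()))))
    elif kind == "axis":
        n_ticks = int(aes["ticks"])
        lo, hi = sector.xlim
        ticks = np.linspace(lo, hi, n_ticks)
        y_axis = band.ylim[1] if aes["side"] == "top" else band.ylim[0]
        r_axis = band.y_to_r(y_axis)
        base = {"fill": "none", "stroke": aes["color"], **meta}
        arc_pts = tuple(
            polar_to_canvas(PolarPoint(sector.x_to_theta(lo + (hi - lo) * i / 32),
                                       r_axis))
            for i in range(33)
        )
        em.prims.append(PolylinePrim(points=arc_pts,
                                     style=tuple(sorted(base.items()))))
        tick_len = 0.015 if aes["side"] == "top" else -0.015
        for i, tx in enumerate(ticks):
            th = sector.x_to_theta(float(tx))
            p0 = polar_to_canvas(PolarPoint(th, r_axis))
            p1 = polar_to_canvas(PolarPoint(th, r_axis + tick_len))
            em.prims.append(PolylinePrim(points=(p0, p1),
                                         style=tuple(sorted(base.items()))))
            style = {"fill": aes["color"], "font-size": 0.004 * float(aes["font_size"]),
                     **meta}
            lx, ly = polar_to_canvas(PolarPoint(th, r_axis + 2.2 * tick_len))
            em.prims.append(TextPrim(cx=lx, cy=ly, angle=_text_angle(th, "tangential"),
                                     content=f"{tx:g}",
                                     style=tuple(sorted(style.items()))))
    elif kind == "rect":
        n = max(len(x), 1)
        width = aes.get("bar_width") or (sector.xlim[1] - sector.xlim[0]) / n
        for i in range(len(x)):
            style = {"fill": _per_point(aes["fill"], i), "stroke": aes["border"],
                     "opacity": aes["alpha"], **meta}
            em.prims.append(_arc_band(sector, band,
                                      float(x[i]) - width / 2.0,
                                      float(x[i]) + width / 2.0,
                                      band.ylim[0], float(y[i]), style))
    elif kind == "heatmap-cells":
        n = max(len(x), 1)
        width = (sector.xlim[1] - sector.xlim[0]) / n
        lo, hi = band.ylim
        for i in range(len(x)):
            frac = (float(y[i]) - lo) / (hi - lo) if hi > lo else 0.0
            style = {"fill": _grey_ramp(frac), "stroke": aes.get("border"),
                     "opacity": aes["alpha"], **meta}
            em.prims.append(_arc_band(sector, band,
                                      float(x[i]) - width / 2.0,
                                      float(x[i]) + width / 2.0,
                                      lo, hi, style))
    else:  # pragma: no cover - registry guards kinds upstream
        raise CircogramError(f"no drawing rule for geom kind {kind!r}")


# ---------------------------------------------------------------------------
# Track drawing
# ---------------------------------------------------------------------------

def _track_ylim(track: TrackSpec) -> tuple[float, float]:
    if track.ylim is not None:
        return track.ylim
    if track.panel_kind == "ideogram":
        return (0.0, 1.0)
    if track.sector_data is not None and "y" in track.sector_data.columns:
        y = track.sector_data["y"].to_numpy(dtype=float)
        if len(y):
            lo, hi = float(np.min(y)), float(np.max(y))
            if hi > lo:
                pad = 0.05 * (hi - lo)
                return (lo - pad, hi + pad)
            return (lo - 0.5, hi + 0.5)
    return (0.0, 1.0)


def _sector_lookup_id(track: TrackSpec, sector_id: str) -> str:
    return base_sector(sector_id) if isinstance(track, GenomicTrackSpec) else sector_id


def _draw_ideogram(em: _Emitter, track: GenomicTrackSpec, sector: SectorLayout,
                   band: TrackBand, meta: dict[str, Any]) -> None:
    df = track.genomic_data.for_chrom(base_sector(sector.sector_id))
    acen_rows = df[df["stain"] == "acen"]
    for _, row in df.iterrows():
        stain = row["stain"]
        if stain == "acen":
            continue
        style = {"fill": STAIN_FILL[stain], "stroke": "#000000", **meta}
        em.prims.append(_arc_band(sector, band, float(row["start"]),
                                  float(row["end"]), 0.0, 1.0, style))
    # centromere: paired acen bands drawn as triangles pointing to their
    # shared boundary
    for j, (_, row) in enumerate(acen_rows.iterrows()):
        apex_x = float(row["end"]) if j == 0 else float(row["start"])
        base_x = float(row["start"]) if j == 0 else float(row["end"])
        pts = (
            em.mapped(sector, band, base_x, 0.0),
            em.mapped(sector, band, base_x, 1.0),
            em.mapped(sector, band, apex_x, 0.5),
        )
        style = {"fill": STAIN_FILL["acen"], "stroke": "none", **meta}
        em.prims.append(PolygonPrim(points=pts, style=tuple(sorted(style.items()))))


def _resolve_genomic_geom(
    geom: GenomicCellGeomSpec, track: GenomicTrackSpec, chrom: str
) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    if geom.data is ABSENT:
        if track.genomic_data is None:
            raise CircogramError(
                f"genomic geom has no data and the track has none for {chrom!r}"
            )
        df = track.genomic_data.for_chrom(chrom)
    elif callable(geom.data):
        default = (track.genomic_data.for_chrom(chrom)
                   if track.genomic_data is not None else pd.DataFrame())
        df = geom.data(default)
    else:
        df = geom.data.for_chrom(chrom)
    x = (df["start"].to_numpy(dtype=float) + df["end"].to_numpy(dtype=float)) / 2.0
    vcol = geom.value_column
    if vcol is None:
        numeric = [c for c in df.columns[3:]
                   if pd.api.types.is_numeric_dtype(df[c])]
        vcol = numeric[0] if numeric else None
    y = (df[vcol].to_numpy(dtype=float) if vcol is not None
         else np.zeros(len(df)))
    return df.reset_index(drop=True), x, y


def _draw_track(em: _Emitter, index: int, track: TrackSpec,
                sectors: list[SectorLayout], band: TrackBand) -> None:
    band = with_ylim(band, _track_ylim(track))
    for sector in sectors:
        meta = {"track": index, "sector": sector.sector_id}
        # cell border
        border_style = {"fill": "none", "stroke": "#999999", **meta, "role": "border"}
        em.prims.append(ArcBandPrim(theta1=sector.start_angle,
                                    theta2=sector.end_angle,
                                    r_inner=band.r_inner, r_outer=band.r_outer,
                                    style=tuple(sorted(border_style.items()))))
        lookup = _sector_lookup_id(track, sector.sector_id)
        # panel
        if track.panel_kind == "ideogram":
            _draw_ideogram(em, track, sector, band, meta)
        elif track.panel_kind in ("points", "lines", "heatmap") \
                and track.sector_data is not None:
            sub = track.sector_data[
                track.sector_data["category"].astype(str) == lookup]
            x = sub["x"].to_numpy(dtype=float)
            y = (sub["y"].to_numpy(dtype=float) if "y" in sub.columns
                 else np.zeros(len(sub)))
            kind = {"points": "points", "lines": "lines",
                    "heatmap": "heatmap-cells"}[track.panel_kind]
            aes = {**DEFAULT_AES[kind]}
            _emit_resolved(em, kind, x, y, aes, sector, band,
                           {**meta, "role": "panel"})
        # track-wide geoms, addition order
        for g in track.track_geoms:
            if isinstance(g, GenomicCellGeomSpec):  # genomic geom used track-wide
                _, x, y = _resolve_genomic_geom(g, track, lookup)
                aes = {**DEFAULT_AES[g.kind], **g.aesthetics}
                _emit_resolved(em, g.kind, x, y, aes, sector, band,
                               {**meta, "role": "trackgeom"})
            else:
                try:
                    resolved = resolve_track_geom(g, track, lookup)
                except CircogramError:
                    if g.data is None and track.sector_data is None:
                        raise
                    resolved = None
                if resolved is not None:
                    _emit_resolved(em, resolved.kind, resolved.x_values,
                                   resolved.y_values, resolved.aesthetics,
                                   sector, band, {**meta, "role": "trackgeom"})
        # cells targeted at this sector, addition order
        for cell in track.cells:
            if cell.sector_id not in (sector.sector_id, lookup):
                continue
            for g in cell.cell_geoms:
                if isinstance(g, GenomicCellGeomSpec):
                    _, x, y = _resolve_genomic_geom(g, track, lookup)
                    aes = {**DEFAULT_AES[g.kind], **g.aesthetics}
                    _emit_resolved(em, g.kind, x, y, aes, sector, band,
                                   {**meta, "role": "cellgeom"})
                else:
                    resolved = resolve_geom_data(g, track, lookup)
                    _emit_resolved(em, resolved.kind, resolved.x_values,
                                   resolved.y_values, resolved.aesthetics,
                                   sector, band, {**meta, "role": "cellgeom"})


# ---------------------------------------------------------------------------
# Links
# ---------------------------------------------------------------------------

def _endpoint_theta(sectors_by_id: dict[str, SectorLayout], sector_id: str,
                    pos: float) -> float:
    if sector_id not in sectors_by_id:
        raise UnknownSector(f"link endpoint references unknown sector {sector_id!r}")
    sec = sectors_by_id[sector_id]
    x = min(max(pos, sec.xlim[0]), sec.xlim[1])
    return sec.x_to_theta(x)


def _bezier_points(p1: tuple[float, float], c1: tuple[float, float],
                   c2: tuple[float, float], p2: tuple[float, float],
                   ) -> tuple[tuple[float, float], ...]:
    out = []
    for i in range(_BEZIER_SEGMENTS + 1):
        t = i / _BEZIER_SEGMENTS
        mt = 1.0 - t
        x = (mt ** 3 * p1[0] + 3 * mt ** 2 * t * c1[0]
             + 3 * mt * t ** 2 * c2[0] + t ** 3 * p2[0])
        y = (mt ** 3 * p1[1] + 3 * mt ** 2 * t * c1[1]
             + 3 * mt * t ** 2 * c2[1] + t ** 3 * p2[1])
        out.append((x, y))
    return tuple(out)


def _polar(theta: float, r: float) -> tuple[float, float]:
    t = math.radians(theta)
    return (r * math.cos(t), r * math.sin(t))


def _ribbon(theta_1a: float, theta_1b: float, theta_2a: float, theta_2b: float,
            radius: float, style: dict[str, Any]) -> RibbonPrim:
    if theta_1a == theta_1b or theta_2a == theta_2b:
        raise EmptyInterval("ribbon endpoint interval has zero angular width")
    return RibbonPrim(theta_1a=theta_1a, theta_1b=theta_1b,
                      theta_2a=theta_2a, theta_2b=theta_2b,
                      radius=radius, h=0.5 * radius,
                      style=tuple(sorted(style.items())))


def draw_link(link: LinkSpec, sectors: list[SectorLayout], anchor_radius: float,
              params: GlobalParams | None = None) -> list[Any]:
    """Primitives for one link component.

    Point-to-point links become a single cubic Bezier pulled toward the
    origin (control radius ``h``, default half the anchor radius); interval
    links become ribbons.  The anchor radius is the innermost free radius
    times the link's scale factor; scaling never moves endpoint angles.
    """
    by_id = {s.sector_id: s for s in sectors}
    radius = anchor_radius * link.scale
    color = link.aesthetics.get("color", "black")
    alpha = link.aesthetics.get("alpha", 1.0)

    if isinstance(link, GenomicLinkSpec):
        prims: list[Any] = []
        values = link.values if isinstance(link, HeatmapLinkSpec) else None
        vmin = min(values) if values else 0.0
        vspan = (max(values) - vmin) if values and max(values) > vmin else 1.0
        for i, (ep1, ep2) in enumerate(link.rows()):
            (s1, (a1, b1)), (s2, (a2, b2)) = ep1, ep2
            t1a = _endpoint_theta(by_id, s1, a1)
            t1b = _endpoint_theta(by_id, s1, b1)
            t2a = _endpoint_theta(by_id, s2, a2)
            t2b = _endpoint_theta(by_id, s2, b2)
            fill = (_grey_ramp((values[i] - vmin) / vspan) if values is not None
                    else _per_point(color, i))
            style = {"fill": fill, "stroke": "none", "opacity": alpha,
                     "role": "link", "link_index": i}
            prims.append(_ribbon(t1a, t1b, t2a, t2b, radius, style))
        return prims

    (s1, p1), (s2, p2) = link.endpoint_1, link.endpoint_2
    if link.kind == "interval-ribbon":
        i1 = p1 if isinstance(p1, (tuple, list)) else (p1, p1)
        i2 = p2 if isinstance(p2, (tuple, list)) else (p2, p2)
        style = {"fill": color, "stroke": "none", "opacity": alpha, "role": "link"}
        return [_ribbon(_endpoint_theta(by_id, s1, i1[0]),
                        _endpoint_theta(by_id, s1, i1[1]),
                        _endpoint_theta(by_id, s2, i2[0]),
                        _endpoint_theta(by_id, s2, i2[1]),
                        radius, style)]
    t1 = _endpoint_theta(by_id, s1, p1)
    t2 = _endpoint_theta(by_id, s2, p2)
    h = link.aesthetics.get("h", 0.5 * radius)
    pts = _bezier_points(_polar(t1, radius), _polar(t1, h),
                         _polar(t2, h), _polar(t2, radius))
    style = {"fill": "none", "stroke": color, "opacity": alpha,
             "role": "link", "link_radius": round(radius, 9)}
    return [PolylinePrim(points=pts, style=tuple(sorted(style.items())))]


# ---------------------------------------------------------------------------
# show
# ---------------------------------------------------------------------------

def show(plot: PlotSpec) -> Scene:
    """Evaluate a plot description into a Scene (pure, deterministic)."""
    xlims, weights, prelude = _init_sectors(plot)
    params = resolve_pars(plot.pars, n_sectors=len(xlims))
    sectors = allocate_sectors(xlims, params, weights=weights)

    tracks = tuple(prelude) + tuple(plot.tracks)
    heights = [t.height if t.height is not None else params.default_track_height
               for t in tracks]
    bands = allocate_tracks(heights, margins=params.track_margin)

    em = _Emitter()
    for i, (track, band) in enumerate(zip(tracks, bands)):
        try:
            _draw_track(em, i, track, sectors, band)
        except CircogramError as exc:
            raise type(exc)(f"[track {i}] {exc}") from exc

    anchor = min((b.r_inner for b in bands), default=1.0)
    for j, link in enumerate(plot.links):
        try:
            em.prims.extend(draw_link(link, sectors, anchor, params))
        except CircogramError as exc:
            raise type(exc)(f"[link {j}] {exc}") from exc

    return Scene(primitives=tuple(em.prims), clip_warnings=em.clips)
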