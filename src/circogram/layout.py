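"""Circular layout geometry.

Sectors receive angular spans on the unit circle proportionally to their
data ranges (or to explicit width weights, used by zoomed initialization);
tracks receive concentric radial bands stacked inward from the rim; each
cell then carries a local (x, y) coordinate system that maps linearly onto
(angle, radius).

Conventions: angles are in degrees, measured counter-clockwise from the
+x axis (3 o'clock).  The default direction of sector succession is
clockwise, i.e. angles decrease, matching the familiar look of circular
genome plots.  The canvas radius is 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

from .errors import DegenerateRange, GapOverflow, RadiusExhausted
from .grammar import GlobalParams

__all__ = [
    "SectorLayout",
    "TrackBand",
    "PolarPoint",
    "allocate_sectors",
    "allocate_tracks",
    "cell_to_polar",
    "polar_to_canvas",
]


@dataclass(frozen=True)
class SectorLayout:
    """Resolved angular span of one sector.

    ``start_angle``/``end_angle`` are signed degrees; for a clockwise
    layout ``end_angle < start_angle``.  The sweep magnitude is
    proportional to the sector's share of the usable (non-gap) circle.
    """

    sector_id: str
    xlim: tuple[float, float]
    start_angle: float
    end_angle: float

    @property
    def sweep(self) -> float:
        """Signed angular extent in degrees."""
        return self.end_angle - self.start_angle

    def x_to_theta(self, x: float) -> float:
        lo, hi = self.xlim
        frac = (x - lo) / (hi - lo)
        return self.start_angle + frac * self.sweep


@dataclass(frozen=True)
class TrackBand:
    """Radial band of one track; track 0 is outermost."""

    track_index: int
    r_outer: float
    r_inner: float
    ylim: tuple[float, float] = (0.0, 1.0)

    def y_to_r(self, y: float) -> float:
        lo, hi = self.ylim
        frac = (y - lo) / (hi - lo)
        return self.r_inner + frac * (self.r_outer - self.r_inner)


@dataclass(frozen=True)
class PolarPoint:
    theta: float  # degrees
    r: float      # fraction of canvas radius

    def __post_init__(self) -> None:
        if self.r < 0:
            raise ValueError(f"polar radius must be >= 0, got {self.r}")


def allocate_sectors(
    xlims: Mapping[str, tuple[float, float]],
    params: GlobalParams,
    weights: Mapping[str, float] | None = None,
) -> list[SectorLayout]:
    """Allocate angular spans to sectors.

    The usable sweep is 360 minus the total gap; it is divided among the
    sectors proportionally to their xlim ranges, or to explicit ``weights``
    when given (zoomed layouts weight sectors independently of data range).
    The first sector starts at ``params.start_degree``; gap ``i`` follows
    sector ``i``; direction follows ``params.clockwise``.
    """
    ids = list(xlims)
    if not ids:
        raise DegenerateRange("at least one sector is required")
    gaps = params.gaps_for(len(ids))
    total_gap = sum(gaps)
    if total_gap >= 360.0:
        raise GapOverflow(f"total gap {total_gap} degrees leaves no sweep")

    ranges = {}
    for sid in ids:
        lo, hi = xlims[sid]
        if not hi > lo:
            raise DegenerateRange(f"sector {sid!r} xlim ({lo}, {hi}) has max <= min")
        ranges[sid] = hi - lo
    share = dict(ranges) if weights is None else {sid: float(weights[sid]) for sid in ids}
    total_share = sum(share.values())
    if total_share <= 0:
        raise DegenerateRange("sector width weights must be positive")

    usable = 360.0 - total_gap
    sign = -1.0 if params.clockwise else 1.0
    cursor = params.start_degree
    out: list[SectorLayout] = []
    for sid, gap in zip(ids, gaps):
        width = usable * share[sid] / total_share
        start, end = cursor, cursor + sign * width
        out.append(SectorLayout(sector_id=sid, xlim=tuple(xlims[sid]),
                                start_angle=start, end_angle=end))
        cursor = end + sign * gap
    return out


def allocate_tracks(
    heights: Sequence[float],
    margins: float | tuple[float, float] = (0.01, 0.01),
    outer_margin: float = 0.0,
) -> list[TrackBand]:
    """Stack track bands inward from the rim.

    ``margins`` is the inter-track spacing: a scalar, or a (bottom, top)
    pair whose sum separates consecutive bands.  Raises
    :class:`RadiusExhausted` when a band would close at ``r_inner <= 0``.
    """
    gap = float(margins) if isinstance(margins, (int, float)) else float(sum(margins))
    r = 1.0 - outer_margin
    bands: list[TrackBand] = []
    for i, h in enumerate(heights):
        if not 0.0 < h <= 1.0:
            raise RadiusExhausted(f"track {i} height {h} must be in (0, 1]")
        inner = r - h
        if inner <= 0.0:
            raise RadiusExhausted(
                f"track {i} band ({r:.3f}, {inner:.3f}) exhausts the unit radius"
            )
        bands.append(TrackBand(track_index=i, r_outer=r, r_inner=inner))
        r = inner - gap
    return bands


def cell_to_polar(
    sector: SectorLayout,
    band: TrackBand,
    x: float,
    y: float,
    clip: bool = True,
) -> PolarPoint:
    """Map cell-local (x, y) to polar (theta, r).

    x maps linearly from the sector's xlim onto its angular span; y maps
    linearly from the band's ylim onto [r_inner, r_outer], increasing
    outward.  With ``clip`` (the default) out-of-range coordinates are
    clamped to the cell boundary; use :func:`point_in_cell` to detect
    overflow before clipping.
    """
    if clip:
        x = min(max(x, sector.xlim[0]), sector.xlim[1])
        y = min(max(y, band.ylim[0]), band.ylim[1])
    return PolarPoint(theta=sector.x_to_theta(x), r=band.y_to_r(y))


def point_in_cell(sector: SectorLayout, band: TrackBand, x: float, y: float) -> bool:
    """True when (x, y) lies inside the cell's data ranges."""
    return (sector.xlim[0] <= x <= sector.xlim[1]
            and band.ylim[0] <= y <= band.ylim[1])


def polar_to_canvas(p: PolarPoint) -> tuple[float, float]:
    """Polar to Cartesian canvas coordinates (unit circle, math convention)."""
    t = math.radians(p.theta)
    return (p.r * math.cos(t), p.r * math.sin(t))


def with_ylim(band: TrackBand, ylim: tuple[float, float]) -> TrackBand:
    """Copy of ``band`` with its data ylim attached."""
    lo, hi = ylim
    if not hi > lo:
        raise DegenerateRange(f"ylim ({lo}, {hi}) has max <= min")
    return replace(band, ylim=(float(lo), float(hi)))
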