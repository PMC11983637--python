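"""Genomic specializations of the grammar.

Interval tables use the UCSC/BED convention throughout: coordinates are
0-based, half-open ``[start, end)``.  Chromosomes are ordered naturally
(chr1 < chr2 < ... < chr10 < chrX), not lexicographically.

Provided here: readers for cytoBand.txt and BED-like files, ideogram /
zoomed sector initialization, genomic tracks whose x axis is the
chromosome, genomic cell geoms that default their region data from the
owning track, and genomic / heatmap link variants.
"""

from __future__ import annotations

import gzip
import io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    CoordinateError,
    InvalidParameterValue,
    InvalidStain,
    ParseError,
    RowCountMismatch,
    UnknownChromosome,
    UnknownGeomKind,
)
from .grammar import ABSENT, CellGeomSpec, LinkSpec, TrackSpec
from .geoms import _check_aes, DEFAULT_AES

__all__ = [
    "STAINS",
    "STAIN_FILL",
    "CytobandTable",
    "GenomicTable",
    "GenomicTrackSpec",
    "GenomicCellGeomSpec",
    "GenomicLinkSpec",
    "HeatmapLinkSpec",
    "LINK_SUBCLASSES",
    "read_cytoband",
    "read_bed_like",
    "write_bed_like",
    "genomic_initialize",
    "make_genomic_track",
    "make_genomic_cell_geom",
    "make_genomic_link",
    "make_heatmap_link",
    "natural_chrom_key",
    "base_sector",
    "zoom_sector_id",
]

#: Giemsa stain vocabulary of the UCSC cytoBand.txt dialect.
STAINS = frozenset(
    {"gneg", "gpos25", "gpos50", "gpos75", "gpos100", "acen", "gvar", "stalk"}
)

#: Stain to fill color; acen bands are rendered as red centromere triangles.
STAIN_FILL = {
    "gneg": "#ffffff",
    "gpos25": "#c8c8c8",
    "gpos50": "#969696",
    "gpos75": "#646464",
    "gpos100": "#000000",
    "gvar": "#dcdcdc",
    "stalk": "#6464a0",
    "acen": "#d92f27",
}

_ZOOM_SUFFIX = "_zoom"


def natural_chrom_key(chrom: str) -> tuple:
    """Sort key giving natural chromosome order (chr2 before chr10)."""
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


def zoom_sector_id(chrom: str) -> str:
    return chrom + _ZOOM_SUFFIX


def base_sector(sector_id: str) -> str:
    """Map a (possibly zoom-duplicated) sector id back to its chromosome."""
    if sector_id.endswith(_ZOOM_SUFFIX):
        return sector_id[: -len(_ZOOM_SUFFIX)]
    return sector_id


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class CytobandTable:
    """Validated cytogenetic band table (chrom, start, end, name, stain)."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        required = ["chrom", "start", "end", "name", "stain"]
        if list(df.columns[:5]) != required:
            raise ParseError(f"cytoband table must have columns {required}")
        bad = set(df["stain"]) - STAINS
        if bad:
            raise InvalidStain(f"unknown stain codes: {sorted(bad)}")
        if (df["start"] >= df["end"]).any():
            raise CoordinateError("cytoband rows must have start < end")
        for chrom, sub in df.groupby("chrom", sort=False):
            if not sub["start"].is_monotonic_increasing:
                raise ParseError(f"bands of {chrom} are not sorted by start")
        object.__setattr__(self, "df", df)

    @property
    def chroms(self) -> tuple[str, ...]:
        """Chromosome labels in natural order."""
        seen = dict.fromkeys(self.df["chrom"].astype(str))
        return tuple(sorted(seen, key=natural_chrom_key))

    @property
    def chrom_lengths(self) -> dict[str, int]:
        return {c: int(self.df.loc[self.df["chrom"] == c, "end"].max())
                for c in self.chroms}

    def __len__(self) -> int:
        return len(self.df)


@dataclass(frozen=True, eq=False)
class GenomicTable:
    """Interval table: (chrom, start, end, value columns...), 0-based half-open."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df.reset_index(drop=True)
        if list(df.columns[:3]) != ["chrom", "start", "end"]:
            raise CoordinateError(
                "genomic table must start with columns chrom, start, end"
            )
        if len(df) and (df["start"] < 0).any():
            raise CoordinateError("genomic start coordinates must be >= 0")
        if len(df) and (df["start"] >= df["end"]).any():
            raise CoordinateError("genomic rows must have start < end")
        object.__setattr__(self, "df", df)

    @property
    def value_columns(self) -> tuple[str, ...]:
        return tuple(self.df.columns[3:])

    @property
    def chroms(self) -> tuple[str, ...]:
        seen = dict.fromkeys(self.df["chrom"].astype(str))
        return tuple(sorted(seen, key=natural_chrom_key))

    def for_chrom(self, chrom: str) -> pd.DataFrame:
        return self.df[self.df["chrom"].astype(str) == chrom]

    def midpoints(self) -> np.ndarray:
        return (self.df["start"].to_numpy(dtype=float)
                + self.df["end"].to_numpy(dtype=float)) / 2.0

    def __len__(self) -> int:
        return len(self.df)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _open_text(source: Any) -> io.TextIOBase:
    if hasattr(source, "read"):
        return source
    path = Path(source)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="utf-8")
    return open(path, "r", encoding="utf-8")


def read_cytoband(source: Any) -> CytobandTable:
    """Parse a UCSC cytoBand.txt stream (5-column TSV, plain or gzip).

    Chromosome first-appearance order is preserved in the table; parse
    failures report the offending line number.
    """
    rows = []
    fh = _open_text(source)
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise ParseError(
                    f"line {lineno}: expected 5 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, start_s, end_s, name, stain = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate") from exc
            if start < 0:
                raise ParseError(f"line {lineno}: negative start {start}")
            if start >= end:
                raise ParseError(f"line {lineno}: start {start} >= end {end}")
            if stain not in STAINS:
                raise InvalidStain(f"line {lineno}: unknown stain {stain!r}")
            rows.append((chrom, start, end, name, stain))
    finally:
        if not hasattr(source, "read"):
            fh.close()
    if not rows:
        raise ParseError("cytoband source contains no records")
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "stain"])
    return CytobandTable(df)


def read_bed_like(source: Any, value_columns: int | None = None) -> GenomicTable:
    """Parse a BED-like stream: chrom, start, end plus optional value columns.

    ``value_columns`` pins the expected number of extra columns; by default
    it is inferred from the first record.  Extra columns are parsed as
    floats where possible, else kept as strings.
    """
    rows: list[list[Any]] = []
    n_extra = value_columns
    fh = _open_text(source)
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"line {lineno}: expected >= 3 tab-separated fields"
                )
            if n_extra is None:
                n_extra = len(fields) - 3
            if len(fields) - 3 != n_extra:
                raise ParseError(
                    f"line {lineno}: expected {n_extra} value columns, "
                    f"got {len(fields) - 3}"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer coordinate") from exc
            if start < 0:
                raise CoordinateError(f"line {lineno}: negative start {start}")
            if start >= end:
                raise CoordinateError(f"line {lineno}: start {start} >= end {end}")
            extras: list[Any] = []
            for v in fields[3:]:
                try:
                    extras.append(float(v))
                except ValueError:
                    extras.append(v)
            rows.append([fields[0], start, end, *extras])
    finally:
        if not hasattr(source, "read"):
            fh.close()
    n_extra = n_extra or 0
    cols = ["chrom", "start", "end"] + [f"value{i+1}" if n_extra > 1 else "value"
                                        for i in range(n_extra)]
    df = pd.DataFrame(rows, columns=cols)
    return GenomicTable(df)


def write_bed_like(table: GenomicTable, destination: Any) -> None:
    """Write a genomic table as tab-separated BED-like text."""
    own = not hasattr(destination, "write")
    fh = open(destination, "w", encoding="utf-8") if own else destination
    try:
        for row in table.df.itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")
    finally:
        if own:
            fh.close()


# ---------------------------------------------------------------------------
# Genomic components
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class GenomicTrackSpec(TrackSpec):
    """Track whose x axis is genomic position; carries the interval table."""

    genomic_data: GenomicTable | None = None


@dataclass(frozen=True, eq=False)
class GenomicCellGeomSpec(CellGeomSpec):
    """Cell geometry over genomic regions.

    ``data`` may be :data:`ABSENT` (default from the owning genomic
    track's regions for the sector), a :class:`GenomicTable`, or a
    callable of the default per-sector region frame.
    """

    data: Any = ABSENT
    value_column: str | None = None


@dataclass(frozen=True, eq=False)
class GenomicLinkSpec(LinkSpec):
    """Many-row link: paired region tables joined by ribbons.

    ``endpoint_1``/``endpoint_2`` of the base class hold the first row so
    the link still composes under the Plot + Link rule; rendering iterates
    all rows.
    """

    regions_1: GenomicTable | None = None
    regions_2: GenomicTable | None = None

    def rows(self) -> Iterable[tuple[tuple[str, tuple[float, float]],
                                     tuple[str, tuple[float, float]]]]:
        for r1, r2 in zip(self.regions_1.df.itertuples(index=False),
                          self.regions_2.df.itertuples(index=False)):
            yield ((str(r1.chrom), (float(r1.start), float(r1.end))),
                   (str(r2.chrom), (float(r2.start), float(r2.end))))

    def is_intra(self) -> np.ndarray:
        """Boolean mask: True where both endpoints share a chromosome."""
        return (self.regions_1.df["chrom"].astype(str).to_numpy()
                == self.regions_2.df["chrom"].astype(str).to_numpy())


@dataclass(frozen=True, eq=False)
class HeatmapLinkSpec(GenomicLinkSpec):
    """Genomic link whose ribbons are shaded by a per-row value."""

    values: tuple[float, ...] = ()


#: The two specialized link kinds beyond the base link.
LINK_SUBCLASSES: tuple[type, ...] = (GenomicLinkSpec, HeatmapLinkSpec)


def make_genomic_track(
    data: GenomicTable,
    panel_kind: str = "points",
    ylim: tuple[float, float] | None = None,
    height: float | None = None,
    value_column: str | None = None,
) -> GenomicTrackSpec:
    """Track over a genomic interval table.

    Per-sector (category, x, y) data is derived from the intervals:
    category is the chromosome, x the interval midpoint, y the first value
    column (or ``value_column``), so the generic data-mapping rules apply
    unchanged.
    """
    if not isinstance(data, GenomicTable):
        data = GenomicTable(_coerce_frame(data))
    vcol = value_column or (data.value_columns[0] if data.value_columns else None)
    frame = pd.DataFrame({
        "category": data.df["chrom"].astype(str),
        "x": data.midpoints(),
    })
    if vcol is not None:
        frame["y"] = data.df[vcol].to_numpy(dtype=float)
    return GenomicTrackSpec(
        sector_data=frame.reset_index(drop=True),
        ylim=None if ylim is None else (float(ylim[0]), float(ylim[1])),
        height=None if height is None else float(height),
        panel_kind=panel_kind,
        genomic_data=data,
    )


_GENOMIC_GEOM_KINDS = ("points", "lines", "rect", "text")


def make_genomic_cell_geom(
    kind: str,
    data: Any = ABSENT,
    aesthetics: Mapping[str, Any] | None = None,
    value_column: str | None = None,
) -> GenomicCellGeomSpec:
    """Cell geometry over genomic regions; data may be deferred.

    With ``data`` absent the geometry takes the owning genomic track's
    regions for its sector at render time, exactly like the generic
    coordinate-defaulting rule.
    """
    if kind not in _GENOMIC_GEOM_KINDS:
        raise UnknownGeomKind(
            f"genomic geom kind {kind!r} not in {list(_GENOMIC_GEOM_KINDS)}"
        )
    aes = _check_aes(kind, aesthetics or {})
    if data is not ABSENT and not callable(data) and not isinstance(data, GenomicTable):
        data = GenomicTable(_coerce_frame(data))
    return GenomicCellGeomSpec(kind=kind, x=ABSENT, y=ABSENT, aesthetics=aes,
                               data=data, value_column=value_column)


def _coerce_frame(data: Any) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    return pd.DataFrame(dict(data))


def _first_row_endpoint(t: GenomicTable) -> tuple[str, tuple[float, float]]:
    if len(t) == 0:
        return ("", (0.0, 1.0))
    r = t.df.iloc[0]
    return (str(r["chrom"]), (float(r["start"]), float(r["end"])))


def make_genomic_link(
    regions_1: GenomicTable,
    regions_2: GenomicTable,
    aesthetics: Mapping[str, Any] | None = None,
    scale: float = 1.0,
) -> GenomicLinkSpec:
    """Paired-region link set; one ribbon per row."""
    if not isinstance(regions_1, GenomicTable):
        regions_1 = GenomicTable(_coerce_frame(regions_1))
    if not isinstance(regions_2, GenomicTable):
        regions_2 = GenomicTable(_coerce_frame(regions_2))
    if len(regions_1) != len(regions_2):
        raise RowCountMismatch(
            f"regions_1 has {len(regions_1)} rows, regions_2 has {len(regions_2)}"
        )
    return GenomicLinkSpec(
        endpoint_1=_first_row_endpoint(regions_1),
        endpoint_2=_first_row_endpoint(regions_2),
        aesthetics=dict(aesthetics or {}),
        scale=scale,
        regions_1=regions_1,
        regions_2=regions_2,
    )


def make_heatmap_link(
    regions_1: GenomicTable,
    regions_2: GenomicTable,
    values: Sequence[float],
    aesthetics: Mapping[str, Any] | None = None,
    scale: float = 1.0,
) -> HeatmapLinkSpec:
    """Link set shaded by a per-row value (greyscale ramp by default)."""
    if not isinstance(regions_1, GenomicTable):
        regions_1 = GenomicTable(_coerce_frame(regions_1))
    if not isinstance(regions_2, GenomicTable):
        regions_2 = GenomicTable(_coerce_frame(regions_2))
    if not (len(regions_1) == len(regions_2) == len(values)):
        raise RowCountMismatch(
            f"rows: regions_1={len(regions_1)}, regions_2={len(regions_2)}, "
            f"values={len(values)}"
        )
    return HeatmapLinkSpec(
        endpoint_1=_first_row_endpoint(regions_1),
        endpoint_2=_first_row_endpoint(regions_2),
        aesthetics=dict(aesthetics or {}),
        scale=scale,
        regions_1=regions_1,
        regions_2=regions_2,
        values=tuple(float(v) for v in values),
    )


# ---------------------------------------------------------------------------
# Initialization (ideogram + zoom)
# ---------------------------------------------------------------------------

@dataclass(frozen=True, eq=False)
class GenomicInit:
    """Resolved genomic initialization: sector xlims (addition order),
    angular width weights, and any ideogram tracks to prepend."""

    xlims: dict[str, tuple[float, float]]
    weights: dict[str, float] | None
    tracks: tuple[TrackSpec, ...]


def genomic_initialize(
    source: CytobandTable | Mapping[str, int],
    plot_type: Sequence[str] = ("ideogram",),
    zoom: tuple[Sequence[str], float] | None = None,
    ideogram_height: float = 0.08,
) -> GenomicInit:
    """Build sectors (one per chromosome) and optional ideogram tracks.

    ``source`` is either a cytoband table or a chrom -> length mapping.
    ``zoom`` = (chromosome subset, fraction) duplicates the named
    chromosomes as extra sectors whose combined angular width is forced to
    ``fraction`` of the usable circle via width weights; the remaining
    sectors share 1 - fraction proportionally to their lengths.  Each
    zoomed chromosome keeps its full (0, length) xlim, so every genomic
    record appears in both the normal and the zoomed sector.
    """
    if isinstance(source, CytobandTable):
        lengths = source.chrom_lengths
        cytobands: CytobandTable | None = source
    else:
        lengths = {str(k): int(v) for k, v in source.items()}
        cytobands = None
    chroms = sorted(lengths, key=natural_chrom_key)
    if not chroms:
        raise UnknownChromosome("no chromosomes in initialization source")

    xlims: dict[str, tuple[float, float]] = {
        c: (0.0, float(lengths[c])) for c in chroms
    }
    weights: dict[str, float] | None = None
    if zoom is not None:
        subset, fraction = zoom
        subset = [str(c) for c in subset]
        missing = [c for c in subset if c not in lengths]
        if missing:
            raise UnknownChromosome(f"zoom names unknown chromosomes: {missing}")
        if not 0.0 < fraction < 1.0:
            raise InvalidParameterValue("zoom fraction must be in (0, 1)")
        for c in subset:
            xlims[zoom_sector_id(c)] = (0.0, float(lengths[c]))
        normal_total = sum(lengths[c] for c in chroms)
        zoom_total = sum(lengths[c] for c in subset)
        weights = {}
        for c in chroms:
            weights[c] = (1.0 - fraction) * lengths[c] / normal_total
        for c in subset:
            weights[zoom_sector_id(c)] = fraction * lengths[c] / zoom_total

    tracks: tuple[TrackSpec, ...] = ()
    if cytobands is not None and "ideogram" in plot_type:
        ideo = GenomicTrackSpec(
            sector_data=None,
            ylim=(0.0, 1.0),
            height=float(ideogram_height),
            panel_kind="ideogram",
            genomic_data=GenomicTable(
                cytobands.df[["chrom", "start", "end", "name", "stain"]]
            ),
        )
        tracks = (ideo,)
    return GenomicInit(xlims=xlims, weights=weights, tracks=tracks)
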