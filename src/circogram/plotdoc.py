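"""Declarative plot documents (JSON/YAML).

A PlotDocument is a serializable description of a plot: an ``init`` block,
``pars``, ``tracks`` (with ``geoms`` and ``cells`` children) and ``links``,
under a ``version`` tag.  Documents round-trip losslessly for all
non-callable content; callable coordinate mappings are a library-only
feature and raise :class:`DocumentError` on serialization (no code in
config).

``validate_document`` performs structural (schema) validation and returns
path-anchored messages; ``from_document`` then *composes* the plot through
the normal grammar, so illegal compositions — e.g. a cell-scoped geom
placed directly in a track's geom list — surface as the grammar's own
errors, not as schema errors.
"""

from __future__ import annotations

from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import DocumentError, IllegalComposition
from .geoms import make_cell_geom, make_track, make_track_geom
from .genomic import (
    CytobandTable,
    GenomicLinkSpec,
    GenomicTable,
    GenomicTrackSpec,
    make_genomic_link,
    make_genomic_track,
)
from .grammar import (
    ABSENT,
    CellGeomSpec,
    CellSpec,
    LinkSpec,
    ParSpec,
    PlotSpec,
    TrackGeomSpec,
    TrackSpec,
    combine,
    make_link,
    make_plot,
)

__all__ = [
    "SCHEMA_VERSION",
    "load_document",
    "dump_document",
    "validate_document",
    "from_document",
    "to_document",
]

SCHEMA_VERSION = 1

_TRACK_KEYS = {"data", "genomic", "ylim", "height", "panel", "geoms", "cells"}
_GEOM_KEYS = {"kind", "scope", "data", "x", "y", "aes", "value_column"}
_LINK_KEYS = {"sector1", "pos1", "interval1", "sector2", "pos2", "interval2",
              "regions1", "regions2", "aes", "scale"}


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def load_document(source: Any) -> dict:
    """Parse a document from a path, stream, or string (YAML superset of JSON)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        try:
            with open(source, "r", encoding="utf-8") as fh:
                text = fh.read()
        except (OSError, ValueError):
            text = str(source)
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping):
        raise DocumentError("document root must be a mapping")
    return dict(doc)


def dump_document(doc: Mapping[str, Any], destination: Any = None) -> str:
    """Serialize a document to YAML (sorted keys, stable output)."""
    text = yaml.safe_dump(dict(doc), sort_keys=True, default_flow_style=None)
    if destination is not None:
        if hasattr(destination, "write"):
            destination.write(text)
        else:
            with open(destination, "w", encoding="utf-8") as fh:
                fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Schema validation
# ---------------------------------------------------------------------------

def validate_document(doc: Mapping[str, Any]) -> list[str]:
    """Structural validation; returns path-anchored error messages."""
    errors: list[str] = []
    if not isinstance(doc, Mapping):
        return ["document root must be a mapping"]
    if doc.get("version") != SCHEMA_VERSION:
        errors.append(f"version: expected {SCHEMA_VERSION}, got {doc.get('version')!r}")
    init = doc.get("init")
    if not isinstance(init, Mapping) or "mode" not in init:
        errors.append("init: required mapping with a 'mode' key")
    elif not isinstance(init["mode"], str):
        errors.append("init.mode: must be a string")
    if not isinstance(doc.get("pars", []), list):
        errors.append("pars: must be a list")
    else:
        for i, p in enumerate(doc.get("pars", [])):
            if not isinstance(p, Mapping):
                errors.append(f"pars[{i}]: must be a mapping")
    tracks = doc.get("tracks", [])
    if not isinstance(tracks, list):
        errors.append("tracks: must be a list")
        tracks = []
    for i, t in enumerate(tracks):
        if not isinstance(t, Mapping):
            errors.append(f"tracks[{i}]: must be a mapping")
            continue
        for key in set(t) - _TRACK_KEYS:
            errors.append(f"tracks[{i}].{key}: unknown key")
        for j, g in enumerate(t.get("geoms", []) or []):
            if not isinstance(g, Mapping):
                errors.append(f"tracks[{i}].geoms[{j}]: must be a mapping")
                continue
            if "kind" not in g:
                errors.append(f"tracks[{i}].geoms[{j}]: missing 'kind'")
            for key in set(g) - _GEOM_KEYS:
                errors.append(f"tracks[{i}].geoms[{j}].{key}: unknown key")
        for j, c in enumerate(t.get("cells", []) or []):
            if not isinstance(c, Mapping) or "sector" not in c:
                errors.append(f"tracks[{i}].cells[{j}]: required mapping with 'sector'")
                continue
            for k, g in enumerate(c.get("geoms", []) or []):
                if not isinstance(g, Mapping) or "kind" not in g:
                    errors.append(
                        f"tracks[{i}].cells[{j}].geoms[{k}]: required mapping "
                        f"with 'kind'")
    links = doc.get("links", [])
    if not isinstance(links, list):
        errors.append("links: must be a list")
        links = []
    for i, l in enumerate(links):
        if not isinstance(l, Mapping):
            errors.append(f"links[{i}]: must be a mapping")
            continue
        for key in set(l) - _LINK_KEYS:
            errors.append(f"links[{i}].{key}: unknown key")
        genomic = "regions1" in l or "regions2" in l
        if genomic:
            if not ("regions1" in l and "regions2" in l):
                errors.append(f"links[{i}]: genomic links need regions1 and regions2")
        else:
            for side in ("1", "2"):
                if f"sector{side}" not in l:
                    errors.append(f"links[{i}]: missing sector{side}")
                if f"pos{side}" not in l and f"interval{side}" not in l:
                    errors.append(
                        f"links[{i}]: missing pos{side} or interval{side}")
    return errors


# ---------------------------------------------------------------------------
# Document -> components
# ---------------------------------------------------------------------------

def _frame(cols: Mapping[str, Any]) -> pd.DataFrame:
    return pd.DataFrame({k: list(v) for k, v in cols.items()})


def _init_args_from_doc(mode: str, args: Mapping[str, Any]) -> dict:
    out = dict(args)
    if "cytoband" in out and isinstance(out["cytoband"], Mapping):
        out["cytoband"] = CytobandTable(_frame(out["cytoband"]))
    if "data" in out and isinstance(out["data"], Mapping) \
            and {"chrom", "start", "end"} <= set(out["data"]):
        out["data"] = GenomicTable(_frame(out["data"]))
    if "zoom" in out and isinstance(out["zoom"], Mapping):
        out["zoom"] = (list(out["zoom"]["sectors"]), float(out["zoom"]["fraction"]))
    if "xlims" in out:
        out["xlims"] = [tuple(x) for x in out["xlims"]]
    return out


def _geom_from_doc(g: Mapping[str, Any], cell_scope: bool) -> Any:
    kind = g["kind"]
    aes = dict(g.get("aes", {}) or {})
    scope = g.get("scope", "cell" if cell_scope else "track")
    if scope == "cell":
        return make_cell_geom(kind,
                              x=g.get("x", ABSENT) if "x" in g else ABSENT,
                              y=g.get("y", ABSENT) if "y" in g else ABSENT,
                              aesthetics=aes)
    data = g.get("data")
    return make_track_geom(kind, data=None if data is None else _frame(data),
                           aesthetics=aes)


def from_document(doc: Mapping[str, Any]) -> PlotSpec:
    """Compose a plot from a validated document via the grammar."""
    schema_errors = validate_document(doc)
    if schema_errors:
        raise DocumentError("; ".join(schema_errors))
    init = doc["init"]
    plot = make_plot(init["mode"], _init_args_from_doc(init["mode"],
                                                       init.get("args", {}) or {}))
    for p in doc.get("pars", []):
        settings = {k: tuple(v) if isinstance(v, list) and k != "gap.degree" else v
                    for k, v in p.items()}
        plot = combine(plot, ParSpec(settings))
    for t in doc.get("tracks", []):
        if t.get("genomic") is not None:
            track: TrackSpec = make_genomic_track(
                GenomicTable(_frame(t["genomic"])),
                panel_kind=t.get("panel", "points"),
                ylim=t.get("ylim"), height=t.get("height"))
        else:
            track = make_track(
                data=None if t.get("data") is None else _frame(t["data"]),
                ylim=t.get("ylim"), height=t.get("height"),
                panel_kind=t.get("panel", "points"))
        for g in t.get("geoms", []) or []:
            track = combine(track, _geom_from_doc(g, cell_scope=False))
        for c in t.get("cells", []) or []:
            cell = CellSpec(sector_id=str(c["sector"]))
            for g in c.get("geoms", []) or []:
                cell = combine(cell, _geom_from_doc(g, cell_scope=True))
            track = combine(track, cell)
        plot = combine(plot, track)
    for l in doc.get("links", []):
        aes = dict(l.get("aes", {}) or {})
        scale = float(l.get("scale", 1.0))
        if "regions1" in l:
            link: LinkSpec = make_genomic_link(
                GenomicTable(_frame(l["regions1"])),
                GenomicTable(_frame(l["regions2"])),
                aesthetics=aes, scale=scale)
        else:
            pos1 = l.get("interval1", l.get("pos1"))
            pos2 = l.get("interval2", l.get("pos2"))
            link = make_link(str(l["sector1"]), pos1, str(l["sector2"]), pos2,
                             aesthetics=aes, scale=scale)
        plot = combine(plot, link)
    return plot


# ---------------------------------------------------------------------------
# Components -> document
# ---------------------------------------------------------------------------

def _jsonable(v: Any) -> Any:
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, np.ndarray):
        return [_jsonable(x) for x in v.tolist()]
    if isinstance(v, (tuple, list)):
        return [_jsonable(x) for x in v]
    if isinstance(v, Mapping):
        return {k: _jsonable(x) for k, x in v.items()}
    return v


def _cols(df: pd.DataFrame, int_cols: tuple[str, ...] = ("start", "end")) -> dict:
    out: dict[str, list] = {}
    for c in df.columns:
        vals = df[c].tolist()
        if c in int_cols:
            vals = [int(v) for v in vals]
        out[str(c)] = [_jsonable(v) for v in vals]
    return out


def _geom_to_doc(g: Any) -> dict:
    out: dict[str, Any] = {"kind": g.kind}
    if isinstance(g, CellGeomSpec):
        out["scope"] = "cell"
        for name, v in (("x", g.x), ("y", g.y)):
            if callable(v):
                raise DocumentError(
                    f"cell geom {g.kind!r} has a callable {name}; callables are "
                    "not expressible in plot documents")
            if v is not ABSENT:
                out[name] = _jsonable(v)
    else:
        out["scope"] = "track"
        if g.data is not None:
            out["data"] = _cols(g.data, int_cols=())
    if g.aesthetics:
        out["aes"] = _jsonable(dict(g.aesthetics))
    return out


def to_document(plot: PlotSpec) -> dict:
    """Serialize a plot to a document; callables raise DocumentError."""
    init_args: dict[str, Any] = {}
    for k, v in dict(plot.init_args).items():
        if isinstance(v, CytobandTable):
            init_args[k] = _cols(v.df)
        elif isinstance(v, GenomicTable):
            init_args[k] = _cols(v.df)
        elif k == "zoom" and isinstance(v, (tuple, list)):
            init_args[k] = {"sectors": [str(s) for s in v[0]],
                            "fraction": float(v[1])}
        else:
            init_args[k] = _jsonable(v)
    doc: dict[str, Any] = {
        "version": SCHEMA_VERSION,
        "init": {"mode": plot.init_mode, "args": init_args},
        "pars": [_jsonable(dict(p.settings)) for p in plot.pars],
        "tracks": [],
        "links": [],
    }
    for t in plot.tracks:
        td: dict[str, Any] = {"panel": t.panel_kind}
        if isinstance(t, GenomicTrackSpec) and t.genomic_data is not None:
            td["genomic"] = _cols(t.genomic_data.df)
        elif t.sector_data is not None:
            td["data"] = _cols(t.sector_data, int_cols=())
        if t.ylim is not None:
            td["ylim"] = [float(t.ylim[0]), float(t.ylim[1])]
        if t.height is not None:
            td["height"] = float(t.height)
        if t.track_geoms:
            td["geoms"] = [_geom_to_doc(g) for g in t.track_geoms]
        if t.cells:
            td["cells"] = [{"sector": c.sector_id,
                            "geoms": [_geom_to_doc(g) for g in c.cell_geoms]}
                           for c in t.cells]
        doc["tracks"].append(td)
    for l in plot.links:
        ld: dict[str, Any] = {}
        if isinstance(l, GenomicLinkSpec):
            ld["regions1"] = _cols(l.regions_1.df)
            ld["regions2"] = _cols(l.regions_2.df)
        else:
            for side, (sec, pos) in (("1", l.endpoint_1), ("2", l.endpoint_2)):
                ld[f"sector{side}"] = sec
                if isinstance(pos, (tuple, list)):
                    ld[f"interval{side}"] = [float(pos[0]), float(pos[1])]
                else:
                    ld[f"pos{side}"] = float(pos)
        if l.aesthetics:
            ld["aes"] = _jsonable(dict(l.aesthetics))
        if l.scale != 1.0:
            ld["scale"] = float(l.scale)
        doc["links"].append(ld)
    return doc
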