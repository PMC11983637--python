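# circogram

A layered, composable grammar for circular (polar sector/track/cell)
genomic visualization, with a deterministic SVG backend.

Circular layout plots place data categories — typically chromosomes — in
angular **sectors**, stack concentric **tracks** inward from the rim, and
call the intersection of a sector and a track a **cell**, which carries its
own local (x, y) coordinate system.  **Links** (chords and ribbons) cross
the circle's interior to show relationships such as structural variations.
Most tools build such figures procedurally: each call paints immediately,
so changing an early parameter means rerunning everything.  `circogram`
instead treats the figure as a value.  Plots are assembled from immutable
components with `+`, and nothing is computed until `show()` evaluates the
description into a scene.

## The component algebra

Seven primary component categories and exactly six addition rules:

| container | + component | result |
|---|---|---|
| Plot with *n* Pars | Par | Plot with *n* + 1 Pars |
| Plot with *n* Tracks | Track | Plot with *n* + 1 Tracks |
| Plot with *n* Links | Link | Plot with *n* + 1 Links |
| Track with *n* TrackGeoms | TrackGeom | Track with *n* + 1 TrackGeoms |
| Track with *n* Cells | Cell | Track with *n* + 1 Cells |
| Cell with *n* CellGeoms | CellGeom | Cell with *n* + 1 CellGeoms |

Any other pair raises `IllegalComposition` — notably, cell-local geometry
can never be added directly to a track; it must pass through a `Cell`.
Addition never mutates: every `+` returns a new container, so intermediate
tracks and plots can be reused across figures.

Two features carry most of the convenience:

- **Data mapping.**  A geom may omit its coordinates; at render time the
  owning track's data for the corresponding sector is the default.  A
  coordinate may also be a function `f(x_default, y_default)` whose return
  value is used — remapping against the parent data without repeating it.
- **Deferred evaluation.**  `show(plot)` resolves global parameters from
  the accumulated Pars (last wins per key), initializes sectors from the
  chosen `initMode` (`initialize`, `heatmap.initialize`,
  `initializeWithIdeogram`, `genomicInitialize`), draws tracks in addition
  order, then links, and returns a `Scene` whose SVG serialization is
  byte-for-byte reproducible.

Genomic specializations add UCSC `cytoBand.txt` and BED-like readers,
ideogram tracks with Giemsa-stain shading, zoomed sector duplication, and
genomic/heatmap link variants (0-based half-open coordinates throughout).

## Worked example

```python
import pandas as pd
import circogram as cg

df = pd.DataFrame({
    "category": ["a"] * 4 + ["b"] * 3,
    "x": [0.5, 1.5, 2.5, 3.5, 0.4, 1.0, 1.6],
    "y": [0.2, 0.8, 0.5, 0.9, 0.1, 0.6, 0.3],
})
plot = (
    cg.make_plot("initialize", {"categories": ["a", "b"],
                                "xlims": [(0, 4), (0, 2)]})
    + cg.ParSpec({"gap.degree": 5, "track.height": 0.25})
    + (cg.make_track(df, ylim=(0, 1)) + cg.make_track_geom("lines"))
    + cg.make_link("a", 2.0, "b", 1.0, aesthetics={"color": "steelblue"})
)
scene = cg.show(plot)
stats = cg.scene_stats(scene)
print("primitives:", stats.total)
print("by kind:", stats.by_kind)
print("by sector:", stats.by_sector)
cg.write_svg(scene, "example.svg")
```

prints

```
primitives: 12
by kind: {'arc_band': 2, 'point': 7, 'polyline': 3}
by sector: {'a': 6, 'b': 5}
```

Two `arc_band`s are the cell borders of the two sectors; the 7 data rows
render as points (the track's default panel) and, via the `lines`
track-geom defaulting from the same data, as one polyline per sector; the
link is the third polyline, a cubic Bézier pulled toward the center.
Sector `a` spans twice the angle of `b` because its x-range is twice as
large; a 5° gap separates the sectors.

## Command line

```sh
circogram demo example1 -o e1.svg --seed 7    # zoomed ideogram + scatter
circogram demo example2 -o e2.svg --seed 7    # CN / BAF rings + SV links
circogram render plot.yaml -o out.svg         # declarative documents
circogram validate plot.yaml
```

`example1` duplicates the first two synthetic chromosomes as zoomed
sectors on half of the circle, with the scatter layer's coordinates left
absent to exercise data mapping.  `example2` emulates a tumor profile:
copy-number dots on [-1, 1] colored red/grey/green by the ±0.15 gain/loss
rule, a B-allele-frequency ring on [0, 1], and structural-variation
ribbons — intra-chromosomal black, inter-chromosomal red and reduced in
radial scale.  Declarative plot documents (JSON/YAML, versioned schema)
round-trip losslessly for all non-callable content; exit codes distinguish
schema (1), composition (2) and render (3) failures.

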