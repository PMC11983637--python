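# Methods

## The model: a grammar of circular plots

A figure is a value built from immutable components.  The root `PlotSpec`
holds an initialization mode plus ordered lists of parameter bundles
(`ParSpec`), tracks (`TrackSpec`) and links (`LinkSpec`); tracks hold
track-wide geometry (`TrackGeomSpec`) and cells (`CellSpec`); cells hold
cell-local geometry (`CellGeomSpec`).  These seven categories and the six
addition rules in the README are the whole algebra; every other
(container, component) pair raises `IllegalComposition` at composition
time, not at render time.  Four named specializations exist —
`GenomicTrackSpec`, `GenomicCellGeomSpec`, and the two link subclasses
`GenomicLinkSpec` and `HeatmapLinkSpec` — each composing under its base
class's rule.  Component counting, ordering and immutability are the
grammar's invariants: `a + b` returns a new container with `b` appended
last and leaves `a` untouched, so partial figures are reusable.

Composition is intentionally side-effect free so that the second half of
the contract can hold: `show()` is a pure function from a `PlotSpec` to a
`Scene`, and serializing equal scenes yields byte-identical SVG.

## Global parameters

`ParSpec` keys come from a closed registry (unknown keys are rejected at
construction):

| key | meaning | default |
|---|---|---|
| `start.degree` | angle of the first sector's start, degrees CCW from 3 o'clock | 0 |
| `gap.degree` | gap after each sector; scalar (broadcast) or per-sector list | 1 |
| `clock.wise` | direction of sector succession | true |
| `track.height` | default track height, fraction of the unit radius | 0.2 |
| `track.margin` | (bottom, top) spacing between consecutive tracks | (0.01, 0.01) |
| `cell.padding` | reserved; accepted and carried but not applied to the coordinate maps | zeros |

Multiple Pars merge last-wins in addition order; Pars with disjoint keys
therefore commute.  The total gap must stay below 360°; the check runs as
soon as the sector count is known (at resolution when given, otherwise at
sector allocation).

## Layout geometry

Angles are degrees, counter-clockwise from the +x axis; the canvas radius
is 1.  The source material for this layout style shows the geometry only
schematically, so the formulas here are this package's own conventions,
chosen to match the familiar look of circular genome figures (first sector
at 3 o'clock, clockwise succession).

- **Sectors**: usable sweep = 360 − Σgaps, divided proportionally to each
  sector's x-range (or to explicit width weights; see zoom below).  Gap
  *i* follows sector *i*.  Conservation — Σ|sweeps| + Σgaps = 360 — holds
  to 1e−9 by construction and is property-tested.
- **Tracks**: stacked inward; track 0 gets `r_outer = 1 − outer margin`,
  each later band starts below the previous minus the inter-track margin.
  A band that would close at `r_inner ≤ 0` raises `RadiusExhausted`.
- **Cells**: x maps linearly from the sector xlim onto the angular span;
  y maps linearly from the track ylim onto `[r_inner, r_outer]`,
  increasing outward.  Both maps are invertible, which the round-trip
  tests exploit.

Out-of-range data points are clipped to the cell boundary and counted in
the scene's `clip_warnings` rather than raising — real data routinely
overflows a fixed ylim.  When a track has no explicit ylim it is inferred
as the min/max of the track's y data across all sectors, padded by 5%.  A
per-sector ylim was considered and rejected: a track band carries a single
y scale, and giving each cell its own would make radial positions
incomparable across sectors.

## Data mapping and deferred evaluation

A cell geom's `x`/`y` may each be absent, a concrete vector, or a callable
of the per-sector default vectors `(x_default, y_default)`.  Absent
coordinates default from the owning track's data for that sector
(`NoDefaultAvailable` when the track has none); callables are invoked at
resolve time with the defaults and their return value is validated
(`CallableResultInvalid` on wrong shape).  Three guarantees are tested:

- a geom with absent coordinates and one explicitly given the track's
  sector data render byte-identical scenes;
- an identity callable is indistinguishable from absent coordinates;
- construction never touches track data (observable with side-effect
  counters) — only `show()` does.

Track-wide geoms default symmetrically from the track's full table
restricted to each sector.  Callables receive the default vectors only,
never the other coordinate's explicit value; passing resolved siblings
would make resolution order observable.

`show()` evaluates in a fixed order: resolve Pars → initialize sectors
(prepending ideogram tracks for `initializeWithIdeogram`) → tracks in
addition order (panel, then track geoms, then each cell's geoms in
addition order) → links last.  Links-after-tracks is a paint-order choice,
not a constraint of the grammar; links anchor at the innermost track's
inner radius so they occupy the free center.  Errors raised during
evaluation are re-tagged with the failing component path
(`[track 2] ...`).

## Genomic conventions

Coordinates are 0-based half-open everywhere (UCSC/BED).  Chromosomes
order naturally (chr2 < chr10).  The cytoband reader accepts the 5-column
`cytoBand.txt` dialect (plain or gzip) and validates stain codes against
the Giemsa vocabulary; stains map to a fixed grayscale palette, except
`acen` bands, which render as paired red triangles pointing at the
centromere boundary.  Ideogram bands must tile each chromosome exactly;
the synthetic generator guarantees this and the invariant is tested.

**Zoom.**  `zoom=(subset, fraction)` duplicates the named chromosomes as
extra sectors (`chrN_zoom`) whose combined angular width is forced to
`fraction` of the usable circle through width weights; the remaining
sectors share `1 − fraction` proportionally to length.  Zoomed sectors
keep the full `(0, length)` xlim, so every record of a genomic track
renders in both the normal and the zoomed sector.  Links are drawn on the
base sectors only.  The default zoom fraction is 0.5.

**Links.**  Point-to-point links are single cubic Béziers whose control
points sit at radius `h` (default half the anchor radius; `h = 0` gives a
straight chord).  Interval endpoints produce ribbons: two anchor arcs
joined by Bézier flanks.  A link's `scale` multiplies the anchor radius
only — endpoint angles never move — which is how a second link set can be
tucked inside a first (the tumor demo draws inter-chromosomal ribbons at
scale 0.8 beneath the intra-chromosomal ones).  Zero-width ribbon
intervals raise `EmptyInterval`; degenerate point self-loops are allowed
as stubs.

## SVG backend

SVG was chosen as the canonical backend because determinism is testable:
fixed element order (paint order), fixed attribute order, 6-decimal
coordinates, and arcs flattened at a fixed 2° step so no viewer-dependent
arc rendering is involved.  Non-presentation style entries (track index,
sector id, role) are emitted as `data-*` attributes, which is what the
statistics and the tests inspect.  Raster export is deliberately absent.

## Synthetic data

The generators emulate the structure, not the biology, of real inputs:

- `generate_random_genome(n_chrom=3, mean_length=1e8, seed)` — lengths
  uniform within ±40% of the mean; 6–12 bands per arm with cycling stains
  and a two-band `acen` centromere near 40% of the length.
- `generate_random_regions` — intervals uniform over the genome, with the
  chromosome chosen proportionally to its length (tested against binomial
  99% bounds).
- `generate_vcap_like_dataset` — copy-number log-ratios near 0 with one
  gained and one lost segment of about ±0.4, clipped to [−1, 1]; B-allele
  frequencies clustered at {0.05, 0.33, 0.5, 0.67, 0.95} with σ = 0.04,
  clipped to [0, 1]; 40 structural-variation breakpoint pairs,
  intra-chromosomal with probability 0.75.

Defaults (400 CN probes, 400 BAF probes, 40 SVs, 3 chromosomes) keep the
demos legible and fast while exercising every code path; real SNP-array
profiles are two orders of magnitude denser but add nothing structurally.
Everything is seeded and reproducible; no data files ship with the
package.  Passing tests therefore demonstrate the grammar, layout and
rendering contracts on well-formed input — they say nothing about
assembly-specific cytoband quirks, missing values, or adversarially
malformed files beyond the parser checks.

## Numerical and design notes

- The copy-number color thresholds are ±0.15 with the boundaries assigned
  to the colored extremes (≥ 0.15 red, ≤ −0.15 green); the stated ranges
  overlap at the thresholds, so a tie-break had to be chosen.
- `resolve_pars` takes an optional sector count; a scalar gap is broadcast
  then, and a per-sector gap list is validated against it.
- Plot documents cannot express callable coordinates (no code in config);
  that path is library-only.  Heatmap links are likewise library-only.
- The grammar family this design follows describes 12 classes but names
  only 11; this package implements the 7 primary categories plus the 4
  named subclasses and leaves the unnamed remainder out of scope.
- `heatmap.initialize` defines sectors from the matrix split only; the
  heatmap content itself is drawn by a `heatmap` panel or `heatmap-cells`
  geoms, keeping initialization and drawing orthogonal.

## Known limitations

Log-scale and reversed axes, nested multi-ring zooms, interactive output,
and link-ordering optimization for heatmap links are out of scope.  Text
placement uses a simple tangential-with-upright-flip rule and makes no
attempt at collision avoidance.  `cell.padding` is accepted for
compatibility but not applied.
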