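"""Seeded synthetic genomes and demo datasets.

Real cytoband and SNP-array tables are large and assembly-specific; the
generators here emulate their structure — chromosome band tables in the
UCSC dialect, uniformly placed interval records, copy-number ratios on
[-1, 1] with gained/lost segments, B-allele frequencies on [0, 1] with the
usual allelic clusters, and paired structural-variation breakpoints mixing
intra- and inter-chromosomal events.  Every generator is reproducible:
the same seed yields identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .geoms import classify_cn_colors, make_track_geom
from .genomic import (
    CytobandTable,
    GenomicTable,
    make_genomic_link,
    make_genomic_track,
    natural_chrom_key,
)
from .grammar import PlotSpec, make_plot

__all__ = [
    "SyntheticGenome",
    "VcapLikeDataset",
    "generate_random_genome",
    "generate_random_regions",
    "generate_vcap_like_dataset",
    "default_genome",
    "build_example1",
    "build_example2",
]

#: Seed of the packaged default genome used when no cytoband source is given.
DEFAULT_GENOME_SEED = 42

_STAIN_CYCLE = ("gneg", "gpos25", "gneg", "gpos50", "gneg", "gpos75",
                "gneg", "gpos100", "gvar", "stalk")


@dataclass(frozen=True, eq=False)
class SyntheticGenome:
    """A small synthetic genome: chromosome lengths plus a band table."""

    chroms: tuple[str, ...]
    lengths: dict[str, int]
    cytobands: CytobandTable
    seed: int


@dataclass(frozen=True, eq=False)
class VcapLikeDataset:
    """Synthetic tumor-profile dataset: copy-number ratios, B-allele
    frequencies, and paired SV breakpoint regions."""

    copy_number: GenomicTable
    baf: GenomicTable
    sv_regions_1: GenomicTable
    sv_regions_2: GenomicTable
    sv_is_intra: np.ndarray


def generate_random_genome(
    n_chrom: int = 3,
    mean_length: int = 100_000_000,
    seed: int = 0,
) -> SyntheticGenome:
    """Generate chromosome lengths and a plausible cytoband table.

    Lengths are uniform within +-40% of ``mean_length``.  Each chromosome
    gets 6-12 bands per arm with cycling Giemsa stains and a two-band
    ``acen`` centromere near 40% of its length.
    """
    if n_chrom < 1:
        raise ValueError("n_chrom must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = tuple(f"chr{i + 1}" for i in range(n_chrom))
    lengths = {
        c: int(rng.uniform(0.6, 1.4) * mean_length) for c in chroms
    }
    rows = []
    for c in chroms:
        length = lengths[c]
        cen = int(length * rng.uniform(0.3, 0.5))
        cen_half = max(1, int(length * 0.01))
        for arm, lo, hi in (("p", 0, cen - cen_half), ("q", cen + cen_half, length)):
            n_bands = int(rng.integers(6, 13))
            cuts = np.sort(rng.uniform(lo, hi, size=n_bands - 1)).astype(int)
            edges = [lo, *dict.fromkeys(int(v) for v in cuts), hi]
            edges = sorted(set(edges))
            for i in range(len(edges) - 1):
                if edges[i + 1] <= edges[i]:
                    continue
                stain = _STAIN_CYCLE[int(rng.integers(0, len(_STAIN_CYCLE)))]
                rows.append((c, edges[i], edges[i + 1], f"{arm}{i + 1}", stain))
            if arm == "p":
                rows.append((c, cen - cen_half, cen, "p_cen", "acen"))
            else:
                pass
        # insert the q-side acen just after the p-side one
        rows.append((c, cen, cen + cen_half, "q_cen", "acen"))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "stain"])
    df = df.sort_values(["chrom", "start"],
                        key=lambda s: s.map(natural_chrom_key) if s.name == "chrom" else s,
                        kind="mergesort").reset_index(drop=True)
    return SyntheticGenome(chroms=chroms, lengths=lengths,
                           cytobands=CytobandTable(df), seed=seed)


def default_genome() -> SyntheticGenome:
    """The packaged synthetic 3-chromosome genome (fixed seed)."""
    return generate_random_genome(n_chrom=3, mean_length=100_000_000,
                                  seed=DEFAULT_GENOME_SEED)


def generate_random_regions(
    genome: SyntheticGenome,
    n: int,
    value_distributions: Mapping[str, tuple] | None = None,
    seed: int = 0,
    width: int = 1,
) -> GenomicTable:
    """``n`` intervals uniform over the genome (chromosome chosen with
    probability proportional to its length), with seeded value columns.

    ``value_distributions`` maps column name to ``("uniform", lo, hi)`` or
    ``("normal", mean, sd)``; default is one uniform [0, 1] ``value``.
    """
    rng = np.random.default_rng(seed)
    dists = dict(value_distributions or {"value": ("uniform", 0.0, 1.0)})
    lens = np.array([genome.lengths[c] for c in genome.chroms], dtype=float)
    cols: dict[str, list] = {"chrom": [], "start": [], "end": []}
    if n > 0:
        idx = rng.choice(len(genome.chroms), size=n, p=lens / lens.sum())
        for i in idx:
            c = genome.chroms[i]
            start = int(rng.integers(0, max(1, genome.lengths[c] - width)))
            cols["chrom"].append(c)
            cols["start"].append(start)
            cols["end"].append(start + width)
    for name, spec in dists.items():
        kind, a, b = spec
        if kind == "uniform":
            vals = rng.uniform(a, b, size=n)
        elif kind == "normal":
            vals = rng.normal(a, b, size=n)
        else:
            raise ValueError(f"unknown distribution {kind!r}")
        cols[name] = list(vals)
    return GenomicTable(pd.DataFrame(cols))


def generate_vcap_like_dataset(
    genome: SyntheticGenome,
    seed: int = 0,
    n_cn: int = 400,
    n_baf: int = 400,
    n_sv: int = 40,
    intra_fraction: float = 0.75,
) -> VcapLikeDataset:
    """Synthetic SNP-array-like tumor profile.

    Copy-number log ratios sit near 0 with whole-arm gains/losses of about
    +-0.4 and are clipped to [-1, 1]; B-allele frequencies cluster at the
    usual allelic bands {0.05, 0.33, 0.5, 0.67, 0.95} and are clipped to
    [0, 1]; SV breakpoint pairs are intra-chromosomal with probability
    ``intra_fraction``.
    """
    rng = np.random.default_rng(seed)
    cn = generate_random_regions(genome, n_cn, {"value": ("normal", 0.0, 0.08)},
                                 seed=int(rng.integers(2 ** 31)), width=1000)
    # whole-arm shifts: one gained and one lost segment per genome
    cn_df = cn.df.copy()
    for shift in (0.4, -0.4):
        c = genome.chroms[int(rng.integers(len(genome.chroms)))]
        length = genome.lengths[c]
        lo = int(rng.uniform(0, 0.5) * length)
        hi = int(rng.uniform(0.6, 1.0) * length)
        mask = (cn_df["chrom"] == c) & (cn_df["start"] >= lo) & (cn_df["end"] <= hi)
        cn_df.loc[mask, "value"] += shift + rng.normal(0.0, 0.03)
    cn_df["value"] = cn_df["value"].clip(-1.0, 1.0)
    copy_number = GenomicTable(cn_df)

    baf = generate_random_regions(genome, n_baf, {"value": ("uniform", 0.0, 1.0)},
                                  seed=int(rng.integers(2 ** 31)), width=1000)
    baf_df = baf.df.copy()
    clusters = np.array([0.05, 0.33, 0.5, 0.67, 0.95])
    picks = clusters[rng.integers(0, len(clusters), size=len(baf_df))]
    baf_df["value"] = np.clip(picks + rng.normal(0.0, 0.04, size=len(baf_df)),
                              0.0, 1.0)
    baf = GenomicTable(baf_df)

    sv_width = 200_000
    r1 = {"chrom": [], "start": [], "end": []}
    r2 = {"chrom": [], "start": [], "end": []}
    intra = np.zeros(n_sv, dtype=bool)
    for i in range(n_sv):
        c1 = genome.chroms[int(rng.integers(len(genome.chroms)))]
        if rng.uniform() < intra_fraction or len(genome.chroms) == 1:
            c2 = c1
        else:
            others = [c for c in genome.chroms if c != c1]
            c2 = others[int(rng.integers(len(others)))]
        intra[i] = c1 == c2
        for c, r in ((c1, r1), (c2, r2)):
            start = int(rng.integers(0, max(1, genome.lengths[c] - sv_width)))
            r["chrom"].append(c)
            r["start"].append(start)
            r["end"].append(start + sv_width)
    return VcapLikeDataset(
        copy_number=copy_number,
        baf=baf,
        sv_regions_1=GenomicTable(pd.DataFrame(r1)),
        sv_regions_2=GenomicTable(pd.DataFrame(r2)),
        sv_is_intra=intra,
    )


# ---------------------------------------------------------------------------
# Demo builders
# ---------------------------------------------------------------------------

def build_example1(genome: SyntheticGenome | None = None,
                   n_points: int = 120, seed: int = 1) -> PlotSpec:
    """Ideogram ring + inner scatter, with the first two chromosomes
    duplicated as zoomed sectors on half of the circle.

    The scatter layer's coordinates are deliberately left absent so they
    default from the owning track's per-sector data — the data-mapping
    rule the grammar exists for.
    """
    genome = genome or default_genome()
    regions = generate_random_regions(genome, n_points,
                                      {"value": ("uniform", 0.0, 1.0)}, seed=seed)
    plot = make_plot("initializeWithIdeogram", {
        "cytoband": genome.cytobands,
        "zoom": (list(genome.chroms[:2]), 0.5),
    })
    track = make_genomic_track(regions, panel_kind="region-only",
                               ylim=(0.0, 1.0), height=0.25)
    scatter = make_track_geom("points", data=None,
                              aesthetics={"color": "#d95f02", "size": 0.8})
    return plot + (track + scatter)


def build_example2(dataset: VcapLikeDataset | None = None,
                   genome: SyntheticGenome | None = None,
                   seed: int = 2) -> PlotSpec:
    """Tumor-profile ring stack: ideogram, copy-number dots colored by the
    +-0.15 gain/loss rule, a B-allele-frequency ring, then SV links —
    intra-chromosomal in black, inter-chromosomal in red with the red
    ribbons reduced in radial scale."""
    genome = genome or default_genome()
    dataset = dataset or generate_vcap_like_dataset(genome, seed=seed)

    plot = make_plot("initializeWithIdeogram", {"cytoband": genome.cytobands})

    cn_track = make_genomic_track(dataset.copy_number, panel_kind="region-only",
                                  ylim=(-1.0, 1.0), height=0.18)
    cn_colors = classify_cn_colors(dataset.copy_number.df["value"])
    cn_track = cn_track + make_track_geom(
        "points", data=None, aesthetics={"color": cn_colors, "size": 0.6})

    baf_track = make_genomic_track(dataset.baf, panel_kind="region-only",
                                   ylim=(0.0, 1.0), height=0.18)
    baf_track = baf_track + make_track_geom(
        "points", data=None, aesthetics={"color": "#555555", "size": 0.6})

    intra = dataset.sv_is_intra
    def subset(table: GenomicTable, mask: np.ndarray) -> GenomicTable:
        return GenomicTable(table.df[mask].reset_index(drop=True))

    links = []
    if intra.any():
        links.append(make_genomic_link(subset(dataset.sv_regions_1, intra),
                                       subset(dataset.sv_regions_2, intra),
                                       aesthetics={"color": "black"}, scale=1.0))
    if (~intra).any():
        links.append(make_genomic_link(subset(dataset.sv_regions_1, ~intra),
                                       subset(dataset.sv_regions_2, ~intra),
                                       aesthetics={"color": "red"}, scale=0.8))

    plot = plot + cn_track + baf_track
    for link in links:
        plot = plot + link
    return plot
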