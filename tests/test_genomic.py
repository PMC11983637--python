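"""Genomic readers, ideogram/zoom initialization, and genomic components."""

import io

import numpy as np
import pandas as pd
import pytest

import circogram as cg
from circogram.errors import (
    CoordinateError,
    InvalidStain,
    ParseError,
    RowCountMismatch,
    UnknownChromosome,
)
from circogram.genomic import (
    base_sector,
    natural_chrom_key,
    write_bed_like,
    zoom_sector_id,
)
from circogram.grammar import GlobalParams


def test_read_cytoband_single_record():
    t = cg.read_cytoband(io.StringIO("chr1\t0\t100\tp1\tgneg\n"))
    assert len(t) == 1
    assert t.chrom_lengths == {"chr1": 100}


def test_read_cytoband_reports_line_numbers():
    src = io.StringIO("chr1\t0\t100\tp1\tgneg\nchr1\t200\t150\tp2\tgneg\n")
    with pytest.raises(ParseError, match="line 2"):
        cg.read_cytoband(src)
    with pytest.raises(InvalidStain, match="line 1"):
        cg.read_cytoband(io.StringIO("chr1\t0\t100\tp1\tmagenta\n"))
    with pytest.raises(ParseError):
        cg.read_cytoband(io.StringIO("chr1\t0\t100\n"))


def test_synthetic_genome_round_trips_through_text(genome, tmp_path):
    path = tmp_path / "cytoBand.txt"
    with open(path, "w") as fh:
        for row in genome.cytobands.df.itertuples(index=False):
            fh.write("\t".join(str(v) for v in row) + "\n")
    back = cg.read_cytoband(path)
    assert back.chroms == genome.chroms
    # per-chromosome spans equal the generator's lengths (the oracle)
    assert back.chrom_lengths == genome.lengths


def test_read_bed_like_minimal_and_errors():
    t = cg.read_bed_like(io.StringIO("chr1\t10\t20\n"))
    assert len(t) == 1 and t.value_columns == ()
    with pytest.raises(CoordinateError):
        cg.read_bed_like(io.StringIO("chr1\t-5\t20\n"))
    with pytest.raises(ParseError):
        cg.read_bed_like(io.StringIO("chr1\t10\n"))


def test_bed_like_write_read_round_trip(genome, tmp_path):
    regions = cg.generate_random_regions(genome, 50, seed=3)
    path = tmp_path / "regions.bed"
    write_bed_like(regions, path)
    back = cg.read_bed_like(path)
    pd.testing.assert_frame_equal(back.df, regions.df)


def test_natural_chromosome_order():
    labels = ["chr10", "chr2", "chr1", "chrX"]
    assert sorted(labels, key=natural_chrom_key) == \
        ["chr1", "chr2", "chr10", "chrX"]


def test_ideogram_bands_tile_each_chromosome(genome):
    df = genome.cytobands.df
    for chrom in genome.chroms:
        sub = df[df["chrom"] == chrom]
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        assert starts[0] == 0
        assert ends[-1] == genome.lengths[chrom]
        assert (starts[1:] == ends[:-1]).all()  # contiguous, no overlap


def test_genomic_initialize_without_zoom(genome):
    init = cg.genomic_initialize(genome.cytobands)
    assert set(init.xlims) == set(genome.chroms)
    for c in genome.chroms:
        assert init.xlims[c] == (0.0, float(genome.lengths[c]))
    assert init.weights is None
    assert len(init.tracks) == 1  # ideogram


def test_zoomed_sectors_get_the_requested_circle_fraction(genome):
    subset = list(genome.chroms[:2])
    init = cg.genomic_initialize(genome.cytobands, zoom=(subset, 0.5))
    sectors = cg.allocate_sectors(init.xlims, GlobalParams(gap_degrees=1.0),
                                  weights=init.weights)
    usable = 360.0 - len(sectors) * 1.0
    zoom_ids = {zoom_sector_id(c) for c in subset}
    zoom_sweep = sum(abs(s.sweep) for s in sectors if s.sector_id in zoom_ids)
    assert zoom_sweep == pytest.approx(0.5 * usable, abs=1e-9)
    # zoomed duplicates keep the full data range of their chromosome
    for c in subset:
        assert init.xlims[zoom_sector_id(c)] == init.xlims[c]


def test_zoom_of_unknown_chromosome_rejected(genome):
    with pytest.raises(UnknownChromosome):
        cg.genomic_initialize(genome.cytobands, zoom=(["chrX"], 0.5))


def test_genomic_track_derives_midpoint_coordinates():
    table = cg.GenomicTable(pd.DataFrame({
        "chrom": ["chr1", "chr1", "chr2"],
        "start": [0, 100, 50],
        "end": [10, 200, 150],
        "value": [0.1, 0.2, 0.3],
    }))
    track = cg.make_genomic_track(table)
    sub = track.sector_data[track.sector_data["category"] == "chr1"]
    assert list(sub["x"]) == [5.0, 150.0]
    assert list(sub["y"]) == [0.1, 0.2]


def test_genomic_cell_geom_defaults_from_owning_track():
    table = cg.GenomicTable(pd.DataFrame({
        "chrom": ["chr1", "chr2"], "start": [0, 10],
        "end": [10, 30], "value": [1.0, 2.0],
    }))
    track = cg.make_genomic_track(table, panel_kind="region-only", ylim=(0, 3))
    geom = cg.make_genomic_cell_geom("points")  # region data absent
    from circogram.render import _resolve_genomic_geom
    df, x, y = _resolve_genomic_geom(geom, track, "chr2")
    assert list(df["chrom"]) == ["chr2"]
    assert list(x) == [20.0] and list(y) == [2.0]


def test_genomic_link_row_count_mismatch():
    a = pd.DataFrame({"chrom": ["chr1", "chr1"], "start": [0, 5], "end": [1, 6]})
    b = pd.DataFrame({"chrom": ["chr2"], "start": [0], "end": [1]})
    with pytest.raises(RowCountMismatch):
        cg.make_genomic_link(a, b)


def test_intra_inter_classification_counts():
    r1 = pd.DataFrame({"chrom": ["chr1", "chr1", "chr2", "chr1"],
                       "start": [0, 10, 20, 30], "end": [5, 15, 25, 35]})
    r2 = pd.DataFrame({"chrom": ["chr1", "chr1", "chr2", "chr3"],
                       "start": [50, 60, 70, 80], "end": [55, 65, 75, 85]})
    link = cg.make_genomic_link(r1, r2)
    intra = link.is_intra()
    assert (int(intra.sum()), int((~intra).sum())) == (3, 1)


def test_link_subclass_registry():
    assert cg.LINK_SUBCLASSES == (cg.GenomicLinkSpec, cg.HeatmapLinkSpec)
    for cls in cg.LINK_SUBCLASSES:
        assert issubclass(cls, cg.LinkSpec)


def test_base_sector_mapping():
    assert base_sector(zoom_sector_id("chr7")) == "chr7"
    assert base_sector("chr7") == "chr7"


def test_genomic_table_invariants():
    with pytest.raises(CoordinateError):
        cg.GenomicTable(pd.DataFrame({"chrom": ["c"], "start": [5], "end": [5]}))
    with pytest.raises(CoordinateError):
        cg.GenomicTable(pd.DataFrame({"chrom": ["c"], "start": [-1], "end": [5]}))
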