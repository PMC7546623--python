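from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from promoterz import (
    CoverageTrack,
    FragmentSet,
    GenomeLayout,
    LayoutError,
    ParseError,
    coverage_from_fragments,
    read_bedgraph,
    read_fragments,
    read_tss_bed,
    region_rpkm,
    sample_random_regions,
    split_by_size,
    write_bedgraph,
)
from tests._oracles import coverage_bruteforce
from tests.conftest import random_fragments


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestLayout:
    def test_rejects_empty_and_nonpositive(self):
        with pytest.raises(LayoutError):
            GenomeLayout({})
        with pytest.raises(LayoutError):
            GenomeLayout({"chr1": 0})

    def test_unknown_chromosome(self, toy_layout):
        with pytest.raises(LayoutError):
            toy_layout.size("chrX")

    def test_sizes_file_roundtrip(self, toy_layout, tmp_path):
        path = tmp_path / "genome.tsv"
        toy_layout.to_file(path)
        assert GenomeLayout.from_file(path).chrom_sizes == toy_layout.chrom_sizes


class TestReadTssBed:
    def test_strand_determines_tss(self, toy_layout, tmp_path):
        path = _write(
            tmp_path, "tss.bed",
            "chr1\t999\t2000\tgeneA\t0\t+\nchr1\t999\t2000\tgeneB\t0\t-\n",
        )
        recs = read_tss_bed(path, toy_layout)
        assert (recs[0].tss, recs[0].strand, recs[0].gene_id) == (999, "+", "geneA")
        assert (recs[1].tss, recs[1].strand, recs[1].gene_id) == (1999, "-", "geneB")

    @pytest.mark.parametrize(
        "line, err",
        [
            ("chr1\t100\t200\tg\t0\t.", ParseError),      # undefined strand
            ("chr1\t100\t200\tg\t0", ParseError),         # too few columns
            ("chr1\tabc\t200\tg\t0\t+", ParseError),      # non-integer coordinate
            ("chrX\t100\t200\tg\t0\t+", LayoutError),     # unknown chromosome
            ("chr1\t20000\t20010\tg\t0\t+", LayoutError), # past the chromosome end
        ],
    )
    def test_rejects_bad_records(self, toy_layout, tmp_path, line, err):
        path = _write(tmp_path, "bad.bed", line + "\n")
        with pytest.raises(err):
            read_tss_bed(path, toy_layout)

    def test_error_names_line_number(self, toy_layout, tmp_path):
        path = _write(tmp_path, "bad.bed", "chr1\t1\t2\tg\t0\t+\nchr1\tzz\t2\tg\t0\t+\n")
        with pytest.raises(ParseError, match=":2:"):
            read_tss_bed(path, toy_layout)

    def test_header_lines_skipped(self, toy_layout, tmp_path):
        path = _write(
            tmp_path, "tss.bed",
            "track name=test\n# comment\nchr1\t10\t20\tg\t0\t+\n",
        )
        assert len(read_tss_bed(path, toy_layout)) == 1


class TestReadFragments:
    def test_fragment_bed(self, toy_layout, tmp_path):
        path = _write(tmp_path, "f.bed", "chr1\t100\t200\n")
        frags = read_fragments(path, toy_layout)
        assert list(frags.lengths) == [100]

    def test_bedpe_outer_span(self, toy_layout, tmp_path):
        path = _write(
            tmp_path, "f.bedpe",
            "chr1\t100\t150\tchr1\t250\t300\tpair1\t0\t+\t-\n",
        )
        frags = read_fragments(path, toy_layout)
        assert (int(frags.start[0]), int(frags.end[0])) == (100, 300)
        assert list(frags.lengths) == [200]

    def test_empty_file_is_empty_set(self, toy_layout, tmp_path):
        frags = read_fragments(_write(tmp_path, "e.bed", ""), toy_layout)
        assert len(frags) == 0 and frags.n_rejected == 0

    def test_bad_records_counted_not_fatal(self, toy_layout, tmp_path):
        path = _write(
            tmp_path, "f.bedpe",
            "chr1\t100\t150\tchr1\t250\t300\tp\t0\t+\t-\n"
            "chr1\t100\t150\tchr2\t250\t300\tp\t0\t+\t-\n"   # inter-chromosomal
            "chr1\t300\t250\tchr1\t300\t250\tp\t0\t+\t-\n",  # inverted span
        )
        frags = read_fragments(path, toy_layout)
        assert len(frags) == 1 and frags.n_rejected == 2

    def test_unsupported_column_count(self, toy_layout, tmp_path):
        with pytest.raises(ParseError):
            read_fragments(_write(tmp_path, "f.bed", "chr1\t1\t2\tx\n"), toy_layout)


class TestSplitBySize:
    def test_boundary_length_is_nucleosomal(self):
        frags = FragmentSet.from_intervals(
            [("chr1", 0, 80), ("chr1", 0, 149), ("chr1", 0, 150), ("chr1", 0, 151)]
        )
        nnf, nuc = split_by_size(frags, cutoff=150)
        assert sorted(nnf.lengths) == [80, 149]
        assert sorted(nuc.lengths) == [150, 151]

    def test_cutoff_one_gives_empty_nnf(self):
        frags = FragmentSet.from_intervals([("chr1", 0, 10)])
        nnf, nuc = split_by_size(frags, cutoff=1)
        assert len(nnf) == 0 and len(nuc) == 1

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.integers(min_value=1, max_value=500), min_size=0, max_size=40))
    def test_conserves_count_and_length_multiset(self, lengths):
        frags = FragmentSet.from_intervals([("chr1", 0, ln) for ln in lengths])
        nnf, nuc = split_by_size(frags)
        assert len(nnf) + len(nuc) == len(frags)
        assert sorted(list(nnf.lengths) + list(nuc.lengths)) == sorted(lengths)


class TestCoverage:
    def test_counts_overlapping_fragments(self, toy_layout):
        frags = FragmentSet.from_intervals([("chr1", 0, 100), ("chr1", 50, 150)])
        track = coverage_from_fragments(frags, toy_layout)
        v = track.values("chr1")
        assert v[0] == 1 and v[49] == 1 and v[50] == 2 and v[99] == 2
        assert v[100] == 1 and v[149] == 1 and v[150] == 0

    def test_cpm_scales_by_million_over_count(self, toy_layout):
        frags = FragmentSet.from_intervals([("chr1", 0, 100), ("chr1", 50, 150)])
        raw = coverage_from_fragments(frags, toy_layout)
        cpm = coverage_from_fragments(frags, toy_layout, normalize="cpm")
        np.testing.assert_allclose(cpm.values("chr1"), raw.values("chr1") * 500_000)

    def test_cpm_of_empty_set_is_error(self, toy_layout):
        with pytest.raises(ValueError):
            coverage_from_fragments(FragmentSet.empty(), toy_layout, normalize="cpm")

    def test_matches_per_base_bruteforce(self, rng):
        layout = GenomeLayout({"c1": 1_000, "c2": 700})
        for _ in range(10):
            frags = random_fragments(rng, layout, int(rng.integers(1, 60)))
            track = coverage_from_fragments(frags, layout)
            for chrom in layout.chrom_names:
                expected = coverage_bruteforce(list(frags), chrom, layout.size(chrom))
                np.testing.assert_array_equal(track.values(chrom), expected)

    def test_total_equals_sum_of_lengths(self, rng, toy_layout):
        frags = random_fragments(rng, toy_layout, 50)
        track = coverage_from_fragments(frags, toy_layout)
        assert track.total() == pytest.approx(float(frags.lengths.sum()))


class TestRegionRpkm:
    def test_definition(self):
        rows = [("chr1", 100, 200)] * 10 + [("chr1", 5_000, 5_100)] * 999_990
        frags = FragmentSet.from_intervals(rows)
        assert region_rpkm(frags, ("chr1", 0, 1_000)) == pytest.approx(10.0)

    def test_no_overlap_is_zero(self):
        frags = FragmentSet.from_intervals([("chr1", 5_000, 5_100)])
        assert region_rpkm(frags, ("chr1", 0, 1_000)) == 0.0

    def test_zero_length_region_is_error(self):
        frags = FragmentSet.from_intervals([("chr1", 0, 10)])
        with pytest.raises(ValueError):
            region_rpkm(frags, ("chr1", 5, 5))

    def test_matches_enumeration(self, rng):
        layout = GenomeLayout({"c1": 2_000})
        frags = random_fragments(rng, layout, 7)
        region = ("c1", 100, 400)
        hits = sum(1 for c, s, e in frags if c == "c1" and s < 400 and e > 100)
        expected = hits / ((300 / 1000) * (len(frags) / 1e6))
        assert region_rpkm(frags, region) == pytest.approx(expected)


class TestBedgraph:
    def test_roundtrip_two_runs(self, toy_layout, tmp_path):
        track = CoverageTrack.zeros(toy_layout)
        track.values("chr1")[0:50] = 1.0
        track.values("chr1")[50:100] = 2.0
        path = tmp_path / "t.bedgraph"
        write_bedgraph(track, path)
        assert len(path.read_text().splitlines()) == 2
        back = read_bedgraph(path, toy_layout)
        for chrom in toy_layout.chrom_names:
            np.testing.assert_array_equal(back.values(chrom), track.values(chrom))

    def test_all_zero_track_writes_nothing(self, toy_layout, tmp_path):
        path = tmp_path / "z.bedgraph"
        write_bedgraph(CoverageTrack.zeros(toy_layout), path)
        assert path.read_text() == ""

    def test_random_tracks_roundtrip_exactly(self, rng, tmp_path):
        layout = GenomeLayout({"c1": 500})
        for i in range(10):
            track = CoverageTrack.zeros(layout)
            pos = 0
            for _ in range(10):
                width = int(rng.integers(1, 50))
                track.values("c1")[pos : pos + width] = rng.random() * 10
                pos += width + int(rng.integers(0, 20))
                if pos >= 500:
                    break
            path = tmp_path / f"r{i}.bedgraph"
            write_bedgraph(track, path)
            back = read_bedgraph(path, layout)
            np.testing.assert_array_equal(back.values("c1"), track.values("c1"))

    def test_overlapping_intervals_rejected(self, toy_layout, tmp_path):
        path = tmp_path / "o.bedgraph"
        path.write_text("chr1\t0\t100\t1.0\nchr1\t50\t150\t2.0\n")
        with pytest.raises(ParseError):
            read_bedgraph(path, toy_layout)


class TestSampleRandomRegions:
    def test_deterministic_under_seed(self, toy_layout):
        a = sample_random_regions(toy_layout, n=3, width=300, seed=9)
        b = sample_random_regions(toy_layout, n=3, width=300, seed=9)
        assert a.intervals == b.intervals

    def test_width_equal_to_chromosome(self):
        layout = GenomeLayout({"only": 300})
        peaks = sample_random_regions(layout, n=5, width=300, seed=0)
        assert all(iv == ("only", 0, 300) for iv in peaks)

    def test_chromosome_share_proportional_to_size(self):
        layout = GenomeLayout({"big": 3_000_000, "small": 1_000_000})
        peaks = sample_random_regions(layout, n=10_000, width=300, seed=4)
        share = sum(1 for c, _, _ in peaks if c == "big") / 10_000
        sigma = np.sqrt(0.75 * 0.25 / 10_000)
        assert abs(share - 0.75) < 3 * sigma

    def test_width_larger_than_chromosome_is_error(self, toy_layout):
        with pytest.raises(LayoutError):
            sample_random_regions(toy_layout, n=1, width=6_000, seed=0)
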