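"""Interval primitives, format round-trips, and boundary conventions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acylscape.genomic_io import (
    CoverageTrack,
    GeneModel,
    GenomeAnnotation,
    Interval,
    ParseError,
    PeakSet,
    merge_intervals,
    overlaps,
    read_coverage,
    read_gene_models,
    read_peaks,
    upstream_region,
    write_coverage,
    write_gene_models,
    write_peaks,
)


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestGFF3:
    def test_one_based_inclusive_converted_to_half_open(self, tmp_path):
        p = _write(tmp_path, "a.gff3", "chr1\t.\tgene\t101\t200\t.\t+\t.\tID=g1\n")
        ann = read_gene_models(p)
        g = next(iter(ann))
        assert (g.gene_id, g.interval.start, g.interval.end) == ("g1", 100, 200)
        assert g.interval.strand == "+" and g.feature_class == "coding"

    def test_te_keyword_classifies_te_related(self, tmp_path):
        p = _write(
            tmp_path, "a.gff3",
            "chr1\t.\tgene\t101\t200\t.\t+\t.\tID=g1;Note=transposon\n",
        )
        ann = read_gene_models(p, te_keywords=["transposon"])
        assert next(iter(ann)).feature_class == "te_related"

    def test_empty_file_yields_empty_annotation(self, tmp_path):
        ann = read_gene_models(_write(tmp_path, "a.gff3", ""))
        assert len(ann) == 0

    def test_malformed_line_names_line_number(self, tmp_path):
        p = _write(
            tmp_path, "a.gff3",
            "chr1\t.\tgene\t101\t200\t.\t+\t.\tID=g1\nchr1\tgene\t5\n",
        )
        with pytest.raises(ParseError, match=":2"):
            read_gene_models(p)

    def test_duplicate_gene_id_rejected(self, tmp_path):
        p = _write(
            tmp_path, "a.gff3",
            "chr1\t.\tgene\t101\t200\t.\t+\t.\tID=g1\n"
            "chr1\t.\tgene\t301\t400\t.\t-\t.\tID=g1\n",
        )
        with pytest.raises(ParseError, match="duplicate"):
            read_gene_models(p)

    def test_round_trip_preserves_coordinates_exactly(self, tmp_path):
        genes = [
            GeneModel("g1", Interval("chr1", 100, 200, "+"), "coding"),
            GeneModel("g2", Interval("chr1", 500, 901, "-"), "te_related"),
            GeneModel("g3", Interval("chr2", 0, 50, "+"), "coding"),
        ]
        ann = GenomeAnnotation(genes, {"chr1": 1000, "chr2": 100})
        path = tmp_path / "rt.gff3"
        write_gene_models(ann, path)
        back = read_gene_models(path)
        assert back.chrom_sizes == ann.chrom_sizes
        pd.testing.assert_frame_equal(back.df, ann.df)


class TestPeaks:
    def test_bookended_intervals_merge(self, tmp_path):
        p = _write(tmp_path, "p.bed", "chr1\t0\t100\nchr1\t100\t200\n")
        ps = read_peaks(p, "s", "Kbu", 1)
        assert ps.peaks.to_records(index=False).tolist() == [("chr1", 0, 200)]

    def test_separated_intervals_stay_apart(self, tmp_path):
        p = _write(tmp_path, "p.bed", "chr1\t0\t100\nchr1\t150\t200\n")
        assert len(read_peaks(p, "s", "Kbu", 1)) == 2

    def test_empty_bed(self, tmp_path):
        assert len(read_peaks(_write(tmp_path, "p.bed", ""), "s", "Kcr", 2)) == 0

    @pytest.mark.parametrize("line", ["chr1\t100\t100", "chr1\tx\t200"])
    def test_invalid_rows_rejected(self, tmp_path, line):
        with pytest.raises((ParseError, ValueError)):
            read_peaks(_write(tmp_path, "p.bed", line + "\n"), "s", "Kbu", 1)

    @given(
        st.lists(
            st.tuples(st.integers(0, 500), st.integers(1, 100)),
            min_size=0,
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None)
    def test_merge_is_idempotent(self, spans):
        df = pd.DataFrame(
            [("chr1", s, s + w) for s, w in spans], columns=["chrom", "start", "end"]
        )
        once = merge_intervals(df)
        twice = merge_intervals(once)
        pd.testing.assert_frame_equal(once, twice)
        # merged intervals are disjoint and non-bookended
        if len(once) > 1:
            assert (once["start"].to_numpy()[1:] > once["end"].to_numpy()[:-1]).all()

    def test_round_trip(self, tmp_path):
        ps = PeakSet(
            "s", "Kbu", 1,
            [Interval("chr1", 5, 50), Interval("chr2", 0, 10), Interval("chr1", 60, 80)],
        )
        path = tmp_path / "rt.bed"
        write_peaks(ps, path)
        back = read_peaks(path, "s", "Kbu", 1)
        pd.testing.assert_frame_equal(back.peaks, ps.peaks)


class TestCoverage:
    def test_record_tiling_two_bins_splits_value(self, tmp_path):
        p = _write(tmp_path, "c.bg", "chr1\t0\t2000\t4\n")
        t = read_coverage(p, "s", "Kbu", 1, bin_width=1000, total_mapped_tags=1e6)
        assert t.values["chr1"].tolist() == [4.0, 4.0]

    def test_half_overlapping_record_is_apportioned(self, tmp_path):
        p = _write(tmp_path, "c.bg", "chr1\t500\t1500\t2\n")
        t = read_coverage(p, "s", "Kbu", 1, bin_width=1000, total_mapped_tags=1e6)
        assert t.values["chr1"].tolist() == [1.0, 1.0]

    def test_absent_chromosome_reads_as_zero(self, tmp_path):
        p = _write(tmp_path, "c.bg", "chr1\t0\t1000\t3\n")
        t = read_coverage(p, "s", "Kbu", 1, 1000, 1e6)
        assert t.interval_sum("chr2", 0, 5000) == 0.0

    def test_negative_value_rejected(self, tmp_path):
        with pytest.raises(ParseError, match="negative"):
            read_coverage(_write(tmp_path, "c.bg", "chr1\t0\t100\t-1\n"), "s", "Kbu", 1, 100, 1e6)

    def test_record_beyond_chromosome_rejected(self, tmp_path):
        with pytest.raises(ParseError, match="beyond"):
            read_coverage(
                _write(tmp_path, "c.bg", "chr1\t0\t5000\t1\n"),
                "s", "Kbu", 1, 1000, 1e6, chrom_sizes={"chr1": 2000},
            )

    def test_round_trip_of_binned_track(self, tmp_path):
        rng = np.random.default_rng(0)
        t = CoverageTrack(
            "s", "Kcr", 1, 50, 1e6,
            {"chr1": rng.poisson(2.0, 40).astype(float)},
        )
        path = tmp_path / "rt.bg"
        write_coverage(t, path)
        back = read_coverage(path, "s", "Kcr", 1, 50, 1e6, {"chr1": 2000})
        np.testing.assert_allclose(back.values["chr1"], t.values["chr1"])

    def test_interval_sum_apportions_partial_bins(self):
        t = CoverageTrack("s", "Kbu", 1, 100, 1e6, {"chr1": np.array([10.0, 20.0])})
        assert t.interval_sum("chr1", 50, 150) == pytest.approx(5 + 10)


class TestUpstreamAndOverlap:
    def test_plus_strand_upstream(self):
        g = GeneModel("g", Interval("chr1", 2000, 5000, "+"))
        assert upstream_region(g, 2000, {"chr1": 6000}) == Interval("chr1", 0, 2000, ".")

    def test_minus_strand_upstream_clipped_at_chrom_end(self):
        g = GeneModel("g", Interval("chr1", 2000, 5000, "-"))
        assert upstream_region(g, 2000, {"chr1": 6000}) == Interval("chr1", 5000, 6000, ".")

    def test_plus_strand_upstream_clipped_at_zero(self):
        g = GeneModel("g", Interval("chr1", 500, 900, "+"))
        assert upstream_region(g, 2000, {"chr1": 6000}) == Interval("chr1", 0, 500, ".")

    def test_empty_upstream_at_edge_is_none(self):
        g = GeneModel("g", Interval("chr1", 0, 900, "+"))
        assert upstream_region(g, 2000, {"chr1": 6000}) is None

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (Interval("chr1", 0, 100), Interval("chr1", 100, 200), False),
            (Interval("chr1", 0, 100), Interval("chr1", 99, 200), True),
            (Interval("chr1", 0, 100), Interval("chr2", 0, 100), False),
        ],
    )
    def test_half_open_overlap_semantics(self, a, b, expected):
        assert overlaps(a, b) is expected
        assert overlaps(b, a) is expected

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            Interval("chr1", 10, 10)
        with pytest.raises(ValueError):
            Interval("", 0, 10)
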