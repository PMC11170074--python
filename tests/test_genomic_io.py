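import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crmcval.genomic_io import (
    BedFormatError,
    ConservationTrack,
    Crmc,
    GenomeManifest,
    GenomicInterval,
    ValidatedElement,
    interval_overlap,
    intersect_sets,
    merge_intervals,
    read_bed,
    read_score_track,
    subtract_sets,
    total_bp,
    write_bed,
)


class TestGenomicInterval:
    def test_length_and_validation(self):
        iv = GenomicInterval("chr1", 100, 200)
        assert iv.length() == 100
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 100, 100)  # empty
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("chr 1", 0, 5)  # whitespace in name

    @pytest.mark.parametrize(
        "a, b, expected",
        [
            (("chr1", 100, 200), ("chr1", 150, 400), 50),
            (("chr1", 100, 200), ("chr1", 200, 300), 0),  # half-open abutment
            (("chr1", 100, 200), ("chr1", 100, 200), 100),  # identity
            (("chr1", 100, 200), ("chr2", 100, 200), 0),  # different chrom
        ],
    )
    def test_overlap(self, a, b, expected):
        assert interval_overlap(GenomicInterval(*a), GenomicInterval(*b)) == expected

    @settings(derandomize=True, max_examples=100)
    @given(
        s1=st.integers(0, 500), l1=st.integers(1, 500),
        s2=st.integers(0, 500), l2=st.integers(1, 500),
    )
    def test_overlap_symmetric_and_bounded(self, s1, l1, s2, l2):
        a = GenomicInterval("chr1", s1, s1 + l1)
        b = GenomicInterval("chr1", s2, s2 + l2)
        ov = interval_overlap(a, b)
        assert ov == interval_overlap(b, a)
        assert 0 <= ov <= min(a.length(), b.length())


class TestTypeInvariants:
    def test_crmc_p_value_bounds(self):
        iv = GenomicInterval("chr1", 0, 10)
        Crmc(iv, "c1", 1.0)
        for bad in (0.0, -0.1, 1.5):
            with pytest.raises(ValueError):
                Crmc(iv, "c1", bad)

    def test_element_label(self):
        iv = GenomicInterval("chr1", 0, 10)
        assert ValidatedElement(iv, "e1", "VNR").label == "VNR"
        with pytest.raises(ValueError):
            ValidatedElement(iv, "e1", "vnr")

    def test_manifest_validation(self):
        with pytest.raises(ValueError):
            GenomeManifest([("chr1", 10), ("chr1", 20)])
        with pytest.raises(ValueError):
            GenomeManifest([("chr1", 0)])


class TestBedIO:
    def test_read_element_line(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("chr1\t100\t200\tE1\t0\tVNR\n")
        (rec,) = read_bed(p, kind="element")
        assert rec == ValidatedElement(GenomicInterval("chr1", 100, 200), "E1", "VNR")

    @pytest.mark.parametrize(
        "line, kind",
        [
            ("chr1\t100\t100\tE1\t0\tVNR", "element"),  # empty interval
            ("chr1\t100\t200\tE1\t0\tMAYBE", "element"),  # unknown label
            ("chr1\t100\t200\tC1\t2.5", "crmc"),  # p outside (0,1]
            ("chr1\t100\t200\tC1\tnotanumber", "crmc"),
            ("chr1\t100", "plain"),  # too few columns
        ],
    )
    def test_malformed_lines_name_line_number(self, tmp_path, line, kind):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t50\tX\t0.5\tVPR\n" + line + "\n")
        with pytest.raises(BedFormatError, match=":2"):
            read_bed(p, kind=kind)

    def test_round_trip_identity(self, tmp_path):
        records = [
            ValidatedElement(GenomicInterval("chr2", 5, 50), "a", "VPR"),
            ValidatedElement(GenomicInterval("chr1", 100, 200), "b", "VNR"),
            ValidatedElement(GenomicInterval("chr1", 10, 20), "c", "VNR"),
        ]
        path = tmp_path / "rt.bed"
        write_bed(records, path)
        assert read_bed(path, kind="element") == records

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        data=st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(0, 10_000),
                st.integers(1, 500),
                st.floats(1e-12, 1.0, exclude_min=False),
            ),
            max_size=12,
        )
    )
    def test_crmc_round_trip_property(self, tmp_path_factory, data):
        records = [
            Crmc(GenomicInterval(c, s, s + l), f"id{i}", p)
            for i, (c, s, l, p) in enumerate(data)
        ]
        path = tmp_path_factory.mktemp("rt") / "c.bed"
        write_bed(records, path)
        assert read_bed(path, kind="crmc") == records

    def test_sorted_write_uses_manifest_order(self, tmp_path):
        manifest = GenomeManifest([("chrB", 1000), ("chrA", 1000)])
        records = [
            GenomicInterval("chrA", 0, 10),
            GenomicInterval("chrB", 5, 15),
            GenomicInterval("chrB", 0, 4),
        ]
        path = tmp_path / "s.bed"
        write_bed(records, path, manifest=manifest, sort=True)
        assert read_bed(path) == [records[2], records[1], records[0]]

    def test_empty_record_list(self, tmp_path):
        path = tmp_path / "empty.bed"
        write_bed([], path)
        assert path.read_text() == ""
        assert read_bed(path) == []


class TestScoreTrack:
    def make(self, tmp_path, text, chrom_len=5):
        p = tmp_path / "t.bedGraph"
        p.write_text(text)
        return p, GenomeManifest([("chr1", chrom_len)])

    def test_fill_and_missing(self, tmp_path):
        p, m = self.make(tmp_path, "chr1\t0\t3\t1.5\n")
        track = read_score_track(p, m)
        arr = track.scores["chr1"]
        assert list(arr[:3]) == [1.5, 1.5, 1.5]
        assert np.isnan(arr[3:]).all()

    def test_abutting_intervals(self, tmp_path):
        p, m = self.make(tmp_path, "chr1\t0\t2\t1.0\nchr1\t2\t4\t2.0\n")
        arr = read_score_track(p, m).scores["chr1"]
        assert list(arr[:4]) == [1.0, 1.0, 2.0, 2.0] and np.isnan(arr[4])

    def test_overlapping_intervals_rejected(self, tmp_path):
        p, m = self.make(tmp_path, "chr1\t0\t3\t1.0\nchr1\t2\t4\t2.0\n")
        with pytest.raises(BedFormatError, match="overlap"):
            read_score_track(p, m)

    def test_out_of_bounds_rejected(self, tmp_path):
        p, m = self.make(tmp_path, "chr1\t0\t9\t1.0\n")
        with pytest.raises(BedFormatError, match="beyond"):
            read_score_track(p, m)

    def test_covered_count_equals_interval_mass(self, tmp_path):
        text = "chr1\t0\t10\t1.0\nchr1\t20\t35\t-0.5\nchr2\t5\t6\t2.0\n"
        p = tmp_path / "t.bedGraph"
        p.write_text(text)
        m = GenomeManifest([("chr1", 50), ("chr2", 10)])
        track = read_score_track(p, m)
        assert track.n_covered() == 10 + 15 + 1

    def test_missing_values_dropped_not_zeroed(self, tmp_path):
        p, m = self.make(tmp_path, "chr1\t0\t2\t3.0\n")
        track = read_score_track(p, m)
        vals = track.values([GenomicInterval("chr1", 0, 5)])
        assert list(vals) == [3.0, 3.0]  # the 3 uncovered bases do not appear as 0


class TestIntervalSets:
    def test_merge_intersect_subtract(self):
        a = [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 5, 20)]
        b = [GenomicInterval("chr1", 8, 12)]
        assert merge_intervals(a) == [GenomicInterval("chr1", 0, 20)]
        assert intersect_sets(a, b) == [GenomicInterval("chr1", 8, 12)]
        assert subtract_sets(a, b) == [
            GenomicInterval("chr1", 0, 8),
            GenomicInterval("chr1", 12, 20),
        ]
        assert total_bp(a) == 20

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        xs=st.lists(st.tuples(st.integers(0, 200), st.integers(1, 40)), max_size=10),
        ys=st.lists(st.tuples(st.integers(0, 200), st.integers(1, 40)), max_size=10),
    )
    def test_set_algebra_matches_masks(self, xs, ys):
        a = [GenomicInterval("c", s, s + l) for s, l in xs]
        b = [GenomicInterval("c", s, s + l) for s, l in ys]
        ma, mb = np.zeros(300, bool), np.zeros(300, bool)
        for s, l in xs:
            ma[s : s + l] = True
        for s, l in ys:
            mb[s : s + l] = True
        assert total_bp(intersect_sets(a, b)) == int((ma & mb).sum())
        assert total_bp(subtract_sets(a, b)) == int((ma & ~mb).sum())
        assert total_bp(merge_intervals(a)) == int(ma.sum())
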