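"""Domain types and text I/O: validation, normalization, round trips."""

import logging

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitoloop import io as mio
from mitoloop.core import (
    CompactionRecord,
    ContactList,
    Fragment,
    GenomicInterval,
    KaryotypeRecord,
    MotifSite,
    ValidationError,
)


class TestGenomicInterval:
    def test_valid_interval(self):
        iv = GenomicInterval("chr1", 100, 120, "+")
        assert len(iv) == 20

    @pytest.mark.parametrize(
        "chrom,start,end,strand",
        [
            ("chr1", 120, 100, "+"),   # inverted
            ("chr1", 100, 100, "+"),   # empty
            ("chr1", -5, 100, "+"),    # negative
            ("", 0, 10, "+"),          # empty chrom
            ("chr1", 0, 10, "x"),      # bad strand
        ],
    )
    def test_invalid_interval(self, chrom, start, end, strand):
        with pytest.raises(ValidationError):
            GenomicInterval(chrom, start, end, strand)

    def test_overlap_is_half_open(self):
        a = GenomicInterval("c", 100, 119)
        assert a.overlaps(GenomicInterval("c", 90, 130))
        assert not a.overlaps(GenomicInterval("c", 119, 140))
        assert not a.overlaps(GenomicInterval("d", 90, 130))


class TestMotifSite:
    def test_center_is_floor_midpoint(self):
        site = MotifSite(GenomicInterval("c", 100, 119, "+"), "bookmarked")
        assert site.center == 109
        even = MotifSite(GenomicInterval("c", 100, 120, "-"), "lost")
        assert even.center == 110

    def test_requires_strand_and_known_category(self):
        with pytest.raises(ValidationError):
            MotifSite(GenomicInterval("c", 0, 10, "."), "bookmarked")
        with pytest.raises(ValidationError):
            MotifSite(GenomicInterval("c", 0, 10, "+"), "mystery")


class TestContactList:
    def test_intra_normalized_pos1_le_pos2(self):
        cl = ContactList(["chrA"], [500], ["chrA"], [100])
        assert cl.pos1[0] == 100 and cl.pos2[0] == 500

    def test_inter_chromosomal_not_swapped(self):
        cl = ContactList(["chrB"], [500], ["chrA"], [100])
        assert cl.pos1[0] == 500 and cl.pos2[0] == 100
        assert cl.n_inter == 1

    def test_count_validation(self):
        with pytest.raises(ValidationError):
            ContactList(["c"], [1], ["c"], [2], [0])

    @given(st.lists(st.tuples(st.integers(0, 10**6), st.integers(0, 10**6)), max_size=30))
    def test_normalization_invariant(self, pairs):
        cl = ContactList(
            ["c"] * len(pairs), [p[0] for p in pairs], ["c"] * len(pairs), [p[1] for p in pairs]
        )
        assert np.all(cl.pos1 <= cl.pos2)


class TestRecords:
    def test_fragment_midpoint_may_be_half_integral(self):
        assert Fragment("c", 1000, 1081).midpoint == 1040.5
        assert Fragment("c", 1000, 1080).length == 80

    def test_karyotype_centromere_inside(self):
        with pytest.raises(ValidationError):
            KaryotypeRecord("c", 100, 100)

    def test_compaction_positive(self):
        with pytest.raises(ValidationError):
            CompactionRecord("g", -1.0, 90.0)


class TestBedIO:
    def test_read_write_roundtrip(self, tmp_path):
        path = tmp_path / "m.bed"
        path.write_text("chr1\t100\t120\tm1\t0\t+\nchr1\t300\t320\tm2\t0\t-\n")
        records = mio.read_intervals(path)
        assert len(records) == 2
        assert records[0] == GenomicInterval("chr1", 100, 120, "+")
        out = tmp_path / "out.bed"
        mio.write_intervals(out, records)
        assert mio.read_intervals(out) == records

    def test_category_column_yields_motif_sites(self, tmp_path):
        path = tmp_path / "m.bed"
        path.write_text("chr1\t100\t120\tm1\t0\t+\tbookmarked\n")
        (site,) = mio.read_intervals(path)
        assert isinstance(site, MotifSite)
        assert site.category == "bookmarked"

    def test_inverted_coordinates_error_names_line(self, tmp_path):
        path = tmp_path / "bad.bed"
        path.write_text("chr1\t100\t120\n" "chr1\t120\t100\n")
        with pytest.raises(ValidationError, match="2"):
            mio.read_intervals(path)

    def test_order_preserved(self, tmp_path):
        path = tmp_path / "m.bed"
        lines = [f"chr1\t{i * 100}\t{i * 100 + 50}" for i in range(1, 5)]
        path.write_text("\n".join(lines) + "\n")
        records = mio.read_intervals(path)
        assert [r.start for r in records] == [100, 200, 300, 400]

    def test_one_based_conversion(self):
        (out,) = mio.convert_one_based([GenomicInterval("c", 101, 120)])
        assert (out.start, out.end) == (100, 120)


class TestContactIO:
    def test_normalization_and_default_count(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text("# header\nchrA 500 chrA 100\nchrA 100 chrB 200 3\n")
        cl = mio.read_contacts(path)
        assert (cl.pos1[0], cl.pos2[0], cl.count[0]) == (100, 500, 1)
        assert (cl.chrom2[1], cl.count[1]) == ("chrB", 3)

    def test_comment_only_file_is_empty(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text("# nothing\n# here\n")
        assert len(mio.read_contacts(path)) == 0

    def test_non_integer_position_raises(self, tmp_path):
        path = tmp_path / "p.txt"
        path.write_text("chrA x chrA 100\n")
        with pytest.raises(mio.ParseError):
            mio.read_contacts(path)

    def test_roundtrip(self, tmp_path):
        cl = ContactList(["a", "a", "b"], [5, 1, 9], ["a", "a", "a"], [7, 4, 2], [1, 2, 3])
        path = tmp_path / "p.txt"
        mio.write_contacts(path, cl)
        assert mio.read_contacts(path) == cl


class TestFragmentIO:
    def test_bed_fragment(self, tmp_path):
        path = tmp_path / "f.bed"
        path.write_text("chrA\t1000\t1080\n")
        (f,) = mio.read_fragments(path)
        assert (f.length, f.midpoint) == (80, 1040)

    def test_bedpe_collapses_mates(self, tmp_path):
        path = tmp_path / "f.bedpe"
        path.write_text("chrA\t1000\t1036\tchrA\t1044\t1080\n")
        (f,) = mio.read_fragments(path, format="bedpe")
        assert (f.start, f.end, f.length) == (1000, 1080, 80)

    def test_bedpe_interchromosomal_skipped_with_warning(self, tmp_path, caplog):
        path = tmp_path / "f.bedpe"
        path.write_text(
            "chrA\t1000\t1036\tchrB\t1044\t1080\n"
            "chrA\t1000\t1036\tchrA\t1044\t1080\n"
        )
        with caplog.at_level(logging.WARNING):
            frags = mio.read_fragments(path, format="bedpe")
        assert len(frags) == 1
        assert "different chromosomes" in caplog.text

    def test_roundtrip(self, tmp_path):
        frags = [Fragment("c", 10, 90), Fragment("c", 55, 56)]
        path = tmp_path / "f.bed"
        mio.write_fragments(path, frags)
        assert mio.read_fragments(path) == frags


class TestTripletIO:
    def test_matrix_roundtrip(self, tmp_path, rng):
        from mitoloop.matrix import bin_contacts

        n = 200
        p1 = rng.integers(0, 500_000, n)
        p2 = rng.integers(0, 500_000, n)
        cl = ContactList(["c"] * n, p1, ["c"] * n, p2)
        m = bin_contacts(cl, "c", 500_000, 10_000)
        path = tmp_path / "m.txt"
        mio.write_triplet(path, m)
        m2 = mio.read_triplet(path)
        assert m2.bin_size == m.bin_size and m2.n_bins == m.n_bins
        assert (m.counts != m2.counts).nnz == 0


class TestTableIO:
    def test_karyotype_csv(self, tmp_path):
        path = tmp_path / "k.csv"
        path.write_text("chrom,length_bp,centromere_bp\nchr1,100000000,30000000\n")
        (rec,) = mio.read_karyotype(path)
        assert rec.centromere_bp == 30_000_000

    def test_compaction_csv_missing_column(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("group,chromatid_length_um\nHeLa,9.0\n")
        with pytest.raises(mio.ParseError):
            mio.read_compaction(path)
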