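"""Interval containers, pileup/molecule parsing, binning and bedGraph I/O."""

import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cendip.errors import ConsistencyError, CoordinateError, ParseError, RangeError
from cendip.tracks import (
    BinnedTrack,
    GenomicInterval,
    MoleculeRead,
    bin_track,
    read_bedgraph,
    read_molecules,
    read_pileup,
    write_bedgraph,
    write_molecules,
)


def _pileup_line(chrom="chr1_hap1", start=100, frac="45.00", n_valid="20"):
    # bedmethyl dialect: 11+ columns, col 10 = valid coverage, col 11 = fraction
    return "\t".join(
        [chrom, str(start), str(start + 1), "m", ".", "+", str(start),
         str(start + 1), "0,0,0", n_valid, frac]
    )


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 10, 10)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 5)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 5)

    def test_overlap_half_open(self):
        a = GenomicInterval("chr1", 0, 10)
        assert a.overlap(GenomicInterval("chr1", 10, 20)) == 0
        assert a.overlap(GenomicInterval("chr1", 5, 20)) == 5
        assert a.overlap(GenomicInterval("chr2", 5, 20)) == 0


class TestReadPileup:
    def test_percent_dialect_divides_by_100(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text(_pileup_line(frac="45.00") + "\n")
        (rec,) = read_pileup(p, mod_code="m", dialect="percent")
        assert rec.frac_modified == pytest.approx(0.45)
        assert rec.n_valid == 20
        assert len(rec.position) == 1

    def test_fraction_dialect_taken_as_is(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text(_pileup_line(frac="0.45") + "\n")
        (rec,) = read_pileup(p, dialect="fraction")
        assert rec.frac_modified == pytest.approx(0.45)

    def test_empty_file_and_zero(self, tmp_path):
        p = tmp_path / "empty.bed"
        p.write_text("")
        assert read_pileup(p) == []
        p.write_text(_pileup_line(frac="0.00") + "\n")
        assert read_pileup(p)[0].frac_modified == 0.0

    def test_sorted_by_chrom_start(self, tmp_path):
        p = tmp_path / "p.bed"
        lines = [
            _pileup_line(chrom="chr2_hap1", start=5),
            _pileup_line(chrom="chr1_hap1", start=50),
            _pileup_line(chrom="chr1_hap1", start=10),
        ]
        p.write_text("\n".join(lines) + "\n")
        recs = read_pileup(p)
        keys = [(r.position.chrom, r.position.start) for r in recs]
        assert keys == sorted(keys)

    def test_malformed_line_names_line_number(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text(_pileup_line() + "\nchr1\t1\t2\n")
        with pytest.raises(ParseError, match="line 2"):
            read_pileup(p)

    def test_out_of_range_value_rejected_per_dialect(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text(_pileup_line(frac="145.0") + "\n")
        with pytest.raises(RangeError):
            read_pileup(p, dialect="percent")
        p.write_text(_pileup_line(frac="45.0") + "\n")
        with pytest.raises(RangeError):
            read_pileup(p, dialect="fraction")

    def test_gzip_transparent(self, tmp_path):
        p = tmp_path / "p.bed.gz"
        with gzip.open(p, "wt") as fh:
            fh.write(_pileup_line(frac="12.5") + "\n")
        assert read_pileup(p)[0].frac_modified == pytest.approx(0.125)


class TestReadMolecules:
    def test_block_decoding(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text(
            "chr1_hap1\t1000\t2000\tread1\t0\t.\t1000\t2000\t0,0,0\t3\t1,1,1\t0,100,200\n"
        )
        (read,) = read_molecules(p)
        assert read.mod_offsets == (0, 100, 200)
        assert list(read.mod_positions()) == [1000, 1100, 1200]

    def test_zero_blocks(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text("chr1\t0\t500\tr\t0\t.\t0\t500\t0,0,0\t0\t\t\n")
        (read,) = read_molecules(p)
        assert read.mod_offsets == ()

    def test_block_count_mismatch(self, tmp_path):
        p = tmp_path / "m.bed"
        p.write_text("chr1\t0\t500\tr\t0\t.\t0\t500\t0,0,0\t2\t1,1,1\t0,5,10\n")
        with pytest.raises(ConsistencyError):
            read_molecules(p)

    def test_offset_outside_span_rejected(self):
        with pytest.raises(CoordinateError):
            MoleculeRead("chr1", 0, 100, "r", (0, 100))

    def test_roundtrip_preserves_byte_layout(self, tmp_path):
        line = "chr1_hap1\t1000\t2000\tread1\t0\t.\t1000\t2000\t0,0,0\t2\t1,1\t5,900\n"
        src = tmp_path / "in.bed"
        src.write_text(line)
        reads = read_molecules(src)
        dst = tmp_path / "out.bed"
        write_molecules(reads, dst)
        assert dst.read_text() == line


class TestBinTrack:
    REGION = GenomicInterval("chr1", 0, 10)

    def test_mean_of_positions(self):
        track = bin_track([(0, 0.2), (1, 0.4)], self.REGION, bin_size=2)
        assert track.values[0] == pytest.approx(0.3)

    def test_empty_bin_is_nan_and_bin_count(self):
        track = bin_track([(0, 0.2)], self.REGION, bin_size=3)
        assert track.n_bins == 4  # ceil(10 / 3)
        assert np.isnan(track.values[1:]).all()

    def test_bin_size_one_identity(self):
        vals = [(i, i / 10) for i in range(10)]
        track = bin_track(vals, self.REGION, bin_size=1)
        np.testing.assert_allclose(track.values, [v for _, v in vals])

    @given(st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_constant_input_gives_constant_bins(self, c):
        track = bin_track([(i, c) for i in range(10)], self.REGION, bin_size=4)
        covered = ~np.isnan(track.values)
        np.testing.assert_allclose(track.values[covered], c)


class TestBedgraph:
    def test_roundtrip_within_1e6(self, tmp_path, rng):
        vals = rng.random(50)
        vals[7] = np.nan
        track = BinnedTrack("chr1", 100, 1000, vals)
        path = tmp_path / "t.bedgraph"
        write_bedgraph(track, path)
        assert len(path.read_text().splitlines()) == 49  # missing bin omitted
        back = read_bedgraph(path, region=track.region, bin_size=100)
        assert np.isnan(back.values[7])
        ok = ~np.isnan(vals)
        np.testing.assert_allclose(back.values[ok], vals[ok], atol=1e-6)

    def test_mean_in_overlap_weighted(self):
        track = BinnedTrack("chr1", 10, 0, [0.0, 1.0])
        # region covers all of bin 0 and half of bin 1
        assert track.mean_in(GenomicInterval("chr1", 0, 15)) == pytest.approx(1 / 3)
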