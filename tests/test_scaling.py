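"""Length-normalized rows, heat-map matrices, aggregate profiles, ratios."""

import numpy as np
import pytest

from cendip.errors import CendipError
from cendip.scaling import (
    CDR_SCHEME,
    HOR_SCHEME,
    ScalingScheme,
    aggregate_profile,
    build_heatmap,
    inside_outside_ratio,
    scale_region,
)
from cendip.tracks import BinnedTrack, GenomicInterval


def const_track(level=0.5, n_bins=4_000, bin_size=1_000, chrom="chr1_hap1"):
    return BinnedTrack(chrom, bin_size, 0, np.full(n_bins, float(level)))


class TestScaleRegion:
    REGION = GenomicInterval("chr1_hap1", 1_500_000, 2_500_000)

    def test_constant_track_gives_constant_row(self):
        row = scale_region(const_track(0.5), self.REGION, HOR_SCHEME)
        covered = ~np.isnan(row)
        np.testing.assert_allclose(row[covered], 0.5)

    def test_hor_row_length_2000(self):
        row = scale_region(const_track(), self.REGION, HOR_SCHEME)
        assert len(row) == 2_000 == HOR_SCHEME.row_length

    def test_cdr_row_length_450(self):
        region = GenomicInterval("chr1_hap1", 1_000_000, 1_100_000)
        row = scale_region(const_track(), region, CDR_SCHEME)
        assert len(row) == 450 == CDR_SCHEME.row_length

    def test_linear_ramp_resamples_monotonically(self):
        n = 1_000
        ramp = BinnedTrack("chr1_hap1", 1_000, 1_500_000, np.linspace(0, 1, n))
        region = GenomicInterval("chr1_hap1", 1_500_000, 1_500_000 + n * 1_000)
        scheme = ScalingScheme(body_bins=100, flank_bp=10_000, flank_bins=10)
        body = scale_region(ramp, region, scheme)[10:-10]
        assert np.all(np.diff(body) > 0)
        assert body[0] <= 1 / 100 + 1e-9
        assert body[-1] >= 1 - 1 / 100 - 1e-9

    def test_affine_commutation(self):
        track = BinnedTrack(
            "chr1_hap1", 1_000, 0, np.random.default_rng(7).random(4_000)
        )
        a, b = 2.5, -0.3
        scaled = BinnedTrack("chr1_hap1", 1_000, 0, a * track.values + b)
        region = GenomicInterval("chr1_hap1", 1_200_000, 2_000_000)
        scheme = ScalingScheme(body_bins=50, flank_bp=100_000, flank_bins=20)
        r1 = scale_region(scaled, region, scheme)
        r2 = a * scale_region(track, region, scheme) + b
        np.testing.assert_allclose(r1, r2, atol=1e-12)

    def test_uncovered_flank_is_missing(self):
        region = GenomicInterval("chr1_hap1", 100_000, 200_000)
        row = scale_region(const_track(n_bins=300), region, CDR_SCHEME)
        # left flank reaches below coordinate 0 partially; row keeps NaN there
        assert len(row) == 450
        assert not np.isnan(row[125:325]).any()


class TestBuildHeatmap:
    def _regions(self):
        return {
            "chr10_hap1": GenomicInterval("chr10_hap1", 1_500_000, 2_000_000),
            "chr2_hap2": GenomicInterval("chr2_hap2", 1_500_000, 2_000_000),
            "chr2_hap1": GenomicInterval("chr2_hap1", 1_500_000, 2_000_000),
        }

    def test_rows_sorted_numerically(self):
        regions = self._regions()
        tracks = {k: const_track(chrom=k) for k in regions}
        hm = build_heatmap(tracks, regions, CDR_SCHEME)
        assert hm.row_labels == ("chr2_hap1", "chr2_hap2", "chr10_hap1")
        assert hm.matrix.shape == (3, 450)

    def test_missing_track_gives_all_nan_row(self):
        regions = self._regions()
        tracks = {k: const_track(chrom=k) for k in list(regions)[:2]}
        hm = build_heatmap(tracks, regions, CDR_SCHEME)
        idx = hm.row_labels.index("chr2_hap1")
        assert np.isnan(hm.matrix[idx]).all()

    def test_input_order_irrelevant(self):
        regions = self._regions()
        tracks = {k: const_track(chrom=k) for k in regions}
        hm1 = build_heatmap(tracks, regions, CDR_SCHEME)
        rev = dict(reversed(list(regions.items())))
        hm2 = build_heatmap(tracks, rev, CDR_SCHEME)
        assert hm1.row_labels == hm2.row_labels
        np.testing.assert_array_equal(hm1.matrix, hm2.matrix)


class TestAggregateProfile:
    def test_single_center_equals_region_trace(self):
        rng = np.random.default_rng(3)
        track = BinnedTrack("chr1_hap1", 1_000, 0, rng.random(4_000))
        center = 2_000_000
        prof = aggregate_profile(track, [center], flank_bp=250_000, n_bins=100)
        np.testing.assert_array_equal(prof.mean, prof.per_region[0])
        assert len(prof.mean) == 100
        assert (prof.n == 1).all()

    def test_k_copies_equal_single_trace(self):
        track = const_track(0.4)
        single = aggregate_profile(track, [2_000_000])
        multi = aggregate_profile(track, [2_000_000] * 5)
        np.testing.assert_allclose(single.mean, multi.mean)

    def test_mirror_regions_give_symmetric_aggregate(self):
        n = 4_000
        vals = np.linspace(0, 1, n)
        up = BinnedTrack("chr1_hap1", 1_000, 0, vals)
        down = BinnedTrack("chr1_hap1", 1_000, 0, vals[::-1].copy())
        prof = aggregate_profile([up, down], [2_000_000, 2_000_000],
                                 flank_bp=200_000, n_bins=50)
        np.testing.assert_allclose(prof.mean, prof.mean[::-1], atol=1e-9)

    def test_boundary_step_gives_sigmoid_crossing(self):
        # high outside the CDR (left of boundary), low inside
        boundary = 2_000_000
        vals = np.where(np.arange(4_000) * 1_000 < boundary, 0.8, 0.1)
        track = BinnedTrack("chr1_hap1", 1_000, 0, vals.astype(float))
        prof = aggregate_profile(
            track, [boundary], flank_bp=100_000, n_bins=100,
            center_definition="cdr_boundary",
        )
        assert prof.mean[0] == pytest.approx(0.8)
        assert prof.mean[-1] == pytest.approx(0.1)
        assert np.all(np.diff(prof.mean) <= 0)

    def test_flip_mirrors_trace(self):
        vals = np.linspace(0, 1, 4_000)
        track = BinnedTrack("chr1_hap1", 1_000, 0, vals)
        plain = aggregate_profile(track, [2_000_000], flank_bp=100_000, n_bins=20)
        flipped = aggregate_profile(
            track, [2_000_000], flank_bp=100_000, n_bins=20, flip=[True]
        )
        np.testing.assert_allclose(flipped.mean, plain.mean[::-1])

    def test_no_centers_rejected(self):
        with pytest.raises(CendipError):
            aggregate_profile(const_track(), [])


class TestInsideOutsideRatio:
    CDR = GenomicInterval("chr1_hap1", 2_000_000, 2_100_000)

    def test_uniform_track_is_one(self):
        assert inside_outside_ratio(const_track(0.3), self.CDR) == pytest.approx(1.0)

    def test_zero_flanks_flagged(self):
        vals = np.zeros(4_000)
        vals[2_000:2_100] = 0.5
        track = BinnedTrack("chr1_hap1", 1_000, 0, vals)
        assert inside_outside_ratio(track, self.CDR) is None

    def test_arithmetic(self):
        vals = np.full(4_000, 0.1)
        vals[2_000:2_100] = 0.2
        track = BinnedTrack("chr1_hap1", 1_000, 0, vals)
        assert inside_outside_ratio(track, self.CDR) == pytest.approx(2.0)
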