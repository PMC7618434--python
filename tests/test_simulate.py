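"""Synthetic epigenome generator: determinism, calibration, truth recovery."""

import numpy as np
import pytest

from cendip.calling import CallOutcome, pileup_molecules
from cendip.cdr import detect_valleys
from cendip.density import DensityParams, per_read_density
from cendip.drift import peak_center
from cendip.errors import ConfigurationError
from cendip.simulate import (
    DriftParams,
    SimConfig,
    simulate,
    simulate_timecourse,
)
from cendip.tracks import GenomicInterval


class TestDeterminism:
    def test_same_seed_identical_bundles(self):
        a = simulate(SimConfig(seed=7))
        b = simulate(SimConfig(seed=7))
        for target in a.tracks:
            np.testing.assert_array_equal(a.tracks[target].values, b.tracks[target].values)
            assert a.molecules[target] == b.molecules[target]

    def test_different_seed_differs(self):
        a = simulate(SimConfig(seed=7))
        b = simulate(SimConfig(seed=8))
        assert a.molecules["cenpa"] != b.molecules["cenpa"]


class TestConfigValidation:
    def test_cdr_outside_hor_rejected(self):
        from cendip.simulate import CdrSpec, _default_contig

        bad = CdrSpec(interval=GenomicInterval("chr1_hap1", 100, 200))
        with pytest.raises(ConfigurationError):
            SimConfig(truth_cdrs=(bad,))

    def test_new_cdr_too_close_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(new_cdr=(400_000, 0.05))

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(genotype="banana")


class TestCalibration:
    def test_cenpa_pileup_fraction_matches_occupancy(self, default_bundle):
        """Thresholded call fractions converge on the generating rate."""
        bundle = default_bundle
        domain = bundle.truth.cdrs[0].interval
        occ = bundle.truth.cdrs[0].cenpa_occupancy
        records = [
            r
            for r in bundle.pileups["cenpa"]
            if domain.start <= r.position.start < domain.end
        ]
        n_calls = sum(r.n_valid for r in records)
        assert n_calls >= 2_000
        n_mod = sum(round(r.frac_modified * r.n_valid) for r in records)
        frac = n_mod / n_calls
        se = np.sqrt(occ * (1 - occ) / n_calls)
        assert abs(frac - occ) < 3 * se + 0.005  # 3 SE + small threshold bias

    def test_mcg_pileup_matches_background_level(self, default_bundle):
        bundle = default_bundle
        hor = bundle.truth.hor
        cdr = bundle.truth.cdrs[0].interval
        records = [
            r
            for r in bundle.pileups["mcg"]
            if hor.start <= r.position.start < cdr.start
        ]
        n_calls = sum(r.n_valid for r in records)
        frac = sum(round(r.frac_modified * r.n_valid) for r in records) / n_calls
        assert frac == pytest.approx(bundle.config.mcg_high, abs=0.02)

    def test_igg_reads_have_no_positional_structure(self, default_bundle):
        """IgG density inside truth domains matches density outside."""
        bundle = default_bundle
        domain = bundle.truth.cdrs[0].interval
        outside = GenomicInterval(domain.chrom, 3_000_000, 3_800_000)
        params = DensityParams(excluded_chroms=frozenset())
        d_in = [
            r.density
            for r in per_read_density(bundle.molecules["igg"], [(domain, "in")], params)
        ]
        d_out = [
            r.density
            for r in per_read_density(bundle.molecules["igg"], [(outside, "out")], params)
        ]
        se = np.sqrt(np.var(d_in) / len(d_in) + np.var(d_out) / len(d_out))
        assert abs(np.mean(d_in) - np.mean(d_out)) < 3 * se


class TestGenotypes:
    def _mean_h3k9(self, genotype):
        b = simulate(SimConfig(seed=21, genotype=genotype, n_reads=10))
        track = b.tracks["h3k9me3"]
        hor = b.truth.hor
        peri = b.truth.pericentromere[0]
        return track.mean_in(hor), track.mean_in(peri)

    def test_suv39_like_lowers_both_compartments(self):
        wt_hor, wt_peri = self._mean_h3k9("parental")
        mut_hor, mut_peri = self._mean_h3k9("suv39_like")
        assert mut_hor < wt_hor and mut_peri < wt_peri

    def test_setdb1_like_restricted_to_hor(self):
        wt_hor, wt_peri = self._mean_h3k9("parental")
        mut_hor, mut_peri = self._mean_h3k9("setdb1_like")
        assert mut_hor < wt_hor
        assert mut_peri == pytest.approx(wt_peri)

    def test_triple_like_strongest_in_hor(self):
        suv_hor, _ = self._mean_h3k9("suv39_like")
        tri_hor, tri_peri = self._mean_h3k9("triple_like")
        assert tri_hor < suv_hor
        assert tri_peri < self._mean_h3k9("parental")[1]


class TestTruthRecovery:
    def test_cdr_detection_recovers_truth_without_false_calls(self, default_bundle):
        bundle = default_bundle
        track = bundle.tracks["mcg"].slice(bundle.truth.hor)
        calls = detect_valleys(track)
        truths = [c.interval for c in bundle.truth.cdrs]
        assert len(calls) == len(truths)
        for call, truth in zip(calls, truths):
            assert abs(call.interval.start - truth.start) <= 10_000
            assert abs(call.interval.end - truth.end) <= 10_000
        # decoy dip lies in no call
        for decoy, _level in bundle.truth.decoy_dips:
            assert all(c.interval.overlap(decoy) == 0 for c in calls)


class TestTimecourse:
    def test_null_drift_centers_fixed(self):
        tc = simulate_timecourse(
            SimConfig(seed=5, drift=DriftParams(sd_kb=0.0)), n_clones=9
        )
        assert (tc.truth_centers == tc.truth_centers[0, 0]).all()
        ref_center = peak_center(tc.reference)
        shifts = [abs(peak_center(c) - ref_center) for c in tc.clones]
        assert np.mean(shifts) <= 1_000

    def test_programmed_displacement_recovered(self):
        tc = simulate_timecourse(
            SimConfig(seed=6, drift=DriftParams(programmed_shift_kb=1.0)),
            n_clones=3,
            n_generations=10,
        )
        ref_center = peak_center(tc.reference)
        for clone in tc.clones:
            assert abs((peak_center(clone) - ref_center) - 10_000) <= 1_000

    def test_random_walk_variance_matches_generator(self):
        """Empirical |shift| lies in the central 95% Monte-Carlo band."""
        sd_kb, n_gen, n_clones = 5.0, 4, 9
        tc = simulate_timecourse(
            SimConfig(seed=9, drift=DriftParams(sd_kb=sd_kb)),
            n_clones=n_clones,
            n_generations=n_gen,
        )
        final = tc.truth_centers[:, -1] - tc.truth_centers[:, 0]
        observed = np.mean(np.abs(final)) / 1_000.0
        # direct Monte-Carlo reference from the generating distribution
        rng = np.random.default_rng(0)
        sims = np.abs(
            rng.normal(0, sd_kb * np.sqrt(n_gen), size=(20_000, n_clones))
        ).mean(axis=1)
        lo, hi = np.quantile(sims, [0.025, 0.975])
        assert lo <= observed <= hi

    def test_domain_width_held_constant(self):
        tc = simulate_timecourse(
            SimConfig(seed=10, drift=DriftParams(sd_kb=5.0)), n_clones=3, noisy=False
        )
        for clone in tc.clones:
            width = np.sum(clone.values > 0.5 * np.nanmax(clone.values))
            ref_width = np.sum(
                tc.reference.values > 0.5 * np.nanmax(tc.reference.values)
            )
            assert abs(int(width) - int(ref_width)) <= 1
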