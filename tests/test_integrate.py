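"""Peak-gene-junction-timing integration operations."""
import numpy as np
import pytest

from rloopscape.core import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    JunctionSet,
    PeakSet,
)
from rloopscape import integrate as itg


class TestPromoterGC:
    def test_all_g(self):
        g = GeneModel("g", "chr1", "+", 3000, 5000)
        genome = {"chr1": "G" * 10_000}
        assert itg.promoter_gc(g, genome) == 1.0

    def test_acgt_repeat(self):
        g = GeneModel("g", "chr1", "+", 3000, 5000)
        genome = {"chr1": "ACGT" * 2500}
        assert itg.promoter_gc(g, genome) == pytest.approx(0.5, abs=1e-3)

    def test_matches_counting_oracle(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGTN"), 10_000,
                                 p=[0.3, 0.2, 0.2, 0.25, 0.05]))
        g = GeneModel("g", "chr1", "+", 3000, 5000)
        window = seq[1000:5001]
        expect = sum(b in "GC" for b in window) / sum(b in "ACGT" for b in window)
        assert itg.promoter_gc(g, {"chr1": seq}) == pytest.approx(expect)


class TestAssignPeaks:
    GENES = [
        GeneModel("g1", "chr1", "+", 10_000, 20_000),
        GeneModel("g2", "chr1", "+", 18_000, 30_000),
    ]

    def test_internal_peak_single_gene(self):
        peaks = [GenomicInterval("chr1", 12_000, 12_500)]
        res = itg.assign_peaks_to_genes(peaks, self.GENES)
        assert len(res["g1"]) == 1 and len(res["g2"]) == 0

    def test_desert_peak_unassigned(self):
        peaks = [GenomicInterval("chr1", 50_000, 50_500)]
        res = itg.assign_peaks_to_genes(peaks, self.GENES)
        assert all(len(v) == 0 for v in res.values())

    def test_shared_peak_serves_both_genes(self):
        peaks = [GenomicInterval("chr1", 18_500, 19_000)]
        res = itg.assign_peaks_to_genes(peaks, self.GENES)
        assert len(res["g1"]) == 1 and len(res["g2"]) == 1

    def test_promoter_extension_and_body_only(self):
        # peak 1 kb upstream of g1's TSS: counted via the promoter window,
        # excluded in body-only mode
        peaks = [GenomicInterval("chr1", 8_800, 9_200)]
        res = itg.assign_peaks_to_genes(peaks, self.GENES)
        assert len(res["g1"]) == 1
        res2 = itg.assign_peaks_to_genes(peaks, self.GENES, body_only=True)
        assert len(res2["g1"]) == 0


class TestPeakDensity:
    def test_formula(self):
        g = GeneModel("g", "chr1", "+", 0, 10_000)
        peaks = [GenomicInterval("chr1", 1, 2), GenomicInterval("chr1", 5, 6)]
        assert itg.peak_density(g, peaks) == pytest.approx(0.2)
        assert itg.peak_density(g, []) == 0.0

    def test_inverse_length_scaling(self):
        long_g = GeneModel("g", "chr1", "+", 0, 10_000)
        short_g = GeneModel("g", "chr1", "+", 0, 5_000)
        peaks = [GenomicInterval("chr1", 1, 2)]
        assert itg.peak_density(short_g, peaks) == \
            pytest.approx(2 * itg.peak_density(long_g, peaks))


class TestJunctionProximity:
    def test_brute_force_oracle(self):
        """Sorted-scan proximity equals the all-pairs gap check on random
        interval sets."""
        rng = np.random.default_rng(1)
        for trial in range(10):
            peaks = [GenomicInterval("chr1", int(s), int(s) + int(w))
                     for s, w in zip(rng.integers(0, 50_000, 40),
                                     rng.integers(50, 2000, 40))]
            juncs = [GenomicInterval("chr1", int(p), int(p) + 1)
                     for p in rng.integers(0, 52_000, 60)]
            window = int(rng.integers(0, 3000))
            n_in, n_tot, frac = itg.junction_peak_proximity(juncs, peaks, window)
            oracle = sum(
                any(j.gap_to(p) is not None and j.gap_to(p) <= window
                    for p in peaks)
                for j in juncs
            )
            assert n_in == oracle and n_tot == 60
            assert frac == pytest.approx(oracle / 60)
            assert 0 <= frac <= 1 and n_in <= n_tot

    def test_boundary_exactly_window_plus_one(self):
        peaks = [GenomicInterval("chr1", 0, 100)]
        at_window = [GenomicInterval("chr1", 2100, 2101)]      # gap 2000
        past_window = [GenomicInterval("chr1", 2101, 2102)]    # gap 2001
        assert itg.junction_peak_proximity(at_window, peaks, 2000)[0] == 1
        assert itg.junction_peak_proximity(past_window, peaks, 2000)[0] == 0

    def test_all_inside_peaks(self):
        peaks = [GenomicInterval("chr1", 0, 1000)]
        juncs = [GenomicInterval("chr1", i, i + 1) for i in range(0, 1000, 100)]
        assert itg.junction_peak_proximity(juncs, peaks, 0)[2] == 1.0

    def test_empty_junctions_rejected(self):
        from rloopscape.core import ValidationError
        with pytest.raises(ValidationError):
            itg.junction_peak_proximity([], [GenomicInterval("chr1", 0, 10)])

    def test_printed_count_pair(self):
        """98 of 1871 junctions near a peak prints as 5.24%."""
        n_in, n_tot = 98, 1871
        assert round(100.0 * n_in / n_tot, 2) == 5.24


class TestPeaksNearJunctionsPerGene:
    def test_counts_peaks_not_pairs(self):
        g = GeneModel("g", "chr1", "+", 0, 50_000)
        peaks = [GenomicInterval("chr1", 10_000, 10_500)]
        juncs = JunctionSet([
            GenomicInterval("chr1", 9_500, 9_501, ".", "g"),
            GenomicInterval("chr1", 10_200, 10_201, ".", "g"),
            GenomicInterval("chr1", 11_000, 11_001, ".", "g"),
        ], "RDC")
        assert itg.peaks_near_junctions_per_gene(peaks, juncs, [g]) == {"g": 1}

    def test_no_peaks_zero(self):
        g = GeneModel("g", "chr1", "+", 0, 50_000)
        juncs = JunctionSet([GenomicInterval("chr1", 10, 11, ".", "g")], "RDC")
        assert itg.peaks_near_junctions_per_gene([], juncs, [g]) == {"g": 0}


class TestTiming:
    def test_constant_track(self):
        t = CoverageTrack({"chr1": [(0, 10_000, 1.5)]})
        assert itg.interval_timing(GenomicInterval("chr1", 100, 200), t) == 1.5

    def test_equal_bp_weighted_median_interpolates(self):
        t = CoverageTrack({"chr1": [(0, 100, 1.0), (100, 200, 3.0)]})
        assert itg.interval_timing(GenomicInterval("chr1", 0, 200), t) == 2.0

    def test_unequal_weights_pick_majority_value(self):
        t = CoverageTrack({"chr1": [(0, 300, 1.0), (300, 400, 3.0)]})
        assert itg.interval_timing(GenomicInterval("chr1", 0, 400), t) == 1.0

    def test_unreported_region_missing(self):
        t = CoverageTrack({"chr1": [(0, 100, 1.0)]})
        assert itg.interval_timing(GenomicInterval("chr1", 500, 600), t) is None

    def test_planted_direction_on_toy(self, toy_sim, toy_called_peaks):
        """Early-planted peak timing median exceeds the RDC-gene median."""
        early = itg.peak_timing_values(list(toy_called_peaks), toy_sim.timing)
        rdc = [
            v for g in toy_sim.genes
            if toy_sim.truth.attrs[g.gene_id].is_rdc
            if (v := itg.interval_timing(g.span(), toy_sim.timing)) is not None
        ]
        assert np.median(early) > np.median(rdc)


class TestVenn:
    def test_basic_sets(self):
        v = itg.common_unique_gene_sets({"g1", "g2"}, {"g2", "g3"})
        assert v.common == {"g2"}
        assert v.unique_a == {"g1"} and v.unique_b == {"g3"}

    def test_identity_arithmetic(self):
        rng = np.random.default_rng(2)
        a = {f"g{i}" for i in rng.integers(0, 500, 200)}
        b = {f"g{i}" for i in rng.integers(0, 500, 200)}
        v = itg.common_unique_gene_sets(a, b)
        assert len(v.common) + len(v.unique_a) == len(a)
        assert len(v.common) + len(v.unique_b) == len(b)

    def test_equal_sets_have_no_uniques(self):
        v = itg.common_unique_gene_sets({"x", "y"}, {"x", "y"})
        assert not v.unique_a and not v.unique_b
        assert v.pct_common_of_a == 100.0

    def test_printed_shared_percentages(self):
        """7127 common genes against 7127+1303 and 7127+3514 print as
        84.54% and 66.98%."""
        a = {f"a{i}" for i in range(7127 + 3514)}       # first condition
        b = {f"a{i}" for i in range(7127)} | {f"b{i}" for i in range(1303)}
        v = itg.common_unique_gene_sets(a, b)
        assert len(v.common) == 7127
        assert v.pct_common_of_a == 66.98
        assert v.pct_common_of_b == 84.54


class TestDownsample:
    def test_identity_and_empty(self):
        peaks = PeakSet([GenomicInterval("chr1", i, i + 10)
                         for i in range(0, 100, 10)])
        assert len(itg.downsample_peaks(peaks, len(peaks), 0)) == len(peaks)
        assert len(itg.downsample_peaks(peaks, 0, 0)) == 0
        with pytest.raises(Exception):
            itg.downsample_peaks(peaks, 11, 0)

    def test_deterministic_and_uniform(self):
        peaks = PeakSet([GenomicInterval("chr1", i, i + 10)
                         for i in range(0, 500, 10)])
        a = itg.downsample_peaks(peaks, 20, seed=3)
        b = itg.downsample_peaks(peaks, 20, seed=3)
        assert [p.start for p in a] == [p.start for p in b]
        # inclusion frequency ~ k/n across repeats (binomial 3-sigma band)
        counts = np.zeros(50)
        reps = 300
        for s in range(reps):
            for p in itg.downsample_peaks(peaks, 20, seed=s):
                counts[p.start // 10] += 1
        expect = reps * 20 / 50
        sigma = np.sqrt(reps * (20 / 50) * (1 - 20 / 50))
        assert np.all(np.abs(counts - expect) < 5 * sigma)


class TestProfiles:
    def test_constant_track_flat(self):
        t = CoverageTrack({"chr1": [(0, 50_000, 2.0)]})
        g = GeneModel("g", "chr1", "+", 10_000, 20_000)
        meta = itg.metagene_profile(t, [g])
        assert np.allclose(meta, 2.0)
        tss = itg.tss_profile(t, [g])
        assert np.allclose(tss, 2.0)

    def test_tss_signal_peaks_at_center(self):
        t = CoverageTrack({"chr1": [(9_950, 10_050, 5.0)]})
        g = GeneModel("g", "chr1", "+", 10_000, 20_000)
        prof = itg.tss_profile(t, [g], flank_bp=2000, bin_size=50)
        assert prof.argmax() in (39, 40)
        meta = itg.metagene_profile(t, [g])
        assert meta.argmax() in (19, 20)

    def test_strand_mirror_symmetry(self):
        """A minus-strand gene with mirrored signal yields the same profile
        as its plus-strand counterpart."""
        gp = GeneModel("gp", "chr1", "+", 10_000, 16_000)
        gm = GeneModel("gm", "chr1", "-", 10_000, 16_000)
        rng = np.random.default_rng(4)
        runs = [(8_000 + 100 * i, 8_100 + 100 * i, float(v))
                for i, v in enumerate(rng.random(100))]
        fwd = CoverageTrack({"chr1": runs})
        # mirror around the gene midpoint 13_000
        mir_runs = sorted((26_000 - e, 26_000 - s, v) for s, e, v in runs)
        rev = CoverageTrack({"chr1": mir_runs})
        assert np.allclose(itg.metagene_profile(fwd, [gp]),
                           itg.metagene_profile(rev, [gm]))
        assert np.allclose(itg.tss_profile(fwd, [gp]),
                           itg.tss_profile(rev, [gm]))

    def test_short_gene_rescaled_without_error(self):
        t = CoverageTrack({"chr1": [(0, 10_000, 1.0)]})
        g = GeneModel("g", "chr1", "+", 5_000, 5_050)   # shorter than body bins
        meta = itg.metagene_profile(t, [g], body_bins=100)
        assert np.allclose(meta, 1.0)
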