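"""Synthetic-data generator: determinism, planted structure, inversions."""
import numpy as np
import pytest

from rloopscape.core import ValidationError
from rloopscape import gc_skew, peak_hmm
from rloopscape import simulate as sim
from rloopscape.transcription import expression_from_track


class TestDeterminism:
    def test_same_seed_byte_identical(self, small_config, tmp_path):
        a = sim.simulate(small_config)
        b = sim.simulate(small_config)
        assert a.genome == b.genome
        assert a.drip == b.drip
        assert [(p.chrom, p.start, p.end) for p in a.planted_peaks] == \
            [(p.chrom, p.start, p.end) for p in b.planted_peaks]
        da, db = tmp_path / "a", tmp_path / "b"
        sim.write_all(a, str(da))
        sim.write_all(b, str(db))
        for name in ("genome.fa", "drip.bedGraph", "genes.gtf", "manifest.tsv"):
            assert (da / name).read_bytes() == (db / name).read_bytes()

    def test_different_seed_differs(self, small_config):
        import dataclasses
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        assert sim.simulate(small_config).genome != sim.simulate(other).genome

    def test_stage_functions_match_bundle(self, small_config):
        """Standalone stage calls reproduce the bundled simulate() output
        (per-stage substreams of the one seed)."""
        bundle = sim.simulate(small_config)
        genes, truth = sim.plan_genes(small_config)
        genome, _, _ = sim.generate_genome(small_config, truth)
        assert genome == bundle.genome
        drip, planted = sim.generate_drip(genes, truth, small_config)
        assert drip == bundle.drip


class TestGenomeAndSkew:
    def test_no_skew_when_fraction_zero(self):
        cfg = sim.SimConfig(seed=3, genome_size=400_000, n_genes=40,
                            n_rdc_genes=2, n_tss_junction_genes=8,
                            fraction_skewed_promoters=0.0)
        s = sim.simulate(cfg)
        assert s.truth.gene_ids(skew_class="strong") == []

    def test_skewed_promoters_have_positive_skew(self, small_config):
        """Mean (G-C)/(G+C) on the non-template strand of planted skewed
        promoters exceeds 0.2 (expectation 1/3 at the default
        composition), by the window-counting oracle."""
        s = sim.simulate(small_config)
        values = []
        for g in s.genes:
            if s.truth.attrs[g.gene_id].skew_class != "strong":
                continue
            lo, hi = g.tss - 2000, g.tss + 2001
            window = s.genome[g.chrom][max(0, lo):hi]
            if g.strand == "-":
                window = gc_skew.reverse_complement(window)
            gn, cn = window.count("G"), window.count("C")
            values.append((gn - cn) / (gn + cn))
        assert values and np.mean(values) > 0.2

    def test_unskewed_promoters_balanced(self, small_config):
        s = sim.simulate(small_config)
        values = []
        for g in s.genes:
            a = s.truth.attrs[g.gene_id]
            if a.skew_class != "none" or a.is_rdc:
                continue
            window = s.genome[g.chrom][g.tss - 2000:g.tss + 2001]
            gn, cn = window.count("G"), window.count("C")
            values.append((gn - cn) / (gn + cn))
        assert abs(np.mean(values)) < 0.05


class TestGeneModels:
    def test_counts_and_nonoverlap(self, small_config):
        genes = sim.generate_gene_models(small_config)
        assert len(genes) == small_config.n_genes
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for glist in by_chrom.values():
            glist.sort(key=lambda g: g.tx_start)
            for a, b in zip(glist[:-1], glist[1:]):
                assert a.tx_end <= b.tx_start

    def test_rdc_genes_longer_than_median(self, small_config):
        s = sim.simulate(small_config)
        lengths = {g.gene_id: g.length for g in s.genes}
        med = np.median(list(lengths.values()))
        for gid in s.truth.gene_ids(is_rdc=True):
            assert lengths[gid] > med
            assert lengths[gid] >= small_config.rdc_min_length

    def test_infeasible_packing_raises(self):
        cfg = sim.SimConfig(seed=0, genome_size=100_000, n_genes=60,
                            n_rdc_genes=2, n_tss_junction_genes=5)
        with pytest.raises(ValidationError):
            sim.plan_genes(cfg)


class TestGro:
    def test_rpkm_inversion(self, small_config):
        """RPKM computed from the generated coverage recovers the planted
        rate to 1e-9 (closed-form inversion)."""
        s = sim.simulate(small_config)
        table = expression_from_track(s.genes, s.gro, s.truth.library_size)
        for g in s.genes:
            planted = s.truth.attrs[g.gene_id].rpkm
            assert table[g.gene_id] == pytest.approx(planted, abs=1e-9)

    def test_silent_gene_zero_coverage(self, small_config):
        s = sim.simulate(small_config)
        for g in s.genes:
            if s.truth.attrs[g.gene_id].rpkm == 0:
                assert s.gro.values_over(g.span()).sum() == 0.0
                break
        else:
            pytest.skip("no fully silent gene drawn at this seed")

    def test_all_three_classes_populated(self, toy_sim):
        m = toy_sim.truth.manifest()
        counts = m["transcription_class"].value_counts()
        assert set(counts.index) == {"active", "ambiguous", "inactive"}


class TestDrip:
    def test_inactive_genes_carry_no_planted_peaks(self, small_config):
        s = sim.simulate(small_config)
        for g in s.genes:
            a = s.truth.attrs[g.gene_id]
            if a.transcription_class == "active" or a.is_rdc:
                continue
            span = g.span()
            for p in s.planted_peaks:
                assert not p.overlaps(span)

    def test_planted_peaks_near_transcribed_genes(self, small_config):
        """Every planted peak lies within 2 kb of a transcribed gene."""
        s = sim.simulate(small_config)
        active_spans = [
            g for g in s.genes
            if s.truth.attrs[g.gene_id].transcription_class == "active"
        ]
        for p in s.planted_peaks:
            assert any(
                p.gap_to(g.span()) is not None and p.gap_to(g.span()) <= 2000
                for g in active_spans
            )

    def test_noiseless_recovery_is_exact(self):
        """With Poisson noise off the caller recovers the planted peaks
        at high Jaccard (bin-edge quantization only)."""
        cfg = sim.SimConfig(seed=5, genome_size=400_000, n_genes=40,
                            n_rdc_genes=2, n_tss_junction_genes=8,
                            poisson_noise=False)
        s = sim.simulate(cfg)
        peaks = peak_hmm.call_peaks_from_tracks([s.drip], s.chrom_sizes,
                                                bin_size=100)
        rec = sim.evaluate_peak_recovery(list(s.planted_peaks), list(peaks))
        assert rec["fraction_recovered"] == 1.0
        assert rec["mean_best_jaccard"] > 0.8


class TestJunctions:
    def test_tss_junctions_within_promoter(self, small_config):
        s = sim.simulate(small_config)
        tss_pos = {g.gene_id: g.tss for g in s.genes}
        assert len(s.junctions_tss) == \
            small_config.n_tss_junction_genes * small_config.tss_junctions_per_gene
        for j in s.junctions_tss:
            assert abs(j.start - tss_pos[j.name]) <= 2000

    def test_rdc_junctions_avoid_all_tss(self, small_config):
        s = sim.simulate(small_config)
        tss_positions = [(g.chrom, g.tss) for g in s.genes]
        for j in s.junctions_rdc:
            for chrom, tss in tss_positions:
                if chrom == j.chrom:
                    assert abs(j.start - tss) > 2000

    def test_counts_match_manifest(self, small_config):
        s = sim.simulate(small_config)
        m = s.truth.manifest().set_index("gene_id")
        for gid in s.truth.gene_ids(is_rdc=True):
            assert m.loc[gid, "n_junctions"] == small_config.rdc_junctions_per_gene


class TestTiming:
    def test_signs_by_label(self, small_config):
        from rloopscape.integrate import interval_timing
        s = sim.simulate(small_config)
        for g in s.genes:
            label = s.truth.attrs[g.gene_id].timing_label
            t = interval_timing(g.span(), s.timing)
            if label == "early":
                assert t == small_config.early_value
            elif label == "late":
                assert t == small_config.late_value

    def test_labels_recoverable_by_sign(self, small_config):
        from rloopscape.integrate import interval_timing
        s = sim.simulate(small_config)
        for g in s.genes:
            label = s.truth.attrs[g.gene_id].timing_label
            t = interval_timing(g.span(), s.timing)
            if label in ("early", "late"):
                assert (t > 0) == (label == "early")


def test_gene_sets_contain_planted_terms(small_config):
    s = sim.simulate(small_config)
    sets = sim.generate_gene_sets(s.truth, small_config)
    assert set(sets["PLANTED_RDC_LIKE"]) == set(s.truth.gene_ids(is_rdc=True))
    assert any(t.startswith("RANDOM") for t in sets)
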