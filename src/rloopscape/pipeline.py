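"""End-to-end orchestration: simulate (optional) -> peak calling -> skew
classification -> expression -> annotation -> integration -> enrichment ->
report.

A single YAML config drives the run; every stage writes TSV/BED artifacts
into the output directory, the run log records stage wall times and input
hashes, and the final markdown report tabulates the figure-analog numbers.
Two runs with identical config produce identical output hashes.
"""
from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set

import numpy as np
import pandas as pd
import yaml

from . import annotation as ann
from . import gc_skew
from . import integrate as itg
from . import io as rio
from . import peak_hmm
from . import simulate as sim
from . import stats as st
from . import transcription as tx
from .config import AnalysisConfig
from .core import ChromSizes, CoverageTrack, JunctionSet, PeakSet, ValidationError

log = logging.getLogger("rloopscape")


@dataclass
class PipelineConfig:
    outdir: str = "rloopscape_out"
    do_simulate: bool = True
    sim: sim.SimConfig = field(default_factory=sim.SimConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    # input paths, required when do_simulate is False
    inputs: Dict[str, object] = field(default_factory=dict)
    log_level: str = "INFO"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        cfg = cls(
            outdir=d.get("outdir", "rloopscape_out"),
            do_simulate=d.get("simulate", True),
            inputs=d.get("inputs", {}),
            log_level=d.get("log_level", "INFO"),
            seed=d.get("seed", 0),
        )
        if "sim" in d:
            cfg.sim = sim.SimConfig.from_dict({**d["sim"], "seed": d.get("seed", d["sim"].get("seed", 0))})
        else:
            cfg.sim = sim.SimConfig(seed=cfg.seed)
        if "analysis" in d:
            cfg.analysis = AnalysisConfig.from_dict(d["analysis"])
        return cfg


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _pct(x: float) -> str:
    return f"{round(100.0 * x, 2):.2f}"


@dataclass
class PipelineResult:
    outdir: str
    numbers: Dict[str, float]
    artifact_hashes: Dict[str, str]
    report_path: str


def run_all(config: PipelineConfig) -> PipelineResult:
    """Run every stage in order and write the summary report."""
    os.makedirs(config.outdir, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    run_log = os.path.join(config.outdir, "run.log")
    handler = logging.FileHandler(run_log, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    acfg = config.analysis
    artifacts: Dict[str, str] = {}
    t0 = time.time()
    try:
        # ---- inputs -----------------------------------------------------
        if config.do_simulate:
            log.info("stage simulate: toy genome %d bp, %d genes",
                     config.sim.genome_size, config.sim.n_genes)
            simres = sim.simulate(config.sim)
            simdir = os.path.join(config.outdir, "sim")
            paths = sim.write_all(simres, simdir)
            artifacts.update(paths)
            genome, chrom_sizes = simres.genome, simres.chrom_sizes
            genes = simres.genes
            drip_tracks = [simres.drip]
            gro = simres.gro
            timing = simres.timing
            junctions_tss, junctions_rdc = simres.junctions_tss, simres.junctions_rdc
            truth: Optional[sim.GroundTruth] = simres.truth
            gene_sets = sim.generate_gene_sets(simres.truth, config.sim)
            gmt_path = os.path.join(simdir, "gene_sets.gmt")
            st.write_gmt(gene_sets, gmt_path)
            artifacts["gene_sets"] = gmt_path
        else:
            inp = config.inputs
            for key in ("drip", "gro", "genes", "genome", "chrom_sizes"):
                if key not in inp:
                    raise ValidationError(f"missing input path: {key}")
            chrom_sizes = rio.read_chrom_sizes(str(inp["chrom_sizes"]))
            genome = rio.read_fasta(str(inp["genome"]), chrom_sizes)
            genes = rio.read_gtf_genes(str(inp["genes"]))
            drip_paths = inp["drip"]
            if isinstance(drip_paths, str):
                drip_paths = [drip_paths]
            drip_tracks = [rio.read_bedgraph(p) for p in drip_paths]
            gro = rio.read_bedgraph(str(inp["gro"]))
            timing = (sim.read_signed_bedgraph(str(inp["timing"]))
                      if "timing" in inp else None)
            junctions_tss = JunctionSet(
                rio.read_bed(str(inp["junctions_tss"])), "TSS-proximal"
            ) if "junctions_tss" in inp else JunctionSet(label="TSS-proximal")
            junctions_rdc = JunctionSet(
                rio.read_bed(str(inp["junctions_rdc"])), "RDC"
            ) if "junctions_rdc" in inp else JunctionSet(label="RDC")
            truth = None
            gene_sets = st.read_gmt(str(inp["gmt"])) if "gmt" in inp else {}

        # toy genomes need finer bins than the mammalian-scale default
        bin_size = acfg.bin_size
        if config.do_simulate and config.sim.genome_size <= 10_000_000:
            bin_size = 100

        # ---- peak calling ----------------------------------------------
        t = time.time()
        peaks = peak_hmm.call_peaks_from_tracks(
            drip_tracks, chrom_sizes, bin_size=bin_size,
            min_bins=acfg.min_bins, merge_gap_bins=acfg.merge_gap_bins,
        )
        peaks_path = os.path.join(config.outdir, "peaks.bed")
        rio.write_bed(list(peaks), peaks_path)
        artifacts["peaks"] = peaks_path
        log.info("stage callpeaks: %d peaks (%.1fs)", len(peaks), time.time() - t)

        # ---- GC skew ----------------------------------------------------
        t = time.time()
        model = gc_skew.make_model(acfg.skew_stringency)
        skew_classes = gc_skew.classify_genes(
            genome, genes, model, acfg.promoter_halfwidth
        )
        classes_path = os.path.join(config.outdir, "skew_classes.tsv")
        pd.DataFrame(
            sorted(skew_classes.items()), columns=["gene_id", "skew_class"]
        ).to_csv(classes_path, sep="\t", index=False)
        artifacts["skew_classes"] = classes_path
        log.info("stage skew: %d genes classified (%.1fs)",
                 len(skew_classes), time.time() - t)

        # ---- expression -------------------------------------------------
        t = time.time()
        library_size = truth.library_size if truth is not None else 1e6
        expr = tx.expression_from_track(genes, gro, library_size)
        tclasses = expr.classes(acfg)
        expr_path = os.path.join(config.outdir, "expression.tsv")
        expr.to_dataframe(genes, acfg).to_csv(expr_path, sep="\t", index=False)
        artifacts["expression"] = expr_path
        log.info("stage expression: %d genes (%.1fs)", len(expr.rpkm),
                 time.time() - t)

        # ---- annotation -------------------------------------------------
        t = time.time()
        model_ann = ann.build_annotation(
            genes, chrom_sizes, acfg.promoter_halfwidth, acfg.tts_halfwidth
        )
        annot = ann.observed_vs_expected(list(peaks), model_ann) if len(peaks) \
            else pd.DataFrame(columns=["category", "observed_fraction",
                                       "expected_fraction", "peak_count"])
        annot_path = os.path.join(config.outdir, "annotation.tsv")
        annot.to_csv(annot_path, sep="\t", index=False)
        artifacts["annotation"] = annot_path
        coverage_fraction = ann.genome_coverage_fraction(list(peaks), chrom_sizes)
        log.info("stage annotate (%.1fs)", time.time() - t)

        # ---- integration ------------------------------------------------
        t = time.time()
        tss_junction_genes = {j.name for j in junctions_tss if j.name}
        rdc_genes = ({g for g in truth.gene_ids(is_rdc=True)} if truth
                     else {j.name for j in junctions_rdc if j.name})
        stats_df = itg.build_gene_stats(
            genes, expr.rpkm, tclasses, skew_classes, list(peaks),
            genome=genome, timing=timing,
            tss_junction_genes=tss_junction_genes, rdc_genes=rdc_genes,
            promoter_halfwidth=acfg.promoter_halfwidth,
        )
        stats_path = os.path.join(config.outdir, "gene_stats.tsv")
        stats_df.to_csv(stats_path, sep="\t", index=False)
        artifacts["gene_stats"] = stats_path

        numbers: Dict[str, float] = {
            "n_peaks": len(peaks),
            "genome_coverage_pct": round(100.0 * coverage_fraction, 2),
            "n_genes": len(genes),
            "genes_with_peaks": int((stats_df["peak_count"] > 0).sum()),
        }
        for cls in tx.TRANSCRIPTION_CLASSES:
            numbers[f"n_{cls}"] = int((stats_df["transcription_class"] == cls).sum())
        for cls in ("strong", "weak", "none", "reverse"):
            numbers[f"skew_{cls}"] = int((stats_df["skew_class"] == cls).sum())

        prox: Dict[str, pd.DataFrame] = {}
        for jset in (junctions_tss, junctions_rdc):
            key = "tss" if jset.label == "TSS-proximal" else "rdc"
            if len(jset):
                n_in, n_tot, frac = itg.junction_peak_proximity(
                    jset, list(peaks), acfg.junction_window
                )
                numbers[f"junction_prox_{key}_within"] = n_in
                numbers[f"junction_prox_{key}_total"] = n_tot
                numbers[f"junction_prox_{key}_pct"] = round(100.0 * frac, 2)
        rdc_models = [g for g in genes if g.gene_id in rdc_genes]
        per_rdc = itg.peaks_near_junctions_per_gene(
            list(peaks), junctions_rdc, rdc_models, acfg.junction_window
        ) if rdc_models else {}
        per_rdc_path = os.path.join(config.outdir, "rdc_peak_counts.tsv")
        pd.DataFrame(sorted(per_rdc.items()),
                     columns=["gene_id", "peaks_near_junctions"]
                     ).to_csv(per_rdc_path, sep="\t", index=False)
        artifacts["rdc_peak_counts"] = per_rdc_path

        if timing is not None and len(peaks):
            peak_t = itg.peak_timing_values(list(peaks), timing)
            if peak_t:
                numbers["peak_timing_median"] = float(np.median(peak_t))
            rdc_t = [
                v for g in rdc_models
                if (v := itg.interval_timing(g.span(), timing)) is not None
            ]
            if rdc_t:
                numbers["rdc_timing_median"] = float(np.median(rdc_t))

        # called-vs-planted gene Venn (two-set comparison surface)
        genes_called = set(stats_df.loc[stats_df["peak_count"] > 0, "gene_id"])
        if truth is not None:
            planted_assigned = itg.assign_peaks_to_genes(
                list(truth.planted_peaks), genes, acfg.promoter_halfwidth
            )
            genes_planted = {g for g, p in planted_assigned.items() if p}
            venn = itg.common_unique_gene_sets(genes_called, genes_planted)
            numbers["venn_common"] = len(venn.common)
            numbers["venn_unique_called"] = len(venn.unique_a)
            numbers["venn_unique_planted"] = len(venn.unique_b)
            numbers["venn_common_pct_of_called"] = venn.pct_common_of_a
            numbers["venn_common_pct_of_planted"] = venn.pct_common_of_b

        # metagene / TSS profiles over active genes
        active = [g for g in genes if tclasses.get(g.gene_id) == "active"]
        if active:
            drip_pooled = peak_hmm.pool_tracks(drip_tracks)
            meta = itg.metagene_profile(drip_pooled, active)
            tssp = itg.tss_profile(drip_pooled, active)
            prof_path = os.path.join(config.outdir, "profiles.tsv")
            pd.DataFrame({
                "bin": range(max(len(meta), len(tssp))),
                "metagene": pd.Series(meta),
                "tss": pd.Series(tssp),
            }).to_csv(prof_path, sep="\t", index=False)
            artifacts["profiles"] = prof_path
        log.info("stage integrate (%.1fs)", time.time() - t)

        # ---- enrichment -------------------------------------------------
        if gene_sets:
            t = time.time()
            universe = [g.gene_id for g in genes]
            # enrichment over genes with promoter-proximal R-loop peaks:
            # a focused list, analogous to condition-specific R-loop genes
            promoter_peak_genes = {
                g.gene_id for g in genes
                if any(p.overlaps(g.promoter(acfg.promoter_halfwidth))
                       for p in peaks)
            }
            records = [
                st.hypergeometric_enrichment(promoter_peak_genes, members,
                                             universe, term)
                for term, members in sorted(gene_sets.items())
            ]
            clustered = st.filter_and_cluster_terms(records)
            enr_path = os.path.join(config.outdir, "enrichment.tsv")
            pd.DataFrame([
                {"term": r.term, "k": r.k, "n": r.n, "K": r.K, "N": r.N,
                 "p": r.p, "factor": r.factor, "q": r.q,
                 "cluster": r.cluster, "representative": r.representative}
                for r in clustered
            ]).to_csv(enr_path, sep="\t", index=False)
            artifacts["enrichment"] = enr_path
            numbers["n_enriched_terms"] = len(clustered)
            if clustered:
                numbers["top_term_is_planted"] = float(
                    clustered[0].representative.startswith("PLANTED"))
            log.info("stage enrich: %d surviving terms (%.1fs)",
                     len(clustered), time.time() - t)

        # ---- report -----------------------------------------------------
        hashes = {k: _sha256(p) for k, p in sorted(artifacts.items())}
        report_path = write_report(config.outdir, numbers, annot, per_rdc, hashes)
        artifacts["report"] = report_path
        with open(os.path.join(config.outdir, "numbers.json"), "w") as fh:
            json.dump(numbers, fh, indent=2, sort_keys=True)
        log.info("pipeline complete in %.1fs", time.time() - t0)
        return PipelineResult(config.outdir, numbers, hashes, report_path)
    except Exception as exc:
        log.error("pipeline aborted: %s", exc)
        raise
    finally:
        log.removeHandler(handler)
        handler.close()


def write_report(outdir: str, numbers: Dict[str, float],
                 annot: pd.DataFrame, per_rdc: Dict[str, int],
                 hashes: Dict[str, str]) -> str:
    """Human-readable markdown summary of the run."""
    lines = ["# rloopscape run report", ""]
    lines.append("## Peaks")
    lines.append(f"- R-loop peaks called: {int(numbers.get('n_peaks', 0))}")
    lines.append(f"- Genome covered by peaks: "
                 f"{numbers.get('genome_coverage_pct', 0.0):.2f}%")
    lines.append(f"- Genes with >= 1 peak: {int(numbers.get('genes_with_peaks', 0))} "
                 f"of {int(numbers.get('n_genes', 0))}")
    lines.append("")
    lines.append("## Transcription classes")
    for cls in ("active", "ambiguous", "inactive"):
        lines.append(f"- {cls}: {int(numbers.get(f'n_{cls}', 0))}")
    lines.append("")
    lines.append("## GC-skew classes (promoter-anchored)")
    for cls in ("strong", "weak", "none", "reverse"):
        lines.append(f"- {cls}: {int(numbers.get(f'skew_{cls}', 0))}")
    lines.append("")
    if not annot.empty:
        lines.append("## Peak annotation (observed vs expected fraction)")
        lines.append("| category | observed | expected | peaks |")
        lines.append("|---|---|---|---|")
        for _, row in annot.iterrows():
            lines.append(
                f"| {row['category']} | {row['observed_fraction']:.4f} "
                f"| {row['expected_fraction']:.4f} | {int(row['peak_count'])} |"
            )
        lines.append("")
    lines.append("## Junction-peak proximity (2 kb window)")
    for key, label in (("tss", "TSS-proximal junctions"), ("rdc", "RDC junctions")):
        if f"junction_prox_{key}_total" in numbers:
            lines.append(
                f"- {label}: {int(numbers[f'junction_prox_{key}_within'])} of "
                f"{int(numbers[f'junction_prox_{key}_total'])} within 2 kb of a "
                f"peak ({numbers[f'junction_prox_{key}_pct']:.2f}%)"
            )
    lines.append("")
    if per_rdc:
        lines.append("## Peaks near junctions per RDC-like gene")
        for gid, count in sorted(per_rdc.items()):
            lines.append(f"- {gid}: {count}")
        lines.append("")
    if "peak_timing_median" in numbers:
        lines.append("## Replication timing")
        lines.append(f"- Median timing ratio over peaks: "
                     f"{numbers['peak_timing_median']:+.2f}")
        if "rdc_timing_median" in numbers:
            lines.append(f"- Median timing ratio over RDC-like genes: "
                         f"{numbers['rdc_timing_median']:+.2f}")
        lines.append("")
    if "venn_common" in numbers:
        common = int(numbers["venn_common"])
        ua = int(numbers["venn_unique_called"])
        ub = int(numbers["venn_unique_planted"])
        lines.append("## Called vs planted gene sets")
        lines.append(f"- common: {common}; unique to called: {ua}; "
                     f"unique to planted: {ub}")
        lines.append(f"- identity check: {common} + {ua} = {common + ua} "
                     f"(= |called|); {common} + {ub} = {common + ub} (= |planted|)")
        lines.append(f"- common share: {numbers['venn_common_pct_of_called']:.2f}% "
                     f"of called, {numbers['venn_common_pct_of_planted']:.2f}% "
                     f"of planted")
        lines.append("")
    lines.append("## Artifact hashes (sha256)")
    for name, h in sorted(hashes.items()):
        lines.append(f"- {name}: {h}")
    lines.append("")
    path = os.path.join(outdir, "report.md")
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
    return path
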