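"""Synthetic genome with planted R-loop ground truth.

The generator emulates, at toy scale (2 Mb over two chromosomes, 200
genes), the structure of the R-loop landscape in neural stem/progenitor
cells under mild replication stress:

* transcribed genes with GC-skewed promoters (G-rich non-template strand
  over the promoter and the first quarter of the gene body) carrying DRIP
  signal at TSS, gene body and TES;
* non-skewed active genes with TES-biased DRIP signal only;
* long, late-replicating RDC-like genes (recurrent DSB cluster analogs)
  carrying clustered body junctions but few R-loop peaks;
* short, highly transcribed genes with TSS-proximal junctions;
* an early/late replication-timing ratio track (+ over skewed/active gene
  neighborhoods, - over RDC-like genes).

Every stage draws from its own substream of the single seed
(``default_rng([stage, seed])``), so stage outputs are byte-reproducible
whether generated standalone or through :func:`simulate`. Length
thresholds are stated at toy scale; the genome-size ratio to a mammalian
genome (2 Mb / 2.5 Gb) lives in the config, not the code.
"""
from __future__ import annotations

import os
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
import yaml

from .core import (
    ChromSizes,
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    JunctionSet,
    PeakSet,
    ValidationError,
    merge_intervals,
)
from . import io as rio

_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)

# rng substream tags, one per stochastic stage
_STAGE_GENES, _STAGE_SEQ, _STAGE_DRIP, _STAGE_JUNC, _STAGE_GMT = 1, 2, 4, 5, 6


@dataclass
class SimConfig:
    genome_size: int = 2_000_000
    n_chroms: int = 2
    n_genes: int = 200
    fraction_skewed_promoters: float = 0.45
    # gene lengths: log-normal body of the distribution plus an RDC tail
    gene_length_log_mean: float = float(np.log(3000.0))
    gene_length_log_sigma: float = 0.45
    gene_length_min: int = 800
    gene_length_max: int = 12_000
    n_rdc_genes: int = 10
    rdc_min_length: int = 30_000       # "long gene" at toy scale (300 kb / 10)
    rdc_max_length: int = 50_000
    n_tss_junction_genes: int = 40
    # transcription-class mixture and RPKM draws
    p_active: float = 0.70
    p_ambiguous: float = 0.15
    p_inactive: float = 0.15
    active_log10_rpkm_mean: float = -0.5
    active_log10_rpkm_sigma: float = 0.5
    library_size: float = 1e6
    # promoter skew composition on the non-template strand
    skew_p_g: float = 0.40
    skew_p_c: float = 0.20
    skew_body_fraction: float = 0.25
    promoter_halfwidth: int = 2000
    # DRIP signal
    drip_background_rate: float = 2.0  # Poisson mean per 10-bp step
    drip_snr: float = 10.0             # in-peak rate multiplier
    drip_step: int = 10
    poisson_noise: bool = True
    tss_peak_width: int = 800
    body_peak_width: int = 600
    tes_peak_width: int = 600
    rdc_peak_prob: float = 0.2
    planted_merge_gap: int = 300       # sub-resolution gaps fused at planting
    # junctions
    tss_junctions_per_gene: int = 5
    rdc_junctions_per_gene: int = 30
    # replication timing
    early_value: float = 1.5
    late_value: float = -1.5
    timing_flank: int = 2000
    # placement
    min_gene_gap: int = 4100           # keeps promoters/neighborhoods disjoint
    chrom_margin: int = 3000
    seed: int = 0
    genome_scale_reference: float = 2.5e9   # mammalian genome the toy scales from

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_chroms <= 0 or self.genome_size <= 0:
            raise ValidationError("counts and sizes must be > 0")
        if not 0 <= self.fraction_skewed_promoters <= 1:
            raise ValidationError("fraction_skewed_promoters must be in [0, 1]")
        if self.n_rdc_genes + 1 > self.n_genes:
            raise ValidationError("n_rdc_genes must be < n_genes")
        probs = (self.p_active, self.p_ambiguous, self.p_inactive)
        if any(p < 0 for p in probs) or abs(sum(probs) - 1) > 1e-9:
            raise ValidationError("transcription-class probabilities must sum to 1")

    def chrom_sizes(self) -> ChromSizes:
        per = self.genome_size // self.n_chroms
        return ChromSizes({f"chr{i + 1}": per for i in range(self.n_chroms)})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)


@dataclass
class GeneTruth:
    skew_class: str = "none"           # planted: strong | none
    rpkm: float = 0.0
    transcription_class: str = "inactive"
    is_rdc: bool = False
    has_tss_junction: bool = False
    timing_label: str = "none"         # early | late | none


@dataclass
class GroundTruth:
    genes: List[GeneModel] = field(default_factory=list)
    attrs: Dict[str, GeneTruth] = field(default_factory=dict)
    planted_peaks: PeakSet = field(default_factory=PeakSet)
    junctions_tss: JunctionSet = field(default_factory=lambda: JunctionSet(label="TSS-proximal"))
    junctions_rdc: JunctionSet = field(default_factory=lambda: JunctionSet(label="RDC"))
    library_size: float = 1e6

    def gene_ids(self, **flags) -> List[str]:
        """Gene ids whose truth attributes match all keyword filters."""
        out = []
        for g in self.genes:
            a = self.attrs[g.gene_id]
            if all(getattr(a, k) == v for k, v in flags.items()):
                out.append(g.gene_id)
        return out

    def manifest(self) -> pd.DataFrame:
        n_junc: Dict[str, int] = {}
        for jset in (self.junctions_tss, self.junctions_rdc):
            for j in jset:
                n_junc[j.name] = n_junc.get(j.name, 0) + 1
        rows = []
        for g in self.genes:
            a = self.attrs[g.gene_id]
            rows.append({
                "gene_id": g.gene_id, "chrom": g.chrom, "strand": g.strand,
                "tx_start": g.tx_start, "tx_end": g.tx_end, "length": g.length,
                "skew_class": a.skew_class, "rpkm": a.rpkm,
                "transcription_class": a.transcription_class,
                "is_rdc": a.is_rdc, "has_tss_junction": a.has_tss_junction,
                "timing_label": a.timing_label,
                "n_junctions": n_junc.get(g.gene_id, 0),
            })
        return pd.DataFrame(rows)


def _draw_exons(rng: np.random.Generator, start: int, end: int) -> Tuple[Tuple[int, int], ...]:
    length = end - start
    if length < 3000:
        return ((start, end),)
    n_ex = int(rng.integers(2, 5))
    n_blocks = 2 * n_ex - 1
    min_w = 100
    weights = rng.dirichlet(np.ones(n_blocks))
    widths = (min_w + weights * (length - min_w * n_blocks)).astype(int)
    widths[-1] = length - int(widths[:-1].sum())
    exons = []
    cursor = start
    for i, w in enumerate(widths):
        if i % 2 == 0:
            exons.append((cursor, cursor + int(w)))
        cursor += int(w)
    return tuple(exons)


def plan_genes(config: SimConfig) -> Tuple[List[GeneModel], GroundTruth]:
    """Place non-overlapping genes and assign planted classes.

    Deterministic given the config seed. Raises when the genome cannot
    accommodate the requested genes with the configured gaps and margins.
    """
    rng = np.random.default_rng([_STAGE_GENES, config.seed])
    sizes = config.chrom_sizes()
    chroms = sorted(sizes)
    n_other = config.n_genes - config.n_rdc_genes
    rdc_lengths = rng.integers(config.rdc_min_length, config.rdc_max_length + 1,
                               config.n_rdc_genes)
    other = np.exp(rng.normal(config.gene_length_log_mean,
                              config.gene_length_log_sigma, n_other))
    other = np.clip(other.astype(int), config.gene_length_min,
                    config.gene_length_max)
    entries = [(int(length), True) for length in rdc_lengths] + \
              [(int(length), False) for length in other]
    order = rng.permutation(len(entries))
    entries = [entries[i] for i in order]
    # greedy assignment to the chromosome with most free capacity
    free = {c: sizes[c] - 2 * config.chrom_margin for c in chroms}
    per_chrom: Dict[str, List[Tuple[int, bool]]] = {c: [] for c in chroms}
    for length, is_rdc in entries:
        target = max(chroms, key=lambda c: free[c])
        per_chrom[target].append((length, is_rdc))
        free[target] -= length + config.min_gene_gap
    genes: List[GeneModel] = []
    truth = GroundTruth(library_size=config.library_size)
    idx = 0
    for chrom in chroms:
        placed = per_chrom[chrom]
        k = len(placed)
        if k == 0:
            continue
        needed = (sum(length for length, _ in placed)
                  + (k - 1) * config.min_gene_gap + 2 * config.chrom_margin)
        slack = sizes[chrom] - needed
        if slack < 0:
            raise ValidationError(
                f"genes cannot be placed on {chrom}: need {needed} bp of "
                f"{sizes[chrom]} — shrink genes or grow the genome"
            )
        extras = np.floor(rng.dirichlet(np.ones(k + 1)) * slack).astype(int)
        cursor = config.chrom_margin + int(extras[0])
        for gi, (length, is_rdc) in enumerate(placed):
            idx += 1
            gid = f"gene{idx:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            tx_start, tx_end = cursor, cursor + length
            genes.append(GeneModel(gid, chrom, strand, tx_start, tx_end,
                                   _draw_exons(rng, tx_start, tx_end)))
            truth.attrs[gid] = GeneTruth(is_rdc=is_rdc)
            cursor = tx_end + config.min_gene_gap + int(extras[gi + 1])
    truth.genes = genes

    # planted transcription classes and rates
    classes = ("active", "ambiguous", "inactive")
    probs = (config.p_active, config.p_ambiguous, config.p_inactive)
    for g in genes:
        a = truth.attrs[g.gene_id]
        cls = "active" if a.is_rdc else rng.choice(classes, p=probs)
        a.transcription_class = str(cls)
        if cls == "active":
            mu = -0.8 if a.is_rdc else config.active_log10_rpkm_mean
            sd = 0.3 if a.is_rdc else config.active_log10_rpkm_sigma
            a.rpkm = max(0.025, float(10 ** rng.normal(mu, sd)))
        elif cls == "ambiguous":
            a.rpkm = float(rng.uniform(0.0025, 0.025))
        else:
            a.rpkm = float(rng.uniform(0.0, 0.0025)) if rng.random() < 0.5 else 0.0

    # planted GC-skew classes (RDC-like genes stay unskewed)
    for g in genes:
        a = truth.attrs[g.gene_id]
        if not a.is_rdc and rng.random() < config.fraction_skewed_promoters:
            a.skew_class = "strong"

    # TSS-junction genes: shortest skewed+active genes, padded with other
    # short active genes if the skewed pool is too small
    cand = sorted(truth.gene_ids(skew_class="strong",
                                 transcription_class="active", is_rdc=False),
                  key=lambda gid: next(g.length for g in genes
                                       if g.gene_id == gid))
    if len(cand) < config.n_tss_junction_genes:
        extra = sorted(
            set(truth.gene_ids(transcription_class="active", is_rdc=False))
            - set(cand),
            key=lambda gid: next(g.length for g in genes if g.gene_id == gid))
        cand += extra
    for gid in cand[:config.n_tss_junction_genes]:
        truth.attrs[gid].has_tss_junction = True

    # timing labels
    for g in genes:
        a = truth.attrs[g.gene_id]
        if a.is_rdc:
            a.timing_label = "late"
        elif a.skew_class == "strong" and a.transcription_class == "active":
            a.timing_label = "early"
    return genes, truth


def _skew_regions(gene: GeneModel, config: SimConfig) -> List[Tuple[int, int]]:
    """Forward-strand spans carrying the skewed composition: promoter plus
    the first ``skew_body_fraction`` of the gene body."""
    hw = config.promoter_halfwidth
    body = int(gene.length * config.skew_body_fraction)
    promoter = (gene.tss - hw, gene.tss + hw + 1)
    if gene.strand == "+":
        first = (gene.tx_start, gene.tx_start + body)
    else:
        first = (gene.tx_end - body, gene.tx_end)
    lo = min(promoter[0], first[0])
    hi = max(promoter[1], first[1])
    # promoter and first-body regions always touch at the TSS: one span
    return [(max(0, lo), hi)]


def generate_genome(config: SimConfig,
                    truth: Optional[GroundTruth] = None
                    ) -> Tuple[Dict[str, str], ChromSizes, GroundTruth]:
    """Background-uniform ACGT genome with skewed promoters planted.

    For each gene planted "strong", the non-template (coding) strand of the
    promoter and first quarter of the gene body has elevated G frequency
    (default P(G) = 0.40, P(C) = 0.20).
    """
    if truth is None:
        _, truth = plan_genes(config)
    rng = np.random.default_rng([_STAGE_SEQ, config.seed])
    sizes = config.chrom_sizes()
    pg, pc = config.skew_p_g, config.skew_p_c
    rest = (1.0 - pg - pc) / 2.0
    plus_probs = np.array([rest, pc, pg, rest])      # coding == forward
    minus_probs = np.array([rest, pg, pc, rest])     # complement composition
    genome: Dict[str, str] = {}
    for chrom in sorted(sizes):
        arr = rng.integers(0, 4, sizes[chrom], dtype=np.uint8)
        for g in sorted(truth.genes, key=lambda g: g.tx_start):
            if g.chrom != chrom or truth.attrs[g.gene_id].skew_class != "strong":
                continue
            probs = plus_probs if g.strand == "+" else minus_probs
            for lo, hi in _skew_regions(g, config):
                hi = min(hi, sizes[chrom])
                arr[lo:hi] = rng.choice(4, size=hi - lo, p=probs).astype(np.uint8)
        genome[chrom] = _BASE_BYTES[arr].tobytes().decode("ascii")
    return genome, sizes, truth


def generate_gene_models(config: SimConfig) -> List[GeneModel]:
    return plan_genes(config)[0]


def generate_groseq(genes: Sequence[GeneModel], truth: GroundTruth,
                    config: SimConfig) -> CoverageTrack:
    """Uniform within-gene coverage: per-bp read density rpkm * library /
    1e9, which inverts exactly under RPKM computation."""
    runs: Dict[str, List[Tuple[int, int, float]]] = {}
    for g in genes:
        rpkm = truth.attrs[g.gene_id].rpkm
        value = rpkm * config.library_size / 1e9
        if value > 0:
            runs.setdefault(g.chrom, []).append((g.tx_start, g.tx_end, value))
    return CoverageTrack(runs)


def _plant_peaks(genes: Sequence[GeneModel], truth: GroundTruth,
                 config: SimConfig, rng: np.random.Generator,
                 sizes: ChromSizes) -> PeakSet:
    peaks: List[GenomicInterval] = []
    for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start)):
        a = truth.attrs[g.gene_id]
        mine: List[Tuple[int, int]] = []
        if a.is_rdc:
            if rng.random() < config.rdc_peak_prob:
                w = config.body_peak_width
                lo = g.tx_start + config.promoter_halfwidth + 1 if g.strand == "+" \
                    else g.tx_start
                hi = g.tx_end if g.strand == "+" \
                    else g.tx_end - config.promoter_halfwidth - 1
                center = int(rng.integers(lo + w, hi - w))
                mine.append((center - w // 2, center + w // 2))
        elif a.transcription_class == "active":
            if a.skew_class == "strong":
                w = config.tss_peak_width
                mine.append((g.tss - w // 2, g.tss + w // 2))
                w = config.body_peak_width
                mid = (g.tx_start + g.tx_end) // 2
                mine.append((mid - w // 2, mid + w // 2))
            w = config.tes_peak_width
            mine.append((g.tes - w // 2, g.tes + w // 2))
        for lo, hi in mine:
            lo, hi = max(0, lo), min(hi, sizes[g.chrom])
            if lo < hi:
                peaks.append(GenomicInterval(g.chrom, lo, hi))
    merged = merge_intervals(peaks, gap=config.planted_merge_gap)
    return PeakSet(merged, {"planted": True})


def generate_drip(genes: Sequence[GeneModel], truth: GroundTruth,
                  config: SimConfig) -> Tuple[CoverageTrack, PeakSet]:
    """DRIP coverage with Poisson counts per step: background rate outside
    planted peaks, background * SNR inside."""
    rng = np.random.default_rng([_STAGE_DRIP, config.seed])
    sizes = config.chrom_sizes()
    planted = _plant_peaks(genes, truth, config, rng, sizes)
    truth.planted_peaks = planted
    step = config.drip_step
    track = CoverageTrack()
    for chrom in sorted(sizes):
        length = sizes[chrom]
        n_steps = -(-length // step)
        lam = np.full(n_steps, config.drip_background_rate)
        for p in planted:
            if p.chrom == chrom:
                lam[p.start // step:-(-p.end // step)] = (
                    config.drip_background_rate * config.drip_snr
                )
        counts = rng.poisson(lam).astype(float) if config.poisson_noise else lam
        runs = [
            (i * step, min((i + 1) * step, length), counts[i] / step)
            for i in range(n_steps) if counts[i] > 0
        ]
        track.set_chrom(chrom, runs)
    return track, planted


def generate_junctions(genes: Sequence[GeneModel], truth: GroundTruth,
                       config: SimConfig) -> Tuple[JunctionSet, JunctionSet]:
    """TSS-class junctions uniform in TSS +/- 2 kb of designated short
    active genes; RDC-class junctions uniform across RDC gene bodies
    excluding TSS +/- 2 kb."""
    rng = np.random.default_rng([_STAGE_JUNC, config.seed])
    hw = config.promoter_halfwidth
    tss = JunctionSet(label="TSS-proximal", source="synthetic")
    rdc = JunctionSet(label="RDC", source="synthetic")
    for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start)):
        a = truth.attrs[g.gene_id]
        if a.has_tss_junction:
            pos = rng.integers(g.tss - hw, g.tss + hw + 1,
                               config.tss_junctions_per_gene)
            for p in np.sort(pos):
                tss.junctions.append(
                    GenomicInterval(g.chrom, int(p), int(p) + 1, ".", g.gene_id))
        if a.is_rdc:
            if g.strand == "+":
                lo, hi = g.tss + hw + 1, g.tx_end
            else:
                lo, hi = g.tx_start, g.tss - hw
            pos = rng.integers(lo, hi, config.rdc_junctions_per_gene)
            for p in np.sort(pos):
                rdc.junctions.append(
                    GenomicInterval(g.chrom, int(p), int(p) + 1, ".", g.gene_id))
    truth.junctions_tss, truth.junctions_rdc = tss, rdc
    return tss, rdc


def generate_timing(genes: Sequence[GeneModel], truth: GroundTruth,
                    config: SimConfig) -> CoverageTrack:
    """Replication-timing ratio track: early_value over skewed/active gene
    neighborhoods, late_value over RDC-like genes, unreported elsewhere."""
    sizes = config.chrom_sizes()
    runs: Dict[str, List[Tuple[int, int, float]]] = {}
    for g in genes:
        a = truth.attrs[g.gene_id]
        if a.timing_label == "early":
            lo = max(0, g.tx_start - config.timing_flank)
            hi = min(sizes[g.chrom], g.tx_end + config.timing_flank)
            runs.setdefault(g.chrom, []).append((lo, hi, config.early_value))
        elif a.timing_label == "late":
            runs.setdefault(g.chrom, []).append(
                (g.tx_start, g.tx_end, config.late_value))
    return CoverageTrack(runs, signed=True)


@dataclass
class SimResult:
    config: SimConfig
    genome: Dict[str, str]
    chrom_sizes: ChromSizes
    genes: List[GeneModel]
    truth: GroundTruth
    gro: CoverageTrack
    drip: CoverageTrack
    planted_peaks: PeakSet
    junctions_tss: JunctionSet
    junctions_rdc: JunctionSet
    timing: CoverageTrack


def simulate(config: Optional[SimConfig] = None) -> SimResult:
    """Run every generation stage in order and bundle the outputs."""
    config = config or SimConfig()
    genes, truth = plan_genes(config)
    genome, sizes, truth = generate_genome(config, truth)
    gro = generate_groseq(genes, truth, config)
    drip, planted = generate_drip(genes, truth, config)
    jt, jr = generate_junctions(genes, truth, config)
    timing = generate_timing(genes, truth, config)
    return SimResult(config, genome, sizes, genes, truth, gro, drip,
                     planted, jt, jr, timing)


def write_all(sim: SimResult, outdir: str) -> Dict[str, str]:
    """Write every synthetic artifact; returns {label: path}."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "genome": os.path.join(outdir, "genome.fa"),
        "chrom_sizes": os.path.join(outdir, "genome.chrom.sizes"),
        "genes": os.path.join(outdir, "genes.gtf"),
        "drip": os.path.join(outdir, "drip.bedGraph"),
        "gro": os.path.join(outdir, "gro.bedGraph"),
        "timing": os.path.join(outdir, "timing.bedGraph"),
        "planted_peaks": os.path.join(outdir, "planted_peaks.bed"),
        "junctions_tss": os.path.join(outdir, "junctions_tss.bed"),
        "junctions_rdc": os.path.join(outdir, "junctions_rdc.bed"),
        "manifest": os.path.join(outdir, "manifest.tsv"),
        "config": os.path.join(outdir, "sim_config.yaml"),
    }
    rio.write_fasta(sim.genome, paths["genome"])
    rio.write_chrom_sizes(sim.chrom_sizes, paths["chrom_sizes"])
    rio.write_gtf_genes(sim.genes, paths["genes"])
    rio.write_bedgraph(sim.drip, paths["drip"])
    rio.write_bedgraph(sim.gro, paths["gro"])
    _write_signed_bedgraph(sim.timing, paths["timing"])
    rio.write_bed(list(sim.planted_peaks), paths["planted_peaks"])
    rio.write_bed(list(sim.junctions_tss), paths["junctions_tss"])
    rio.write_bed(list(sim.junctions_rdc), paths["junctions_rdc"])
    sim.truth.manifest().to_csv(paths["manifest"], sep="\t", index=False)
    sim.config.to_yaml(paths["config"])
    return paths


def _write_signed_bedgraph(track: CoverageTrack, path: str) -> None:
    with open(path, "w") as fh:
        for chrom in track.chroms:
            starts, ends, values = track.runs(chrom)
            for s, e, v in zip(starts, ends, values):
                fh.write(f"{chrom}\t{s}\t{e}\t{v:g}\n")


def read_signed_bedgraph(path: str) -> CoverageTrack:
    """Read a timing (signed-ratio) bedGraph, bypassing the non-negativity
    rule coverage tracks otherwise enforce."""
    runs: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            chrom, s, e, v = line.split("\t")[:4]
            runs.setdefault(chrom, []).append((int(s), int(e), float(v)))
    return CoverageTrack(runs, signed=True)


def generate_gene_sets(truth: GroundTruth, config: SimConfig,
                       n_random_terms: int = 20,
                       random_term_size: int = 15) -> Dict[str, Set[str]]:
    """Synthetic gene-set collection (GMT-style) with planted structure.

    Planted terms mirror the simulated biology (skewed genes, RDC-like
    genes, active genes); random terms draw genes uniformly, so in an
    enrichment of genes-with-R-loops the planted skewed-gene term should
    rank first.
    """
    rng = np.random.default_rng([_STAGE_GMT, config.seed])
    all_ids = [g.gene_id for g in truth.genes]
    sets: Dict[str, Set[str]] = {
        "PLANTED_SKEWED_PROMOTER": set(truth.gene_ids(skew_class="strong")),
        "PLANTED_RDC_LIKE": set(truth.gene_ids(is_rdc=True)),
        "PLANTED_ACTIVE": set(truth.gene_ids(transcription_class="active")),
    }
    for i in range(n_random_terms):
        members = rng.choice(all_ids, size=min(random_term_size, len(all_ids)),
                             replace=False)
        sets[f"RANDOM_{i:02d}"] = set(str(m) for m in members)
    return sets


# ---------------------------------------------------------------------------
# recovery metrics against the planted truth


def jaccard(a: GenomicInterval, b: GenomicInterval) -> float:
    if a.chrom != b.chrom:
        return 0.0
    inter = min(a.end, b.end) - max(a.start, b.start)
    if inter <= 0:
        return 0.0
    union = max(a.end, b.end) - min(a.start, b.start)
    return inter / union


def best_jaccards(planted: Sequence[GenomicInterval],
                  called: Sequence[GenomicInterval]) -> List[float]:
    """Best per-planted-peak Jaccard against any called peak."""
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for c in called:
        by_chrom.setdefault(c.chrom, []).append(c)
    out = []
    for p in planted:
        cands = by_chrom.get(p.chrom, [])
        out.append(max((jaccard(p, c) for c in cands), default=0.0))
    return out


def evaluate_peak_recovery(planted: Sequence[GenomicInterval],
                           called: Sequence[GenomicInterval],
                           min_jaccard: float = 0.5) -> Dict[str, float]:
    js = best_jaccards(planted, called)
    return {
        "n_planted": len(js),
        "n_called": len(list(called)),
        "fraction_recovered": float(np.mean([j >= min_jaccard for j in js]))
        if js else 0.0,
        "mean_best_jaccard": float(np.mean(js)) if js else 0.0,
    }


def evaluate_skew_recovery(truth: GroundTruth,
                           predicted: Mapping[str, str]) -> Dict[str, float]:
    """Label-recovery rates for planted strong-skew and no-skew genes."""
    strong = truth.gene_ids(skew_class="strong")
    none = truth.gene_ids(skew_class="none")
    return {
        "strong_recovered": float(np.mean([predicted[g] == "strong"
                                           for g in strong])) if strong else 1.0,
        "none_recovered": float(np.mean([predicted[g] == "none"
                                         for g in none])) if none else 1.0,
        "n_strong": len(strong),
        "n_none": len(none),
    }
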