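"""Integrative computations relating R-loop peaks to genes, breakpoint
junctions, replication timing, promoter GC content and a second cell type.

Conventions fixed here:

* a gene "contains" a peak when the peak overlaps the gene span united
  with the TSS +/- 2 kb promoter window by >= 1 bp (restrictable to the
  gene body);
* a "breakpoint region" is a junction position +/- the proximity window,
  so a junction is near a peak when the edge gap is <= window bp;
* replication-timing summaries are bp-weighted medians of the ratio track
  (early > 0 > late) over reported positions only — missing values are
  excluded, never zero-filled;
* percentages print at two decimals, round-half-even.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .core import (
    CoverageTrack,
    GeneModel,
    GenomicInterval,
    JunctionSet,
    PeakSet,
    ValidationError,
)


def promoter_gc(gene: GeneModel, genome: Mapping[str, str],
                halfwidth: int = 2000) -> float:
    """Fractional G+C content over TSS +/- halfwidth; N bases are excluded
    from the denominator, and an all-N promoter is an error."""
    if gene.chrom not in genome:
        raise ValidationError(f"gene {gene.gene_id}: chromosome {gene.chrom!r} "
                              "absent from genome")
    seq = genome[gene.chrom]
    start = max(0, gene.tss - halfwidth)
    end = min(len(seq), gene.tss + halfwidth + 1)
    window = seq[start:end].upper()
    denom = sum(window.count(b) for b in "ACGT")
    if denom == 0:
        raise ValidationError(f"gene {gene.gene_id}: promoter is all N")
    return (window.count("G") + window.count("C")) / denom


def _extended_span(gene: GeneModel, promoter_halfwidth: int) -> Tuple[int, int]:
    lo = min(gene.tx_start, gene.tss - promoter_halfwidth)
    hi = max(gene.tx_end, gene.tss + promoter_halfwidth + 1)
    return max(0, lo), hi


def assign_peaks_to_genes(
    peaks: Iterable[GenomicInterval], genes: Sequence[GeneModel],
    promoter_halfwidth: int = 2000, body_only: bool = False,
) -> Dict[str, List[GenomicInterval]]:
    """Peaks per gene; a peak counts for every gene whose span (united with
    its promoter window unless body_only) it overlaps by >= 1 bp."""
    assigned: Dict[str, List[GenomicInterval]] = {g.gene_id: [] for g in genes}
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for p in peaks:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda p: p.start)
    for g in genes:
        if body_only:
            lo, hi = g.tx_start, g.tx_end
        else:
            lo, hi = _extended_span(g, promoter_halfwidth)
        chrom_peaks = by_chrom.get(g.chrom, [])
        starts = [p.start for p in chrom_peaks]
        import bisect as _bisect
        i = _bisect.bisect_left(starts, lo)
        # walk left: peaks starting before lo may still reach into the span
        j = i - 1
        while j >= 0 and chrom_peaks[j].end > lo:
            assigned[g.gene_id].append(chrom_peaks[j])
            j -= 1
        while i < len(chrom_peaks) and chrom_peaks[i].start < hi:
            assigned[g.gene_id].append(chrom_peaks[i])
            i += 1
        assigned[g.gene_id].sort(key=lambda p: (p.start, p.end))
    return assigned


def peak_density(gene: GeneModel,
                 peaks: Sequence[GenomicInterval]) -> float:
    """Assigned peaks per kb of gene length."""
    return len(peaks) / (gene.length / 1000.0)


def junction_peak_proximity(
    junctions: Iterable[GenomicInterval], peaks: Iterable[GenomicInterval],
    window: int = 2000,
) -> Tuple[int, int, float]:
    """(n_within, n_total, fraction) of junctions with a peak within
    ``window`` bp (edge gap <= window; overlap counts)."""
    if window < 0:
        raise ValidationError("window must be >= 0")
    junctions = list(junctions)
    if not junctions:
        raise ValidationError("empty junction set")
    by_chrom: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}
    tmp: Dict[str, List[Tuple[int, int]]] = {}
    for p in peaks:
        tmp.setdefault(p.chrom, []).append((p.start, p.end))
    for chrom, pe in tmp.items():
        pe.sort()
        starts = np.array([s for s, _ in pe])
        # running max of ends, so "any peak left of i reaching j" is O(1)
        maxend = np.maximum.accumulate(np.array([e for _, e in pe]))
        by_chrom[chrom] = (starts, maxend)
    n_within = 0
    for j in junctions:
        if j.chrom in by_chrom:
            starts, maxend = by_chrom[j.chrom]
            # near iff some peak has start <= j.end + window and
            # end >= j.start - window
            i = int(np.searchsorted(starts, j.end + window, side="right"))
            if i > 0 and maxend[i - 1] >= j.start - window:
                n_within += 1
    return n_within, len(junctions), n_within / len(junctions)


def peaks_near_junctions_per_gene(
    peaks: Iterable[GenomicInterval], junctions: JunctionSet,
    genes: Sequence[GeneModel], window: int = 2000,
) -> Dict[str, int]:
    """Per gene, the number of distinct peaks having >= 1 of that gene's
    junctions within ``window`` bp (counting peaks, not pairs). Junction
    names carry the gene id."""
    by_gene: Dict[str, List[GenomicInterval]] = {g.gene_id: [] for g in genes}
    for j in junctions:
        if j.name in by_gene:
            by_gene[j.name].append(j)
    peaks = list(peaks)
    out: Dict[str, int] = {}
    for g in genes:
        count = 0
        for p in peaks:
            if p.chrom != g.chrom:
                continue
            if any(p.gap_to(j) is not None and p.gap_to(j) <= window
                   for j in by_gene[g.gene_id]):
                count += 1
        out[g.gene_id] = count
    return out


def weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median with midpoint interpolation at an exact 50% split."""
    order = np.argsort(values)
    v = np.asarray(values, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    cum = np.cumsum(w)
    half = cum[-1] / 2.0
    i = int(np.searchsorted(cum, half))
    if np.isclose(cum[i], half) and i + 1 < len(v):
        return float((v[i] + v[i + 1]) / 2.0)
    return float(v[i])


def interval_timing(interval: GenomicInterval,
                    timing: CoverageTrack) -> Optional[float]:
    """bp-weighted median replication-timing ratio over the interval,
    using reported positions only; None when nothing is reported."""
    starts, ends, values = timing.runs(interval.chrom)
    vs, ws = [], []
    for s, e, v in zip(starts, ends, values):
        a, b = max(s, interval.start), min(e, interval.end)
        if a < b:
            vs.append(v)
            ws.append(b - a)
    if not vs:
        return None
    return weighted_median(np.array(vs), np.array(ws))


def peak_timing_values(peaks: Iterable[GenomicInterval],
                       timing: CoverageTrack) -> List[float]:
    """Per-peak timing medians, pooled (missing peaks excluded)."""
    out = []
    for p in peaks:
        t = interval_timing(p, timing)
        if t is not None:
            out.append(t)
    return out


@dataclass
class VennResult:
    common: Set[str]
    unique_a: Set[str]
    unique_b: Set[str]
    pct_common_of_a: float     # two decimals, round-half-even
    pct_common_of_b: float


def common_unique_gene_sets(genes_with_peaks_a: Iterable[str],
                            genes_with_peaks_b: Iterable[str]) -> VennResult:
    """Common/unique gene sets for two conditions plus the shared
    percentages at print precision."""
    a, b = set(genes_with_peaks_a), set(genes_with_peaks_b)
    common = a & b
    pct_a = round(100.0 * len(common) / len(a), 2) if a else 0.0
    pct_b = round(100.0 * len(common) / len(b), 2) if b else 0.0
    return VennResult(common, a - b, b - a, pct_a, pct_b)


def downsample_peaks(peaks: PeakSet, k: int, seed: int = 0) -> PeakSet:
    """Uniform sample of exactly k peaks without replacement (the
    normalization used before cross-condition peak comparisons)."""
    n = len(peaks)
    if not (0 <= k <= n):
        raise ValidationError(f"cannot sample {k} of {n} peaks")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(n, size=k, replace=False))
    return PeakSet([peaks.peaks[i] for i in idx],
                   {**peaks.provenance, "downsampled_to": k, "seed": seed})


def _window_values(track: CoverageTrack, chrom: str, start: int,
                   end: int) -> np.ndarray:
    """Per-bp values over [start, end) with zero padding outside [0, inf)."""
    out = np.zeros(end - start, dtype=float)
    s = max(0, start)
    if s < end:
        vals = track.values_over(GenomicInterval(chrom, s, end))
        out[s - start:] = vals
    return out


def _rescale(arr: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean of a per-bp array over n_bins equal (fractional) chunks, exact
    for piecewise-constant signal."""
    cs = np.concatenate(([0.0], np.cumsum(arr)))
    edges = np.linspace(0, len(arr), n_bins + 1)
    integ = np.interp(edges, np.arange(len(arr) + 1), cs)
    widths = np.diff(edges)
    return np.diff(integ) / widths


def metagene_profile(track: CoverageTrack, genes: Sequence[GeneModel],
                     body_bins: int = 100, flank_bp: int = 2000,
                     flank_bins: int = 20) -> np.ndarray:
    """Mean signal profile: fixed-width upstream flank, gene body rescaled
    to ``body_bins``, fixed-width downstream flank; minus-strand genes are
    reversed so bin 0 is always 5' of the TSS."""
    if not genes:
        raise ValidationError("no genes for metagene profile")
    profiles = []
    for g in genes:
        arr = _window_values(track, g.chrom, g.tx_start - flank_bp,
                             g.tx_end + flank_bp)
        if g.strand == "-":
            arr = arr[::-1]
        up, body, down = (arr[:flank_bp], arr[flank_bp:flank_bp + g.length],
                          arr[flank_bp + g.length:])
        profiles.append(np.concatenate([
            _rescale(up, flank_bins), _rescale(body, body_bins),
            _rescale(down, flank_bins),
        ]))
    return np.mean(profiles, axis=0)


def tss_profile(track: CoverageTrack, genes: Sequence[GeneModel],
                flank_bp: int = 2000, bin_size: int = 50) -> np.ndarray:
    """Mean strand-oriented signal over TSS +/- flank in fixed bins."""
    if not genes:
        raise ValidationError("no genes for TSS profile")
    if flank_bp % bin_size:
        raise ValidationError("flank_bp must be a multiple of bin_size")
    n_bins = 2 * flank_bp // bin_size
    profiles = []
    for g in genes:
        # gene-oriented offsets -flank .. flank-1 relative to the TSS bp;
        # on the minus strand offset d sits at genomic position tss - d
        if g.strand == "+":
            arr = _window_values(track, g.chrom, g.tss - flank_bp,
                                 g.tss + flank_bp)
        else:
            arr = _window_values(track, g.chrom, g.tss - flank_bp + 1,
                                 g.tss + flank_bp + 1)[::-1]
        profiles.append(arr.reshape(n_bins, bin_size).mean(axis=1))
    return np.mean(profiles, axis=0)


def build_gene_stats(
    genes: Sequence[GeneModel],
    expression: Mapping[str, float],
    transcription_classes: Mapping[str, str],
    skew_classes: Mapping[str, str],
    peaks: Iterable[GenomicInterval],
    genome: Optional[Mapping[str, str]] = None,
    timing: Optional[CoverageTrack] = None,
    tss_junction_genes: Optional[Set[str]] = None,
    rdc_genes: Optional[Set[str]] = None,
    promoter_halfwidth: int = 2000,
) -> pd.DataFrame:
    """Per-gene summary table used by the report and downstream set logic."""
    assigned = assign_peaks_to_genes(peaks, genes, promoter_halfwidth)
    rows = []
    for g in genes:
        p = assigned[g.gene_id]
        rows.append({
            "gene_id": g.gene_id,
            "chrom": g.chrom,
            "strand": g.strand,
            "length": g.length,
            "rpkm": expression.get(g.gene_id, float("nan")),
            "transcription_class": transcription_classes.get(g.gene_id, ""),
            "skew_class": skew_classes.get(g.gene_id, ""),
            "peak_count": len(p),
            "peak_density": peak_density(g, p),
            "promoter_gc": (promoter_gc(g, genome, promoter_halfwidth)
                            if genome is not None else float("nan")),
            "median_timing": (interval_timing(g.span(), timing)
                              if timing is not None else float("nan")),
            "has_tss_junction": g.gene_id in (tss_junction_genes or set()),
            "is_rdc": g.gene_id in (rdc_genes or set()),
        })
    return pd.DataFrame(rows)
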