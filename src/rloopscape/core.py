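"""Core genomic data types.

All coordinates in this package are 0-based, half-open ([start, end)),
the native convention of BED and bedGraph. GTF input is converted on read.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple

import numpy as np

STRANDS = ("+", "-", ".")


class ValidationError(ValueError):
    """Raised when a genomic object violates its invariants."""


@dataclass(frozen=True)
class GenomicInterval:
    """A span on a chromosome, 0-based half-open.

    Strand '.' marks unstranded features (peaks, junctions); genes are
    always stranded.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    name: str = ""
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def gap_to(self, other: "GenomicInterval") -> Optional[int]:
        """Distance in bp between closest edges; 0 if overlapping/adjacent.

        None when on different chromosomes.
        """
        if self.chrom != other.chrom:
            return None
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start, other.start) - min(self.end, other.end)


class ChromSizes(dict):
    """Mapping chromosome name -> length (bp)."""

    def __init__(self, sizes: Mapping[str, int]):
        super().__init__()
        for name, length in sizes.items():
            if name in self:
                raise ValidationError(f"duplicate chromosome {name!r}")
            length = int(length)
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has length {length} <= 0")
            self[name] = length

    def check_interval(self, iv: GenomicInterval) -> None:
        if iv.chrom not in self:
            raise ValidationError(f"chromosome {iv.chrom!r} not in chrom sizes")
        if iv.end > self[iv.chrom]:
            raise ValidationError(
                f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                f"chromosome length {self[iv.chrom]}"
            )

    @property
    def genome_size(self) -> int:
        return sum(self.values())


@dataclass(frozen=True)
class GeneModel:
    """A gene: transcription unit with exon structure.

    TSS/TES are strand-aware single-bp positions: for a '+' gene the TSS is
    tx_start and the TES is tx_end - 1; reversed for '-' genes.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if not (0 <= self.tx_start < self.tx_end):
            raise ValidationError(
                f"gene {self.gene_id}: invalid span {self.tx_start}-{self.tx_end}"
            )
        prev_end = None
        for s, e in self.exons:
            if s < self.tx_start or e > self.tx_end or s >= e:
                raise ValidationError(
                    f"gene {self.gene_id}: exon {s}-{e} outside span "
                    f"{self.tx_start}-{self.tx_end} or empty"
                )
            if prev_end is not None and s < prev_end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons overlap or unsorted at {s}"
                )
            prev_end = e

    @property
    def tss(self) -> int:
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    @property
    def tes(self) -> int:
        return self.tx_end - 1 if self.strand == "+" else self.tx_start

    @property
    def length(self) -> int:
        return self.tx_end - self.tx_start

    def span(self, name: Optional[str] = None) -> GenomicInterval:
        return GenomicInterval(
            self.chrom, self.tx_start, self.tx_end, self.strand, name or self.gene_id
        )

    def promoter(self, halfwidth: int = 2000,
                 chrom_sizes: Optional[ChromSizes] = None) -> GenomicInterval:
        """TSS +/- halfwidth, clipped to the chromosome when sizes are bound."""
        start = self.tss - halfwidth
        end = self.tss + halfwidth + 1
        if chrom_sizes is not None and self.chrom in chrom_sizes:
            end = min(end, chrom_sizes[self.chrom])
        start = max(0, start)
        return GenomicInterval(self.chrom, start, end, self.strand, self.gene_id)


class CoverageTrack:
    """Stepwise numeric signal per chromosome.

    Per chromosome the track holds sorted, non-overlapping (start, end, value)
    runs; unreported positions have value 0. Values must be finite and >= 0
    unless the track is signed (replication-timing ratio tracks carry sign:
    early > 0 > late).
    """

    def __init__(self,
                 data: Optional[Mapping[str, Iterable[Tuple[int, int, float]]]] = None,
                 signed: bool = False):
        self.signed = signed
        self._runs: Dict[str, Tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        if data:
            for chrom, runs in data.items():
                self.set_chrom(chrom, runs)

    @property
    def chroms(self) -> List[str]:
        return sorted(self._runs)

    def set_chrom(self, chrom: str, runs: Iterable[Tuple[int, int, float]]) -> None:
        runs = sorted(runs)
        starts = np.array([r[0] for r in runs], dtype=np.int64)
        ends = np.array([r[1] for r in runs], dtype=np.int64)
        values = np.array([r[2] for r in runs], dtype=float)
        if len(starts):
            if np.any(starts >= ends):
                raise ValidationError(f"{chrom}: empty or inverted coverage run")
            if np.any(starts < 0):
                raise ValidationError(f"{chrom}: negative coordinate")
            if np.any(ends[:-1] > starts[1:]):
                raise ValidationError(f"{chrom}: overlapping coverage runs")
            if not np.all(np.isfinite(values)):
                raise ValidationError(f"{chrom}: coverage values must be finite")
            if not self.signed and np.any(values < 0):
                raise ValidationError(f"{chrom}: coverage values must be >= 0")
        self._runs[chrom] = (starts, ends, values)

    def runs(self, chrom: str) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
        return self._runs.get(
            chrom,
            (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, float)),
        )

    def to_array(self, chrom: str, length: int) -> np.ndarray:
        """Dense per-bp values over [0, length)."""
        arr = np.zeros(length, dtype=float)
        starts, ends, values = self.runs(chrom)
        for s, e, v in zip(starts, ends, values):
            arr[max(0, s):min(length, e)] = v
        return arr

    def values_over(self, iv: GenomicInterval) -> np.ndarray:
        """Per-bp values across an interval (zeros where unreported)."""
        arr = np.zeros(len(iv), dtype=float)
        starts, ends, values = self.runs(iv.chrom)
        if len(starts) == 0:
            return arr
        lo = int(np.searchsorted(ends, iv.start, side="right"))
        hi = int(np.searchsorted(starts, iv.end, side="left"))
        for s, e, v in zip(starts[lo:hi], ends[lo:hi], values[lo:hi]):
            a = max(s, iv.start) - iv.start
            b = min(e, iv.end) - iv.start
            if a < b:
                arr[a:b] = v
        return arr

    def total_signal(self) -> float:
        """Sum over all bp of the value (the track's 'read mass')."""
        total = 0.0
        for starts, ends, values in self._runs.values():
            total += float(np.sum((ends - starts) * values))
        return total

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoverageTrack):
            return NotImplemented
        if self.chroms != other.chroms:
            return False
        for c in self.chroms:
            for a, b in zip(self.runs(c), other.runs(c)):
                if not np.array_equal(a, b):
                    return False
        return True


def merge_intervals(intervals: Iterable[GenomicInterval],
                    gap: int = 0) -> List[GenomicInterval]:
    """Union of intervals, merging any pair separated by <= gap bp."""
    by_chrom: Dict[str, List[GenomicInterval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append(iv)
    out: List[GenomicInterval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda i: (i.start, i.end))
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e + gap:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def sort_intervals(intervals: Iterable[GenomicInterval]) -> List[GenomicInterval]:
    return sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))


@dataclass
class PeakSet:
    """Called peaks plus provenance (sample ids, model hash, bin size)."""

    peaks: List[GenomicInterval] = field(default_factory=list)
    provenance: Dict[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def sorted(self) -> "PeakSet":
        return PeakSet(sort_intervals(self.peaks), dict(self.provenance))


@dataclass
class JunctionSet:
    """Breakpoint junction positions with a class label (TSS-proximal | RDC)."""

    junctions: List[GenomicInterval] = field(default_factory=list)
    label: str = ""
    source: str = ""

    def __len__(self) -> int:
        return len(self.junctions)

    def __iter__(self):
        return iter(self.junctions)
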