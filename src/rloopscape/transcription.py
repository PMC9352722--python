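"""Per-gene nascent-transcription quantification and classification.

GRO-seq signal over the full (unspliced) gene span is converted to RPKM and
each gene falls into one of three classes: active (RPKM >= 0.025),
ambiguous (0.0025 <= RPKM < 0.025) or inactive (RPKM < 0.0025). A greedy
nearest-neighbour matcher builds transcription-rate-matched control gene
sets for density comparisons.
"""
from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import math

import pandas as pd

from .config import AnalysisConfig
from .core import CoverageTrack, GeneModel, ValidationError

TRANSCRIPTION_CLASSES = ("active", "ambiguous", "inactive")


@dataclass
class ExpressionTable:
    """gene_id -> RPKM, plus the library size the values were computed at."""

    rpkm: Dict[str, float] = field(default_factory=dict)
    library_size: float = 1e6

    def __getitem__(self, gene_id: str) -> float:
        return self.rpkm[gene_id]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.rpkm

    def classes(self, config: Optional[AnalysisConfig] = None) -> Dict[str, str]:
        config = config or AnalysisConfig()
        return {g: classify_transcription(r, config) for g, r in self.rpkm.items()}

    def to_dataframe(self, genes: Optional[Sequence[GeneModel]] = None,
                     config: Optional[AnalysisConfig] = None) -> pd.DataFrame:
        config = config or AnalysisConfig()
        lengths = {g.gene_id: g.length for g in genes} if genes else {}
        rows = [
            {
                "gene_id": gid,
                "length": lengths.get(gid, pd.NA),
                "rpkm": r,
                "class": classify_transcription(r, config),
            }
            for gid, r in sorted(self.rpkm.items())
        ]
        return pd.DataFrame(rows, columns=["gene_id", "length", "rpkm", "class"])


def compute_rpkm(counts: float, gene_length_bp: int, library_size: float) -> float:
    """RPKM = counts * 1e9 / (gene length in bp * library size)."""
    if library_size <= 0:
        raise ValidationError(f"library_size must be > 0, got {library_size}")
    if gene_length_bp <= 0:
        raise ValidationError(f"gene length must be > 0, got {gene_length_bp}")
    return counts * 1e9 / (gene_length_bp * library_size)


def gene_counts(gene: GeneModel, track: CoverageTrack) -> float:
    """Read mass over the full gene span (per-bp signal summed)."""
    return float(track.values_over(gene.span()).sum())


def expression_from_track(genes: Sequence[GeneModel], track: CoverageTrack,
                          library_size: float = 1e6) -> ExpressionTable:
    table = ExpressionTable(library_size=library_size)
    for gene in genes:
        table.rpkm[gene.gene_id] = compute_rpkm(
            gene_counts(gene, track), gene.length, library_size
        )
    return table


def classify_transcription(rpkm: float,
                           config: Optional[AnalysisConfig] = None) -> str:
    """Three-way transcription class; thresholds inclusive at the lower
    bound (RPKM exactly 0.025 is active, exactly 0.0025 ambiguous)."""
    config = config or AnalysisConfig()
    if rpkm < 0 or not math.isfinite(rpkm):
        raise ValidationError(f"RPKM must be finite and >= 0, got {rpkm}")
    if rpkm >= config.active_threshold:
        return "active"
    if rpkm >= config.ambiguous_threshold:
        return "ambiguous"
    return "inactive"


def similar_transcription(rpkm_a: float, rpkm_b: float,
                          tolerance: float = 0.05) -> bool:
    """True iff the rates differ by at most ``tolerance`` of the larger one
    (two silent genes count as similar)."""
    if rpkm_a < 0 or rpkm_b < 0:
        raise ValidationError("RPKM values must be >= 0")
    hi = max(rpkm_a, rpkm_b)
    if hi == 0:
        return True
    diff, band = abs(rpkm_a - rpkm_b), tolerance * hi
    # boundary cases (e.g. 2.0 vs 1.9 at 5%) must not fail on float noise
    return diff <= band or math.isclose(diff, band, rel_tol=1e-9)


@dataclass
class MatchResult:
    pairs: Dict[str, str]          # target gene -> matched control gene
    dropped: List[str]             # targets with no candidate within the cap

    @property
    def matched(self) -> List[str]:
        return sorted(self.pairs.values())


def match_by_transcription(
    target_genes: Iterable[str], candidate_pool: Iterable[str],
    expression: ExpressionTable, seed: int = 0,
    tolerance: float = 0.05, log10_cap: float = 0.5,
) -> MatchResult:
    """Greedy nearest-neighbour matching in log10(RPKM + 1e-6).

    Each target takes, without replacement, the candidate nearest in log
    rate; candidates within the +/-``tolerance`` band are preferred, and a
    target with no candidate closer than ``log10_cap`` log10 units is
    dropped. Targets are processed sorted by rate (then id), so the result
    is independent of input order; ``seed`` is accepted for interface
    stability but the procedure has no random step.
    """
    targets = sorted(set(target_genes))
    pool = sorted(set(candidate_pool))
    if set(targets) & set(pool):
        raise ValidationError("candidate pool must be disjoint from targets")
    if not pool:
        raise ValidationError("empty candidate pool")
    for gid in targets + pool:
        if gid not in expression:
            raise ValidationError(f"gene {gid} missing from expression table")

    def logr(gid: str) -> float:
        return math.log10(expression[gid] + 1e-6)

    targets.sort(key=lambda g: (expression[g], g))
    cand = sorted(((logr(g), g) for g in pool))
    pairs: Dict[str, str] = {}
    dropped: List[str] = []
    for t in targets:
        if not cand:
            dropped.append(t)
            continue
        lt = logr(t)
        i = bisect.bisect_left(cand, (lt, ""))
        best_j, best_d, best_sim = -1, float("inf"), False
        for j in (i - 1, i):
            if 0 <= j < len(cand):
                d = abs(cand[j][0] - lt)
                sim = similar_transcription(
                    expression[t], expression[cand[j][1]], tolerance
                )
                # within-band candidates beat out-of-band ones at any distance
                if (sim, -d) > (best_sim, -best_d):
                    best_j, best_d, best_sim = j, d, sim
        if best_j < 0 or best_d > log10_cap:
            dropped.append(t)
            continue
        pairs[t] = cand[best_j][1]
        del cand[best_j]
    return MatchResult(pairs, dropped)
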