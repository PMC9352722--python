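"""Four-state GC-skew HMM: decode genome sequence into skew states and
assign each gene a promoter-anchored skew class.

GC skew — strand asymmetry in G vs C content, (G-C)/(G+C) — marks regions
prone to R-loop formation when the non-template (coding) strand is G-rich.
The decoder is a hidden Markov chain over per-bp nucleotide emissions with
states STRONG, WEAK, NONE and REVERSE skew. Two stringencies are provided:
the "stringent" model (expected segment length 1e6 bp, used for gene
classification) and the "lenient" model (expected length 7600 bp, used for
metaplots). Emission and transition defaults are declared approximations
of the published two-phase skew pipeline's model files, whose exact
parameters are not public; every number is overridable from YAML.

Genes are classified on their coding-strand orientation: minus-strand
genes are decoded on the reverse complement, so STRONG always means
"G-rich non-template strand" regardless of genomic strand.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import yaml

from .core import GeneModel, GenomicInterval, ValidationError

STATES = ("STRONG", "WEAK", "NONE", "REVERSE")
BASES = "ACGT"
# class priority when a promoter touches several states
CLASS_PRIORITY = ("strong", "weak", "reverse", "none")
# tie-break preference during decoding (NONE wins exact ties)
_TIE_ORDER = (2, 0, 1, 3)

_COMP = str.maketrans("ACGTN", "TGCAN")

DEFAULT_EMISSIONS = {
    "STRONG": {"A": 0.20, "C": 0.20, "G": 0.40, "T": 0.20},
    "WEAK": {"A": 0.25, "C": 0.20, "G": 0.30, "T": 0.25},
    "NONE": {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25},
    "REVERSE": {"A": 0.20, "C": 0.40, "G": 0.20, "T": 0.20},
}
# expected segment lengths implied by the stringency presets
STRINGENCY_LENGTH = {"stringent": 1_000_000, "lenient": 7_600}


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass
class SkewHmmModel:
    """4-state nucleotide-emission HMM."""

    emissions: np.ndarray            # (4 states, 4 bases), rows sum to 1
    trans: np.ndarray                # (4, 4), rows sum to 1
    stringency: str = "custom"
    pi: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.emissions.shape != (4, 4) or self.trans.shape != (4, 4):
            raise ValidationError("skew model must have 4 states over ACGT")
        if not np.allclose(self.emissions.sum(axis=1), 1.0):
            raise ValidationError("emission rows must sum to 1")
        if not np.allclose(self.trans.sum(axis=1), 1.0):
            raise ValidationError("transition rows must sum to 1")
        s = {st: i for i, st in enumerate(STATES)}
        pg = self.emissions[:, BASES.index("G")]
        pc = self.emissions[:, BASES.index("C")]
        skews = pg - pc
        if skews[s["STRONG"]] < skews.max() - 1e-12:
            raise ValidationError("STRONG must have the maximal P(G) - P(C)")
        if pc[s["REVERSE"]] < pg[s["REVERSE"]] - 1e-12:
            raise ValidationError("REVERSE must have P(C) >= P(G)")

    def log_emission_lookup(self) -> np.ndarray:
        """(4 states, 5 symbols) log-emission table; column 4 is N (prob 1,
        likelihood-neutral under every state)."""
        table = np.full((4, 5), 0.0)
        table[:, :4] = np.log(np.maximum(self.emissions, 1e-300))
        return table


def make_model(stringency: str = "stringent",
               emissions: Optional[Mapping[str, Mapping[str, float]]] = None,
               expected_segment_length: Optional[float] = None) -> SkewHmmModel:
    """Build a model from a stringency preset.

    Self-transition is 1 - 1/expected_segment_length; the off-diagonal mass
    is split evenly across the other three states.
    """
    if expected_segment_length is None:
        if stringency not in STRINGENCY_LENGTH:
            raise ValidationError(
                f"unknown stringency {stringency!r}; expected one of "
                f"{sorted(STRINGENCY_LENGTH)} or an explicit segment length"
            )
        expected_segment_length = STRINGENCY_LENGTH[stringency]
    p_leave = 1.0 / expected_segment_length
    trans = np.full((4, 4), p_leave / 3.0)
    np.fill_diagonal(trans, 1.0 - p_leave)
    em = emissions or DEFAULT_EMISSIONS
    emat = np.array([[em[st][b] for b in BASES] for st in STATES])
    return SkewHmmModel(emat, trans, stringency)


def load_model(path: str) -> SkewHmmModel:
    """Load a model from YAML (keys: emissions, expected_segment_length or
    transitions, stringency)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if "transitions" in cfg:
        return SkewHmmModel(
            np.array([[cfg["emissions"][st][b] for b in BASES] for st in STATES]),
            np.array(cfg["transitions"]),
            cfg.get("stringency", "custom"),
        )
    return make_model(
        cfg.get("stringency", "custom"),
        emissions=cfg.get("emissions"),
        expected_segment_length=cfg.get("expected_segment_length"),
    )


def encode_sequence(seq: str) -> np.ndarray:
    """Map ACGTN to 0..4; any other character is an error."""
    lut = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(BASES + "N"):
        lut[ord(b)] = i
        lut[ord(b.lower())] = i
    obs = lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(obs < 0):
        raise ValidationError("sequence contains non-IUPAC characters")
    return obs


def viterbi_sequence(model: SkewHmmModel, seq: str) -> np.ndarray:
    """Per-bp most probable state path (indices into STATES).

    Exact ties in the dynamic program resolve to NONE first, then STRONG,
    WEAK, REVERSE — so an uninformative model yields an all-NONE path.
    """
    if len(seq) == 0:
        raise ValidationError("empty sequence")
    obs = encode_sequence(seq)
    log_e = model.log_emission_lookup()
    log_a = np.log(np.maximum(model.trans, 1e-300))
    log_pi = np.log(np.maximum(model.pi, 1e-300))
    n = len(obs)
    pref = np.array(_TIE_ORDER)
    back = np.zeros((n, 4), dtype=np.int8)
    delta = log_pi + log_e[:, obs[0]]
    for t in range(1, n):
        cand = delta[:, None] + log_a           # cand[i, j]
        best = pref[np.argmax(cand[pref], axis=0)]
        back[t] = best
        delta = cand[best, np.arange(4)] + log_e[:, obs[t]]
    path = np.zeros(n, dtype=np.int8)
    path[-1] = pref[int(np.argmax(delta[pref]))]
    for t in range(n - 2, -1, -1):
        path[t] = back[t + 1][path[t + 1]]
    return path


def path_log_prob(model: SkewHmmModel, seq: str, path: Sequence[int]) -> float:
    """Joint log-probability of a sequence and a state path (oracle hook)."""
    obs = encode_sequence(seq)
    log_e = model.log_emission_lookup()
    log_a = np.log(np.maximum(model.trans, 1e-300))
    log_pi = np.log(np.maximum(model.pi, 1e-300))
    lp = log_pi[path[0]] + log_e[path[0], obs[0]]
    for t in range(1, len(obs)):
        lp += log_a[path[t - 1], path[t]] + log_e[path[t], obs[t]]
    return float(lp)


@dataclass(frozen=True)
class SkewSegment:
    interval: GenomicInterval
    state: str

    @property
    def is_skew(self) -> bool:
        return self.state != "NONE"


def segments_from_path(path: np.ndarray, chrom: str,
                       offset: int = 0) -> List[SkewSegment]:
    """Run-length encode a state path into segments that partition it.

    NONE segments are retained (flagged non-skew via ``is_skew``).
    """
    segments: List[SkewSegment] = []
    if len(path) == 0:
        return segments
    change = np.flatnonzero(np.diff(path)) + 1
    bounds = np.concatenate(([0], change, [len(path)]))
    for a, b in zip(bounds[:-1], bounds[1:]):
        segments.append(
            SkewSegment(
                GenomicInterval(chrom, offset + int(a), offset + int(b)),
                STATES[int(path[a])],
            )
        )
    return segments


def classify_gene(gene: GeneModel, segments: Sequence[SkewSegment],
                  promoter_halfwidth: int = 2000) -> str:
    """Promoter-anchored skew class: the highest-priority state
    (strong > weak > reverse > none) whose segment overlaps TSS +/-
    halfwidth by >= 1 bp."""
    promoter = gene.promoter(promoter_halfwidth)
    present = set()
    for seg in segments:
        if seg.interval.overlaps(promoter):
            present.add(seg.state.lower())
    if not present:
        raise ValidationError(
            f"gene {gene.gene_id}: no decoded segments overlap its promoter"
        )
    for cls in CLASS_PRIORITY:
        if cls in present:
            return cls
    return "none"


def _oriented_window(gene: GeneModel, genome: Mapping[str, str],
                     start: int, end: int) -> Tuple[str, int, int]:
    """Coding-strand sequence of [start, end) clipped to the chromosome."""
    if gene.chrom not in genome:
        raise ValidationError(f"gene {gene.gene_id}: chromosome {gene.chrom!r} "
                              "absent from genome sequence")
    seq = genome[gene.chrom]
    start = max(0, start)
    end = min(len(seq), end)
    window = seq[start:end]
    if gene.strand == "-":
        window = reverse_complement(window)
    return window, start, end


def classify_genes(genome: Mapping[str, str], genes: Sequence[GeneModel],
                   model: SkewHmmModel, promoter_halfwidth: int = 2000,
                   mode: str = "promoter") -> Dict[str, str]:
    """Skew class per gene, decoding each gene's region on its coding strand.

    mode='promoter' (default) decodes and classifies TSS +/- halfwidth;
    mode='gene' decodes the gene span plus the promoter window and accepts
    skew anywhere in it.
    """
    classes: Dict[str, str] = {}
    for gene in genes:
        if mode == "promoter":
            lo, hi = gene.tss - promoter_halfwidth, gene.tss + promoter_halfwidth + 1
        elif mode == "gene":
            lo = min(gene.tx_start, gene.tss - promoter_halfwidth)
            hi = max(gene.tx_end, gene.tss + promoter_halfwidth + 1)
        else:
            raise ValidationError(f"unknown classification mode {mode!r}")
        window, start, end = _oriented_window(gene, genome, lo, hi)
        path = viterbi_sequence(model, window)
        if gene.strand == "-":
            path = path[::-1].copy()
        segments = segments_from_path(path, gene.chrom, offset=start)
        classes[gene.gene_id] = classify_gene(gene, segments, promoter_halfwidth)
    return classes


def decode_genome(genome: Mapping[str, str],
                  model: SkewHmmModel) -> List[SkewSegment]:
    """Forward-strand decode of every chromosome into skew segments."""
    segments: List[SkewSegment] = []
    for chrom in sorted(genome):
        path = viterbi_sequence(model, genome[chrom])
        segments.extend(segments_from_path(path, chrom))
    return segments


def skew_profile(seq: str, window: int = 100) -> Tuple[np.ndarray, np.ndarray]:
    """Per-window (G-C)/(G+C) and a flag marking windows with G+C = 0
    (value reported as 0 there). Diagnostic used to audit planted skew."""
    if window <= 0:
        raise ValidationError(f"window must be > 0, got {window}")
    obs = encode_sequence(seq)
    n_windows = -(-len(obs) // window)
    values = np.zeros(n_windows)
    flags = np.zeros(n_windows, dtype=bool)
    for i in range(n_windows):
        chunk = obs[i * window:(i + 1) * window]
        g = int(np.sum(chunk == BASES.index("G")))
        c = int(np.sum(chunk == BASES.index("C")))
        if g + c == 0:
            flags[i] = True
        else:
            values[i] = (g - c) / (g + c)
    return values, flags
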