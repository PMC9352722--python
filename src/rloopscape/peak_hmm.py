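"""Two-state HMM segmentation of binned DRIP-seq coverage into R-loop peaks.

Coverage is binned, log1p-transformed, and modeled with a hidden Markov
chain whose two states ("background", "enriched") emit Gaussian values.
Parameters are fitted by Baum-Welch (EM); the peak track is the Viterbi
path post-processed by run merging and a minimum-length filter.

State 0 is always background and state 1 enriched (enforced by relabeling
after every fit so that the enriched emission mean is the larger one).
Viterbi ties break toward background, which makes peak calls conservative.
"""
from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .core import ChromSizes, CoverageTrack, GenomicInterval, PeakSet, ValidationError

_LOG_EPS = 1e-300
_SD_FLOOR = 1e-3


@dataclass
class BinnedTrack:
    """Mean coverage per fixed-width bin, one array per chromosome.

    The trailing partial bin is included; its mean is still taken over the
    full bin width (missing bp count as zero coverage), which slightly
    deflates the last bin rather than inflating it.
    """

    bin_size: int
    bins: Dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def chroms(self) -> List[str]:
        return sorted(self.bins)

    def concat(self) -> np.ndarray:
        return np.concatenate([self.bins[c] for c in self.chroms]) if self.bins \
            else np.empty(0)


@dataclass
class PeakHmmModel:
    """Two-state Gaussian HMM on log1p(binned coverage)."""

    pi: np.ndarray          # initial state probabilities, shape (2,)
    trans: np.ndarray       # transition matrix, shape (2, 2), rows sum to 1
    means: np.ndarray       # emission means, shape (2,)
    sds: np.ndarray         # emission sds, shape (2,), > 0

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.sds = np.asarray(self.sds, dtype=float)
        if self.pi.shape != (2,) or self.trans.shape != (2, 2):
            raise ValidationError("model must have exactly 2 states")
        if np.any(self.pi < 0) or not math.isclose(self.pi.sum(), 1.0, abs_tol=1e-8):
            raise ValidationError("pi must be a probability vector")
        if np.any(self.trans < 0) or not np.allclose(self.trans.sum(axis=1), 1.0):
            raise ValidationError("transition rows must sum to 1")
        if np.any(self.sds <= 0):
            raise ValidationError("emission sds must be > 0")

    def relabeled(self) -> "PeakHmmModel":
        """Ensure state 1 has the larger emission mean."""
        if self.means[1] >= self.means[0]:
            return self
        perm = [1, 0]
        return PeakHmmModel(
            self.pi[perm], self.trans[np.ix_(perm, perm)],
            self.means[perm], self.sds[perm],
        )

    def log_emission(self, x: np.ndarray) -> np.ndarray:
        """Log density of each observation under each state; shape (n, 2)."""
        x = np.asarray(x, dtype=float)[:, None]
        return (
            -0.5 * ((x - self.means) / self.sds) ** 2
            - np.log(self.sds)
            - 0.5 * math.log(2 * math.pi)
        )

    def digest(self) -> str:
        h = hashlib.sha256()
        for a in (self.pi, self.trans, self.means, self.sds):
            h.update(np.ascontiguousarray(a).tobytes())
        return h.hexdigest()[:12]


def bin_coverage(track: CoverageTrack, bin_size: int,
                 chrom_sizes: ChromSizes) -> BinnedTrack:
    """Mean coverage per bin over every chromosome in chrom_sizes."""
    if bin_size <= 0:
        raise ValidationError(f"bin_size must be > 0, got {bin_size}")
    out = BinnedTrack(bin_size=bin_size)
    for chrom in sorted(chrom_sizes):
        length = chrom_sizes[chrom]
        n_bins = -(-length // bin_size)
        sums = np.zeros(n_bins, dtype=float)
        starts, ends, values = track.runs(chrom)
        for s, e, v in zip(starts, ends, values):
            e = min(int(e), length)
            s = int(s)
            if s >= e:
                continue
            b0, b1 = s // bin_size, (e - 1) // bin_size
            if b0 == b1:
                sums[b0] += v * (e - s)
            else:
                sums[b0] += v * ((b0 + 1) * bin_size - s)
                sums[b1] += v * (e - b1 * bin_size)
                if b1 > b0 + 1:
                    sums[b0 + 1:b1] += v * bin_size
        out.bins[chrom] = sums / bin_size
    return out


def pool_tracks(tracks: Sequence[CoverageTrack]) -> CoverageTrack:
    """Per-bp sum of coverage tracks (combined replicate signal)."""
    if not tracks:
        raise ValidationError("no tracks to pool")
    if len(tracks) == 1:
        return tracks[0]
    universe = set(tracks[0].chroms)
    for t in tracks[1:]:
        if set(t.chroms) - universe and universe:
            extra = set(t.chroms) - universe
            raise ValidationError(f"chromosome mismatch across tracks: {sorted(extra)}")
    pooled = CoverageTrack()
    for chrom in sorted(universe):
        # breakpoints of the union step function
        edges = set()
        for t in tracks:
            starts, ends, _ = t.runs(chrom)
            edges.update(starts.tolist())
            edges.update(ends.tolist())
        edges = sorted(edges)
        runs = []
        for a, b in zip(edges[:-1], edges[1:]):
            total = 0.0
            for t in tracks:
                starts, ends, values = t.runs(chrom)
                idx = np.searchsorted(starts, a, side="right") - 1
                if idx >= 0 and ends[idx] > a:
                    total += values[idx]
            if total > 0:
                runs.append((a, b, total))
        # merge adjacent equal-valued runs
        merged = []
        for s, e, v in runs:
            if merged and merged[-1][1] == s and merged[-1][2] == v:
                merged[-1] = (merged[-1][0], e, v)
            else:
                merged.append((s, e, v))
        pooled.set_chrom(chrom, merged)
    return pooled


def init_model_from_quantiles(binned: BinnedTrack) -> PeakHmmModel:
    """Moment-based initialization: background from bins below the median,
    enriched from the top decile, on the log1p scale."""
    x = np.log1p(binned.concat())
    if x.size == 0 or np.all(x == x[0]):
        raise ValidationError(
            "degenerate input: all bins equal; use fixed-parameter decoding"
        )
    lo = x[x <= np.median(x)]
    hi = x[x >= np.quantile(x, 0.9)]
    means = np.array([lo.mean(), hi.mean()])
    sds = np.maximum([lo.std(), hi.std()], _SD_FLOOR)
    if means[1] <= means[0]:
        means[1] = means[0] + 10 * _SD_FLOOR
    return PeakHmmModel(
        pi=np.array([0.9, 0.1]),
        trans=np.array([[0.99, 0.01], [0.05, 0.95]]),
        means=means, sds=sds,
    )


def _forward_backward(model: PeakHmmModel, x: np.ndarray):
    """Scaled forward-backward. Returns (gamma, xi_sum, log_likelihood)."""
    n = len(x)
    b = np.exp(model.log_emission(x))  # (n, 2)
    alpha = np.zeros((n, 2))
    beta = np.zeros((n, 2))
    scale = np.zeros(n)
    alpha[0] = model.pi * b[0]
    scale[0] = alpha[0].sum() + _LOG_EPS
    alpha[0] /= scale[0]
    for t in range(1, n):
        alpha[t] = (alpha[t - 1] @ model.trans) * b[t]
        scale[t] = alpha[t].sum() + _LOG_EPS
        alpha[t] /= scale[t]
    beta[-1] = 1.0
    for t in range(n - 2, -1, -1):
        beta[t] = model.trans @ (b[t + 1] * beta[t + 1]) / scale[t + 1]
    gamma = alpha * beta
    gamma /= gamma.sum(axis=1, keepdims=True) + _LOG_EPS
    xi_sum = np.zeros((2, 2))
    for t in range(n - 1):
        xi = (alpha[t][:, None] * model.trans) * (b[t + 1] * beta[t + 1])[None, :]
        xi /= xi.sum() + _LOG_EPS
        xi_sum += xi
    return gamma, xi_sum, float(np.sum(np.log(scale)))


def fit_hmm(binned: BinnedTrack, init: Optional[PeakHmmModel] = None,
            max_iter: int = 200, tol: float = 1e-4):
    """Baum-Welch on log1p(binned coverage) across all chromosomes.

    Chromosomes are independent observation sequences sharing one parameter
    set. Returns (model, log_likelihood_trace); the trace is non-decreasing
    up to floating-point noise (EM guarantee).
    """
    seqs = [np.log1p(binned.bins[c]) for c in binned.chroms]
    allx = np.concatenate(seqs) if seqs else np.empty(0)
    if allx.size == 0 or np.all(allx == allx[0]):
        raise ValidationError(
            "degenerate input: all bins equal; use fixed-parameter decoding"
        )
    model = (init or init_model_from_quantiles(binned)).relabeled()
    trace: List[float] = []
    for _ in range(max_iter):
        pi_acc = np.zeros(2)
        xi_acc = np.zeros((2, 2))
        gam_acc = np.zeros(2)
        mean_acc = np.zeros(2)
        var_acc = np.zeros(2)
        ll = 0.0
        gammas = []
        for x in seqs:
            gamma, xi_sum, seq_ll = _forward_backward(model, x)
            ll += seq_ll
            pi_acc += gamma[0]
            xi_acc += xi_sum
            gam_acc += gamma.sum(axis=0)
            mean_acc += gamma.T @ x
            gammas.append(gamma)
        trace.append(ll)
        new_means = mean_acc / (gam_acc + _LOG_EPS)
        for x, gamma in zip(seqs, gammas):
            var_acc += (gamma * (x[:, None] - new_means) ** 2).sum(axis=0)
        new_sds = np.maximum(np.sqrt(var_acc / (gam_acc + _LOG_EPS)), _SD_FLOOR)
        row_sums = xi_acc.sum(axis=1, keepdims=True)
        new_trans = np.where(row_sums > 0, xi_acc / (row_sums + _LOG_EPS),
                             np.eye(2))
        new_trans /= new_trans.sum(axis=1, keepdims=True)
        model = PeakHmmModel(
            pi=pi_acc / pi_acc.sum(), trans=new_trans,
            means=new_means, sds=new_sds,
        ).relabeled()
        if len(trace) >= 2 and abs(trace[-1] - trace[-2]) < tol:
            break
    return model, trace


def viterbi(model: PeakHmmModel, binned: BinnedTrack) -> Dict[str, np.ndarray]:
    """Most probable state path per chromosome; ties break toward state 0."""
    paths: Dict[str, np.ndarray] = {}
    log_pi = np.log(model.pi + _LOG_EPS)
    log_a = np.log(model.trans + _LOG_EPS)
    for chrom in binned.chroms:
        x = np.log1p(binned.bins[chrom])
        n = len(x)
        if n == 0:
            paths[chrom] = np.empty(0, dtype=np.int8)
            continue
        log_b = model.log_emission(x)
        delta = log_pi + log_b[0]
        back = np.zeros((n, 2), dtype=np.int8)
        for t in range(1, n):
            cand = delta[:, None] + log_a      # cand[i, j]: from i to j
            back[t] = np.argmax(cand, axis=0)  # ties -> lower index (state 0)
            delta = cand[back[t], [0, 1]] + log_b[t]
        path = np.zeros(n, dtype=np.int8)
        path[-1] = int(np.argmax(delta))       # tie -> state 0
        for t in range(n - 2, -1, -1):
            path[t] = back[t + 1][path[t + 1]]
        paths[chrom] = path
    return paths


def viterbi_log_prob(model: PeakHmmModel, x: np.ndarray,
                     path: np.ndarray) -> float:
    """Joint log-probability of one observation sequence and state path."""
    log_pi = np.log(model.pi + _LOG_EPS)
    log_a = np.log(model.trans + _LOG_EPS)
    log_b = model.log_emission(np.log1p(np.asarray(x, dtype=float)))
    lp = log_pi[path[0]] + log_b[0, path[0]]
    for t in range(1, len(path)):
        lp += log_a[path[t - 1], path[t]] + log_b[t, path[t]]
    return float(lp)


def call_peaks(paths: Dict[str, np.ndarray], bin_size: int,
               min_bins: int = 3, merge_gap_bins: int = 1,
               provenance: Optional[dict] = None) -> PeakSet:
    """Convert state paths to peak intervals.

    Maximal runs of the enriched state become intervals; runs separated by
    <= merge_gap_bins background bins are merged first, then runs shorter
    than min_bins are dropped.
    """
    peaks: List[GenomicInterval] = []
    for chrom in sorted(paths):
        path = np.asarray(paths[chrom])
        if path.size == 0:
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([0], path, [0]))))
        runs = [(int(edges[i]), int(edges[i + 1])) for i in range(0, len(edges), 2)]
        merged: List[List[int]] = []
        for s, e in runs:
            if merged and s - merged[-1][1] <= merge_gap_bins:
                merged[-1][1] = e
            else:
                merged.append([s, e])
        for s, e in merged:
            if e - s >= min_bins:
                peaks.append(GenomicInterval(chrom, s * bin_size, e * bin_size))
    return PeakSet(peaks, dict(provenance or {}))


def call_peaks_from_tracks(
    tracks: Sequence[CoverageTrack], chrom_sizes: ChromSizes,
    bin_size: int = 500, min_bins: int = 3, merge_gap_bins: int = 1,
    mode: str = "pooled", min_support: int = 1,
    max_iter: int = 200, tol: float = 1e-4,
) -> PeakSet:
    """End-to-end peak calling.

    mode='pooled' (default) sums replicate tracks and calls once — the
    analysis path matching combined-signal peak calling. mode='intersect-k'
    calls per replicate and keeps bp supported by >= min_support replicates.
    """
    if mode == "pooled":
        pooled = pool_tracks(list(tracks))
        binned = bin_coverage(pooled, bin_size, chrom_sizes)
        model, trace = fit_hmm(binned, max_iter=max_iter, tol=tol)
        paths = viterbi(model, binned)
        return call_peaks(
            paths, bin_size, min_bins, merge_gap_bins,
            provenance={"mode": "pooled", "n_tracks": len(tracks),
                        "bin_size": bin_size, "model_hash": model.digest(),
                        "n_iter": len(trace)},
        )
    if mode != "intersect-k":
        raise ValidationError(f"unknown mode {mode!r}")
    support: Dict[str, np.ndarray] = {}
    for track in tracks:
        binned = bin_coverage(track, bin_size, chrom_sizes)
        model, _ = fit_hmm(binned, max_iter=max_iter, tol=tol)
        for chrom, path in viterbi(model, binned).items():
            if chrom not in support:
                support[chrom] = np.zeros(len(path), dtype=int)
            support[chrom] += path
    paths = {c: (s >= min_support).astype(np.int8) for c, s in support.items()}
    return call_peaks(
        paths, bin_size, min_bins, merge_gap_bins,
        provenance={"mode": "intersect-k", "min_support": min_support,
                    "n_tracks": len(tracks), "bin_size": bin_size},
    )
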