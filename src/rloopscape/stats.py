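"""Statistical tests and gene-set enrichment.

Small samples get exact treatment: the Mann-Whitney U test enumerates all
label assignments when the combined sample size is at most 12 and there
are no ties, switching to the tie- and continuity-corrected normal
approximation otherwise. Enrichment follows the cumulative-hypergeometric
scheme with Benjamini-Hochberg q-values, an enrichment-factor filter, and
kappa-similarity clustering of surviving terms (average linkage; sub-trees
with similarity above the threshold form a cluster represented by their
most significant term).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy

from .core import ValidationError


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: Tuple[int, ...]
    exact: bool = False
    extra: Dict[str, float] = field(default_factory=dict)


def mann_whitney_u(x: Sequence[float], y: Sequence[float],
                   exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U test.

    U is the number of (x, y) pairs with x > y (ties count half); the
    complement U' satisfies U + U' = |x||y|. Exact p by enumeration of all
    C(n, n1) labelings when |x| + |y| <= exact_max_n and the data are
    tie-free; otherwise the normal approximation with tie correction and
    continuity correction.
    """
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    if not x or not y:
        raise ValidationError("both samples must be non-empty")
    n1, n2 = len(x), len(y)
    u = 0.0
    for xi in x:
        for yj in y:
            u += 1.0 if xi > yj else (0.5 if xi == yj else 0.0)
    has_ties = len(set(x + y)) < n1 + n2
    if n1 + n2 <= exact_max_n and not has_ties:
        pooled = x + y
        total = 0
        le = ge = 0
        u_lo = min(u, n1 * n2 - u)
        u_hi = n1 * n2 - u_lo
        for idx in combinations(range(n1 + n2), n1):
            xs = set(idx)
            uu = sum(
                1 for i in idx for j in range(n1 + n2)
                if j not in xs and pooled[i] > pooled[j]
            )
            total += 1
            if uu <= u_lo:
                le += 1
            if uu >= u_hi:
                ge += 1
        p = min(1.0, (le + ge) / total)
        return TestResult(u, p, "mann-whitney-exact", (n1, n2), exact=True)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return TestResult(u, float(res.pvalue), "mann-whitney-asymptotic",
                      (n1, n2), exact=False)


def one_way_anova(groups: Sequence[Sequence[float]]) -> TestResult:
    """One-way ANOVA F test across >= 2 groups of >= 2 values each."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 groups with >= 2 values each")
    allv = np.concatenate(groups)
    if np.all(allv == allv[0]) or all(np.all(g == g[0]) for g in groups):
        raise ValidationError("degenerate input: no within-group variance")
    f, p = sps.f_oneway(*groups)
    return TestResult(float(f), float(p), "one-way-anova",
                      tuple(len(g) for g in groups))


def tukey_hsd(groups: Sequence[Sequence[float]]) -> List[TestResult]:
    """Studentized-range (Tukey HSD) adjusted pairwise comparisons.

    Each result also carries the unadjusted pooled-variance t-test p for
    the same pair in ``extra['p_unadjusted']``; the adjusted p is never
    smaller.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    one_way_anova(groups)  # validates
    res = sps.tukey_hsd(*groups)
    k = len(groups)
    n_tot = sum(len(g) for g in groups)
    df = n_tot - k
    mse = sum(((g - g.mean()) ** 2).sum() for g in groups) / df
    out: List[TestResult] = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = groups[i].mean() - groups[j].mean()
            se = np.sqrt(mse * (1 / len(groups[i]) + 1 / len(groups[j])))
            t = diff / se if se > 0 else 0.0
            p_unadj = 2 * sps.t.sf(abs(t), df)
            out.append(TestResult(
                float(res.statistic[i, j]), float(res.pvalue[i, j]),
                "tukey-hsd", (len(groups[i]), len(groups[j])),
                extra={"pair": (i, j), "p_unadjusted": float(p_unadj)},
            ))
    return out


@dataclass
class EnrichmentRecord:
    term: str
    k: int                 # overlap count
    n: int                 # gene-list size
    K: int                 # term size
    N: int                 # universe size
    p: float               # cumulative hypergeometric P(X >= k)
    factor: float          # (k/n) / (K/N)
    members: Set[str] = field(default_factory=set)   # overlap genes
    q: float = float("nan")
    cluster: int = -1
    representative: str = ""


def hypergeometric_enrichment(gene_list: Iterable[str],
                              term_genes: Iterable[str],
                              universe: Iterable[str],
                              term: str = "") -> EnrichmentRecord:
    """Over-representation of a term in a gene list: upper hypergeometric
    tail P(X >= k) and enrichment factor (k/n)/(K/N)."""
    universe = set(universe)
    gene_list = set(gene_list)
    term_genes = set(term_genes)
    if not gene_list <= universe:
        raise ValidationError("gene list must be a subset of the universe")
    if not term_genes <= universe:
        raise ValidationError("term genes must be a subset of the universe")
    overlap = gene_list & term_genes
    k, n, K, N = len(overlap), len(gene_list), len(term_genes), len(universe)
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    factor = (k / n) / (K / N) if n and K else 0.0
    return EnrichmentRecord(term, k, n, K, N, p, factor, overlap)


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, mapped back to input order."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def cohen_kappa(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's kappa between two binary membership vectors."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    n = a.size
    po = np.mean(a == b)
    pa, pb = a.mean(), b.mean()
    pe = pa * pb + (1 - pa) * (1 - pb)
    if np.isclose(pe, 1.0):
        return 1.0 if po == 1.0 else 0.0
    return float((po - pe) / (1 - pe))


def filter_and_cluster_terms(
    records: Sequence[EnrichmentRecord],
    kappa_threshold: float = 0.3,
    p_max: float = 0.01,
    min_count: int = 3,
    min_factor: float = 1.5,
) -> List[EnrichmentRecord]:
    """Filter terms (p < p_max, count >= min_count, factor > min_factor;
    the inequalities on p and factor are strict) and cluster survivors by
    kappa similarity of their overlap-gene membership vectors.

    Average-linkage hierarchical clustering on distance 1 - kappa, cut so
    that sub-trees with similarity > kappa_threshold stay together. Each
    cluster is labeled by its smallest-p term.
    """
    surviving = [
        r for r in records
        if r.p < p_max and r.k >= min_count and r.factor > min_factor
    ]
    if not surviving:
        return []
    qs = bh_fdr([r.p for r in surviving])
    for r, q in zip(surviving, qs):
        r.q = float(q)
    gene_union = sorted(set().union(*(r.members for r in surviving)))
    gidx = {g: i for i, g in enumerate(gene_union)}
    vecs = np.zeros((len(surviving), len(gene_union)), dtype=bool)
    for i, r in enumerate(surviving):
        for g in r.members:
            vecs[i, gidx[g]] = True
    if len(surviving) == 1:
        labels = np.array([1])
    else:
        m = len(surviving)
        dist = np.zeros(m * (m - 1) // 2)
        idx = 0
        for i in range(m):
            for j in range(i + 1, m):
                dist[idx] = 1.0 - cohen_kappa(vecs[i], vecs[j])
                idx += 1
        link = hierarchy.linkage(dist, method="average")
        labels = hierarchy.fcluster(
            link, t=1.0 - kappa_threshold - 1e-9, criterion="distance"
        )
    reps: Dict[int, EnrichmentRecord] = {}
    for r, lab in zip(surviving, labels):
        r.cluster = int(lab)
        if lab not in reps or (r.p, r.term) < (reps[lab].p, reps[lab].term):
            reps[lab] = r
    for r in surviving:
        r.representative = reps[r.cluster].term
    return sorted(surviving, key=lambda r: (r.cluster, r.p, r.term))


def read_gmt(path: str) -> Dict[str, Set[str]]:
    """Read gene sets from GMT (term <TAB> description <TAB> genes...)."""
    sets: Dict[str, Set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line needs term, description, genes"
                )
            sets[fields[0]] = set(f for f in fields[2:] if f)
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path: str) -> None:
    with open(path, "w") as fh:
        for term in sorted(sets):
            genes = "\t".join(sorted(sets[term]))
            fh.write(f"{term}\tna\t{genes}\n")
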