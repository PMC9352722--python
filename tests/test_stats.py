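"""Exact small-sample tests, enrichment arithmetic, BH and kappa clustering."""
import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from rloopscape.core import ValidationError
from rloopscape.stats import (
    EnrichmentRecord,
    bh_fdr,
    cohen_kappa,
    filter_and_cluster_terms,
    hypergeometric_enrichment,
    mann_whitney_u,
    one_way_anova,
    read_gmt,
    tukey_hsd,
    write_gmt,
)


def enumeration_p(x, y):
    """Independent oracle: exact two-sided Mann-Whitney p by enumerating
    every C(n1+n2, n1) group labeling of the pooled values."""
    pooled = list(x) + list(y)
    n1, n2 = len(x), len(y)
    u_obs = sum(1 for xi in x for yj in y if xi > yj)
    u_lo = min(u_obs, n1 * n2 - u_obs)
    u_hi = n1 * n2 - u_lo
    count = total = 0
    for idx in itertools.combinations(range(n1 + n2), n1):
        xs = set(idx)
        u = sum(1 for i in idx for j in range(n1 + n2)
                if j not in xs and pooled[i] > pooled[j])
        total += 1
        if u <= u_lo or u >= u_hi:
            count += 1
    return min(1.0, count / total)


class TestMannWhitney:
    def test_worked_example(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0
        assert res.exact
        assert res.p_value == pytest.approx(2 / 6)

    def test_u_symmetry_on_identical_samples(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.statistic == 3 * 3 / 2

    def test_u_plus_uprime_invariant(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=6), rng.normal(size=5)
        u_x = mann_whitney_u(x, y).statistic
        u_y = mann_whitney_u(y, x).statistic
        assert u_x + u_y == len(x) * len(y)

    def test_exact_equals_enumeration_all_small_sizes(self):
        """Exhaustive agreement with the enumeration oracle for every
        (n1, n2) with n1 + n2 <= 12."""
        rng = np.random.default_rng(1)
        for n1 in range(1, 12):
            for n2 in range(1, 13 - n1):
                x = list(rng.permutation(100)[:n1].astype(float))
                y = list(rng.permutation(1000)[:n2].astype(float) + 0.5)
                res = mann_whitney_u(x, y)
                assert res.exact
                assert res.p_value == pytest.approx(enumeration_p(x, y))

    def test_asymptotic_close_to_exact(self):
        rng = np.random.default_rng(2)
        x = list(rng.normal(0, 1, 8))
        y = list(rng.normal(0.5, 1, 8))
        approx = mann_whitney_u(x, y, exact_max_n=0)
        assert not approx.exact
        assert abs(approx.p_value - enumeration_p(x, y)) < 0.02

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])


class TestAnova:
    def test_identical_groups_f_zero(self):
        res = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_f(self):
        """Sums-of-squares oracle for {1,2,3} vs {4,5,6}: MSB = 13.5,
        MSW = 1, F = 13.5."""
        res = one_way_anova([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(13.5)
        assert res.p_value == pytest.approx(float(sps.f.sf(13.5, 1, 4)))

    def test_label_permutation_invariance(self):
        g = [[1.0, 2.5, 3.0], [2.0, 4.0, 5.5], [0.5, 1.5, 2.0]]
        f1 = one_way_anova(g).statistic
        f2 = one_way_anova([g[2], g[0], g[1]]).statistic
        assert f1 == pytest.approx(f2)

    def test_degenerate_variance_rejected(self):
        with pytest.raises(ValidationError):
            one_way_anova([[1, 1], [1, 1]])


class TestTukey:
    def test_two_groups_studentized_range_relation(self):
        """With k = 2, the Tukey q statistic equals t * sqrt(2) and the
        adjusted p equals the pooled-variance t-test p."""
        a, b = [1.0, 2.0, 3.0, 2.5], [4.0, 5.0, 4.5, 6.0]
        (res,) = tukey_hsd([a, b])
        t = sps.ttest_ind(a, b).statistic
        # q distribution with k=2: p identical to two-sided t
        assert res.p_value == pytest.approx(res.extra["p_unadjusted"], abs=1e-6)
        assert abs(res.statistic) == pytest.approx(
            abs(np.mean(a) - np.mean(b)))

    def test_identical_groups_p_near_one(self):
        results = tukey_hsd([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert all(r.p_value > 0.99 for r in results)

    def test_adjusted_at_least_unadjusted(self):
        rng = np.random.default_rng(3)
        groups = [list(rng.normal(m, 1, 6)) for m in (0, 0.5, 1.0, 0.2)]
        for r in tukey_hsd(groups):
            assert r.p_value >= r.extra["p_unadjusted"] - 1e-9


class TestHypergeometric:
    def test_combinatorial_oracle(self):
        """N=20, K=5, n=4, k=4: p = C(5,4)/C(20,4) = 5/4845."""
        universe = [f"g{i}" for i in range(20)]
        term = universe[:5]
        gene_list = universe[:4]
        rec = hypergeometric_enrichment(gene_list, term, universe)
        assert rec.k == 4
        assert rec.p == pytest.approx(5 / 4845)

    def test_zero_overlap_p_one(self):
        universe = [f"g{i}" for i in range(20)]
        rec = hypergeometric_enrichment(universe[:4], universe[10:15], universe)
        assert rec.k == 0
        assert rec.p == pytest.approx(1.0)

    def test_neutral_factor(self):
        universe = [f"g{i}" for i in range(20)]
        # k/n = 2/4 equals K/N = 10/20 -> factor 1
        rec = hypergeometric_enrichment(
            universe[:2] + universe[10:12], universe[:10], universe)
        assert rec.factor == pytest.approx(1.0)

    def test_list_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            hypergeometric_enrichment(["zzz"], ["g1"], ["g1", "g2"])

    def test_tail_conservation(self):
        # P(X >= 0) == 1 and pmf sums to 1 across k
        N, K, n = 30, 8, 10
        total = sum(float(sps.hypergeom.pmf(k, N, K, n)) for k in range(n + 1))
        assert total == pytest.approx(1.0)


class TestBH:
    def test_single_p(self):
        assert bh_fdr([0.04]).tolist() == [0.04]

    def test_step_up_hand_oracle(self):
        """[0.01, 0.02, 0.03] -> [0.03, 0.03, 0.03] by the step-up rule."""
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_equal(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.5])

    def test_matches_reference_implementation(self):
        sm = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(4)
        p = rng.random(50)
        _, q_ref, _, _ = sm.multipletests(p, method="fdr_bh")
        assert np.allclose(bh_fdr(p), q_ref)

    def test_rejection_equivalence(self):
        """Thresholding q <= alpha rejects exactly the step-up set."""
        rng = np.random.default_rng(5)
        p = rng.random(40) ** 2
        alpha = 0.1
        q = bh_fdr(p)
        order = np.argsort(p)
        m = len(p)
        kmax = 0
        for rank, idx in enumerate(order, start=1):
            if p[idx] <= alpha * rank / m:
                kmax = rank
        stepup_rejected = set(order[:kmax])
        assert set(np.flatnonzero(q <= alpha)) == stepup_rejected


class TestKappaClustering:
    def rec(self, term, members, p, n=20, N=200):
        k = len(members)
        return EnrichmentRecord(term, k, n, max(k, 5), N, p,
                                factor=3.0, members=set(members))

    def test_identical_terms_cluster_together(self):
        genes = {f"g{i}" for i in range(6)}
        recs = [self.rec("A", genes, 1e-5), self.rec("B", genes, 1e-4)]
        out = filter_and_cluster_terms(recs)
        assert out[0].cluster == out[1].cluster
        assert all(r.representative == "A" for r in out)

    def test_disjoint_terms_split(self):
        a = {f"a{i}" for i in range(6)}
        b = {f"b{i}" for i in range(6)}
        recs = [self.rec("A", a, 1e-5), self.rec("B", b, 1e-4)]
        out = filter_and_cluster_terms(recs)
        assert out[0].cluster != out[1].cluster
        # kappa for disjoint equal-size sets is <= 0 by the 2x2 oracle
        va = np.array([1] * 6 + [0] * 6, bool)
        vb = np.array([0] * 6 + [1] * 6, bool)
        assert cohen_kappa(va, vb) <= 0

    def test_filters_apply_strictly(self):
        recs = [
            self.rec("low_count", {"g1", "g2"}, 1e-6),        # k=2 < 3
            self.rec("weak_p", {"g1", "g2", "g3"}, 0.05),     # p >= 0.01
            self.rec("ok", {"g1", "g2", "g3"}, 1e-4),
        ]
        recs[1].p = 0.01   # boundary: strict inequality removes it
        out = filter_and_cluster_terms(recs)
        assert [r.term for r in out] == ["ok"]

    def test_factor_filter(self):
        r = self.rec("flat", {"g1", "g2", "g3"}, 1e-4)
        r.factor = 1.5     # boundary: strict > removes it
        assert filter_and_cluster_terms([r]) == []

    def test_q_values_assigned(self):
        recs = [self.rec(f"T{i}", {f"g{j}" for j in range(i, i + 4)}, 1e-4)
                for i in range(3)]
        out = filter_and_cluster_terms(recs)
        assert all(np.isfinite(r.q) and r.q >= r.p for r in out)


def test_gmt_round_trip(tmp_path):
    sets = {"TERM_A": {"g1", "g2"}, "TERM_B": {"g3"}}
    p = tmp_path / "sets.gmt"
    write_gmt(sets, str(p))
    assert read_gmt(str(p)) == sets
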