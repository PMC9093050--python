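"""Permutation machinery: attainable floors, calibration, and NBS."""

import itertools

import numpy as np
import pytest
from scipy import stats

from zolpiscope import perm_stats as ps


class TestCountPermutations:
    @pytest.mark.parametrize("design,n,expected", [
        ("within", 4, 16),
        ("within", 8, 256),
        ("between", (4, 4), 70),
        ("correlation", 5, 120),
    ])
    def test_counts(self, design, n, expected):
        assert ps.count_permutations(design, n) == expected


class TestScalarPermTest:
    def test_within_floor_n4(self):
        """Exhaustive sign-flip enumeration: the minimum attainable
        two-sided p for 4 paired differences is 1/17 = 0.059."""
        res = ps.perm_test_scalar(np.array([1.0, 1.1, 0.9, 1.05]),
                                  design="within")
        assert res.exhaustive
        assert res.n_perm == 16
        assert res.p == pytest.approx(1.0 / 17.0)

    def test_within_floor_n8(self):
        d = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 1.2, 1.02, 0.98])
        res = ps.perm_test_scalar(d, design="within")
        assert res.n_perm == 256
        assert res.p == pytest.approx(1.0 / 257.0)
        assert round(res.p, 3) == 0.004

    def test_between_floor_4v4(self):
        res = ps.perm_test_scalar(np.array([1.0, 1.1, 0.9, 1.05]),
                                  np.array([5.0, 5.1, 4.9, 5.05]),
                                  design="between")
        assert res.n_perm == 70
        assert res.p == pytest.approx(1.0 / 71.0)
        assert round(res.p, 3) == 0.014

    def test_exhaustive_matches_manual_enumeration(self, rng):
        d = rng.standard_normal(5)
        res = ps.perm_test_scalar(d, design="within")
        t_obs = d.mean() / (d.std(ddof=1) / np.sqrt(5))
        count = 0
        for signs in itertools.product((1.0, -1.0), repeat=5):
            x = d * np.array(signs)
            t = x.mean() / (x.std(ddof=1) / np.sqrt(5))
            if abs(t) > abs(t_obs):
                count += 1
        assert res.p == pytest.approx((count + 1) / 33.0)

    def test_random_mode_floor_and_agreement(self, rng):
        """Sampled mode keeps the add-one floor and approximates the
        exhaustive p."""
        d = rng.standard_normal(14) + 1.5
        exact = ps.perm_test_scalar(d, design="within", max_perm=2 ** 14)
        sampled = ps.perm_test_scalar(d, design="within", max_perm=2000, seed=1)
        assert not sampled.exhaustive
        assert sampled.n_perm == 2000
        assert sampled.p >= 1.0 / 2001.0
        assert sampled.p == pytest.approx(exact.p, abs=0.02)

    def test_degenerate_variance_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            res = ps.perm_test_scalar(np.zeros(4), design="within")
        assert res.p == 1.0

    def test_type_one_error_calibrated(self):
        """Null simulations: rejection rate at alpha=0.05 stays within the
        binomial envelope around 0.05 (200 replicates)."""
        rng = np.random.default_rng(7)
        rejections = 0
        for _ in range(200):
            d = rng.standard_normal(8)
            if ps.perm_test_scalar(d, design="within", seed=rng).p < 0.05:
                rejections += 1
        # Binomial(200, 0.05): central 99.9% within [1, 21]
        assert 1 <= rejections <= 21


class TestPermCorr:
    def test_monotone_gives_floor(self):
        res = ps.perm_corr(np.arange(8.0), np.arange(8.0) ** 2)
        assert res.statistic == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0 / (res.n_perm + 1))

    def test_n3_exhaustive_matches_hand_count(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([10.0, 30.0, 20.0])
        res = ps.perm_corr(x, y)
        assert res.exhaustive and res.n_perm == 6
        # observed rho = 0.5; orderings of y-ranks give rho values
        # {1, .5, .5, -.5, -.5, -1}: two strictly exceed |0.5|
        assert res.statistic == pytest.approx(0.5)
        assert res.p == pytest.approx((2 + 1) / 7.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ps.perm_corr(np.ones(5), np.arange(5.0))

    def test_type_one_error_calibrated(self):
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(200):
            x = rng.standard_normal(10)
            y = rng.standard_normal(10)
            if ps.perm_corr(x, y, max_perm=500, seed=rng).p < 0.05:
                rejections += 1
        assert 1 <= rejections <= 21


class TestExactEdgeDistributions:
    def test_signed_rank_matches_scipy_exact(self, rng):
        """Edge-wise exact signed-rank p at n=8 equals scipy's exact mode."""
        _s, cdf, sf = ps._signed_rank_dist(8)
        for _ in range(50):
            d = rng.standard_normal(8)
            w = stats.rankdata(np.abs(d))[d > 0].sum()
            mine = ps._two_sided_from_dist(np.array([w]), cdf, sf)[0]
            ref = stats.wilcoxon(d, method="exact").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)

    def test_rank_sum_matches_scipy_exact(self, rng):
        _s, cdf, sf = ps._rank_sum_dist(8, 8)
        for _ in range(50):
            a, b = rng.standard_normal(8), rng.standard_normal(8)
            r1 = stats.rankdata(np.concatenate([a, b]))[:8].sum()
            mine = ps._two_sided_from_dist(np.array([r1]), cdf, sf)[0]
            ref = stats.mannwhitneyu(a, b, method="exact",
                                     alternative="two-sided").pvalue
            assert mine == pytest.approx(ref, abs=1e-12)


def _paired_stacks(rng, n_sub, n_ch, strong_edges=(), shift=0.0, noise=0.02):
    """Symmetric connectivity stacks; strong_edges get a consistent
    condition difference of ``shift``."""
    base = rng.uniform(0.2, 0.6, size=(n_ch, n_ch))
    base = 0.5 * (base + base.T)
    np.fill_diagonal(base, 1.0)
    A = np.empty((n_sub, n_ch, n_ch))
    B = np.empty((n_sub, n_ch, n_ch))
    for s in range(n_sub):
        na = rng.normal(0, noise, size=(n_ch, n_ch))
        nb = rng.normal(0, noise, size=(n_ch, n_ch))
        a = base + 0.5 * (na + na.T)
        b = base + 0.5 * (nb + nb.T)
        for i, j in strong_edges:
            a[i, j] += shift
            a[j, i] += shift
        np.fill_diagonal(a, 1.0)
        np.fill_diagonal(b, 1.0)
        A[s], B[s] = a, b
    return A, B


class TestNbs:
    def test_component_extraction_matches_networkx(self, rng):
        """Observed components equal networkx's connected components on
        the same supra-threshold graph."""
        import networkx as nx
        strong = [(0, 1), (1, 2), (3, 4)]
        A, B = _paired_stacks(rng, 8, 6, strong, shift=0.3)
        comps = ps.nbs_test(A, B, design="within", n_perm=500, seed=0)
        pos = [c for c in comps if c.sign == 1]
        graph = nx.Graph()
        # rebuild the significant map independently
        iu = np.triu_indices(6, k=1)
        d = (A - B)[:, iu[0], iu[1]]
        for e, (i, j) in enumerate(zip(*iu)):
            p = stats.wilcoxon(d[:, e], method="exact").pvalue
            if p < 0.05 and np.median(d[:, e]) > 0:
                graph.add_edge(int(i), int(j))
        nx_comps = sorted((sorted(frozenset(map(tuple, map(sorted, graph.subgraph(c).edges())))))
                          for c in nx.connected_components(graph) if len(c) > 1)
        mine = sorted(sorted(tuple(sorted(e)) for e in c.edges) for c in pos)
        assert mine == nx_comps

    def test_toy_component_sizes(self, rng):
        strong = [(1, 2), (2, 3), (4, 5)]
        A, B = _paired_stacks(rng, 10, 6, strong, shift=0.3, noise=0.01)
        comps = ps.nbs_test(A, B, design="within", n_perm=500, seed=0)
        pos_sizes = sorted(c.size for c in comps if c.sign == 1)
        assert pos_sizes == [1, 2]

    def test_formula_floor(self, rng):
        """Observed component larger than every null value reaches the
        add-one floor 1/(N+1).

        With n=6 subjects the exact signed-rank test is significant only
        for an all-same-sign pattern, so among the 63 non-identity sign
        flips only the full flip produces any component — and it is
        negative. The observed all-edge positive component therefore
        exceeds every value of the positive null: p = 1/64."""
        n_ch = 5
        all_edges = [(i, j) for i in range(n_ch) for j in range(i + 1, n_ch)]
        A, B = _paired_stacks(rng, 6, n_ch, all_edges, shift=0.3, noise=0.01)
        comps = ps.nbs_test(A, B, design="within", n_perm=2000, seed=0)
        top = comps[0]
        assert top.size == len(all_edges)
        assert top.sign == 1
        assert top.p == pytest.approx(1.0 / 64.0)

    def test_no_significant_edges_returns_empty(self, rng):
        # n=4 within: the exact signed-rank floor is 0.125 > 0.05
        A, B = _paired_stacks(rng, 4, 5)
        assert ps.nbs_test(A, B, design="within", seed=0) == []

    def test_between_design_recovers_group_difference(self, rng):
        strong = [(0, 1), (1, 2), (2, 3), (3, 4)]
        A, B = _paired_stacks(rng, 8, 7, strong, shift=0.3)
        comps = ps.nbs_test(A, B, design="between", n_perm=2000, seed=0)
        top = [c for c in comps if c.sign == 1][0]
        assert set(map(tuple, map(sorted, top.edges))) >= set(strong)
        assert top.p < 0.05

    def test_correlation_design(self, rng):
        n_sub, n_ch = 10, 6
        y = rng.standard_normal(n_sub)
        A = rng.uniform(0.2, 0.4, size=(n_sub, n_ch, n_ch))
        A = 0.5 * (A + A.transpose(0, 2, 1))
        strong = [(0, 1), (1, 2), (2, 3)]
        for s in range(n_sub):
            for i, j in strong:
                A[s, i, j] = A[s, j, i] = 0.4 + 0.2 * y[s] + rng.normal(0, 0.01)
            np.fill_diagonal(A[s], 1.0)
        comps = ps.nbs_test(A, design="correlation", y=y, n_perm=1000, seed=0)
        hit = [c for c in comps
               if set(strong) <= set(map(tuple, map(sorted, c.edges)))]
        assert hit and hit[0].sign == 1 and hit[0].p < 0.05

    def test_type_one_error_nbs(self):
        """No planted effect: family-wise rate of any component with
        p < 0.05 stays near the nominal level (50 replicates)."""
        rng = np.random.default_rng(23)
        families = 0
        for _ in range(50):
            A, B = _paired_stacks(rng, 8, 8)
            comps = ps.nbs_test(A, B, design="within", n_perm=256, seed=rng)
            if any(c.p < 0.05 for c in comps):
                families += 1
        assert families / 50 <= 0.10
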