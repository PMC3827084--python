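"""Irwin–Hall combination and the three focal-set relatedness analyses."""

import math

import networkx as nx
import numpy as np
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hyp_st

from netseed.focal import (combine_pvalues_uniform_sum, distance_null_test,
                           irwin_hall_cdf, neighborhood_enrichment,
                           node_frequency_test, signed_rank_less_p)
from netseed.network import FocalSet, PPINetwork, closed_neighborhood

from conftest import chain_network


class TestIrwinHall:
    @pytest.mark.parametrize("x,n,expected", [
        (0.5, 1, 0.5),      # uniform CDF
        (1.0, 2, 0.5),      # symmetry about n/2
        (3.0, 3, 1.0),      # upper support bound
        (-0.5, 4, 0.0),     # below support
        (0.5, 2, 0.125),    # x^2/2 on [0,1]
    ])
    def test_known_values(self, x, n, expected):
        assert irwin_hall_cdf(x, n) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_scipy_reference(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = int(rng.integers(1, 40))
            x = float(rng.uniform(0, n))
            assert irwin_hall_cdf(x, n) == pytest.approx(
                st.irwinhall(n).cdf(x), abs=1e-10)

    def test_symmetry_about_half_n(self):
        for n in (3, 10, 101):
            for t in (0.1, 0.7, n / 4):
                assert irwin_hall_cdf(n / 2 + t, n) + irwin_hall_cdf(n / 2 - t, n) \
                    == pytest.approx(1.0, abs=1e-9)

    def test_monotone_non_decreasing(self):
        xs = np.linspace(-1, 6, 80)
        vals = [irwin_hall_cdf(x, 5) for x in xs]
        assert all(a <= b + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_large_n_matches_normal_limit(self):
        n = 1000
        sd = math.sqrt(n / 12.0)
        for z in (-3, -1, 0, 0.5, 2):
            x = n / 2 + z * sd
            assert irwin_hall_cdf(x, n) == pytest.approx(st.norm.cdf(z), abs=0.01)

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            irwin_hall_cdf(0.5, 0)


@given(hyp_st.integers(min_value=1, max_value=30),
       hyp_st.floats(min_value=-1.0, max_value=31.0))
@settings(deadline=None, derandomize=True)
def test_irwin_hall_is_a_cdf(n, x):
    """F maps into [0,1], respects the support, and obeys the symmetry
    identity F(x) + F(n-x) = 1."""
    f = irwin_hall_cdf(x, n)
    assert 0.0 <= f <= 1.0
    if x <= 0:
        assert f == 0.0
    if x >= n:
        assert f == 1.0
    if 0 <= x <= n:
        assert f + irwin_hall_cdf(n - x, n) == pytest.approx(1.0, abs=1e-9)


class TestCombinePValues:
    def test_central_sum_gives_half(self):
        assert combine_pvalues_uniform_sum([0.5] * 1000) == pytest.approx(0.5)
        assert combine_pvalues_uniform_sum([0.5] * 7, method="exact") == pytest.approx(0.5)

    def test_all_zero_lower_tail(self):
        assert combine_pvalues_uniform_sum([0.0] * 100) < 1e-12
        assert combine_pvalues_uniform_sum([0.0] * 5, method="exact") == 0.0

    def test_normal_and_exact_agree_for_large_n(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            p = rng.random(150)
            a = combine_pvalues_uniform_sum(p, method="normal")
            b = combine_pvalues_uniform_sum(p, method="exact")
            assert abs(a - b) < 1e-3

    def test_validation(self):
        with pytest.raises(ValueError):
            combine_pvalues_uniform_sum([])
        with pytest.raises(ValueError):
            combine_pvalues_uniform_sum([0.5, 1.2])
        with pytest.raises(ValueError):
            combine_pvalues_uniform_sum([0.5], method="fisher")

    def test_null_uniformity_with_independent_pvalues(self):
        """With genuinely i.i.d. uniform inputs the combined p is itself
        uniform (smaller replicate count than the acceptance check)."""
        rng = np.random.default_rng(2)
        combined = [combine_pvalues_uniform_sum(rng.random(50)) for _ in range(400)]
        assert st.kstest(combined, "uniform").pvalue > 0.01


class TestSignedRank:
    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(100):
            d = rng.normal(size=int(rng.integers(3, 22)))
            ours = signed_rank_less_p(d)
            ref = st.wilcoxon(d, alternative="less", zero_method="wilcox",
                              method="exact").pvalue
            assert ours == pytest.approx(ref, abs=1e-12)

    def test_zero_differences_dropped(self):
        d = np.array([0.0, 0.0, -1.0, -2.0, -3.0])
        assert signed_rank_less_p(d) == signed_rank_less_p(d[2:])

    def test_all_zero_is_noninformative(self):
        assert signed_rank_less_p(np.zeros(6)) == 0.5

    def test_one_sided_direction(self):
        assert signed_rank_less_p(-np.arange(1.0, 11.0)) < 0.01
        assert signed_rank_less_p(np.arange(1.0, 11.0)) > 0.99


class TestNodeFrequency:
    def collections(self):
        mods = lambda *sets: [set(s) for s in sets]
        return [mods({"F1", "F2", "X1"}), mods({"F1", "F2"}, {"X2"}),
                mods({"F1", "F2", "F3"})]

    def test_counts(self):
        res = node_frequency_test(self.collections(), {"F1", "F2", "F3"},
                                  {"X1", "X2", "X3"})
        assert res.focal_counts["F1"] == 3
        assert res.focal_counts["F3"] == 1
        assert res.non_focal_counts["X3"] == 0

    def test_minimal_tail_p_for_clean_separation(self):
        # focal counts all strictly above non-focal: the exact one-sided
        # rank-sum p is 1/C(n1+n2, n1)
        colls = [[{f"F{i}" for i in range(1, 5)}] for _ in range(6)]
        res = node_frequency_test(colls, {f"F{i}" for i in range(1, 5)},
                                  {f"X{i}" for i in range(1, 5)})
        assert res.wilcoxon_p == pytest.approx(1 / math.comb(8, 4))

    def test_type_i_error_under_exchangeability(self):
        """Identically distributed focal and non-focal counts: rejection at
        alpha=0.05 stays near (not above) the nominal rate."""
        rng = np.random.default_rng(4)
        hits = 0
        n_reps = 500
        for _ in range(n_reps):
            counts = rng.integers(0, 10, size=20)
            focal = {f"N{i}": counts[i] for i in range(8)}
            colls = [[{f"N{i}" for i in range(20) if counts[i] > t}]
                     for t in range(10)]
            res = node_frequency_test(colls, {f"N{i}" for i in range(8)},
                                      {f"N{i}" for i in range(8, 20)})
            hits += res.wilcoxon_p <= 0.05
        assert hits / n_reps <= 0.07

    def test_validation(self):
        with pytest.raises(ValueError):
            node_frequency_test([], {"A", "B"}, {"C"})
        with pytest.raises(ValueError):
            node_frequency_test([[{"A"}]], {"A"}, {"B", "C"})
        with pytest.raises(ValueError):
            node_frequency_test([[{"A"}]], {"A", "B"}, {"B"})


class TestNeighborhoodEnrichment:
    def star_net(self):
        g = nx.star_graph([f"N{i}" for i in range(10)])
        g.add_edges_from((f"M{i}", f"M{i+1}") for i in range(30))
        g.add_edge("N0", "M0")
        return PPINetwork(graph=g)

    def test_exact_neighborhood_seed_list_minimal_p(self):
        from netseed.network import SeedGeneList
        from netseed.stats import HypergeomQuery, hypergeom_upper_tail

        net = self.star_net()
        core = FocalSet(core={"N0"})
        hood = closed_neighborhood(net, core.core)
        res = neighborhood_enrichment(net, core, [SeedGeneList(set(hood), "expression")])
        row = res.iloc[0]
        expected = hypergeom_upper_tail(HypergeomQuery(
            N=net.n_nodes, K=len(hood), n=len(hood), k=len(hood)))
        assert row["p"] == pytest.approx(expected)
        assert row["k"] == row["K"] == row["n"]

    def test_disjoint_seeds_p_one(self):
        from netseed.network import SeedGeneList

        net = self.star_net()
        res = neighborhood_enrichment(net, FocalSet(core={"N0"}),
                                      [SeedGeneList({"M10", "M11"}, "snp")])
        assert res.iloc[0]["p"] == 1.0

    def test_union_row_and_bh(self):
        from netseed.network import SeedGeneList

        net = self.star_net()
        res = neighborhood_enrichment(net, FocalSet(core={"N0"}), [
            SeedGeneList({"N1", "N2", "N3"}, "expression"),
            SeedGeneList({"N4", "M20"}, "drug")])
        assert list(res["seed_list"]) == ["expression", "drug", "union"]
        assert (res["adj_p"] >= res["p"] - 1e-15).all()


class TestDistanceNull:
    def hub_net(self):
        """Focal nodes sit on a hub adjacent to every seed; the rest of the
        network hangs far away down a chain."""
        g = nx.Graph()
        seeds = [f"S{i}" for i in range(12)]
        focal = [f"F{i}" for i in range(6)]
        for f in focal:
            g.add_edges_from((f, s) for s in seeds)
        chain = [f"C{i}" for i in range(60)]
        g.add_edge(seeds[0], chain[0])
        g.add_edges_from(zip(chain, chain[1:]))
        return PPINetwork(graph=g), set(focal), set(seeds)

    def test_power_on_hub_topology(self):
        net, focal, seeds = self.hub_net()
        res = distance_null_test(net, focal, seeds, n_resamples=200, mode="avg",
                                 rng_seed=0)
        assert res.combined_p < 0.01

    def test_avg_mode_statistic_length(self):
        net, focal, seeds = self.hub_net()
        res = distance_null_test(net, focal, seeds, n_resamples=5, mode="avg",
                                 rng_seed=1)
        assert res.focal_statistics.shape == (len(focal),)
        res_all = distance_null_test(net, focal, seeds, n_resamples=5, mode="all",
                                     rng_seed=1)
        assert res_all.focal_statistics.shape == (len(focal) * len(seeds),)

    def test_bitwise_reproducible(self):
        net, focal, seeds = self.hub_net()
        a = distance_null_test(net, focal, seeds, n_resamples=20, rng_seed=7)
        b = distance_null_test(net, focal, seeds, n_resamples=20, rng_seed=7)
        assert np.array_equal(a.resample_p_values, b.resample_p_values)
        assert a.combined_p == b.combined_p

    def test_pool_too_small_rejected(self):
        net = chain_network(10)
        nodes = sorted(net.nodes)
        with pytest.raises(ValueError):
            distance_null_test(net, set(nodes[:6]), set(nodes[6:]), n_resamples=2)

    def test_resample_pvalues_in_unit_interval(self):
        net, focal, seeds = self.hub_net()
        res = distance_null_test(net, focal, seeds, n_resamples=30, rng_seed=2)
        assert np.all((res.resample_p_values >= 0) & (res.resample_p_values <= 1))
        assert 0 <= res.combined_p <= 1
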