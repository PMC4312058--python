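"""Median-joining networks, locus weights, founder selection, rho and TMRCA."""
import math

import networkx as nx
import numpy as np
import pytest

from ylineage.network import (
    LocusWeights,
    build_mj_network,
    locus_weights,
    rho_statistic,
    select_founder,
    tmrca_from_rho,
)
from ylineage.simulate import mutate_str, simulate_genealogy
from ylineage.types import STRHaplotype

L2 = ["A", "B"]
L3 = ["A", "B", "C"]


def hap(values, loci=None):
    loci = loci or (L2 if len(values) == 2 else L3)
    return STRHaplotype(dict(zip(loci, values)))


class TestLocusWeights:
    def test_equal_variance_equal_weights(self):
        hs = [hap([10, 10, 10]), hap([12, 12, 12])]
        w = locus_weights(hs, L3)
        assert len(set(w.weights.values())) == 1

    def test_invariant_locus_gets_five(self):
        hs = [hap([10, 10, 10]), hap([10, 12, 14]), hap([10, 14, 11])]
        w = locus_weights(hs, L3)
        assert w.weights["A"] == 5

    def test_rank_binning_five_distinct_variances(self):
        """Five loci with strictly increasing variances map onto weights
        5 (least variable) down to 1 (most variable)."""
        loci = [f"L{i}" for i in range(5)]
        # pairs {13-d, 13+d}: per-locus variance 2d^2, strictly increasing in d
        rows = [[13 - d for d in range(1, 6)], [13 + d for d in range(1, 6)]]
        hs = [STRHaplotype(dict(zip(loci, r))) for r in rows]
        w = locus_weights(hs, loci)
        assert [w.weights[l] for l in loci] == [5, 4, 3, 2, 1]

    def test_weight_bounds_enforced(self):
        with pytest.raises(ValueError):
            LocusWeights({"A": 6})
        with pytest.raises(ValueError):
            LocusWeights({"A": 0})


class TestBuildNetwork:
    def test_two_haplotypes_single_edge(self):
        w = LocusWeights({"A": 3, "B": 2})
        net = build_mj_network([hap([10, 10]), hap([11, 10])], w, L2)
        assert net.number_of_nodes() == 2 and net.number_of_edges() == 1
        (u, v, data), = net.edges(data=True)
        assert data["weight"] == 3.0 and data["steps"] == 1

    def test_star_median_is_existing_node(self):
        # (0,0) is itself the per-locus median of the triple: no new node
        hs = [hap([10, 10]), hap([11, 10]), hap([10, 11])]
        net = build_mj_network(hs, loci=L2)
        assert net.number_of_nodes() == 3
        assert not any(d["is_median"] for _, d in net.nodes(data=True))
        assert net.degree((10, 10)) == 2

    def test_triangle_resolves_to_path(self):
        hs = [hap([10, 10]), hap([11, 11]), hap([11, 10])]
        net = build_mj_network(hs, loci=L2)
        assert net.number_of_edges() == 2
        assert net.size(weight="weight") == 2.0

    def test_median_vector_added_for_symmetric_triple(self):
        """Three haplotypes pairwise two steps apart share a one-step median
        node that shortens the total connection cost from 4 to 3."""
        hs = [hap([10, 10, 10]), hap([11, 11, 10]), hap([10, 11, 11])]
        net = build_mj_network(hs, loci=L3)
        medians = [t for t, d in net.nodes(data=True) if d["is_median"]]
        assert medians == [(10, 11, 10)]
        assert net.degree((10, 11, 10)) == 3
        assert net.size(weight="weight") == 3.0
        assert net.nodes[(10, 11, 10)]["multiplicity"] == 0

    def test_all_observed_haplotypes_remain_nodes(self, rng):
        rows = rng.integers(10, 14, size=(12, 5)).tolist()
        loci = [f"L{i}" for i in range(5)]
        hs = [STRHaplotype(dict(zip(loci, r))) for r in rows]
        net = build_mj_network(hs, loci=loci)
        for h in hs:
            assert tuple(int(v) for v in h.vector(loci)) in net

    def test_network_connected_and_contains_mst(self, rng):
        rows = rng.integers(10, 14, size=(10, 4)).tolist()
        loci = [f"L{i}" for i in range(4)]
        hs = [STRHaplotype(dict(zip(loci, r))) for r in rows]
        net = build_mj_network(hs, loci=loci)
        assert nx.is_connected(net)
        # the minimum-spanning tree over the final node set is a subgraph
        complete = nx.Graph()
        for a in net.nodes:
            for b in net.nodes:
                if a < b:
                    complete.add_edge(a, b, weight=sum(abs(x - y) for x, y in zip(a, b)))
        mst_cost = sum(d["weight"] for _, _, d in nx.minimum_spanning_edges(complete, data=True))
        assert net.size(weight="weight") >= mst_cost - 1e-9

    def test_input_order_invariance(self, rng):
        rows = rng.integers(10, 14, size=(12, 4)).tolist()
        loci = [f"L{i}" for i in range(4)]
        hs = [STRHaplotype(dict(zip(loci, r))) for r in rows]
        net1 = build_mj_network(hs, loci=loci)
        shuffled = list(hs)
        rng.shuffle(shuffled)
        net2 = build_mj_network(shuffled, loci=loci)
        assert set(net1.nodes) == set(net2.nodes)
        assert {frozenset(e) for e in net1.edges} == {frozenset(e) for e in net2.edges}

    def test_single_haplotype_rejected(self):
        with pytest.raises(ValueError):
            build_mj_network([hap([10, 10])], loci=L2)


class TestFounder:
    def test_modal_haplotype_selected(self):
        hs = [hap([10, 10])] * 30 + [hap([11, 10])] * 20 + [hap([12, 10])] * 20
        net = build_mj_network(hs, loci=L2)
        assert select_founder(hs, net, L2) == (10, 10)

    def test_multiplicity_tie_broken_by_degree(self):
        # chain 10-11-12-13; 11 and 13 tied at multiplicity 2, deg(11)=2 > deg(13)=1
        hs = ([hap([11, 10])] * 2 + [hap([13, 10])] * 2
              + [hap([10, 10]), hap([12, 10])])
        net = build_mj_network(hs, loci=L2)
        assert net.degree((11, 10)) == 2 and net.degree((13, 10)) == 1
        assert select_founder(hs, net, L2) == (11, 10)

    def test_override_must_be_node(self):
        hs = [hap([10, 10]), hap([11, 10])]
        net = build_mj_network(hs, loci=L2)
        with pytest.raises(ValueError):
            select_founder(hs, net, L2, override=hap([20, 20]))
        assert select_founder(hs, net, L2, override=hap([11, 10])) == (11, 10)


class TestRho:
    def test_star_arithmetic(self):
        f = hap([10, 10])
        hs = [hap([10, 10]), hap([11, 10]), hap([12, 10])]  # 0, 1, 2 steps
        net = build_mj_network(hs + [f], loci=L2)
        est = rho_statistic(hs, f, net, L2)
        assert est.rho == pytest.approx(1.0)

    def test_all_identical_to_founder(self):
        f = hap([10, 10])
        hs = [hap([10, 10])] * 5
        est = rho_statistic(hs, f, loci=L2)
        assert est.rho == 0.0 and est.sigma == 0.0

    def test_pure_star_sigma_squared_is_rho_over_n(self, rng):
        """For a star (every sampled chromosome on its own branch) the branch
        formula collapses to sigma^2 = rho / n."""
        loci = [f"L{i}" for i in range(15)]
        founder = STRHaplotype({l: 13 for l in loci})
        g = simulate_genealogy(40, "star", 8000.0, 25.0, seed=rng)
        leaves = mutate_str(g, {l: 2e-3 for l in loci}, founder, seed=rng)
        # direct-distance route groups identical haplotypes; keep distinct ones
        distinct = list({h: None for h in leaves})
        est = rho_statistic(distinct, founder, loci=loci)
        assert est.sigma**2 == pytest.approx(est.rho / est.n, rel=1e-12)

    def test_network_rho_equals_direct_distance_on_tree(self, rng):
        """When the network is a homoplasy-free tree, path steps equal the
        direct stepwise distance to the founder."""
        loci = [f"L{i}" for i in range(15)]
        founder = STRHaplotype({l: 13 for l in loci})
        g = simulate_genealogy(25, "star", 6000.0, 25.0, seed=rng)
        leaves = mutate_str(g, {l: 6.9e-4 for l in loci}, founder, seed=rng)
        pool = leaves + [founder]
        net = build_mj_network(pool, loci=loci)
        via_net = rho_statistic(leaves, founder, net, loci)
        direct = rho_statistic(leaves, founder, loci=loci)
        assert via_net.rho == pytest.approx(direct.rho)

    def test_founder_absent_from_network_rejected(self):
        hs = [hap([10, 10]), hap([11, 10])]
        net = build_mj_network(hs, loci=L2)
        with pytest.raises(ValueError):
            rho_statistic(hs, hap([30, 30]), net, L2)


class TestTmrca:
    def test_formula(self):
        t = tmrca_from_rho(2.0, rate=1e-3, gen_years=25, n_loci=10)
        assert t.years == pytest.approx(2.0 * 25 / (10 * 1e-3))

    def test_zero_rho(self):
        assert tmrca_from_rho(0.0).years == 0.0

    def test_sigma_scales_identically(self):
        t = tmrca_from_rho(2.91, sigma=0.81)
        assert t.se_years / t.years == pytest.approx(0.81 / 2.91)

    @pytest.mark.parametrize("kw", [dict(rate=0), dict(rate=-1), dict(n_loci=0),
                                    dict(gen_years=0)])
    def test_invalid_parameters(self, kw):
        with pytest.raises(ValueError):
            tmrca_from_rho(1.0, **kw)
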