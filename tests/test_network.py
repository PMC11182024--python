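import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from cryonet import network
from conftest import toy_table


def spearman_sum_d2(x, y):
    """Independent oracle: rho = 1 - 6*sum(d^2)/(n(n^2-1)) for distinct ranks."""
    rx = np.argsort(np.argsort(x))
    ry = np.argsort(np.argsort(y))
    n = len(x)
    return 1 - 6 * np.sum((rx - ry) ** 2) / (n * (n**2 - 1))


class TestCorrelationMatrix:
    def test_matches_rank_formula_on_distinct_ranks(self):
        x = np.array([30, 10, 40, 15, 90])
        y = np.array([2, 7, 1, 8, 3])
        table = toy_table(np.c_[x, y, x + 3 * y])
        values = table.to_numpy(float)
        rho, _ = network.correlation_matrix(table)
        for i, j in itertools.combinations(range(3), 2):
            expected = spearman_sum_d2(values[:, i], values[:, j])
            assert rho.iloc[i, j] == pytest.approx(expected, abs=1e-12)

    def test_reversed_ranks_give_minus_one(self):
        table = toy_table([[1, 5], [2, 4], [3, 3], [4, 2], [5, 1]])
        rho, p = network.correlation_matrix(table)
        assert rho.iloc[0, 1] == pytest.approx(-1.0)
        assert np.allclose(np.diag(rho), 1.0)

    def test_constant_taxon_flagged_as_zero(self):
        table = toy_table([[1, 7], [2, 7], [3, 7], [4, 7]])
        with pytest.warns(UserWarning, match="constant"):
            rho, p = network.correlation_matrix(table)
        assert rho.iloc[0, 1] == 0.0 and p.iloc[0, 1] == 1.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            network.correlation_matrix(toy_table([[1, 2], [2, 1], [3, 3]]))


class TestBhAdjust:
    def test_hand_applied_step_up(self):
        adjusted = network.bh_adjust([0.01, 0.02, 0.03])
        assert np.allclose(adjusted, [0.03, 0.03, 0.03], atol=1e-12)

    def test_single_and_saturated(self):
        assert network.bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(network.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_monotone_in_rank(self):
        rng = np.random.default_rng(0)
        p = rng.random(50)
        adjusted = network.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adjusted[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            network.bh_adjust([0.5, 1.5])


def matrix_pair(rho_vals, p_vals, ids):
    rho = pd.DataFrame(rho_vals, index=ids, columns=ids)
    p = pd.DataFrame(p_vals, index=ids, columns=ids)
    return rho, p


class TestBuildNetwork:
    def test_threshold_rule_and_sign_convention(self):
        ids = ["a", "b", "c", "d"]
        rho = np.eye(4)
        p = np.zeros((4, 4))
        rho[0, 1] = rho[1, 0] = 0.7     # kept, +
        rho[0, 2] = rho[2, 0] = -0.8    # kept, - (magnitude convention)
        rho[1, 2] = rho[2, 1] = 0.59    # below r_min
        rho[2, 3] = rho[3, 2] = 0.9
        p[2, 3] = p[3, 2] = 0.02        # above p_max
        g = network.build_network(*matrix_pair(rho, p, ids), r_min=0.6, p_max=0.01)
        assert set(map(frozenset, g.edges)) == {frozenset("ab"), frozenset("ac")}
        assert g.edges["a", "b"]["sign"] == "+"
        assert g.edges["a", "c"]["sign"] == "-"
        assert g.number_of_nodes() == 4  # isolated node d retained

    def test_threshold_monotone_in_r_min(self):
        rng = np.random.default_rng(4)
        n = 12
        r = np.clip((rng.random((n, n)) * 2 - 1), -1, 1)
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        p = np.zeros((n, n))
        ids = [f"t{i}" for i in range(n)]
        previous = None
        for r_min in (0.2, 0.4, 0.6, 0.8):
            edges = set(map(frozenset, network.build_network(
                *matrix_pair(r, p, ids), r_min=r_min).edges))
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_invalid_r_min_rejected(self):
        ids = ["a", "b"]
        rho, p = matrix_pair(np.eye(2), np.zeros((2, 2)), ids)
        with pytest.raises(ValueError):
            network.build_network(rho, p, r_min=0.0)


class TestDetectModules:
    def test_two_cliques_split_exactly(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        part = network.detect_modules(g)
        assert sorted(part.sizes.values()) == [5, 5]
        left = {part.membership[n] for n in range(5)}
        right = {part.membership[n] for n in range(5, 10)}
        assert len(left) == 1 and len(right) == 1 and left != right

    def test_triangle_is_single_module(self):
        part = network.detect_modules(nx.cycle_graph(3))
        assert part.sizes == {1: 3}

    def test_edgeless_network_gives_singletons(self):
        g = nx.empty_graph(5)
        part = network.detect_modules(g)
        assert sorted(part.sizes.values()) == [1] * 5
        assert part.modularity == 0.0

    def test_disconnected_components_never_merged(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.cycle_graph(5))
        part = network.detect_modules(g)
        comp_modules = [
            {part.membership[n] for n in comp} for comp in nx.connected_components(g)
        ]
        assert not set.intersection(*comp_modules)

    def test_module_ids_ordered_by_size(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(6))
        part = network.detect_modules(g)
        assert part.sizes[1] == 6 and part.sizes[2] == 3


def two_module_toy():
    """Two K4 modules bridged by one edge; Zi/Pi known in closed form."""
    g = nx.Graph()
    m1, m2 = ["a", "b", "c", "d"], ["e", "f", "g", "h"]
    for module in (m1, m2):
        g.add_edges_from(itertools.combinations(module, 2))
    g.add_edge("a", "e")
    membership = {n: 1 for n in m1} | {n: 2 for n in m2}
    partition = network.ModulePartition(membership, 0.0, {1: 4, 2: 4})
    return g, partition


class TestZiPi:
    def test_hand_computed_toy_graph(self):
        g, partition = two_module_toy()
        topo = network.zipi(g, partition)
        # bridge node: degree 4, 3 within + 1 across -> Pi = 1 - (9+1)/16
        assert topo.loc["a", "pi"] == pytest.approx(1 - (0.75**2 + 0.25**2), abs=1e-12)
        # pure within-module node
        assert topo.loc["b", "pi"] == 0.0
        # within-module degree equal across each K4 -> sd = 0 -> Zi = 0
        assert (topo["zi"] == 0.0).all()
        assert not topo["keystone"].any()

    def test_even_split_pi_half(self):
        g = nx.star_graph(["hub", "x1", "x2", "y1", "y2"])
        membership = {"hub": 1, "x1": 1, "x2": 1, "y1": 2, "y2": 2}
        partition = network.ModulePartition(membership, 0.0)
        topo = network.zipi(g, partition)
        assert topo.loc["hub", "pi"] == pytest.approx(0.5, abs=1e-12)

    def test_connector_keystone_rule(self):
        # a node with Pi > 0.625 is a connector keystone even with low Zi
        g = nx.Graph()
        g.add_edges_from([("hub", f"m{i}") for i in range(4)])
        membership = {"hub": 1} | {f"m{i}": i + 2 for i in range(4)}
        partition = network.ModulePartition(membership, 0.0)
        topo = network.zipi(g, partition)
        assert topo.loc["hub", "pi"] == pytest.approx(0.75)
        assert topo.loc["hub", "role"] == "connector"
        assert bool(topo.loc["hub", "keystone"])

    def test_isolated_node_pi_zero(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        g.add_edge("a", "b")
        g.add_node("iso")
        partition = network.ModulePartition({"a": 1, "b": 1, "iso": 2}, 0.0)
        topo = network.zipi(g, partition)
        assert topo.loc["iso", "pi"] == 0.0

    def test_partition_must_cover_nodes(self):
        g, partition = two_module_toy()
        partition.membership.pop("h")
        with pytest.raises(ValueError, match="does not cover"):
            network.zipi(g, partition)


def exhaustive_star_robustness(fraction):
    """Brute-force oracle: average over all removal sets of a 5-node star."""
    g = nx.star_graph(4)  # node 0 is the hub
    n = 5
    n_remove = int(np.floor(fraction * n))
    values = []
    for removed in itertools.combinations(range(n), n_remove):
        keep = [v for v in range(n) if v not in removed]
        sub = g.subgraph(keep)
        values.append(sum(1 for v in keep if sub.degree(v) >= 1) / n)
    return float(np.mean(values))


class TestRobustness:
    def test_complete_graph_is_maximally_robust(self):
        value = network.robustness(nx.complete_graph(10), 0.5, trials=20, seed=0)
        assert value == pytest.approx(0.5)

    def test_edgeless_network_zero(self):
        assert network.robustness(nx.empty_graph(6), 0.5, trials=10, seed=0) == 0.0

    def test_star_matches_exhaustive_enumeration(self):
        oracle = exhaustive_star_robustness(0.4)
        estimate = network.robustness(nx.star_graph(4), 0.4, trials=4000, seed=1)
        assert oracle == pytest.approx(0.36)
        assert estimate == pytest.approx(oracle, abs=0.02)

    def test_non_increasing_in_removal_fraction(self):
        g = nx.erdos_renyi_graph(30, 0.15, seed=3)
        values = [
            network.robustness(g, f, trials=300, seed=7)
            for f in (0.1, 0.3, 0.5, 0.7, 0.9)
        ]
        assert all(a >= b - 0.03 for a, b in zip(values, values[1:]))

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ValueError):
            network.robustness(nx.complete_graph(4), 1.5)


class TestConnectedness:
    def test_hand_values(self):
        assert network.connectedness(nx.complete_graph(6)) == 1.0
        assert network.connectedness(nx.empty_graph(4)) == 0.0
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(2))
        assert network.connectedness(g) == pytest.approx((6 + 2) / 20)

    def test_largest_component_variant(self):
        g = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(2))
        assert network.connectedness(g, method="largest_component") == pytest.approx(0.6)


class TestPnRatio:
    def _graph(self, n_pos, n_neg):
        g = nx.Graph()
        for i in range(n_pos):
            g.add_edge(f"p{i}", f"q{i}", sign="+")
        for i in range(n_neg):
            g.add_edge(f"n{i}", f"m{i}", sign="-")
        return g

    def test_hand_ratio(self):
        ratio = network.pn_ratio(self._graph(6, 2))
        assert ratio.ratio == pytest.approx(3.0)
        assert ratio.defined

    def test_no_negative_edges_undefined(self):
        ratio = network.pn_ratio(self._graph(5, 0))
        assert not ratio.defined and np.isnan(ratio.ratio) and ratio.n_positive == 5

    def test_random_signs_near_unity(self):
        rng = np.random.default_rng(0)
        g = nx.Graph()
        for i in range(1000):
            g.add_edge(f"a{i}", f"b{i}", sign="+" if rng.random() < 0.5 else "-")
        assert 0.8 < network.pn_ratio(g).ratio < 1.25


class TestSubnetwork:
    def test_all_samples_identity(self, small_dataset):
        table, _, _ = small_dataset
        g = nx.Graph()
        g.add_nodes_from(table.columns[:10])
        g.add_edge(table.columns[0], table.columns[1], sign="+")
        sub = network.subnetwork(g, table, list(table.index))
        assert set(sub.nodes) == set(g.nodes)
        assert sub.number_of_edges() == 1

    def test_absent_taxon_removed(self):
        table = toy_table([[5, 0, 1], [3, 0, 2], [0, 4, 0]])
        g = nx.Graph()
        g.add_edges_from([("t1", "t2", {"sign": "+"}), ("t1", "t3", {"sign": "+"})])
        sub = network.subnetwork(g, table, ["s1", "s2"])
        assert set(sub.nodes) == {"t1", "t3"}
        assert set(map(frozenset, sub.edges)) == {frozenset(("t1", "t3"))}

    def test_unknown_samples_rejected(self, small_dataset):
        table, _, _ = small_dataset
        with pytest.raises(KeyError):
            network.subnetwork(nx.Graph(), table, ["nope"])


class TestModuleAbundance:
    def test_zscores_centered(self, small_dataset):
        table, truth, _ = small_dataset
        membership = {t: m for t, m in truth.module_of_taxon.items()}
        for t in table.columns:
            membership.setdefault(t, 99)
        partition = network.ModulePartition(membership, 0.0)
        z = network.module_abundance(table, partition, modules=[1, 2])
        assert np.allclose(z.mean(axis=0), 0.0, atol=1e-10)
        assert np.allclose(z.std(ddof=1), 1.0, atol=1e-10)

    def test_planted_module_enriched_under_residue(self, small_dataset):
        table, truth, design = small_dataset
        membership = dict(truth.module_of_taxon)
        for t in table.columns:
            membership.setdefault(t, 99)
        partition = network.ModulePartition(membership, 0.0)
        z = network.module_abundance(table, partition, modules=[1])["Module_1"]
        rr = design["residue"] == "RR"
        assert z[rr].mean() > z[~rr].mean() + 0.5

    def test_whole_table_module_degenerate(self):
        table = toy_table([[1, 1], [2, 2], [3, 3]])
        partition = network.ModulePartition({"t1": 1, "t2": 1}, 0.0)
        with pytest.warns(UserWarning, match="constant"):
            z = network.module_abundance(table, partition)
        assert z["Module_1"].isna().all()

    def test_missing_module_rejected(self):
        table = toy_table([[1, 2]])
        partition = network.ModulePartition({"other": 1}, 0.0)
        with pytest.raises(ValueError, match="no taxa"):
            network.module_abundance(table, partition)
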