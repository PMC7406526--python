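"""Network estimators, descriptive statistics, and edge-list round trips."""

import itertools
import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fluencynet import (
    DistanceMatrix,
    FluencyDataset,
    FluencyList,
    Scheme,
    SemanticNetwork,
    category_edge_matrix,
    estimate_conceptual_network,
    estimate_correlation_network,
    estimate_first_edge,
    estimate_naive_random_walk,
    estimate_pathfinder,
    export_edge_list,
    import_edge_list,
    intra_category_fraction,
    network_statistics,
    pathfinder_distances,
    pathfinder_union_mst,
)
from conftest import oracle_union_of_msts, random_connected_network


def flat_ds(*token_lists):
    lists = tuple(
        FluencyList("S0", i, tuple(toks)) for i, toks in enumerate(token_lists)
    )
    return FluencyDataset(lists=lists)


def edgeset(net):
    return {tuple(sorted(e)) for e in net.edges}


class TestSemanticNetwork:
    def test_symmetry_and_no_self_edges(self):
        net = SemanticNetwork.from_edges("abc", [("a", "b"), ("b", "a"), ("c", "c")])
        assert edgeset(net) == {("a", "b")}
        df = net.adjacency_dataframe()
        assert (df.to_numpy() == df.to_numpy().T).all()
        assert (np.diag(df.to_numpy()) == 0).all()

    def test_duplicate_nodes_rejected(self):
        with pytest.raises(ValueError):
            SemanticNetwork(nodes=("a", "a"), edges=frozenset())

    def test_toggle_is_involution(self):
        net = SemanticNetwork.from_edges("ab", [])
        assert net.toggle_edge("a", "b").toggle_edge("a", "b") == net


class TestFirstEdgeAndNaiveWalk:
    def test_first_edge_definition(self):
        net = estimate_first_edge(flat_ds(["a", "b", "c"], ["c", "d", "a"]))
        assert edgeset(net) == {("a", "b"), ("c", "d")}
        assert net.nodes == ("a", "b", "c", "d")

    def test_short_list_contributes_nodes_only(self):
        net = estimate_first_edge(flat_ds(["a"]))
        assert net.nodes == ("a",) and not net.edges

    def test_naive_walk_union_across_lists(self):
        net = estimate_naive_random_walk(flat_ds(["a", "b"], ["b", "c"]))
        assert edgeset(net) == {("a", "b"), ("b", "c")}

    def test_first_edge_subset_of_naive_walk(self):
        rng = np.random.default_rng(7)
        lists = [
            [f"n{i}" for i in rng.permutation(6)[: rng.integers(2, 6)]]
            for _ in range(8)
        ]
        ds = flat_ds(*lists)
        assert edgeset(estimate_first_edge(ds)) <= edgeset(
            estimate_naive_random_walk(ds)
        )

    def test_first_transition_of_censored_walk_is_an_edge(self):
        # consecutive first-visits need not be adjacent in the generating
        # network, but the walk's first transition always is
        from fluencynet import WalkParams, simulate_censored_walk

        rng = np.random.default_rng(3)
        net = random_connected_network(rng, 8, 12)
        for seed in range(30):
            fl = simulate_censored_walk(
                net, WalkParams(emit_target=8, seed=seed)
            )
            assert net.has_edge(fl.tokens[0], fl.tokens[1])


class TestPathfinder:
    def test_distance_examples(self):
        dm = pathfinder_distances(flat_ds(["a", "b", "c"]))
        assert dm.value("a", "b") == 1 and dm.value("b", "c") == 1
        assert dm.value("a", "c") == 2

    def test_distance_mean_over_lists(self):
        dm = pathfinder_distances(flat_ds(["a", "b"], ["b", "a"]))
        assert dm.value("a", "b") == 1

    def test_never_colisted_is_infinite(self):
        dm = pathfinder_distances(flat_ds(["a", "b"], ["c", "d"]))
        assert math.isinf(dm.value("a", "c"))

    def test_triangle_cycle_property(self):
        d = np.array([[0, 1, 3], [1, 0, 1], [3, 1, 0]], dtype=float)
        net = pathfinder_union_mst(DistanceMatrix(("a", "b", "c"), d))
        assert edgeset(net) == {("a", "b"), ("b", "c")}

    def test_equilateral_triangle_keeps_all_edges(self):
        d = np.ones((3, 3)) - np.eye(3)
        net = pathfinder_union_mst(DistanceMatrix(("a", "b", "c"), d))
        assert len(net.edges) == 3

    def test_tree_distances_return_tree(self):
        ds = flat_ds(["a", "b"], ["b", "c"], ["c", "d"])
        net = estimate_pathfinder(ds)
        assert edgeset(net) == {("a", "b"), ("b", "c"), ("c", "d")}

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_union_of_msts(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        nodes = tuple(f"n{i}" for i in range(n))
        # small integer weights force ties, the hard case for MST unions
        weights = {
            frozenset(p): float(rng.integers(1, 5))
            for p in itertools.combinations(nodes, 2)
        }
        d = np.zeros((n, n))
        for e, w in weights.items():
            u, v = tuple(e)
            i, j = nodes.index(u), nodes.index(v)
            d[i, j] = d[j, i] = w
        net = pathfinder_union_mst(DistanceMatrix(nodes, d))
        expected = oracle_union_of_msts(nodes, weights)
        assert net.edges == frozenset(expected)

    def test_invariant_to_list_order(self):
        lists = [["a", "b", "c"], ["c", "a", "d"], ["b", "d"]]
        n1 = estimate_pathfinder(flat_ds(*lists))
        n2 = estimate_pathfinder(flat_ds(*reversed(lists)))
        assert n1.edges == n2.edges


class TestCorrelationNetwork:
    def test_identical_presence_gives_edge(self):
        ds = flat_ds(["a", "b"], ["a", "b"], ["c"], ["c"])
        net = estimate_correlation_network(ds, threshold=0.9)
        assert ("a", "b") in edgeset(net)

    def test_antialigned_presence_gives_no_edge(self):
        ds = flat_ds(["a"], ["a"], ["b"], ["b"])
        net = estimate_correlation_network(ds, threshold=-0.5)
        assert ("a", "b") not in edgeset(net)

    def test_zero_variance_item_excluded_with_warning(self):
        ds = flat_ds(["a", "x"], ["b", "x"], ["a", "x"], ["b", "x"])
        with pytest.warns(UserWarning, match="zero-variance"):
            net = estimate_correlation_network(ds, threshold=0.5)
        assert all("x" not in e for e in edgeset(net))
        assert "x" in net.nodes

    def test_requires_two_lists(self):
        with pytest.raises(ValueError, match="2 lists"):
            estimate_correlation_network(flat_ds(["a", "b"]))


class TestConceptualNetwork:
    @staticmethod
    def rotating_lists():
        # ten lists of length five over six items; 'a' and 'b' always adjacent
        items = ["c", "d", "e", "f"]
        lists = []
        for i in range(10):
            rest = [items[(i + k) % 4] for k in range(3)]
            lists.append(["a", "b"] + rest if i % 2 else rest[:1] + ["a", "b"] + rest[1:])
        return lists

    def test_always_adjacent_pair_is_significant(self):
        # per-list null probability with window 1 and m = 5 is 0.4, so ten
        # adjacent co-occurrences have tail 0.4^10 ~ 1e-4 < 0.05
        ds = flat_ds(*self.rotating_lists())
        net = estimate_conceptual_network(ds, window=1, alpha=0.05)
        assert ("a", "b") in edgeset(net)

    def test_single_cooccurrence_not_significant(self):
        ds = flat_ds(["a", "b", "c", "d", "e"], ["c", "d", "e", "f", "g"])
        net = estimate_conceptual_network(ds, window=1, alpha=0.05)
        assert ("a", "b") not in edgeset(net)

    def test_window_spanning_lists_warns_and_yields_nothing(self):
        ds = flat_ds(["a", "b", "c"], ["a", "c", "b"])
        with pytest.warns(UserWarning, match="window"):
            net = estimate_conceptual_network(ds, window=4, alpha=0.05)
        assert not net.edges

    @pytest.mark.parametrize("alphas", [(0.001, 0.05), (0.05, 0.5), (0.001, 0.5)])
    def test_edges_monotone_in_alpha(self, alphas):
        rng = np.random.default_rng(11)
        lists = [
            [f"w{j}" for j in rng.permutation(8)[:6]] for _ in range(15)
        ]
        ds = flat_ds(*lists)
        a1, a2 = alphas
        assert edgeset(estimate_conceptual_network(ds, 2, a1)) <= edgeset(
            estimate_conceptual_network(ds, 2, a2)
        )

    def test_parameter_validation(self):
        ds = flat_ds(["a", "b"], ["a", "b"])
        with pytest.raises(ValueError):
            estimate_conceptual_network(ds, window=0)
        with pytest.raises(ValueError):
            estimate_conceptual_network(ds, alpha=1.5)


class TestEstimatorInvariants:
    @pytest.mark.parametrize("estimator", [
        estimate_first_edge,
        estimate_naive_random_walk,
        estimate_pathfinder,
        lambda ds: estimate_correlation_network(ds, 0.5),
        lambda ds: estimate_conceptual_network(ds, 2, 0.05),
    ])
    def test_symmetric_no_self_edges(self, estimator):
        rng = np.random.default_rng(5)
        lists = [
            [f"n{i}" for i in rng.permutation(7)[: rng.integers(2, 7)]]
            for _ in range(10)
        ]
        net = estimator(flat_ds(*lists))
        df = net.adjacency_dataframe().to_numpy()
        assert (df == df.T).all()
        assert (np.diag(df) == 0).all()


class TestNetworkStatistics:
    def test_triangle(self):
        net = SemanticNetwork.from_edges("abc", [("a", "b"), ("b", "c"), ("a", "c")])
        s = network_statistics(net)
        assert s.clustering_coefficient == 1.0
        assert s.mean_degree == 2.0
        assert s.mean_shortest_path == 1.0
        assert s.n_components == 1

    def test_three_node_path(self):
        net = SemanticNetwork.from_edges("abc", [("a", "b"), ("b", "c")])
        s = network_statistics(net)
        assert s.clustering_coefficient == 0.0
        assert s.mean_degree == pytest.approx(4 / 3)
        assert s.mean_shortest_path == pytest.approx(4 / 3)

    def test_two_disjoint_edges(self):
        net = SemanticNetwork.from_edges("abcd", [("a", "b"), ("c", "d")])
        s = network_statistics(net)
        assert s.n_components == 2
        assert sorted(s.component_sizes) == [2, 2]

    def test_empty_graph_warns(self):
        with pytest.warns(UserWarning, match="empty"):
            s = network_statistics(SemanticNetwork(nodes=(), edges=frozenset()))
        assert s.n_nodes == 0

    def test_exhaustive_small_graphs_against_direct_computation(self):
        # every labeled graph on 4 nodes, checked against a from-scratch
        # computation of each statistic
        names = ("a", "b", "c", "d")
        pairs = list(itertools.combinations(names, 2))
        import itertools as it

        for bits in it.product([0, 1], repeat=len(pairs)):
            edges = [p for p, b in zip(pairs, bits) if b]
            net = SemanticNetwork.from_edges(names, edges)
            s = network_statistics(net)
            adj = {n: set(net.neighbors(n)) for n in names}
            # mean degree
            assert s.mean_degree == pytest.approx(
                sum(len(v) for v in adj.values()) / 4
            )
            # local clustering by triangle counting
            cc = []
            for n in names:
                k = len(adj[n])
                if k < 2:
                    cc.append(0.0)
                else:
                    links = sum(
                        1 for x, y in it.combinations(adj[n], 2) if y in adj[x]
                    )
                    cc.append(2 * links / (k * (k - 1)))
            assert s.clustering_coefficient == pytest.approx(sum(cc) / 4)
            # components by BFS
            seen, comps = set(), []
            for n in names:
                if n in seen:
                    continue
                comp, stack = {n}, [n]
                while stack:
                    for v in adj[stack.pop()]:
                        if v not in comp:
                            comp.add(v)
                            stack.append(v)
                seen |= comp
                comps.append(comp)
            assert s.n_components == len(comps)
            largest = max(comps, key=len)
            # mean shortest path by BFS within largest component
            if len(largest) >= 2:
                dists = []
                for src in largest:
                    depth = {src: 0}
                    frontier = [src]
                    while frontier:
                        nxt = []
                        for u in frontier:
                            for v in adj[u]:
                                if v not in depth:
                                    depth[v] = depth[u] + 1
                                    nxt.append(v)
                        frontier = nxt
                    dists.extend(
                        d for t, d in depth.items() if t != src
                    )
                assert s.mean_shortest_path == pytest.approx(
                    sum(dists) / len(dists)
                )


class TestCategoryEdgeMatrix:
    def test_all_intra(self):
        net = SemanticNetwork.from_edges("abc", [("a", "b"), ("b", "c")])
        m = category_edge_matrix(net, None, {"a": "X", "b": "X", "c": "X"})
        assert intra_category_fraction(m) == pytest.approx(1.0)

    def test_bipartite_is_all_inter(self):
        net = SemanticNetwork.from_edges("abcd", [("a", "c"), ("a", "d"), ("b", "c")])
        m = category_edge_matrix(
            net, None, {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        )
        assert intra_category_fraction(m) == pytest.approx(0.0)
        assert m.to_numpy().sum() == pytest.approx(1.0)

    def test_mixed_counts(self):
        net = SemanticNetwork.from_edges(
            "abcd", [("a", "b"), ("c", "d"), ("a", "c")]
        )
        m = category_edge_matrix(
            net, None, {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        )
        assert intra_category_fraction(m) == pytest.approx(2 / 3)

    def test_unassigned_node_listed_in_error(self):
        net = SemanticNetwork.from_edges("ab", [("a", "b")])
        with pytest.raises(ValueError, match="b"):
            category_edge_matrix(net, None, {"a": "X"})


class TestEdgeListRoundTrip:
    def test_canonical_format(self, tmp_path):
        net = SemanticNetwork.from_edges("ab", [("b", "a")])
        p = tmp_path / "net.csv"
        export_edge_list(net, p)
        text = p.read_text()
        assert "a,b" in text and "b,a" not in text

    def test_isolated_nodes_survive(self, tmp_path):
        net = SemanticNetwork(nodes=("a", "b", "c"), edges=frozenset())
        p = tmp_path / "net.csv"
        export_edge_list(net, p)
        assert import_edge_list(p) == net

    def test_malformed_row_reports_line(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("# nodes\na\nb\n# edges\na,b,c\n", encoding="utf-8")
        with pytest.raises(ValueError, match=":5"):
            import_edge_list(p)

    @given(seed=st.integers(0, 99))
    @settings(deadline=None, max_examples=100)
    def test_identity_on_random_graphs(self, seed, tmp_path_factory):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 9))
        net = random_connected_network(rng, n, int(rng.integers(n - 1, n * 2)))
        p = tmp_path_factory.mktemp("el") / "net.csv"
        export_edge_list(net, p)
        assert import_edge_list(p) == net
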