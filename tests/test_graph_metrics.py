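"""Graph-topology measures: closed forms, brute-force oracles, and the
undirected-as-special-case property."""

import numpy as np
import pytest

from dcovnet.containers import SINK_SOURCE, SOURCE_SINK, BinaryNetwork
from dcovnet.graph_metrics import (
    clustering_transitivity,
    degrees,
    find_partition,
    global_efficiency,
    local_efficiency,
    modularity,
    shortest_paths,
    topology_report,
    triangles,
)
from dcovnet.validation import (
    floyd_warshall,
    modularity_by_tabulation,
    topology_oracle_gap,
)


def _net(adj, directed):
    adj = np.asarray(adj, dtype=bool)
    return BinaryNetwork(adj, directed=directed, threshold=1.0,
                         labels=[f"n{i}" for i in range(adj.shape[0])],
                         convention=SOURCE_SINK)


def _complete(n, directed):
    a = ~np.eye(n, dtype=bool)
    return _net(a, directed)


def _path3():
    a = np.zeros((3, 3), dtype=bool)
    a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = True
    return _net(a, directed=False)


def _two_cliques(k=4):
    n = 2 * k
    a = np.zeros((n, n), dtype=bool)
    a[:k, :k] = ~np.eye(k, dtype=bool)
    a[k:, k:] = ~np.eye(k, dtype=bool)
    return _net(a, directed=False)


class TestDegrees:
    def test_complete_graph(self):
        out, inn = degrees(_complete(5, directed=True))
        assert np.all(out == 4) and np.all(inn == 4)

    def test_single_directed_edge(self):
        a = np.zeros((3, 3), dtype=bool)
        a[0, 1] = True
        out, inn = degrees(_net(a, directed=True))
        assert list(out) == [1, 0, 0]
        assert list(inn) == [0, 1, 0]

    def test_handshake_identity(self):
        rng = np.random.default_rng(0)
        a = rng.random((7, 7)) < 0.4
        np.fill_diagonal(a, False)
        net = _net(a, directed=True)
        out, inn = degrees(net)
        assert out.sum() == inn.sum() == net.n_edges

    def test_sink_convention_is_transposed(self):
        a = np.zeros((3, 3), dtype=bool)
        a[1, 0] = True  # sink row 1, source column 0: edge 0 -> 1
        net = BinaryNetwork(a, directed=True, threshold=1.0,
                            labels=["a", "b", "c"], convention=SINK_SOURCE)
        out, inn = degrees(net)
        assert list(out) == [1, 0, 0]
        assert list(inn) == [0, 1, 0]


class TestShortestPaths:
    def test_undirected_path(self):
        d = shortest_paths(_path3())
        assert d[0, 2] == 2 and d[0, 1] == 1

    def test_directed_unreachable_is_infinite(self):
        a = np.zeros((2, 2), dtype=bool)
        a[0, 1] = True
        d = shortest_paths(_net(a, directed=True))
        assert d[0, 1] == 1 and np.isinf(d[1, 0])

    def test_matches_floyd_warshall(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            a = rng.random((n, n)) < 0.35
            np.fill_diagonal(a, False)
            net = _net(a, directed=True)
            d = shortest_paths(net)
            ref = floyd_warshall(a.astype(float))
            assert np.array_equal(np.isinf(d), np.isinf(ref))
            fin = np.isfinite(d)
            assert np.allclose(d[fin], ref[fin])


class TestGlobalEfficiency:
    def test_complete_graph_is_one(self):
        assert global_efficiency(_complete(6, False)) == 1.0
        assert global_efficiency(_complete(6, True)) == 1.0

    def test_empty_graph_is_zero(self):
        assert global_efficiency(_net(np.zeros((4, 4), dtype=bool), False)) == 0.0

    def test_path_of_three_closed_form(self):
        assert global_efficiency(_path3()) == pytest.approx(5 / 6)

    def test_adding_an_edge_never_decreases_efficiency(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            n = 6
            a = rng.random((n, n)) < 0.3
            np.fill_diagonal(a, False)
            e0 = global_efficiency(_net(a, True))
            empty = np.argwhere(~a & ~np.eye(n, dtype=bool))
            i, j = empty[rng.integers(len(empty))]
            a2 = a.copy()
            a2[i, j] = True
            assert global_efficiency(_net(a2, True)) >= e0 - 1e-12


class TestTriangles:
    def test_undirected_clique(self):
        t = triangles(_complete(3, False))
        assert np.allclose(t, 1.0)

    def test_fully_bidirectional_directed_clique(self):
        # each orientation-sum factor equals 2, so each node counts 8
        t = triangles(_complete(3, True))
        assert np.allclose(t, 8.0)

    def test_star_is_triangle_free(self):
        a = np.zeros((5, 5), dtype=bool)
        a[0, 1:] = a[1:, 0] = True
        assert np.all(triangles(_net(a, False)) == 0)


class TestClusteringTransitivity:
    def test_complete_graph(self):
        C, T = clustering_transitivity(_complete(5, False))
        assert C == pytest.approx(1.0) and T == pytest.approx(1.0)

    def test_square_cycle_has_no_clustering(self):
        a = np.zeros((4, 4), dtype=bool)
        for i in range(4):
            a[i, (i + 1) % 4] = a[(i + 1) % 4, i] = True
        C, T = clustering_transitivity(_net(a, False))
        assert C == 0.0 and T == 0.0


class TestLocalEfficiency:
    def test_complete_graph_is_one(self):
        assert local_efficiency(_complete(5, False)) == pytest.approx(1.0)
        assert local_efficiency(_complete(5, True)) == pytest.approx(1.0)

    def test_star_graph_is_zero(self):
        a = np.zeros((5, 5), dtype=bool)
        a[0, 1:] = a[1:, 0] = True
        assert local_efficiency(_net(a, False)) == 0.0


class TestModularity:
    def test_single_module_is_zero(self):
        net = _two_cliques()
        part = {lab: 0 for lab in net.labels}
        assert modularity(net, part) == pytest.approx(0.0)

    def test_two_disconnected_cliques_give_half(self):
        net = _two_cliques(4)
        part = {lab: (0 if i < 4 else 1) for i, lab in enumerate(net.labels)}
        assert modularity(net, part) == pytest.approx(0.5)

    def test_matches_edge_tabulation_reference(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(3, 9))
            a = rng.random((n, n)) < 0.4
            np.fill_diagonal(a, False)
            net = _net(a, directed=True)
            memb = np.unique(rng.integers(0, 3, n), return_inverse=True)[1]
            part = {net.labels[i]: int(memb[i]) for i in range(n)}
            assert modularity(net, part) == pytest.approx(
                modularity_by_tabulation(a.astype(float), memb), abs=1e-12)

    def test_printed_variant_squares_the_bracket(self):
        net = _two_cliques(4)
        part = {lab: (0 if i < 4 else 1) for i, lab in enumerate(net.labels)}
        # each module: (e_uu - a_u)^2 = (0.5 - 0.5)^2 = 0
        assert modularity(net, part, printed_form=True) == pytest.approx(0.0)

    def test_partial_partition_rejected(self):
        net = _two_cliques(3)
        with pytest.raises(ValueError):
            modularity(net, {net.labels[0]: 0})


class TestFindPartition:
    def test_recovers_disconnected_cliques(self):
        net = _two_cliques(4)
        part = find_partition(net, seed=0)
        ids = [part[lab] for lab in net.labels]
        assert len(set(ids[:4])) == 1 and len(set(ids[4:])) == 1
        assert ids[0] != ids[4]
        assert modularity(net, part) == pytest.approx(0.5)

    def test_complete_graph_has_no_structure(self):
        part = find_partition(_complete(6, False), seed=1)
        assert modularity(_complete(6, False), part) <= 1e-12

    def test_never_worse_than_single_module(self):
        rng = np.random.default_rng(4)
        for s in range(10):
            n = int(rng.integers(3, 9))
            a = rng.random((n, n)) < 0.3
            np.fill_diagonal(a, False)
            if not a.any():
                continue
            net = _net(a, directed=True)
            assert modularity(net, find_partition(net, seed=s)) >= 0.0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(5)
        a = rng.random((8, 8)) < 0.3
        np.fill_diagonal(a, False)
        net2 = _net(a | a.T, directed=False)
        assert find_partition(net2, seed=3) == find_partition(net2, seed=3)


class TestOraclesAndSpecialisation:
    def test_all_measures_match_brute_force(self):
        # distances, triangles, clustering, transitivity, local efficiency
        # and modularity vs independent enumeration; plus the
        # directed-formulas-on-symmetric-graphs specialisation
        assert topology_oracle_gap(n_graphs=100, seed=0) < 1e-10

    def test_isomorphism_invariance(self):
        rng = np.random.default_rng(6)
        a = rng.random((7, 7)) < 0.4
        np.fill_diagonal(a, False)
        perm = rng.permutation(7)
        b = a[np.ix_(perm, perm)]
        na, nb = _net(a, True), _net(b, True)
        assert global_efficiency(na) == pytest.approx(global_efficiency(nb))
        assert clustering_transitivity(na) == pytest.approx(clustering_transitivity(nb))
        assert local_efficiency(na) == pytest.approx(local_efficiency(nb))


class TestTopologyReport:
    def test_report_is_complete_and_serialisable(self):
        import json

        rng = np.random.default_rng(7)
        a = rng.random((8, 8)) < 0.35
        np.fill_diagonal(a, False)
        rep = topology_report(_net(a, True), seed=0)
        payload = json.loads(json.dumps(rep.to_dict()))
        assert set(payload) >= {"out_degree", "in_degree", "triangles",
                                "global_efficiency", "local_efficiency",
                                "clustering", "transitivity", "modularity",
                                "partition"}
        assert len(payload["partition"]) == 8
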