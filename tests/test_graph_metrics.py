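"""Tests of binarization and the graph indices against independent oracles."""

from collections import deque

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nirsnet import (
    average_degree,
    average_path_length,
    binarize,
    clustering_coefficient,
    is_connected,
    network_metrics,
)
from nirsnet.graph_metrics import BinaryNetwork
from tests.test_connectivity import matrix_from


def net_from_adjacency(a):
    a = np.asarray(a, dtype=np.int8)
    return BinaryNetwork(
        labels=[f"N{i}" for i in range(a.shape[0])], adjacency=a, threshold=None
    )


def random_net(rng, n, p):
    upper = rng.random((n, n)) < p
    a = np.triu(upper, k=1)
    a = (a | a.T).astype(np.int8)
    return net_from_adjacency(a)


# -- independent oracles -----------------------------------------------------

def clustering_oracle(a):
    """Exhaustive neighbor-pair enumeration."""
    n = a.shape[0]
    cs = []
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = len(nbrs)
        if k < 2:
            cs.append(0.0)
            continue
        links = sum(
            a[u, v] for ii, u in enumerate(nbrs) for v in nbrs[ii + 1 :]
        )
        cs.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(cs))


def path_length_oracle(a):
    """All-pairs BFS; mean over reachable unordered pairs."""
    n = a.shape[0]
    dists = []
    for s in range(n):
        dist = {s: 0}
        queue = deque([s])
        while queue:
            u = queue.popleft()
            for v in np.flatnonzero(a[u]):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    queue.append(v)
        dists.extend(d for node, d in dist.items() if node > s)
    return float(np.mean(dists))


# -- binarize ----------------------------------------------------------------

class TestBinarize:
    def r3(self, r12, r13, r23):
        return matrix_from(
            [[1.0, r12, r13], [r12, 1.0, r23], [r13, r23, 1.0]]
        )

    def test_absolute_value_rule(self):
        net = binarize(self.r3(0.5, 0.2, -0.3), 0.275)
        assert net.n_edges == 2
        assert net.adjacency[0, 1] == 1 and net.adjacency[1, 2] == 1
        assert net.adjacency[0, 2] == 0

    def test_boundary_equality_included(self):
        net = binarize(self.r3(0.5, 0.2, -0.3), 0.5)
        assert net.n_edges == 1
        assert net.adjacency[0, 1] == 1

    def test_no_self_loops_and_symmetry(self, rng):
        vals = np.clip(rng.uniform(-1, 1, (24, 24)), -1, 1)
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        net = binarize(matrix_from(vals), 0.275)
        net.validate()
        # exhaustive comparison oracle
        expected = sum(
            1
            for i in range(24)
            for j in range(i + 1, 24)
            if abs(vals[i, j]) >= 0.275
        )
        assert net.n_edges == expected

    @pytest.mark.parametrize("t", [0.0, 1.0, -0.2, 1.5])
    def test_threshold_domain(self, t):
        with pytest.raises(ValueError):
            binarize(self.r3(0.5, 0.2, -0.3), t)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_monotone_in_threshold(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.uniform(-1, 1, (10, 10))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        m = matrix_from(vals)
        low, high = binarize(m, 0.3), binarize(m, 0.6)
        # every edge surviving the stricter threshold exists at the looser one
        assert np.all(low.adjacency >= high.adjacency)


# -- indices -----------------------------------------------------------------

class TestClusteringCoefficient:
    def test_complete_graph(self):
        assert clustering_coefficient(net_from_adjacency(1 - np.eye(4))) == 1.0

    def test_star_graph(self):
        a = np.zeros((5, 5), dtype=int)
        a[0, 1:] = a[1:, 0] = 1
        assert clustering_coefficient(net_from_adjacency(a)) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_against_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = random_net(rng, 10, 0.5)
        assert clustering_coefficient(net) == pytest.approx(
            clustering_oracle(net.adjacency), abs=1e-13
        )

    def test_against_networkx(self, rng):
        net = random_net(rng, 12, 0.4)
        g = nx.from_numpy_array(net.adjacency)
        assert clustering_coefficient(net) == pytest.approx(
            nx.average_clustering(g), abs=1e-12
        )


class TestAveragePathLength:
    def test_complete_graph(self):
        assert average_path_length(net_from_adjacency(1 - np.eye(6))) == 1.0

    def test_ring_of_four(self):
        a = np.zeros((4, 4), dtype=int)
        for i in range(4):
            a[i, (i + 1) % 4] = a[(i + 1) % 4, i] = 1
        assert average_path_length(net_from_adjacency(a)) == pytest.approx(4 / 3)

    @pytest.mark.parametrize("seed", range(5))
    def test_against_bfs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        net = random_net(rng, 12, 0.35)
        assert average_path_length(net) == pytest.approx(
            path_length_oracle(net.adjacency), abs=1e-13
        )

    def test_reachable_pairs_only_when_disconnected(self):
        # two disjoint edges: reachable pairs are exactly the two edges
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = a[1, 0] = a[2, 3] = a[3, 2] = 1
        net = net_from_adjacency(a)
        assert average_path_length(net) == 1.0
        assert not is_connected(net)
        m = network_metrics(net)
        assert not m.connected
        assert m.n_unreachable_pairs == 4

    def test_no_edges_is_an_error(self):
        with pytest.raises(ValueError, match="no finite paths"):
            average_path_length(net_from_adjacency(np.zeros((3, 3))))

    def test_adding_edge_never_increases_path_length(self, rng):
        for _ in range(10):
            net = random_net(rng, 10, 0.4)
            if net.n_edges == 0 or not is_connected(net):
                continue
            missing = np.argwhere(np.triu(net.adjacency == 0, k=1))
            if len(missing) == 0:
                continue
            i, j = missing[rng.integers(len(missing))]
            denser = net.adjacency.copy()
            denser[i, j] = denser[j, i] = 1
            assert average_path_length(
                net_from_adjacency(denser)
            ) <= average_path_length(net)


class TestAverageDegree:
    def test_examples(self):
        assert average_degree(net_from_adjacency(1 - np.eye(4))) == 3.0
        assert average_degree(net_from_adjacency(np.zeros((5, 5)))) == 0.0

    @pytest.mark.parametrize("seed", range(5))
    def test_twice_edges_over_nodes(self, seed):
        rng = np.random.default_rng(seed)
        net = random_net(rng, 15, 0.3)
        assert average_degree(net) == 2 * net.n_edges / net.n_nodes


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_indices_invariant_under_relabeling(seed):
    rng = np.random.default_rng(seed)
    net = random_net(rng, 9, 0.45)
    if net.n_edges == 0:
        return
    perm = rng.permutation(9)
    permuted = net_from_adjacency(net.adjacency[np.ix_(perm, perm)])
    assert clustering_coefficient(permuted) == pytest.approx(
        clustering_coefficient(net), abs=1e-13
    )
    assert average_degree(permuted) == average_degree(net)
    assert average_path_length(permuted) == pytest.approx(
        average_path_length(net), abs=1e-13
    )
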