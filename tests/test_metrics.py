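"""Graph metrics, null models and small-world normalization."""

import numpy as np
import networkx as nx
import pytest

from scnkit import _fast
from scnkit.construction import BinaryNetwork
from scnkit.metrics import (
    betweenness_centrality,
    global_metrics,
    modularity_best,
    nodal_metrics,
    random_reference,
    rewire_adjacency,
    small_world,
)

from oracles import (
    bf_betweenness,
    bf_clustering,
    bf_global_efficiency,
    bf_transitivity,
    bf_triangles_per_node,
    random_adjacency,
)


def net_from(a):
    a = np.asarray(a, dtype=np.uint8)
    bn = BinaryNetwork(a=a, density=0.0)
    object.__setattr__(bn, "density", bn.recompute_density())
    return bn


def path_graph(n):
    a = np.zeros((n, n), dtype=np.uint8)
    for i in range(n - 1):
        a[i, i + 1] = a[i + 1, i] = 1
    return a


def complete_graph(n):
    a = np.ones((n, n), dtype=np.uint8)
    np.fill_diagonal(a, 0)
    return a


def star_graph(leaves):
    a = np.zeros((leaves + 1, leaves + 1), dtype=np.uint8)
    a[0, 1:] = a[1:, 0] = 1
    return a


def ring_lattice(n, k):
    """Each node connected to its k nearest neighbors (k even)."""
    a = np.zeros((n, n), dtype=np.uint8)
    for i in range(n):
        for d in range(1, k // 2 + 1):
            j = (i + d) % n
            a[i, j] = a[j, i] = 1
    return a


class TestNodalMetrics:
    def test_path_graph_middleman(self):
        nm = nodal_metrics(net_from(path_graph(3)))
        assert nm.betweenness == pytest.approx([0.0, 1.0, 0.0])
        assert nm.degree.tolist() == [1, 2, 1]

    def test_triangle_clique(self):
        nm = nodal_metrics(net_from(complete_graph(3)))
        assert np.allclose(nm.clustering, 1.0)
        assert nm.degree.tolist() == [2, 2, 2]

    def test_against_path_enumeration_oracle(self, rng):
        for _ in range(20):
            a = random_adjacency(rng, 7, rng.uniform(0.2, 0.8))
            nm = nodal_metrics(net_from(a))
            assert np.allclose(nm.betweenness, bf_betweenness(a.tolist()), atol=1e-9)
            assert np.allclose(nm.clustering, bf_clustering(a.tolist()))
            assert np.array_equal(
                _fast.triangles_per_node(a), bf_triangles_per_node(a.tolist())
            )

    def test_relabeling_equivariance(self, rng):
        a = random_adjacency(rng, 9, 0.4)
        perm = rng.permutation(9)
        b = a[np.ix_(perm, perm)]
        nma, nmb = nodal_metrics(net_from(a)), nodal_metrics(net_from(b))
        for name in ("degree", "betweenness", "clustering"):
            assert np.allclose(
                getattr(nma, name)[perm], getattr(nmb, name), atol=1e-12
            )


class TestGlobalMetrics:
    def test_path_graph_closed_form(self):
        gm = global_metrics(net_from(path_graph(3)))
        assert gm.global_efficiency == pytest.approx((1 + 1 + 0.5) / 3)
        assert gm.path_length == pytest.approx(1.2)
        assert gm.global_efficiency * gm.path_length == pytest.approx(1.0)

    def test_clique_saturation(self):
        gm = global_metrics(net_from(complete_graph(3)))
        assert gm.transitivity == pytest.approx(1.0)
        assert gm.clustering == pytest.approx(1.0)
        assert gm.local_efficiency == pytest.approx(1.0)

    def test_star_is_triangle_free_and_disassortative(self):
        gm = global_metrics(net_from(star_graph(4)))
        assert gm.transitivity == 0.0
        assert gm.assortativity == pytest.approx(-1.0)

    def test_two_disconnected_cliques_modularity(self):
        a = np.zeros((8, 8), dtype=np.uint8)
        a[:4, :4] = complete_graph(4)
        a[4:, 4:] = complete_graph(4)
        gm = global_metrics(net_from(a))
        assert gm.modularity == pytest.approx(0.5)

    def test_transitivity_matches_combinatorial_oracle(self, rng):
        for _ in range(20):
            a = random_adjacency(rng, 8, rng.uniform(0.2, 0.8))
            assert _fast.transitivity(a) == pytest.approx(bf_transitivity(a.tolist()))

    def test_efficiency_path_length_reciprocal_identity(self, rng):
        # holds for connected and fragmented graphs alike
        for p in (0.1, 0.3, 0.7):
            for _ in range(5):
                a = random_adjacency(rng, 10, p)
                if a.sum() == 0:
                    continue
                gm = global_metrics(net_from(a))
                assert gm.global_efficiency * gm.path_length == pytest.approx(1.0)
                assert gm.global_efficiency == pytest.approx(
                    bf_global_efficiency(a.tolist())
                )

    def test_adding_edge_improves_efficiency(self, rng):
        for _ in range(10):
            a = random_adjacency(rng, 8, 0.3)
            off = np.argwhere(np.triu(a == 0, 1))
            if len(off) == 0 or a.sum() == 0:
                continue
            i, j = off[rng.integers(len(off))]
            b = a.copy()
            b[i, j] = b[j, i] = 1
            assert _fast.global_efficiency(b) >= _fast.global_efficiency(a) - 1e-12

    def test_transitivity_equals_clustering_on_vertex_transitive_graphs(self):
        for a in (ring_lattice(12, 4), complete_graph(6)):
            assert _fast.transitivity(a) == pytest.approx(_fast.mean_clustering(a))
        # triangle with a pendant edge: C_p = 7/12 but transitivity = 3/5
        paw = np.zeros((4, 4), dtype=np.uint8)
        for i, j in [(0, 1), (1, 2), (0, 2), (2, 3)]:
            paw[i, j] = paw[j, i] = 1
        assert _fast.mean_clustering(paw) == pytest.approx(7 / 12)
        assert _fast.transitivity(paw) == pytest.approx(3 / 5)

    def test_empty_graph_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            global_metrics(net_from(np.zeros((4, 4), dtype=np.uint8)))

    def test_modularity_reproducible(self, rng):
        a = random_adjacency(rng, 20, 0.3)
        assert modularity_best(a, seed=7) == modularity_best(a, seed=7)

    def test_kernels_match_networkx(self, rng):
        for _ in range(10):
            a = random_adjacency(rng, 12, 0.35)
            if a.sum() == 0:
                continue
            g = nx.from_numpy_array(a.astype(int))
            assert _fast.mean_clustering(a) == pytest.approx(nx.average_clustering(g))
            assert _fast.transitivity(a) == pytest.approx(nx.transitivity(g))
            assert _fast.global_efficiency(a) == pytest.approx(
                nx.global_efficiency(g)
            )
            if np.std(_fast.degrees(a)) > 0:
                assert _fast.degree_assortativity(a) == pytest.approx(
                    nx.degree_assortativity_coefficient(g), abs=1e-9
                )
            bc = nx.betweenness_centrality(g, normalized=True)
            assert np.allclose(
                betweenness_centrality(a), [bc[i] for i in range(12)]
            )


class TestRandomReference:
    def test_degree_sequence_preserved(self, rng):
        a = random_adjacency(rng, 15, 0.3)
        ens = random_reference(net_from(a), m=5, seed=0)
        for member in ens.members:
            assert np.array_equal(
                np.sort(member.sum(axis=0)), np.sort(a.sum(axis=0))
            )
            assert np.array_equal(member, member.T)
            assert not np.diag(member).any()

    def test_complete_graph_yields_identical_copies_with_warning(self):
        with pytest.warns(UserWarning, match="rewired"):
            ens = random_reference(net_from(complete_graph(5)), m=3, seed=0)
        assert ens.c_rand == pytest.approx(1.0)
        assert ens.l_rand == pytest.approx(1.0)
        assert not ens.rewired

    def test_rewiring_destroys_lattice_clustering(self):
        a = ring_lattice(30, 4)
        assert _fast.mean_clustering(a) == pytest.approx(0.5)  # 3(k-2)/(4(k-1))
        ens = random_reference(net_from(a), m=10, seed=1)
        assert ens.c_rand < 0.5

    def test_seeded_reproducibility(self, rng):
        a = random_adjacency(rng, 15, 0.3)
        e1 = random_reference(net_from(a), m=3, seed=42)
        e2 = random_reference(net_from(a), m=3, seed=42)
        for m1, m2 in zip(e1.members, e2.members):
            assert np.array_equal(m1, m2)


class TestSmallWorld:
    def test_self_comparison_is_unity(self):
        net = net_from(complete_graph(5))
        with pytest.warns(UserWarning):
            ens = random_reference(net, m=3, seed=0)
        sw = small_world(net, ens)
        assert sw.gamma == pytest.approx(1.0)
        assert sw.lam == pytest.approx(1.0)
        assert sw.sigma == pytest.approx(1.0)

    def test_lattice_is_small_world_positive(self):
        net = net_from(ring_lattice(30, 4))
        ens = random_reference(net, m=10, seed=3)
        sw = small_world(net, ens)
        assert sw.gamma > 1.0
        assert sw.sigma > 1.0

    def test_sigma_lambda_gamma_identity(self, rng):
        a = random_adjacency(rng, 12, 0.4)
        net = net_from(a)
        ens = random_reference(net, m=5, seed=0)
        sw = small_world(net, ens)
        assert sw.sigma * sw.lam == pytest.approx(sw.gamma)


def test_rewire_preserves_degrees_on_many_graphs(rng):
    for _ in range(10):
        a = random_adjacency(rng, 10, 0.4)
        if a.sum() < 4:
            continue
        b = rewire_adjacency(a, np.random.default_rng(0))
        assert np.array_equal(b.sum(axis=0), a.sum(axis=0))
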