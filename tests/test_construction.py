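"""Covariance-network construction and thresholding."""

import numpy as np
import pandas as pd
import pytest

from scnkit.cohort import ResidualTable
from scnkit.construction import (
    BinaryNetwork,
    CovarianceNetwork,
    DensityGrid,
    correlation_network,
    edge_count_for_density,
    min_connected_density,
    threshold_absolute,
    threshold_density,
)

from oracles import bf_components, bf_pearson


def make_residuals(X, groups):
    X = np.asarray(X, dtype=float)
    labels = tuple(f"roi{j}" for j in range(X.shape[1]))
    g = pd.Series(groups)
    return ResidualTable(
        residuals=pd.DataFrame(X, columns=labels),
        model_terms=(),
        roi_labels=labels,
        groups=g,
        group_levels=tuple(pd.unique(g)),
    )


def make_net(r, group="g"):
    r = np.asarray(r, dtype=float)
    return CovarianceNetwork(
        r=r, roi_labels=tuple(f"roi{j}" for j in range(r.shape[0])),
        group=group, n_subjects=10,
    )


class TestDensityGrid:
    def test_default_grid_has_18_points(self):
        grid = DensityGrid()
        assert len(grid) == 18
        assert grid.densities[0] == 0.33
        assert grid.densities[-1] == 0.50
        assert np.allclose(np.diff(grid.densities), 0.01)

    def test_coarse_subgrid_anchors_at_dmin(self):
        assert DensityGrid(0.33, 0.50, 0.08).densities == (0.33, 0.41, 0.49)

    @pytest.mark.parametrize("dmin,dmax,step", [(0, 0.5, 0.1), (0.5, 0.4, 0.1),
                                                (0.3, 0.5, 0), (0.3, 1.2, 0.1)])
    def test_invalid_grids_rejected(self, dmin, dmax, step):
        with pytest.raises(ValueError):
            DensityGrid(dmin, dmax, step)


class TestCorrelationNetwork:
    def test_perfect_and_anti_correlation(self, rng):
        x = rng.normal(size=8)
        X = np.column_stack([x, x, -x])
        net = correlation_network(make_residuals(X, ["a"] * 8), "a")
        assert net.r[0, 1] == pytest.approx(1.0)
        assert net.r[0, 2] == pytest.approx(-1.0)
        assert np.allclose(np.diag(net.r), 1.0)

    def test_matches_direct_pearson_formula(self, rng):
        X = rng.normal(size=(10, 5))
        net = correlation_network(make_residuals(X, ["a"] * 10), "a")
        for i in range(5):
            for j in range(5):
                assert net.r[i, j] == pytest.approx(
                    bf_pearson(X[:, i], X[:, j]), abs=1e-12
                )

    def test_uses_only_requested_group(self, rng):
        X = rng.normal(size=(12, 4))
        groups = ["a"] * 6 + ["b"] * 6
        net = correlation_network(make_residuals(X, groups), "b")
        assert net.n_subjects == 6
        assert net.r[0, 1] == pytest.approx(bf_pearson(X[6:, 0], X[6:, 1]))

    def test_zero_variance_roi_rejected(self, rng):
        X = rng.normal(size=(8, 3))
        X[:, 1] = 5.0
        with pytest.raises(ValueError, match="roi1"):
            correlation_network(make_residuals(X, ["a"] * 8), "a")


class TestThresholdAbsolute:
    def test_all_pass_gives_complete_graph(self):
        r = np.full((5, 5), 0.5)
        np.fill_diagonal(r, 1.0)
        bn = threshold_absolute(make_net(r), 0.1)
        assert bn.n_edges == 10
        assert bn.density == pytest.approx(1.0)

    def test_none_pass_gives_empty_graph(self):
        r = np.full((5, 5), 0.05)
        np.fill_diagonal(r, 1.0)
        bn = threshold_absolute(make_net(r), 0.1)
        assert bn.n_edges == 0

    def test_matches_elementwise_comparison(self, rng):
        r = rng.uniform(-1, 1, size=(4, 4))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        bn = threshold_absolute(make_net(r), 0.1)
        for i in range(4):
            for j in range(4):
                expected = int(i != j and r[i, j] > 0.1)
                assert bn.a[i, j] == expected

    def test_threshold_out_of_range(self):
        with pytest.raises(ValueError):
            threshold_absolute(make_net(np.eye(4)), 1.0)


class TestThresholdDensity:
    def test_aal_scale_edge_count(self, rng):
        r = rng.uniform(0.01, 1, size=(90, 90))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        bn = threshold_density(make_net(r), 0.33)
        assert bn.n_edges == 1322  # round(0.33 * 4005)
        assert edge_count_for_density(0.33, 90) == 1322

    def test_full_density_gives_complete_graph(self, rng):
        r = rng.uniform(0.01, 1, size=(6, 6))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        bn = threshold_density(make_net(r), 1.0)
        assert bn.n_edges == 15

    def test_keeps_top_entries_by_exhaustive_sort(self, rng):
        r = rng.uniform(0.01, 1, size=(6, 6))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        bn = threshold_density(make_net(r), 0.4)
        e = edge_count_for_density(0.4, 6)  # 6 of 15
        pairs = [(i, j) for i in range(6) for j in range(i + 1, 6)]
        top = set(sorted(pairs, key=lambda p: -r[p])[:e])
        assert set(bn.edge_list()) == top

    def test_unreachable_density_rejected(self):
        r = np.full((6, 6), -0.5)
        np.fill_diagonal(r, 1.0)
        r[0, 1] = r[1, 0] = 0.9
        with pytest.raises(ValueError, match="positive"):
            threshold_density(make_net(r), 0.5)

    def test_density_recomputation_is_exact(self, rng):
        r = rng.uniform(0.01, 1, size=(10, 10))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        for d in (0.2, 0.33, 0.5, 0.77):
            bn = threshold_density(make_net(r), d)
            assert bn.density == bn.recompute_density()
            assert bn.n_edges == edge_count_for_density(d, 10)

    def test_monotone_edge_nesting(self, rng):
        r = rng.uniform(-0.2, 1, size=(12, 12))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        net = make_net(r)
        prev = set()
        for d in (0.1, 0.2, 0.3, 0.4, 0.5):
            edges = set(threshold_density(net, d).edge_list())
            assert prev <= edges
            prev = edges

    def test_agrees_with_absolute_at_matching_cutoff(self, rng):
        r = rng.uniform(0.01, 1, size=(8, 8))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        net = make_net(r)
        d = 0.4
        e = edge_count_for_density(d, 8)
        iu, ju = np.triu_indices(8, 1)
        cutoff = np.sort(r[iu, ju])[::-1][e - 1]
        by_density = threshold_density(net, d)
        by_absolute = threshold_absolute(net, cutoff - 1e-12)
        assert np.array_equal(by_density.a, by_absolute.a)


class TestBinaryNetworkInvariants:
    def test_symmetry_enforced(self):
        a = np.zeros((4, 4), dtype=int)
        a[0, 1] = 1
        with pytest.raises(ValueError, match="symmetric"):
            BinaryNetwork(a=a, density=0.1)

    def test_nonzero_diagonal_rejected(self):
        a = np.eye(4, dtype=int)
        with pytest.raises(ValueError, match="diagonal"):
            BinaryNetwork(a=a, density=0.1)


class TestMinConnectedDensity:
    def test_three_node_example(self):
        r = np.array([[1.0, 0.9, 0.8], [0.9, 1.0, 0.1], [0.8, 0.1, 1.0]])
        grid = DensityGrid(1 / 3, 1.0, 1 / 3)
        # one edge leaves a node isolated; two edges connect all three
        assert min_connected_density(make_net(r), grid) == pytest.approx(2 / 3)

    def test_star_structure_connects_at_tree_density(self):
        n = 6
        r = np.full((n, n), 0.01)
        r[0, 1:] = r[1:, 0] = 0.9
        np.fill_diagonal(r, 1.0)
        grid = DensityGrid(0.1, 1.0, 0.05)
        d = min_connected_density(make_net(r), grid)
        # the top N-1 correlations are exactly the star edges, so the network
        # connects at the first grid density supplying at least N-1 edges
        expected = next(g for g in grid if edge_count_for_density(g, n) >= n - 1)
        assert d == expected

    def test_agrees_with_bfs_oracle(self, rng):
        for _ in range(10):
            r = rng.uniform(-0.5, 1, size=(8, 8))
            r = (r + r.T) / 2
            np.fill_diagonal(r, 1.0)
            net = make_net(r)
            grid = DensityGrid(0.1, 1.0, 0.1)
            expected = None
            for d in grid:
                try:
                    bn = threshold_density(net, d)
                except ValueError:
                    continue
                comps = bf_components(bn.a.tolist())
                if len(comps) == 1:
                    expected = d
                    break
            assert min_connected_density(net, grid) == expected

    def test_sentinel_when_never_connected(self):
        r = np.full((6, 6), -0.5)
        np.fill_diagonal(r, 1.0)
        r[0, 1] = r[1, 0] = 0.9
        grid = DensityGrid(0.1, 1.0, 0.1)
        assert min_connected_density(make_net(r), grid) is None
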