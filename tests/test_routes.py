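"""Route communities, ordination, and subnetwork construction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from routesdm.bias import env_variability_index
from routesdm.grid import GridSpec, RouteNetwork, TruthSSDM
from routesdm.routes import (bray_curtis, build_subnetwork, cluster_and_select,
                             hellinger, nmds, route_community, traversed_cells)


def rasterize_route(grid, vertices, step_frac=0.02):
    """Dense-sampling oracle for the cells a polyline passes through."""
    cells = set()
    step = grid.cell_size * step_frac
    for a, b in zip(vertices[:-1], vertices[1:]):
        seg = np.hypot(*(b - a))
        n = max(2, int(np.ceil(seg / step)))
        for t in np.linspace(0, 1, n):
            p = a + t * (b - a)
            r, c = grid.cell_of(p[0], p[1])
            cells.add((int(r), int(c)))
    return cells


class TestRouteCommunity:
    def test_matches_dense_rasterization(self, small_env, small_truth):
        grid = small_env.grid
        rng = np.random.default_rng(5)
        lon, lat = grid.sea_cell_centers()
        for _ in range(10):
            i, j = rng.choice(len(lon), 2, replace=False)
            jitter = rng.uniform(-0.2, 0.2, 4) * grid.cell_size
            verts = np.array([[lon[i] + jitter[0], lat[i] + jitter[1]],
                              [lon[j] + jitter[2], lat[j] + jitter[3]]])
            oracle = rasterize_route(grid, verts, step_frac=0.005)
            exact = {tuple(rc) for rc in traversed_cells(grid, verts)}
            assert exact == oracle
            cm = route_community(RouteNetwork([("r", verts)]), small_truth)
            sea_cells = [rc for rc in oracle if grid.sea_mask[rc]]
            for s, name in enumerate(small_truth.names):
                expect = sum(small_truth.occupancy[s, r, c] for r, c in sea_cells)
                assert cm.loc["r", name] == expect

    def test_three_cell_route_two_occupied(self):
        grid = GridSpec(1, 3, 0.0, 0.0, 1.0, np.ones((1, 3), dtype=bool))
        occ = np.array([[[1, 0, 1]]], dtype=bool)
        truth = TruthSSDM(grid, [("a", "x")], occ)
        net = RouteNetwork([("r", np.array([[0.3, 0.5], [2.7, 0.5]]))])
        assert route_community(net, truth).loc["r", "a"] == 2

    def test_absent_species_zero_column(self, small_env):
        grid = small_env.grid
        occ = np.zeros((1, grid.n_rows, grid.n_cols), dtype=bool)
        truth = TruthSSDM(grid, [("ghost", "x")], occ)
        lon, lat = grid.sea_cell_centers()
        net = RouteNetwork([("r", np.array([[lon[0], lat[0]], [lon[-1], lat[-1]]]))])
        assert (route_community(net, truth)["ghost"] == 0).all()

    def test_corner_touch_not_traversal(self):
        grid = GridSpec(2, 2, 0.0, 0.0, 1.0, np.ones((2, 2), dtype=bool))
        # diagonal through the shared corner (1,1): touches the off-diagonal
        # cells only at that corner point
        verts = np.array([[0.5, 0.5], [1.5, 1.5]])
        cells = {tuple(rc) for rc in traversed_cells(grid, verts)}
        assert (0, 0) in cells and (1, 1) in cells
        assert (0, 1) not in cells and (1, 0) not in cells


class TestHellinger:
    def test_hand_row(self):
        out = hellinger(pd.DataFrame([[1, 1, 2]]))
        np.testing.assert_allclose(out.to_numpy()[0], [0.5, 0.5, 0.70711],
                                   atol=1e-5)

    def test_binary_row(self):
        np.testing.assert_allclose(hellinger(pd.DataFrame([[4, 0]])).to_numpy()[0],
                                   [1.0, 0.0])

    def test_unit_sum_of_squares_and_zero_rows(self):
        m = pd.DataFrame([[3, 1, 0], [0, 0, 0], [2, 2, 2]])
        out = hellinger(m).to_numpy()
        np.testing.assert_allclose((out ** 2).sum(axis=1), [1.0, 0.0, 1.0])

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            hellinger(pd.DataFrame([[1, -1]]))


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        d = bray_curtis(pd.DataFrame([[1, 2], [1, 2]]))
        assert d.iloc[0, 1] == pytest.approx(0.0)

    def test_disjoint_rows_one(self):
        d = bray_curtis(pd.DataFrame([[1, 0], [0, 1]]))
        assert d.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_example(self):
        d = bray_curtis(pd.DataFrame([[1, 1, 0], [0, 1, 1]]))
        assert d.iloc[0, 1] == pytest.approx(0.5)

    def test_zero_row_pair_defined_as_zero(self):
        d = bray_curtis(pd.DataFrame([[0, 0], [0, 0]]))
        assert d.iloc[0, 1] == 0.0

    def test_row_scaling_invariance_through_hellinger(self):
        m = pd.DataFrame([[2, 1, 3], [1, 4, 0], [5, 5, 1]], dtype=float)
        scaled = m.copy()
        scaled.iloc[1] *= 7.0
        d1 = bray_curtis(hellinger(m)).to_numpy()
        d2 = bray_curtis(hellinger(scaled)).to_numpy()
        np.testing.assert_allclose(d1, d2, atol=1e-12)


class TestNMDS:
    def test_equilateral_triangle_embeds_exactly(self):
        d = pd.DataFrame(0.5 * (1 - np.eye(3)))
        assert nmds(d, seed=1).stress <= 1e-3

    def test_recovers_known_planar_configuration(self):
        pts = np.array([[0, 0], [1, 0], [0.2, 1.3], [2.0, 0.7], [1.1, 2.2]])
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        ordn = nmds(pd.DataFrame(d), seed=2, n_starts=10)
        assert ordn.stress <= 1e-3
        coords = ordn.coordinates.to_numpy()
        rec = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        iu = np.triu_indices(5, 1)
        assert stats.spearmanr(rec[iu], d[iu]).statistic == pytest.approx(1.0)
        np.testing.assert_allclose(coords.mean(axis=0), 0.0, atol=1e-9)

    def test_two_routes_zero_stress(self):
        d = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]])
        assert nmds(d, seed=0).stress <= 1e-3

    def test_more_starts_no_worse(self):
        rng = np.random.default_rng(4)
        pts = rng.random((8, 4))
        d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        s1 = nmds(pd.DataFrame(d), seed=5, n_starts=1).stress
        s10 = nmds(pd.DataFrame(d), seed=5, n_starts=10).stress
        assert s10 <= s1 + 1e-12

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            nmds(pd.DataFrame([[0.0, 0.2], [0.3, 0.0]]))


class TestClusterAndSelect:
    def test_all_zero_dissimilarity_single_cluster(self):
        d = pd.DataFrame(np.zeros((4, 4)), index=list("abcd"), columns=list("abcd"))
        assert len(cluster_and_select(d, cut=0.5, seed=0)) == 1

    def test_all_one_dissimilarity_every_route_own_cluster(self):
        d = pd.DataFrame(1 - np.eye(5), index=list("abcde"), columns=list("abcde"))
        assert sorted(cluster_and_select(d, cut=0.5, seed=0)) == list("abcde")

    def test_two_clean_blocks(self):
        names = list("abcdef")
        d = np.full((6, 6), 0.9)
        d[:3, :3] = 0.05
        d[3:, 3:] = 0.05
        np.fill_diagonal(d, 0.0)
        sel = cluster_and_select(pd.DataFrame(d, index=names, columns=names),
                                 cut=0.5, seed=3)
        assert len(sel) == 2
        assert (sel[0] in "abc") != (sel[0] in "def")
        assert sum(s in "abc" for s in sel) == 1 and sum(s in "def" for s in sel) == 1

    def test_deterministic_per_seed(self):
        d = pd.DataFrame(1 - np.eye(6))
        assert cluster_and_select(d, seed=8) == cluster_and_select(d, seed=8)


class TestBuildSubnetwork:
    def test_random_k_full_network(self, small_net):
        sub = build_subnetwork(small_net, "random_k", k=small_net.n_routes, seed=1)
        assert sorted(sub.names) == sorted(small_net.names)

    def test_random_k_subset_size(self, small_net):
        sub = build_subnetwork(small_net, "random_k", k=3, seed=2)
        assert sub.n_routes == 3 and set(sub.names) <= set(small_net.names)

    def test_environment_greedy_set_cover_trace(self, small_env):
        """A route alone spanning all occupied bins is returned by itself;
        otherwise greedy output still covers every occupied bin."""
        from routesdm.routes import route_env_bins
        from routesdm.world import make_routes
        evi = env_variability_index(small_env)
        net = make_routes(small_env, seed=21, n_routes=3, coverage="extremes")
        bins = route_env_bins(net, evi)
        sea_r, sea_c = small_env.grid.sea_indices()
        target = set(evi.bin_of_cells(sea_r, sea_c).tolist())
        assert set().union(*bins.values()) >= target  # extremes guarantee
        sub = build_subnetwork(net, "environment", index=evi, seed=0)
        full = [n for n in net.names if bins[n] >= target]
        if full:
            assert sub.n_routes == 1 and sub.names[0] == full[0]
        covered = set().union(*(bins[n] for n in sub.names))
        assert covered >= target

    def test_environment_infeasible_reports_bins(self, small_env):
        from routesdm.errors import GenerationError
        evi = env_variability_index(small_env)
        # a stub of the grid's first two sea cells cannot span all five bins
        rows, cols = small_env.grid.sea_indices()
        lon, lat = small_env.grid.cell_center(rows[:2], cols[:2])
        stub = RouteNetwork([("stub", np.column_stack([lon, lat]))])
        with pytest.raises(GenerationError, match="bins"):
            build_subnetwork(stub, "environment", index=evi, seed=0)

    def test_biased_strict_subset_with_multiple_clusters(self, default_trio):
        _, truth, net = default_trio
        from routesdm.routes import _clusters
        dis = bray_curtis(hellinger(route_community(net, truth)))
        assert len(_clusters(dis, 0.5)) >= 2  # the default world has structure
        sub = build_subnetwork(net, "biased", truth=truth, seed=0)
        assert 0 < sub.n_routes < net.n_routes
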