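"""Least-cost paths, circuit solves, centrality, barriers and pinch points."""

import numpy as np
import pytest
from shapely.geometry import LineString

from ecolink.connectivity import (
    BarrierResult, CorridorRecord, CostGraph, barrier_scan, circuit_solve,
    composite_priority, cost_weighted_distance, current_centrality,
    least_cost_corridors, pinch_points, quantile_levels,
)
from ecolink.pipeline import resistance_from_bundle
from ecolink.sources import SourcePatch
from conftest import grid_of, patches_from_reserves

SQRT2 = np.sqrt(2.0)


def patch_at(cells, shape, pid=1) -> SourcePatch:
    mask = np.zeros(shape, dtype=bool)
    for r, c in cells:
        mask[r, c] = True
    return SourcePatch(id=pid, mask=mask, area_km2=0.0, centroid=(0.0, 0.0),
                       from_redline=False)


def lattice_edges(res, cell_size, valid=None):
    """Independent 8-neighbour edge list (mean resistance × distance)."""
    nrow, ncol = res.shape
    if valid is None:
        valid = np.ones(res.shape, dtype=bool)
    edges = []
    for r in range(nrow):
        for c in range(ncol):
            if not valid[r, c]:
                continue
            for dr, dc in ((0, 1), (1, -1), (1, 0), (1, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nrow and 0 <= cc < ncol and valid[rr, cc]:
                    dist = cell_size * (SQRT2 if dr and dc else 1.0)
                    edges.append(((r, c), (rr, cc), 0.5 * (res[r, c] + res[rr, cc]) * dist))
    return edges


def bellman_ford_cwd(res, cell_size, source_cells, valid=None):
    """Brute-force multi-source shortest path by repeated edge relaxation."""
    dist = {}
    nrow, ncol = res.shape
    if valid is None:
        valid = np.ones(res.shape, dtype=bool)
    for r in range(nrow):
        for c in range(ncol):
            if valid[r, c]:
                dist[(r, c)] = 0.0 if (r, c) in source_cells else np.inf
    edges = lattice_edges(res, cell_size, valid)
    changed = True
    while changed:
        changed = False
        for a, b, w in edges:
            if dist[a] + w < dist[b] - 1e-12:
                dist[b] = dist[a] + w
                changed = True
            if dist[b] + w < dist[a] - 1e-12:
                dist[a] = dist[b] + w
                changed = True
    return dist


class TestCostWeightedDistance:
    def test_uniform_straight_line(self):
        g = CostGraph(grid_of(np.ones((5, 5)), cell_size=30))
        cwd, _ = cost_weighted_distance(g, patch_at([(2, 0)], (5, 5)))
        assert cwd.values[2, 0] == 0.0
        for n in range(1, 5):
            assert cwd.values[2, n] == pytest.approx(n * 30.0)

    def test_diagonal_neighbor(self):
        g = CostGraph(grid_of(np.ones((3, 3)), cell_size=30))
        cwd, _ = cost_weighted_distance(g, patch_at([(0, 0)], (3, 3)))
        assert cwd.values[1, 1] == pytest.approx(SQRT2 * 30.0)

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(10):
            res = rng.uniform(1, 50, (6, 6))
            src = {(int(rng.integers(6)), int(rng.integers(6)))}
            g = CostGraph(grid_of(res, cell_size=30))
            cwd, _ = cost_weighted_distance(g, patch_at(src, (6, 6)))
            oracle = bellman_ford_cwd(res, 30.0, src)
            for (r, c), d in oracle.items():
                assert cwd.values[r, c] == pytest.approx(d)

    def test_symmetry_of_pair_cost(self, rng):
        res = rng.uniform(1, 50, (7, 7))
        g = CostGraph(grid_of(res, cell_size=30))
        a, b = patch_at([(0, 0)], (7, 7), 1), patch_at([(6, 6)], (7, 7), 2)
        _, da = cost_weighted_distance(g, a)
        _, db = cost_weighted_distance(g, b)
        cost_ab = da[g.node_of[6, 6]]
        cost_ba = db[g.node_of[0, 0]]
        assert cost_ab == pytest.approx(cost_ba)

    def test_patch_outside_grid_errors(self):
        g = CostGraph(grid_of(np.ones((3, 3))))
        with pytest.raises(ValueError):
            cost_weighted_distance(g, patch_at([], (3, 3)))


class TestCorridors:
    def test_uniform_two_patch_straight_corridor(self):
        res = grid_of(np.ones((9, 9)), cell_size=30)
        g = CostGraph(res)
        a = patch_at([(4, 0)], (9, 9), 1)
        b = patch_at([(4, 8)], (9, 9), 2)
        corridors, cwd = least_cost_corridors(g, [a, b])
        assert len(corridors) == 1
        c = corridors[0]
        assert c.lcp_cost == pytest.approx(8 * 30.0)
        # triangle equality on the optimal path: min CWD_A + CWD_B equals lcp_cost
        total = cwd[1] + cwd[2]
        assert total.min() == pytest.approx(c.lcp_cost)
        rows = {r for r, _ in c.path_cells}
        assert rows == {4}  # straight line

    def test_hourglass_lcp_crosses_bridge(self, hourglass):
        res = resistance_from_bundle(hourglass)
        g = CostGraph(res)
        corridors, _ = least_cost_corridors(g, patches_from_reserves(hourglass))
        assert len(corridors) == 1
        bridge_row = hourglass.lulc.shape[0] // 2
        mid_col = hourglass.lulc.shape[1] // 2
        assert (bridge_row, mid_col) in corridors[0].path_cells

    def test_collinear_middle_patch_in_two_corridors(self):
        res = grid_of(np.ones((5, 15)), cell_size=30)
        g = CostGraph(res)
        patches = [patch_at([(2, 0)], (5, 15), 1),
                   patch_at([(2, 7)], (5, 15), 2),
                   patch_at([(2, 14)], (5, 15), 3)]
        corridors, _ = least_cost_corridors(g, patches, pairing="adjacent")
        pairs = {c.pair for c in corridors}
        # the outer pair's lcp runs through the middle patch and is pruned
        assert pairs == {(1, 2), (2, 3)}
        assert sum(2 in p for p in pairs) == 2

    def test_all_pairs_mode_keeps_everything(self):
        res = grid_of(np.ones((5, 15)), cell_size=30)
        g = CostGraph(res)
        patches = [patch_at([(2, 0)], (5, 15), 1),
                   patch_at([(2, 7)], (5, 15), 2),
                   patch_at([(2, 14)], (5, 15), 3)]
        corridors, _ = least_cost_corridors(g, patches, pairing="all")
        assert {c.pair for c in corridors} == {(1, 2), (1, 3), (2, 3)}

    def test_disconnected_pair_skipped(self):
        vals = np.ones((5, 5))
        mask = np.zeros((5, 5), dtype=bool)
        mask[:, 2] = True  # void column disconnects halves
        res = grid_of(vals, nodata_mask=mask)
        g = CostGraph(res)
        a, b = patch_at([(2, 0)], (5, 5), 1), patch_at([(2, 4)], (5, 5), 2)
        with pytest.raises(ValueError):
            # zero corridors -> empty list; pinch analysis then refuses
            corridors, _ = least_cost_corridors(g, [a, b])
            pinch_points({}, corridors)


class TestCircuit:
    def test_series_chain(self):
        # 3 cells in a row, resistance 1, cell size 1: two unit resistors in series
        g = CostGraph(grid_of(np.ones((1, 3)), cell_size=1.0))
        sol = circuit_solve(g, patch_at([(0, 0)], (1, 3), 1), patch_at([(0, 2)], (1, 3), 2))
        assert sol.effective_resistance == pytest.approx(2.0)
        assert sol.current.values[0, 1] == pytest.approx(1.0)
        assert sol.kcl_residual < 1e-10

    def test_two_equal_parallel_paths_halve_resistance(self):
        vals = np.ones((3, 3))
        open_cells = {(1, 0), (0, 1), (2, 1), (1, 2)}
        mask = np.ones((3, 3), dtype=bool)
        for rc in open_cells:
            mask[rc] = False
        both = grid_of(vals, cell_size=1.0, nodata_mask=mask)
        g2 = CostGraph(both)
        a, b = patch_at([(1, 0)], (3, 3), 1), patch_at([(1, 2)], (3, 3), 2)
        r_two = circuit_solve(g2, a, b).effective_resistance

        mask_one = mask.copy()
        mask_one[2, 1] = True  # close the lower path
        g1 = CostGraph(grid_of(vals, cell_size=1.0, nodata_mask=mask_one))
        r_one = circuit_solve(g1, a, b).effective_resistance
        assert r_two == pytest.approx(r_one / 2)
        # each parallel branch carries half the current
        sol = circuit_solve(g2, a, b)
        assert sol.current.values[0, 1] == pytest.approx(0.5)
        assert sol.current.values[2, 1] == pytest.approx(0.5)

    def test_matches_dense_oracle(self, rng):
        for _ in range(5):
            res = rng.uniform(1, 20, (5, 5))
            g = CostGraph(grid_of(res, cell_size=30))
            a_cell, b_cell = (0, 0), (4, 4)
            sol = circuit_solve(g, patch_at([a_cell], (5, 5), 1),
                                patch_at([b_cell], (5, 5), 2))
            # independent dense solve on the same physics
            edges = lattice_edges(res, 30.0)
            idx = {(r, c): r * 5 + c for r in range(5) for c in range(5)}
            L = np.zeros((25, 25))
            for a, b, w in edges:
                gcond = 1.0 / w
                ia, ib = idx[a], idx[b]
                L[ia, ia] += gcond
                L[ib, ib] += gcond
                L[ia, ib] -= gcond
                L[ib, ia] -= gcond
            rhs = np.zeros(25)
            rhs[idx[a_cell]], rhs[idx[b_cell]] = 1.0, -1.0
            pot = np.linalg.pinv(L) @ rhs
            r_eff = pot[idx[a_cell]] - pot[idx[b_cell]]
            assert sol.effective_resistance == pytest.approx(r_eff, rel=1e-9)
            assert sol.kcl_residual < 1e-8

    def test_effective_resistance_bounded_by_lcp(self, rng):
        res = rng.uniform(1, 50, (6, 6))
        g = CostGraph(grid_of(res, cell_size=30))
        a = patch_at([(0, 0)], (6, 6), 1)
        b = patch_at([(5, 5)], (6, 6), 2)
        _, da = cost_weighted_distance(g, a)
        lcp = da[g.node_of[5, 5]]
        r_eff = circuit_solve(g, a, b).effective_resistance
        assert r_eff <= lcp + 1e-9

    def test_disconnected_is_an_error(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[:, 1] = True
        g = CostGraph(grid_of(np.ones((3, 3)), nodata_mask=mask))
        with pytest.raises(ValueError):
            circuit_solve(g, patch_at([(1, 0)], (3, 3), 1), patch_at([(1, 2)], (3, 3), 2))


def dummy_corridor(a, b, cost):
    line = LineString([(0, 0), (1, 1)])
    return CorridorRecord(source_a=a, source_b=b, path_cells=[], polyline=line,
                          lcp_cost=cost, length_km=0.0,
                          swath_mask=np.zeros((1, 1), dtype=bool),
                          buffer_mask=np.zeros((1, 1), dtype=bool))


def dummy_patch(pid):
    return SourcePatch(id=pid, mask=np.zeros((1, 1), dtype=bool), area_km2=1.0,
                       centroid=(0.0, 0.0), from_redline=False)


class TestCentrality:
    def test_line_network_middle_node_highest(self):
        sources = [dummy_patch(i) for i in (1, 2, 3)]
        corridors = [dummy_corridor(1, 2, 10.0), dummy_corridor(2, 3, 10.0)]
        node_cent, link_cent = current_centrality(sources, corridors)
        assert node_cent[2] > node_cent[1]
        assert node_cent[1] == pytest.approx(node_cent[3])
        assert corridors[0].centrality == pytest.approx(corridors[1].centrality)

    def test_symmetric_cycle_links_equal(self):
        sources = [dummy_patch(i) for i in (1, 2, 3, 4)]
        corridors = [dummy_corridor(1, 2, 5.0), dummy_corridor(2, 3, 5.0),
                     dummy_corridor(3, 4, 5.0), dummy_corridor(1, 4, 5.0)]
        _, link_cent = current_centrality(sources, corridors)
        vals = list(link_cent.values())
        assert np.allclose(vals, vals[0])

    def test_two_components_handled_separately(self):
        sources = [dummy_patch(i) for i in (1, 2, 3, 4)]
        corridors = [dummy_corridor(1, 2, 5.0), dummy_corridor(3, 4, 7.0)]
        node_cent, link_cent = current_centrality(sources, corridors)
        assert all(np.isfinite(v) for v in node_cent.values())
        assert link_cent[(1, 2)] == pytest.approx(1.0)
        assert link_cent[(3, 4)] == pytest.approx(1.0)

    def test_single_node_error(self):
        with pytest.raises(ValueError):
            current_centrality([dummy_patch(1)], [])


class TestPinchPoints:
    def test_hourglass_bridge_is_rank_one(self, hourglass):
        res = resistance_from_bundle(hourglass)
        g = CostGraph(res)
        patches = patches_from_reserves(hourglass)
        corridors, _ = least_cost_corridors(g, patches)
        sol = circuit_solve(g, patches[0], patches[1])
        points, _ = pinch_points({corridors[0].pair: sol.current}, corridors, top_n=5)
        top = points[0]
        bridge_row = hourglass.lulc.shape[0] // 2
        ncol = hourglass.lulc.shape[1]
        assert top.cell[0] == bridge_row
        assert ncol // 3 <= top.cell[1] < 2 * ncol // 3
        # the single-cell bridge carries the full injected current
        assert top.score == pytest.approx(1.0, abs=1e-8)

    def test_top_n_one(self, hourglass):
        res = resistance_from_bundle(hourglass)
        g = CostGraph(res)
        patches = patches_from_reserves(hourglass)
        corridors, _ = least_cost_corridors(g, patches)
        sol = circuit_solve(g, patches[0], patches[1])
        points, _ = pinch_points({corridors[0].pair: sol.current}, corridors, top_n=1)
        assert len(points) == 1

    def test_points_respect_suppression_radius(self, wall):
        res = resistance_from_bundle(wall)
        g = CostGraph(res)
        patches = patches_from_reserves(wall)
        corridors, _ = least_cost_corridors(g, patches)
        sol = circuit_solve(g, patches[0], patches[1])
        points, _ = pinch_points({corridors[0].pair: sol.current}, corridors,
                                 top_n=10, nms_radius_m=300.0)
        cells = [p.cell for p in points]
        for i, a in enumerate(cells):
            for b in cells[i + 1:]:
                assert np.hypot(a[0] - b[0], a[1] - b[1]) * res.cell_size >= 300.0


class TestBarriers:
    def test_uniform_minimum_landscape_has_zero_improvement(self):
        res = grid_of(np.ones((20, 30)), cell_size=100)
        g = CostGraph(res)
        a = patch_at([(10, 1)], (20, 30), 1)
        b = patch_at([(10, 28)], (20, 30), 2)
        corridors, cwd = least_cost_corridors(g, [a, b])
        barriers, is_grid = barrier_scan(g, corridors, cwd,
                                         r_min_m=200, r_max_m=600)
        assert np.nanmax(is_grid.values) == pytest.approx(0.0, abs=1e-9)
        assert barriers == []

    def test_wall_top_barrier_on_wall_matches_transect(self, wall):
        res = resistance_from_bundle(wall)
        g = CostGraph(res)
        patches = patches_from_reserves(wall)
        corridors, cwd = least_cost_corridors(g, patches)
        assert len(corridors) == 1
        lcp_cost = corridors[0].lcp_cost
        barriers, is_grid = barrier_scan(g, corridors, cwd,
                                         r_min_m=200, r_max_m=1000)
        top = barriers[0]
        cs = res.cell_size
        # the top restoration window must overlap the wall
        urban_cols = np.nonzero(res.values[0] > res.values[0].min())[0]
        k_top = int(round(top.radius_m / cs))
        assert top.cell[1] - k_top <= urban_cols.max()
        assert top.cell[1] + k_top >= urban_cols.min()

        # 1-D transect prediction along the corridor row: the best window
        # score over all centres and radii (the 2-D scan ties along a
        # plateau of centres whose window spans the wall)
        row = corridors[0].path_cells[len(corridors[0].path_cells) // 2][0]
        transect = res.values[row]
        a_edge = np.nonzero(patches[0].mask[row])[0].max()
        b_edge = np.nonzero(patches[1].mask[row])[0].min()

        def cwd_from(edge, col, direction):
            cols = range(edge, col, direction)
            return sum(0.5 * (transect[i] + transect[i + direction]) * cs for i in cols)

        r_min_land = res.valid_values.min()
        best = 0.0
        for center in range(a_edge + 1, b_edge):
            for k in range(int(np.ceil(200 / cs)), int(1000 // cs) + 1):
                r = k * cs
                min_a = cwd_from(a_edge, max(center - k, a_edge), +1)
                min_b = cwd_from(b_edge, min(center + k, b_edge), -1)
                restored = min_a + min_b + 2 * r * r_min_land
                best = max(best, (lcp_cost - restored) / (2 * r))
        assert top.score == pytest.approx(best, rel=1e-9)

    def test_radius_below_cell_size_rejected(self):
        g = CostGraph(grid_of(np.ones((5, 5)), cell_size=300))
        with pytest.raises(ValueError):
            barrier_scan(g, [], {}, r_min_m=200, r_max_m=1000)


class TestMonotonicity:
    def test_lowering_resistance_never_hurts(self, rng):
        res0 = rng.uniform(1, 100, (10, 10))
        shape = res0.shape
        a = patch_at([(0, 0)], shape, 1)
        b = patch_at([(9, 9)], shape, 2)

        def metrics(res):
            g = CostGraph(grid_of(res, cell_size=30))
            _, da = cost_weighted_distance(g, a)
            lcp = da[g.node_of[9, 9]]
            r_eff = circuit_solve(g, a, b).effective_resistance
            return lcp, r_eff

        lcp0, reff0 = metrics(res0)
        for _ in range(8):
            res = res0.copy()
            r, c = rng.integers(10), rng.integers(10)
            res[r, c] *= rng.uniform(0.1, 1.0)
            lcp, reff = metrics(res)
            assert lcp <= lcp0 + 1e-9
            assert reff <= reff0 + 1e-9


class TestPrioritization:
    def test_quantile_levels_two_per_class(self):
        levels = quantile_levels([1, 2, 3, 4, 5, 6, 7, 8])
        assert levels == ["L", "L", "M", "M", "H", "H", "V", "V"]

    def test_single_score_is_low(self):
        assert quantile_levels([3.0]) == ["L"]

    def test_composite_cross_tab(self):
        corridors = [dummy_corridor(1, 2, 1.0), dummy_corridor(3, 4, 2.0)]
        corridors[0].improvement_level = "V"
        corridors[0].priority_level = "V"
        corridors[1].improvement_level = "L"
        corridors[1].priority_level = "H"
        labels = composite_priority(corridors)
        assert labels[(1, 2)] == "V&V"
        assert labels[(3, 4)] == "L&H"

    def test_composite_requires_levels(self):
        with pytest.raises(ValueError):
            composite_priority([dummy_corridor(1, 2, 1.0)])
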