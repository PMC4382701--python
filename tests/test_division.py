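"""Division clock, orientation axes and geometric cell splitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pitchersim.division import (check_divisions, division_rate,
                                 execute_division, long_axis, morphogen_axis,
                                 split_cell)
from pitchersim.errors import DivisionError
from pitchersim.mesh import (LAYER_L1, CellStates, TissueMesh, audit_topology,
                             classify_layers)
from pitchersim.params import ClockParams
from conftest import make_onion_mesh, states_for


class TestClock:
    def test_rate_without_morphogen_is_baseline(self):
        assert division_rate(0.0, 1.0) == pytest.approx(1.0)

    def test_rate_saturates_at_P0_plus_P(self):
        assert division_rate(100.0, 100.0) == pytest.approx(21.0, rel=1e-6)

    def test_rate_at_half_saturation(self):
        """Each Hill factor equals 1/2 at its half-saturation constant."""
        p = ClockParams()
        assert division_rate(p.u0, p.S0, p) == pytest.approx(
            p.P0 + p.P / 4, rel=1e-12)  # 6.0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            division_rate(-0.1, 1.0)

    def test_threshold_strict_inequality(self, onion_mesh):
        states = states_for(onion_mesh, adaxial=[25])
        states.clock[:] = 0.0
        states.threshold[:] = 100.0
        inner = int(np.flatnonzero(states.layer != LAYER_L1)[0])
        states.clock[inner] = 100.0  # equal: must NOT divide
        assert check_divisions(onion_mesh, states) == []
        states.clock[inner] = 100.0 + 1e-9
        assert check_divisions(onion_mesh, states) == [inner]

    def test_epidermal_trigger_at_six_edges(self, onion_mesh):
        """An L1 cell with 5 edges is quiet; at 6 edges it is queued."""
        states = states_for(onion_mesh, adaxial=[25])
        states.clock[:] = 0.0
        l1 = int(np.flatnonzero(states.layer == LAYER_L1)[0])
        assert len(onion_mesh.cells[l1]) == 4
        assert l1 not in check_divisions(onion_mesh, states)
        # split the inner neighbour so the L1 cell gains vertices, up to 6
        rng = np.random.default_rng(0)
        while len(onion_mesh.cells[l1]) < 6:
            nbrs = [c for c in onion_mesh.cell_neighbors(l1)
                    if states.layer[c] != LAYER_L1]
            before = len(onion_mesh.cells[l1])
            ev = execute_division(onion_mesh, states, nbrs[0], "hollow", rng)
            assert ev is not None
            classify_layers(onion_mesh, states)
            if len(onion_mesh.cells[l1]) == 5:
                assert l1 not in check_divisions(onion_mesh, states)
        assert l1 in check_divisions(onion_mesh, states)


class TestLongAxis:
    def test_rectangle_long_axis_is_x(self):
        pts = np.array([[-2., -1], [2, -1], [2, 1], [-2, 1]])
        theta, degenerate = long_axis(pts)
        assert not degenerate
        assert theta == pytest.approx(0.0, abs=1e-12)

    def test_square_is_degenerate(self):
        pts = np.array([[-1., -1], [1, -1], [1, 1], [-1, 1]])
        _, degenerate = long_axis(pts)
        assert degenerate

    def test_matches_grid_scan_on_random_hexagons(self):
        """Closed form vs brute-force minimisation of R(theta) on a grid."""
        rng = np.random.default_rng(42)
        grid = np.arange(0.0, np.pi, 1e-4)
        for _ in range(50):
            ang = np.sort(rng.uniform(0, 2 * np.pi, 6))
            r = rng.uniform(0.5, 2.0, 6)
            pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
            c = pts.mean(axis=0)
            theta, degenerate = long_axis(pts)
            if degenerate:
                continue
            d = pts - c
            # R(t) = sum of squared distances to the line at angle t
            R = (np.sin(grid)[:, None] * d[:, 0]
                 - np.cos(grid)[:, None] * d[:, 1]) ** 2
            t_best = grid[np.argmin(R.sum(axis=1))]
            diff = abs(theta - t_best)
            assert min(diff, np.pi - diff) < 1e-4 + 1e-9


class TestMorphogenAxis:
    def test_two_sided_equal_concentration_is_horizontal(self):
        x_c = np.zeros(2)
        r_k = np.array([[-1.0, 0.0], [1.0, 0.0]])
        theta, degenerate = morphogen_axis(x_c, np.array([1.0, 1.0]), r_k)
        assert not degenerate
        assert theta == pytest.approx(0.0, abs=1e-12)

    def test_gradient_across_hexagon_orients_axis(self):
        """Concentrations graded bottom-to-top align the axis with the
        gradient (vertical) to within 5 degrees, matching a grid scan."""
        ang = np.pi / 3 * np.arange(6)
        r_k = np.column_stack([np.cos(ang), np.sin(ang)])
        z_k = np.exp(0.8 * r_k[:, 1])  # higher towards +y
        theta, degenerate = morphogen_axis(np.zeros(2), z_k, r_k)
        assert not degenerate
        assert abs(np.degrees(theta) - 90.0) < 5.0
        # brute-force check on the s_k point set
        s = z_k[:, None] * r_k
        grid = np.arange(0.0, np.pi, 1e-4)
        d = s - s.mean(axis=0)
        R = (np.sin(grid)[:, None] * d[:, 0]
             - np.cos(grid)[:, None] * d[:, 1]) ** 2
        t_best = grid[np.argmin(R.sum(axis=1))]
        diff = abs(theta - t_best)
        assert min(diff, np.pi - diff) < 1e-4 + 1e-9

    def test_uniform_on_regular_hexagon_degenerate(self):
        ang = np.pi / 3 * np.arange(6)
        r_k = np.column_stack([np.cos(ang), np.sin(ang)])
        _, degenerate = morphogen_axis(np.zeros(2), np.ones(6), r_k)
        assert degenerate

    def test_all_zero_concentration_raises(self):
        r_k = np.array([[-1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(DivisionError):
            morphogen_axis(np.zeros(2), np.zeros(3), r_k)


class TestSplitCell:
    def _square_mesh(self):
        mesh = TissueMesh(np.array([[0., 0], [1, 0], [1, 1], [0, 1]]),
                          [[0, 1, 2, 3]])
        states = CellStates.zeros(1)
        classify_layers(mesh, states)
        return mesh, states

    def test_vertical_bisection_of_unit_square(self):
        mesh, states = self._square_mesh()
        rng = np.random.default_rng(0)
        ev = split_cell(mesh, states, 0, np.array([0.5, 0.5]),
                        np.array([0.0, 1.0]), rng)
        areas = mesh.cell_areas()
        assert mesh.n_cells == 2
        assert areas == pytest.approx([0.5, 0.5], abs=1e-12)
        audit_topology(mesh)

    def test_daughters_partition_parent(self):
        mesh, states = self._square_mesh()
        rng = np.random.default_rng(1)
        split_cell(mesh, states, 0, np.array([0.3, 0.5]),
                   np.array([0.3, 1.0]), rng)
        assert mesh.cell_areas().sum() == pytest.approx(1.0, abs=1e-9)

    def test_line_missing_polygon_raises(self):
        mesh, states = self._square_mesh()
        rng = np.random.default_rng(0)
        with pytest.raises(DivisionError):
            split_cell(mesh, states, 0, np.array([5.0, 0.5]),
                       np.array([0.0, 1.0]), rng)

    def test_grazing_vertex_raises(self):
        mesh, states = self._square_mesh()
        rng = np.random.default_rng(0)
        with pytest.raises(DivisionError):
            split_cell(mesh, states, 0, np.array([0.0, 0.0]),
                       np.array([1.0, 1.0]), rng)

    def test_daughters_reset_clock_and_redraw_threshold(self):
        mesh, states = self._square_mesh()
        states.clock[0] = 123.0
        rng = np.random.default_rng(2)
        p = ClockParams(C=100.0)
        ev = split_cell(mesh, states, 0, np.array([0.5, 0.5]),
                        np.array([0.0, 1.0]), rng, params=p)
        for d in ev.daughters:
            assert states.clock[d] == 0.0
            assert 90.0 <= states.threshold[d] <= 110.0

    def test_split_updates_neighbour_cycles(self):
        # stretched 10-sector onion: the hub's long axis is x, and the
        # perpendicular division line passes between hub vertices
        mesh = make_onion_mesh(n_rings=4, n_sectors=10)
        mesh.vertices[:, 0] *= 1.3
        states = states_for(mesh, adaxial=[21])
        rng = np.random.default_rng(3)
        total_before = mesh.cell_areas().sum()
        ev = execute_division(mesh, states, 0, "hollow", rng)
        assert ev is not None and ev.mode == "long-axis"
        audit_topology(mesh)
        assert mesh.cell_areas().sum() == pytest.approx(total_before,
                                                        abs=1e-9)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_random_convex_polygon_split_conserves_area(self, seed):
        """Any executed split partitions the parent area to 1e-9 and
        leaves a valid topology."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        ang = np.sort(rng.uniform(0, 2 * np.pi, n))
        if np.min(np.diff(ang)) < 0.15:
            return  # avoid near-duplicate vertices
        r = rng.uniform(0.8, 1.6, n)
        pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)])
        mesh = TissueMesh(pts, [list(range(n))])
        states = CellStates.zeros(1)
        classify_layers(mesh, states)
        parent_area = mesh.cell_areas()[0]
        theta = rng.uniform(0, np.pi)
        try:
            split_cell(mesh, states, 0, pts.mean(axis=0),
                       np.array([np.cos(theta), np.sin(theta)]), rng)
        except DivisionError:
            return  # grazing/sliver rejections are allowed
        assert mesh.n_cells == 2
        assert mesh.cell_areas().sum() == pytest.approx(parent_area, abs=1e-9)
        audit_topology(mesh)


class TestEpidermalRule:
    def test_six_edge_epidermal_division_restores_four_neighbours(self):
        """Executing the epidermal rule on a six-edge L1 cell yields two
        five-edge daughters with four neighbours each."""
        mesh = make_onion_mesh(n_rings=4, n_sectors=10)
        states = states_for(mesh, adaxial=[25])
        rng = np.random.default_rng(0)
        l1 = int(np.flatnonzero(states.layer == LAYER_L1)[0])
        guard = 0
        while len(mesh.cells[l1]) < 6 and guard < 10:
            nbrs = [c for c in mesh.cell_neighbors(l1)
                    if states.layer[c] != LAYER_L1]
            execute_division(mesh, states, nbrs[0], "hollow", rng)
            classify_layers(mesh, states)
            guard += 1
        assert len(mesh.cells[l1]) == 6
        ev = execute_division(mesh, states, l1, "hollow", rng)
        assert ev is not None and ev.mode == "epidermal"
        for d in ev.daughters:
            assert len(set(mesh.cell_neighbors(d))) == 4
        audit_topology(mesh)
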