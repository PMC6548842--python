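import numpy as np
import pytest

from plotalign.energy import (
    GridCostFunction,
    cell_energies,
    grid_cost,
    grid_cost_hard_limited,
    grid_cost_intra_only,
    inter_cell_energy,
    intra_cell_energy,
    net_cell_energy,
    overlap_region,
)
from plotalign.grid_model import Cell, DisplacementField, make_uniform_grid
from plotalign.scalar_field import build_summed_area_table

from .conftest import random_instance
from .oracle import oracle_energies, oracle_grid_cost, rect_sum_loops


def _cell(u, v, W=4, H=4):
    return Cell(p=1, q=1, u=u, v=v, W=W, H=H)


class TestIntraCellEnergy:
    def test_uniform_field_gives_area_times_value(self):
        sat = build_summed_area_table(np.full((30, 30), 0.25))
        cell = _cell(15, 15, W=6, H=4)
        assert intra_cell_energy(sat, cell) == pytest.approx(0.25 * 24)

    def test_zero_field_gives_zero_for_any_displacement(self, rng):
        sat = build_summed_area_table(np.zeros((20, 20)))
        cell = _cell(10, 10)
        for _ in range(5):
            delta = tuple(rng.uniform(-5, 5, 2))
            assert intra_cell_energy(sat, cell, delta) == 0.0

    def test_matches_double_loop_oracle(self, rng):
        values = rng.uniform(-1, 1, size=(20, 20))
        sat = build_summed_area_table(values)
        cell = _cell(10, 9, W=6, H=4)
        for _ in range(5):
            du, dv = rng.uniform(-4, 4, 2)
            x1 = int(np.rint(cell.u + du - cell.W / 2))
            y1 = int(np.rint(cell.v + dv - cell.H / 2))
            expected = rect_sum_loops(values, x1, y1, x1 + 6, y1 + 4)
            assert intra_cell_energy(sat, cell, (du, dv)) == pytest.approx(expected)

    def test_outside_portion_contributes_zero(self):
        sat = build_summed_area_table(np.ones((10, 10)))
        cell = _cell(0, 5, W=6, H=4)  # half the cell hangs off the left edge
        assert intra_cell_energy(sat, cell) == pytest.approx(3 * 4)


class TestOverlapRegion:
    def test_identical_cells_full_overlap(self):
        a = _cell(10, 10)
        ov = overlap_region(a, (1.0, 2.0), a, (1.0, 2.0))
        assert not ov.empty and ov.area == 16

    def test_distant_cells_empty(self):
        ov = overlap_region(_cell(10, 10), (0, 0), _cell(18, 10), (0, 0))
        assert ov.empty and ov.area == 0

    def test_partial_horizontal_overlap(self):
        ov = overlap_region(_cell(10, 10), (0, 0), _cell(12, 10), (0, 0))
        assert (ov.x2 - ov.x1, ov.y2 - ov.y1) == (2, 4)

    def test_empty_iff_degenerate_edges(self):
        ov = overlap_region(_cell(10, 10), (0, 0), _cell(14, 10), (0, 0))
        assert ov.empty and ov.x1 >= ov.x2  # touching edges do not overlap


class TestInterCellEnergy:
    def test_zero_without_overlap(self, small_grid, random_sat):
        disp = DisplacementField.zeros(3, 3)
        d, _, _ = cell_energies(random_sat, small_grid, disp)
        assert inter_cell_energy(random_sat, small_grid, disp, 2, 2, d) == 0.0

    def test_equal_neighbors_split_overlap_in_half(self):
        # two cells over a uniform field, pushed together to overlap by 2 px
        values = np.full((20, 30), 0.5)
        sat = build_summed_area_table(values)
        grid = make_uniform_grid(1, 2, 6, 6, origin=(8, 10), pitch_u=8)
        disp = DisplacementField(
            du=np.array([[2.0, -2.0]]), dv=np.zeros((1, 2)), bound_u=2, bound_v=2
        )
        d, g, _ = cell_energies(sat, grid, disp)
        overlap_energy = 0.5 * 2 * 6  # S * 2 px x 6 px
        assert d[0, 0] == pytest.approx(d[0, 1])
        assert g[0, 0] == pytest.approx(overlap_energy / 2)
        assert g[0, 0] + g[0, 1] == pytest.approx(overlap_energy)

    def test_matches_term_by_term_oracle(self, rng):
        for _ in range(10):
            values, grid, disp = random_instance(rng)
            sat = build_summed_area_table(values)
            d, g, f = cell_energies(sat, grid, disp)
            d_o, g_o, f_o = oracle_energies(values, grid, disp.du, disp.dv)
            np.testing.assert_allclose(d, d_o, atol=1e-9)
            np.testing.assert_allclose(g, g_o, atol=1e-9)
            np.testing.assert_allclose(f, f_o, atol=1e-12)

    def test_bare_soil_pair_contributes_nothing(self):
        sat = build_summed_area_table(np.zeros((20, 30)))
        grid = make_uniform_grid(1, 2, 6, 6, origin=(8, 10), pitch_u=8)
        disp = DisplacementField(
            du=np.array([[2.0, -2.0]]), dv=np.zeros((1, 2)), bound_u=2, bound_v=2
        )
        d, g, _ = cell_energies(sat, grid, disp)
        assert np.all(d == 0) and np.all(g == 0)


class TestNetEnergyAndCost:
    @pytest.mark.parametrize(
        "d, g, W, H, expected",
        [(5.0, 5.0, 3, 2, 0.0), (24.0, 0.0, 6, 4, 1.0), (10.0, 4.0, 3, 2, 1.0)],
    )
    def test_net_energy_examples(self, d, g, W, H, expected):
        assert net_cell_energy(d, g, W, H) == pytest.approx(expected)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            net_cell_energy(1.0, 0.0, 0, 5)

    def test_zero_field_cost_is_one(self, small_grid):
        sat = build_summed_area_table(np.zeros((40, 40)))
        assert grid_cost(sat, small_grid, DisplacementField.zeros(3, 3)) == 1.0

    def test_unit_field_nonoverlapping_cost_is_exp_minus_one(self, small_grid):
        sat = build_summed_area_table(np.ones((40, 40)))
        cost = grid_cost(sat, small_grid, DisplacementField.zeros(3, 3))
        assert cost == pytest.approx(np.exp(-1.0), rel=1e-12)

    def test_cost_matches_oracle(self, rng):
        for _ in range(10):
            values, grid, disp = random_instance(rng)
            sat = build_summed_area_table(values)
            expected = oracle_grid_cost(values, grid, disp.du, disp.dv)
            assert grid_cost(sat, grid, disp) == pytest.approx(expected, rel=1e-9)


class TestIntraOnlyCost:
    def test_equals_full_cost_without_overlap(self, small_grid, random_sat):
        disp = DisplacementField.zeros(3, 3)
        assert grid_cost_intra_only(random_sat, small_grid, disp) == pytest.approx(
            grid_cost(random_sat, small_grid, disp)
        )

    def test_at_most_full_cost_on_nonnegative_field(self, rng):
        values = rng.uniform(0, 1, size=(50, 50))
        sat = build_summed_area_table(values)
        grid = make_uniform_grid(2, 2, 8, 8, origin=(15, 15), pitch_u=10, pitch_v=10)
        disp = DisplacementField(
            du=np.array([[3.0, -3.0], [3.0, -3.0]]),
            dv=np.array([[3.0, 3.0], [-3.0, -3.0]]),
            bound_u=5, bound_v=5,
        )
        assert grid_cost_intra_only(sat, grid, disp) <= grid_cost(sat, grid, disp)

    def test_matches_oracle_with_g_zeroed(self, rng):
        values, grid, disp = random_instance(rng)
        sat = build_summed_area_table(values)
        expected = oracle_grid_cost(values, grid, disp.du, disp.dv, intra_only=True)
        assert grid_cost_intra_only(sat, grid, disp) == pytest.approx(expected, rel=1e-9)


class TestHardLimitedVariant:
    def test_infinite_on_overlap_else_intra_only(self, rng):
        values = rng.uniform(0, 1, size=(40, 40))
        sat = build_summed_area_table(values)
        grid = make_uniform_grid(1, 2, 6, 6, origin=(10, 20), pitch_u=8)
        apart = DisplacementField.zeros(1, 2)
        together = DisplacementField(
            du=np.array([[2.0, -2.0]]), dv=np.zeros((1, 2)), bound_u=2, bound_v=2
        )
        assert grid_cost_hard_limited(sat, grid, apart) == pytest.approx(
            grid_cost_intra_only(sat, grid, apart)
        )
        assert grid_cost_hard_limited(sat, grid, together) == float("inf")


class TestCostProperties:
    def test_overlap_share_conservation(self, rng):
        """For every overlapping neighbor pair the two attributed shares sum
        exactly to the pair's overlap energy."""
        from plotalign.energy import _pixel_rect
        from plotalign.scalar_field import rect_sums

        checked = 0
        for _ in range(30):
            values, grid, disp = random_instance(rng)
            sat = build_summed_area_table(values)
            d, _, _ = cell_energies(sat, grid, disp)
            from plotalign.grid_model import grid_edges

            for (p, q), (pp, qq) in grid_edges(grid.P, grid.Q):
                a, b = (p - 1, q - 1), (pp - 1, qq - 1)
                x1, y1, x2, y2 = _pixel_rect(
                    grid.centers_u, grid.centers_v, grid.cell_w, grid.cell_h,
                    disp.du, disp.dv,
                )
                ox1, oy1 = max(x1[a], x1[b]), max(y1[a], y1[b])
                ox2, oy2 = min(x2[a], x2[b]), min(y2[a], y2[b])
                if ox1 >= ox2 or oy1 >= oy2 or d[a] + d[b] == 0:
                    continue
                shared = float(rect_sums(sat, ox1, oy1, ox2, oy2))
                share_a = d[b] / (d[a] + d[b]) * shared
                share_b = d[a] / (d[a] + d[b]) * shared
                assert share_a + share_b == pytest.approx(shared, abs=1e-9)
                checked += 1
        assert checked > 0

    def test_translation_equivariance(self, rng):
        values = rng.uniform(-1, 1, size=(60, 60))
        shift = (7, 4)  # (du, dv) integer pixels
        shifted = np.zeros_like(values)
        shifted[shift[1]:, shift[0]:] = values[: -shift[1], : -shift[0]]
        grid_a = make_uniform_grid(2, 2, 6, 6, origin=(15, 15), pitch_u=10, pitch_v=10)
        grid_b = make_uniform_grid(
            2, 2, 6, 6, origin=(15 + shift[0], 15 + shift[1]), pitch_u=10, pitch_v=10
        )
        disp = DisplacementField(
            du=rng.uniform(-3, 3, (2, 2)), dv=rng.uniform(-3, 3, (2, 2)),
            bound_u=3, bound_v=3,
        )
        cost_a = grid_cost(build_summed_area_table(values), grid_a, disp)
        cost_b = grid_cost(build_summed_area_table(shifted), grid_b, disp)
        assert cost_a == pytest.approx(cost_b, rel=1e-12)

    def test_adding_overlap_never_decreases_cost_on_nonnegative_field(self):
        values = np.ones((40, 60))
        sat = build_summed_area_table(values)
        grid = make_uniform_grid(1, 2, 8, 8, origin=(15, 20), pitch_u=10)
        costs = []
        for push in [0.0, 1.0, 2.0, 3.0]:
            disp = DisplacementField(
                du=np.array([[push, -push]]), dv=np.zeros((1, 2)), bound_u=4, bound_v=4
            )
            costs.append(grid_cost(sat, grid, disp))
        assert all(c2 >= c1 - 1e-12 for c1, c2 in zip(costs, costs[1:]))


class TestBatchCostFunction:
    def test_batch_matches_scalar_costs(self, rng):
        values, grid, disp = random_instance(rng)
        sat = build_summed_area_table(values)
        cf = GridCostFunction(sat, grid)
        n = grid.P * grid.Q
        batch = rng.uniform(-2, 2, size=(7, 2 * n))
        out = cf(batch)
        for k in range(7):
            d = DisplacementField.from_flat(batch[k], grid.P, grid.Q, 2, 2)
            assert out[k] == pytest.approx(grid_cost(sat, grid, d), rel=1e-12)

    def test_rejects_wrong_width(self, random_sat, small_grid):
        cf = GridCostFunction(random_sat, small_grid)
        with pytest.raises(ValueError):
            cf(np.zeros((3, 5)))
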