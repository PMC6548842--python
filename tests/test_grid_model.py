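import numpy as np
import pytest

from plotalign.grid_model import (
    DisplacementField,
    apply_displacements,
    assign_plot_sequence,
    export_shapefile,
    grid_edges,
    import_grid,
    make_uniform_grid,
    neighbors,
    resample_to_grid_frame,
    transform_grid,
)
from plotalign.scalar_field import GeoTransform, ScalarField


class TestUniformGrid:
    def test_single_cell_at_origin(self):
        g = make_uniform_grid(1, 1, 10, 20, origin=(5.0, 7.0))
        cell = g.cell(1, 1)
        assert (cell.u, cell.v) == (5.0, 7.0)
        assert (cell.W, cell.H) == (10, 20)

    @pytest.mark.parametrize("P, Q, n", [(5, 12, 60), (48, 12, 576)])
    def test_trial_layout_cell_counts(self, P, Q, n):
        g = make_uniform_grid(P, Q, 150, 500, pitch_u=200, pitch_v=600)
        assert g.n_cells == n
        assert len(list(g.cells())) == n

    def test_center_lattice(self):
        g = make_uniform_grid(2, 3, 4, 4, origin=(10, 20), pitch_u=7, pitch_v=9)
        assert g.cell(2, 3).u == 10 + 2 * 7
        assert g.cell(2, 3).v == 20 + 1 * 9

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            make_uniform_grid(0, 3, 4, 4)
        with pytest.raises(ValueError):
            make_uniform_grid(2, 3, -1, 4)


class TestTransforms:
    def test_translate_identity(self, small_grid):
        g = transform_grid(small_grid, "translate", du=0.0, dv=0.0)
        np.testing.assert_array_equal(g.centers_u, small_grid.centers_u)

    def test_full_rotation_restores_positions(self, small_grid):
        g = transform_grid(small_grid, "rotate", angle_deg=360.0)
        iu, iv = g.grid_to_image(g.centers_u, g.centers_v)
        np.testing.assert_allclose(iu, small_grid.centers_u, atol=1e-9)
        np.testing.assert_allclose(iv, small_grid.centers_v, atol=1e-9)

    def test_translations_compose(self, small_grid):
        a = transform_grid(small_grid, "translate", du=3.0, dv=-2.0)
        ab = transform_grid(a, "translate", du=-1.5, dv=4.0)
        direct = transform_grid(small_grid, "translate", du=1.5, dv=2.0)
        np.testing.assert_allclose(ab.centers_u, direct.centers_u)
        np.testing.assert_allclose(ab.centers_v, direct.centers_v)

    def test_scale_resizes_cells_only(self, small_grid):
        g = transform_grid(small_grid, "scale", cell_w=9.0, cell_h=3.0)
        assert (g.cell_w, g.cell_h) == (9.0, 3.0)
        np.testing.assert_array_equal(g.centers_u, small_grid.centers_u)
        with pytest.raises(ValueError):
            transform_grid(small_grid, "scale", cell_w=0, cell_h=3)

    def test_shift_margin_changes_pitch_not_size(self, small_grid):
        g = transform_grid(small_grid, "shift_margin", pitch_u=12.0, pitch_v=11.0)
        assert (g.cell_w, g.cell_h) == (small_grid.cell_w, small_grid.cell_h)
        assert g.cell(1, 2).u - g.cell(1, 1).u == pytest.approx(12.0)
        assert g.cell(1, 1).u == small_grid.cell(1, 1).u  # anchor fixed

    def test_transforms_preserve_layout(self, small_grid):
        g = small_grid
        for op, kw in [
            ("translate", dict(du=5, dv=5)),
            ("rotate", dict(angle_deg=17)),
            ("shift_margin", dict(pitch_u=8, pitch_v=8)),
        ]:
            g = transform_grid(g, op, **kw)
        assert (g.P, g.Q) == (small_grid.P, small_grid.Q)
        assert (g.cell_w, g.cell_h) == (small_grid.cell_w, small_grid.cell_h)


class TestNeighbors:
    def test_corner_side_interior(self):
        assert neighbors(1, 1, 5, 12) == {(2, 1), (1, 2)}
        assert neighbors(1, 6, 5, 12) == {(1, 5), (1, 7), (2, 6)}
        assert neighbors(3, 6, 5, 12) == {(2, 6), (4, 6), (3, 5), (3, 7)}

    def test_isolated_cell_has_no_neighbors(self):
        assert neighbors(1, 1, 1, 1) == set()

    def test_out_of_range_rejected(self):
        with pytest.raises(IndexError):
            neighbors(0, 1, 3, 3)
        with pytest.raises(IndexError):
            neighbors(1, 4, 3, 3)

    @pytest.mark.parametrize("P, Q", [(1, 1), (1, 5), (3, 3), (5, 12)])
    def test_symmetry_and_edge_count(self, P, Q):
        total = 0
        for p in range(1, P + 1):
            for q in range(1, Q + 1):
                nbrs = neighbors(p, q, P, Q)
                total += len(nbrs)
                for pp, qq in nbrs:
                    assert (p, q) in neighbors(pp, qq, P, Q)
        assert total == 2 * (P * (Q - 1) + Q * (P - 1))
        assert len(grid_edges(P, Q)) == P * (Q - 1) + Q * (P - 1)


class TestDisplacements:
    def test_zero_displacement_is_identity(self, small_grid):
        g = apply_displacements(small_grid, DisplacementField.zeros(3, 3))
        np.testing.assert_array_equal(g.centers_u, small_grid.centers_u)

    def test_constant_shift(self, small_grid):
        disp = DisplacementField(
            du=np.full((3, 3), 3.0), dv=np.zeros((3, 3)), bound_u=5, bound_v=5
        )
        g = apply_displacements(small_grid, disp)
        np.testing.assert_allclose(g.centers_u, small_grid.centers_u + 3.0)
        np.testing.assert_array_equal(g.centers_v, small_grid.centers_v)

    def test_negation_round_trip(self, small_grid, rng):
        du = rng.uniform(-4, 4, size=(3, 3))
        dv = rng.uniform(-4, 4, size=(3, 3))
        fwd = DisplacementField(du=du, dv=dv, bound_u=4, bound_v=4)
        back = DisplacementField(du=-du, dv=-dv, bound_u=4, bound_v=4)
        g = apply_displacements(apply_displacements(small_grid, fwd), back)
        np.testing.assert_allclose(g.centers_u, small_grid.centers_u, atol=1e-12)
        np.testing.assert_allclose(g.centers_v, small_grid.centers_v, atol=1e-12)

    def test_shape_mismatch_rejected(self, small_grid):
        with pytest.raises(ValueError):
            apply_displacements(small_grid, DisplacementField.zeros(2, 2))

    def test_bounds_enforced(self):
        with pytest.raises(ValueError):
            DisplacementField(du=np.array([[3.0]]), dv=np.array([[0.0]]), bound_u=2, bound_v=2)

    def test_flatten_round_trip(self, rng):
        du = rng.uniform(-2, 2, size=(3, 4))
        dv = rng.uniform(-2, 2, size=(3, 4))
        disp = DisplacementField(du=du, dv=dv, bound_u=2, bound_v=2)
        back = DisplacementField.from_flat(disp.flatten(), 3, 4, 2, 2)
        np.testing.assert_array_equal(back.du, du)
        np.testing.assert_array_equal(back.dv, dv)


class TestShapefileRoundTrip:
    def test_single_cell_ring(self, tmp_path):
        g = make_uniform_grid(1, 1, 10, 6, origin=(20, 30))
        path = tmp_path / "one.shp"
        export_shapefile(g, path)
        from plotalign.shapefile_io import read_polygon_shapefile

        polys, records = read_polygon_shapefile(path)
        assert len(polys) == 1 and len(records) == 1
        assert polys[0].shape == (5, 2)  # closed 5-point ring
        np.testing.assert_allclose(polys[0][0], polys[0][-1])

    def test_validation_layout_record_count(self, tmp_path):
        g = make_uniform_grid(5, 12, 150, 500, pitch_u=200, pitch_v=600)
        export_shapefile(g, tmp_path / "val.shp")
        back = import_grid(tmp_path / "val.shp")
        assert back.n_cells == 60

    def test_round_trip_preserves_geometry(self, tmp_path, rng):
        g = make_uniform_grid(3, 4, 15, 40, origin=(50, 60), pitch_u=20, pitch_v=50)
        disp = DisplacementField(
            du=rng.uniform(-5, 5, (3, 4)), dv=rng.uniform(-5, 5, (3, 4)),
            bound_u=5, bound_v=5,
        )
        g = apply_displacements(g, disp)
        g = assign_plot_sequence(g, order="serpentine")
        export_shapefile(g, tmp_path / "grid.shp")
        back = import_grid(tmp_path / "grid.shp")
        np.testing.assert_allclose(back.centers_u, g.centers_u, atol=1e-6)
        np.testing.assert_allclose(back.centers_v, g.centers_v, atol=1e-6)
        assert back.cell_w == pytest.approx(g.cell_w, abs=1e-6)
        assert back.plot_ids[0, 1] == g.plot_ids[0, 1]

    def test_world_coordinates_round_trip(self, tmp_path):
        gt = GeoTransform(origin_x=305000.0, origin_y=6180000.0, scale_x=0.008, scale_y=-0.008)
        g = make_uniform_grid(2, 2, 150, 500, origin=(200, 300), pitch_u=200, pitch_v=600)
        export_shapefile(g, tmp_path / "world.shp", geotransform=gt)
        back = import_grid(tmp_path / "world.shp", geotransform=gt)
        np.testing.assert_allclose(back.centers_u, g.centers_u, atol=1e-6)
        np.testing.assert_allclose(back.centers_v, g.centers_v, atol=1e-6)


class TestPlotSequence:
    def test_row_major_and_serpentine(self):
        g = make_uniform_grid(2, 3, 4, 4, pitch_u=5, pitch_v=5)
        rm = assign_plot_sequence(g, "row_major")
        assert [rm.plot_ids[1, i] for i in range(3)] == ["4", "5", "6"]
        sp = assign_plot_sequence(g, "serpentine")
        assert [sp.plot_ids[1, i] for i in range(3)] == ["6", "5", "4"]


class TestGridFrameResampling:
    def test_unrotated_grid_is_noop(self, small_grid, random_field):
        field, grid = resample_to_grid_frame(random_field, small_grid)
        assert field is random_field and grid is small_grid

    def test_constant_field_unchanged_in_interior(self, small_grid):
        field = ScalarField(values=np.ones((60, 60)))
        g = transform_grid(small_grid, "rotate", angle_deg=30)
        out, g0 = resample_to_grid_frame(field, g)
        assert g0.rotation_deg == 0
        np.testing.assert_allclose(out.values[20:40, 20:40], 1.0, atol=1e-6)
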