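"""binvox / OBJ round trips, voxelization, and dataset loading."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxrecon.synthetic_data import ShapeSpec, generate_shape
from voxrecon.voxel_io import (
    BinvoxFormatError,
    TriangleMesh,
    VoxelGrid,
    load_multiview_dataset,
    mesh_is_watertight,
    read_binvox,
    read_obj,
    voxelize_mesh,
    write_binvox,
    write_obj,
)

UNIT_CUBE_OBJ = """\
v 0 0 0
v 1 0 0
v 1 1 0
v 0 1 0
v 0 0 1
v 1 0 1
v 1 1 1
v 0 1 1
f 1 3 2
f 1 4 3
f 5 6 7
f 5 7 8
f 1 2 6
f 1 6 5
f 2 3 7
f 2 7 6
f 3 4 8
f 3 8 7
f 4 1 5
f 4 5 8
"""


def _write_binvox_bytes(path, dim, rle, translate=b"0.0 0.0 0.0", scale=b"1.0"):
    with open(path, "wb") as fh:
        fh.write(b"#binvox 1\n")
        fh.write(f"dim {dim} {dim} {dim}\n".encode())
        fh.write(b"translate " + translate + b"\n")
        fh.write(b"scale " + scale + b"\n")
        fh.write(b"data\n")
        fh.write(bytes(rle))


class TestBinvox:
    def test_rle_all_zero_and_all_one(self, tmp_path):
        p = tmp_path / "zero.binvox"
        _write_binvox_bytes(p, 2, [0, 8])
        g = read_binvox(p)
        assert g.resolution == 2 and g.occupancy.sum() == 0

        _write_binvox_bytes(p, 2, [1, 8])
        g = read_binvox(p)
        assert g.occupancy.sum() == 8

    def test_write_splits_runs_over_255(self, tmp_path):
        occ = np.zeros(8**3)
        occ[:300] = 1.0  # 300 consecutive voxels in file order
        grid = VoxelGrid(occ.reshape(8, 8, 8).transpose(0, 2, 1))  # x-major file order
        p = tmp_path / "runs.binvox"
        write_binvox(grid, p)
        data = p.read_bytes().split(b"data\n", 1)[1]
        assert data[:4] == bytes([1, 255, 1, 45])

    def test_voxel_order_is_x_major_y_fastest(self, tmp_path):
        # single occupied voxel at flat index 1 => x=0, z=0, y=1
        p = tmp_path / "one.binvox"
        _write_binvox_bytes(p, 2, [0, 1, 1, 1, 0, 6])
        g = read_binvox(p)
        assert g.occupancy[0, 1, 0] == 1.0 and g.occupancy.sum() == 1

    def test_byte_identical_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        grid = VoxelGrid((rng.random((16, 16, 16)) > 0.7).astype(float),
                         translate=np.array([-0.5, 0.25, 1.0]), scale=2.5)
        p1, p2 = tmp_path / "a.binvox", tmp_path / "b.binvox"
        write_binvox(grid, p1)
        write_binvox(read_binvox(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    @settings(max_examples=25, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1), n=st.sampled_from([2, 3, 5, 8]))
    def test_round_trip_identity_on_random_grids(self, tmp_path_factory, seed, n):
        rng = np.random.default_rng(seed)
        grid = VoxelGrid((rng.random((n, n, n)) > 0.5).astype(float),
                         translate=rng.normal(size=3), scale=float(rng.uniform(0.5, 3)))
        p = tmp_path_factory.mktemp("rt") / "g.binvox"
        write_binvox(grid, p)
        back = read_binvox(p)
        assert np.array_equal(back.occupancy, grid.occupancy)
        assert np.array_equal(back.translate, grid.translate)
        assert back.scale == grid.scale

    def test_corrupt_counts_and_bad_magic_raise(self, tmp_path):
        p = tmp_path / "bad.binvox"
        _write_binvox_bytes(p, 2, [0, 5])  # 5 != 8
        with pytest.raises(BinvoxFormatError):
            read_binvox(p)
        p.write_bytes(b"not a binvox\n")
        with pytest.raises(BinvoxFormatError):
            read_binvox(p)

    def test_non_binary_grid_rejected_on_write(self, tmp_path):
        grid = VoxelGrid(np.full((2, 2, 2), 0.5), is_binary=False)
        with pytest.raises(ValueError):
            write_binvox(grid, tmp_path / "x.binvox")


class TestObj:
    def test_unit_cube_fixture(self, tmp_path):
        p = tmp_path / "cube.obj"
        p.write_text(UNIT_CUBE_OBJ)
        mesh = read_obj(p)
        assert len(mesh.vertices) == 8 and len(mesh.faces) == 12
        assert mesh_is_watertight(mesh)

    def test_round_trip_preserves_topology_and_coords(self, tmp_path):
        rng = np.random.default_rng(1)
        mesh = generate_shape(ShapeSpec(kind="sphere", grid_res=16))
        p = tmp_path / "m.obj"
        write_obj(mesh, p)
        back = read_obj(p)
        assert np.array_equal(back.faces, mesh.faces)
        assert np.allclose(back.vertices, mesh.vertices, atol=1e-7)

    def test_quad_face_fan_triangulation(self, tmp_path):
        p = tmp_path / "quad.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 1 1 0\nv 0 1 0\nf 1 2 3 4\n")
        mesh = read_obj(p)
        assert mesh.faces.tolist() == [[0, 1, 2], [0, 2, 3]]

    def test_missing_vertex_reference_raises(self, tmp_path):
        p = tmp_path / "bad.obj"
        p.write_text("v 0 0 0\nv 1 0 0\nv 0 1 0\nf 1 2 9\n")
        with pytest.raises(IndexError):
            read_obj(p)


class TestVoxelize:
    def test_cube_fills_grid_interior(self, tmp_path):
        p = tmp_path / "cube.obj"
        p.write_text(UNIT_CUBE_OBJ)
        g = voxelize_mesh(read_obj(p), 8)
        # cube occupies (1/1.02)^3 of the cubified, 2%-expanded bounds
        assert g.occupancy.mean() > 0.85
        # cell centers strictly inside the cube must all be occupied
        from voxrecon.voxel_io import voxel_centers

        centers = voxel_centers(8, g.translate, g.scale)
        inside = np.all((centers > 1e-9) & (centers < 1 - 1e-9), axis=-1)
        assert np.all(g.occupancy[inside] == 1.0)

    def test_sphere_volume_matches_analytic_ratio(self):
        mesh = generate_shape(ShapeSpec(kind="sphere", size=(1, 1, 1), grid_res=48))
        g = voxelize_mesh(mesh, 32)
        frac = g.occupancy.mean()
        analytic = (4 * np.pi / 3) / g.scale**3
        assert abs(frac - analytic) / analytic < 0.10

    def test_open_mesh_falls_back_to_surface_marking(self):
        tri = TriangleMesh(np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0]]),
                           np.array([[0, 1, 2]]))
        with pytest.warns(RuntimeWarning):
            g = voxelize_mesh(tri, 4)
        assert g.meta.get("surface_only") is True
        assert g.occupancy.sum() > 0

    def test_scaling_convex_mesh_up_never_loses_voxels(self):
        base = generate_shape(ShapeSpec(kind="sphere", grid_res=24))
        small = voxelize_mesh(base, 16)
        bigger = TriangleMesh(base.vertices * 1.15, base.faces)
        # voxelize at the small mesh's fixed grid bounds
        from voxrecon.voxel_io import _parity_occupancy

        occ_small = _parity_occupancy(base, 16, small.translate, small.scale, 0)
        occ_big = _parity_occupancy(bigger, 16, small.translate, small.scale, 0)
        assert np.all(occ_big >= occ_small)


class TestDatasetLoader:
    def test_loads_built_dataset(self, small_dataset_root, small_samples):
        assert len(small_samples) == 3
        for s in small_samples:
            assert len(s.views) == 5
            assert s.ground_truth.resolution == 16
            assert s.mesh is not None
            assert len(s.view_records) == 5
            assert np.allclose(s.view_records[0].relative_position, 0.0)

    def test_empty_root_yields_nothing(self, tmp_path):
        assert list(load_multiview_dataset(tmp_path)) == []

    def test_folder_without_images_skipped(self, tmp_path, caplog):
        (tmp_path / "empty_obj").mkdir()
        assert list(load_multiview_dataset(tmp_path)) == []

    def test_images_without_ground_truth_still_load(self, small_dataset_root, tmp_path):
        import shutil

        src = sorted(small_dataset_root.iterdir())[0]
        dst = tmp_path / "obj"
        shutil.copytree(src / "views", dst / "views")
        samples = list(load_multiview_dataset(tmp_path))
        assert len(samples) == 1
        assert samples[0].ground_truth is None and samples[0].mesh is None
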