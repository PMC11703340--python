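"""Morphometry metrics against analytic phantoms and brute-force oracles."""

import numpy as np
import pytest

from foammech.morphometry import (binarize, compute_morphometry,
                                  connectivity_density, count_objects,
                                  object_metrics, porosity, restack_slices,
                                  slice_stack, structure_thickness)
from foammech.phantoms import generate_phantom
from foammech.volume import VoxelVolume


def vol_of(grid, voxel_size=1.0):
    return VoxelVolume(np.asarray(grid, dtype=np.uint8), voxel_size)


class TestBinarize:
    def test_window_membership(self):
        v = vol_of(np.full((4, 4, 4), 70))
        assert binarize(v, 25, 115).grid.all()
        assert not binarize(v, 115, 255).grid.any()

    def test_two_level_volume_recovers_phases(self):
        g = np.zeros((6, 6, 6), np.uint8)
        g[:3] = 80   # scaffold level
        g[3:] = 200  # dense-label level
        v = vol_of(g)
        foam = binarize(v, 25, 115).grid.astype(bool)
        cells = binarize(v, 116, 255).grid.astype(bool)
        np.testing.assert_array_equal(foam, g == 80)
        np.testing.assert_array_equal(cells, g == 200)

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            binarize(vol_of(np.zeros((2, 2, 2))), 200, 100)


class TestPorosity:
    def test_limits_and_half(self):
        assert porosity(np.zeros((4, 4, 4)))[0] == 100.0
        g = np.zeros((4, 4, 4))
        g[:2] = 1
        poro, frac = porosity(g)
        assert poro == 50.0
        assert poro + frac == pytest.approx(100.0, abs=1e-12)


class TestObjectMetrics:
    def test_cube_volume_exact_surface_close(self):
        cube = generate_phantom("cube", {"side": 50}, voxel_size=2.43)
        ovtv, osov, ostv = object_metrics(cube)
        s_mm = 2.43e-3
        obj_v = 50**3 * s_mm**3
        assert ovtv == pytest.approx(100.0 * obj_v / cube.total_volume_mm3,
                                     rel=1e-12)
        surface = osov * obj_v
        assert surface == pytest.approx(6 * (50 * s_mm) ** 2, rel=0.05)

    def test_sphere_surface_to_volume(self):
        sph = generate_phantom("sphere", {"radius": 20}, voxel_size=2.43)
        _, osov, _ = object_metrics(sph)
        expected = 3.0 / (20 * 2.43e-3)  # 3/r in mm^-1
        assert osov == pytest.approx(expected, rel=0.05)

    def test_surface_error_shrinks_with_radius(self):
        errs = []
        for r in (10, 30):
            sph = generate_phantom("sphere", {"radius": r})
            _, osov, _ = object_metrics(sph)
            errs.append(abs(osov - 3.0 / (r * 1e-3)) / (3.0 / (r * 1e-3)))
        assert errs[1] < errs[0]

    def test_filled_grid_and_empty_phase(self):
        full = vol_of(np.ones((8, 8, 8)))
        assert object_metrics(full)[0] == pytest.approx(100.0)
        empty = vol_of(np.zeros((8, 8, 8)))
        ovtv, osov, ostv = object_metrics(empty)
        assert ovtv == 0.0 and np.isnan(osov) and ostv == 0.0

    def test_voxel_face_mode_biased_high(self):
        sph = generate_phantom("sphere", {"radius": 15})
        _, mc, _ = object_metrics(sph)
        _, faces, _ = object_metrics(sph, surface_mode="voxel_faces")
        assert 1.3 < faces / mc < 1.7


class TestConnectivity:
    def test_ball_and_torus_topology(self):
        sph = generate_phantom("sphere", {"radius": 10})
        conn_dn, chi = connectivity_density(sph)
        assert chi == 1 and conn_dn == 0.0
        tor = generate_phantom("torus")
        conn_dn, chi = connectivity_density(tor)
        assert chi == 0
        assert conn_dn == pytest.approx(1.0 / tor.total_volume_mm3)

    @pytest.mark.parametrize("k", [1, 2, 3])
    def test_k_handle_block_connectivity(self, k):
        """A slab with k parallel through-holes is a genus-k handlebody:
        chi = 1 - k, connectivity = k."""
        g = np.ones((8, 10, 6 + 8 * k), np.uint8)
        for i in range(k):
            g[2:6, :, 8 * i + 3: 8 * i + 6] = 0  # hole through the y axis
        # carve: hole must pierce the slab (along y), keep z faces intact
        conn_dn, chi = connectivity_density(vol_of(g))
        assert chi == 1 - k

    def test_chi_additive_on_disjoint_union(self):
        sph = generate_phantom("sphere", {"radius": 8}).grid
        tor = generate_phantom("torus", {"major_radius": 10,
                                         "minor_radius": 4}).grid
        nz = sph.shape[0] + tor.shape[0] + 3
        ny = max(sph.shape[1], tor.shape[1])
        nx = max(sph.shape[2], tor.shape[2])
        g = np.zeros((nz, ny, nx), np.uint8)
        g[: sph.shape[0], : sph.shape[1], : sph.shape[2]] = sph
        g[-tor.shape[0]:, : tor.shape[1], : tor.shape[2]] = tor
        _, chi = connectivity_density(vol_of(g))
        assert chi == 1 + 0


class TestObjectCount:
    def test_disjoint_blob_phantom(self):
        blobs = generate_phantom("disjoint_blobs", {"n": 7, "radius": 3})
        assert count_objects(blobs) == 7

    def test_empty(self):
        assert count_objects(np.zeros((5, 5, 5))) == 0

    def test_matches_flood_fill_oracle(self):
        """26-connected labelling agrees with a brute-force BFS flood fill
        on a small random grid."""
        rng = np.random.default_rng(42)
        g = (rng.random((16, 16, 16)) < 0.2).astype(np.uint8)

        def flood_count(grid):
            seen = np.zeros_like(grid, dtype=bool)
            shape = grid.shape
            count = 0
            for start in zip(*np.nonzero(grid)):
                if seen[start]:
                    continue
                count += 1
                stack = [start]
                seen[start] = True
                while stack:
                    z, y, x = stack.pop()
                    for dz in (-1, 0, 1):
                        for dy in (-1, 0, 1):
                            for dx in (-1, 0, 1):
                                p = (z + dz, y + dy, x + dx)
                                if all(0 <= p[i] < shape[i] for i in range(3)) \
                                        and grid[p] and not seen[p]:
                                    seen[p] = True
                                    stack.append(p)
            return count

        assert count_objects(g) == flood_count(g)


class TestStructureThickness:
    def test_slab_exact(self):
        slab = generate_phantom("slab", {"thickness": 15}, voxel_size=2.0)
        mean, sd, _ = structure_thickness(slab)
        assert mean == pytest.approx(15 * 2.0, abs=0.5 * 2.0)
        assert sd == pytest.approx(0.0, abs=1e-9)

    def test_cylinder_within_five_percent(self):
        cyl = generate_phantom("cylinder", {"diameter": 24, "length": 30})
        mean, _, _ = structure_thickness(cyl)
        assert mean == pytest.approx(24.0, rel=0.05)

    def test_single_voxel(self):
        g = np.zeros((5, 5, 5), np.uint8)
        g[2, 2, 2] = 1
        mean, sd, _ = structure_thickness(vol_of(g, voxel_size=3.0))
        assert mean == pytest.approx(3.0)

    def test_empty_phase_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            structure_thickness(vol_of(np.zeros((4, 4, 4))))


class TestSliceStack:
    def test_slice_counts(self, tmp_path):
        g = np.zeros((100, 8, 8), np.uint8)
        g[::3] = 1
        v = vol_of(g, voxel_size=2.0)
        m1 = slice_stack(v, tmp_path / "a", interval=2.0)
        assert len(m1["slices"]) == 100
        m2 = slice_stack(v, tmp_path / "b", interval=4.0)
        assert len(m2["slices"]) == 50

    def test_roundtrip_bit_exact(self, tmp_path):
        rng = np.random.default_rng(0)
        g = (rng.random((20, 10, 10)) < 0.3).astype(np.uint8)
        v = vol_of(g)
        slice_stack(v, tmp_path / "s", interval=2.0)
        stacked, manifest = restack_slices(tmp_path / "s")
        np.testing.assert_array_equal(stacked, g[::2])

    def test_interval_below_voxel_rejected(self, tmp_path):
        v = vol_of(np.ones((4, 4, 4)), voxel_size=10.0)
        with pytest.raises(ValueError, match="interval"):
            slice_stack(v, tmp_path / "x", interval=5.0)


class TestInvariances:
    def test_metrics_invariant_under_axis_permutation_and_flip(self):
        tor = generate_phantom("torus", {"major_radius": 10, "minor_radius": 4})
        base = compute_morphometry(tor)
        for g in (np.transpose(tor.grid, (1, 2, 0)), tor.grid[::-1].copy()):
            alt = compute_morphometry(vol_of(g, tor.voxel_size))
            assert alt.euler_characteristic == base.euler_characteristic
            assert alt.n_objects == base.n_objects
            assert alt.obj_v_tv == pytest.approx(base.obj_v_tv, rel=1e-12)
            assert alt.obj_s_obj_v == pytest.approx(base.obj_s_obj_v, rel=1e-6)
            assert alt.structure_thickness_mean == pytest.approx(
                base.structure_thickness_mean, rel=1e-9)

    def test_porosity_complements_volume_fraction(self):
        sph = generate_phantom("sphere", {"radius": 12})
        res = compute_morphometry(sph)
        assert res.porosity + res.obj_v_tv == pytest.approx(100.0, abs=1e-9)
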