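"""Morphometric descriptors against closed-form geometry oracles."""

import math

import numpy as np
import pytest

from cryoht import (
    RITomogram,
    ValidationError,
    concentration,
    dry_mass,
    projection_area,
    sphericity,
    surface_area,
    volume,
)
from .conftest import make_ellipsoid_mask, make_sphere_mask

R2_SPHERE_VOLUME = 4.0 / 3.0 * math.pi * 8.0    # 33.510 µm³
R2_SPHERE_AREA = 4.0 * math.pi * 4.0            # 50.265 µm²


def prolate_spheroid_area(a, b):
    """Closed-form surface area of a prolate spheroid (a > b = c)."""
    e = math.sqrt(1.0 - (b / a) ** 2)
    return 2.0 * math.pi * b**2 * (1.0 + a / (b * e) * math.asin(e))


class TestVolume:
    def test_is_voxel_count_times_voxel_volume(self):
        mask = np.zeros((10, 10, 10), dtype=bool)
        mask.ravel()[:1000] = True
        assert volume(mask, (0.1, 0.1, 0.2)) == pytest.approx(2.0)

    def test_digitized_sphere_matches_analytic(self, sphere_r2_p05):
        mask, vox = sphere_r2_p05
        assert volume(mask, vox) == pytest.approx(R2_SPHERE_VOLUME, rel=0.02)

    def test_empty_mask_is_zero(self):
        assert volume(np.zeros((4, 4, 4), dtype=bool), (0.1, 0.1, 0.1)) == 0.0


class TestSurfaceArea:
    def test_digitized_sphere_matches_analytic(self, sphere_r2_p05):
        mask, vox = sphere_r2_p05
        assert surface_area(mask, vox) == pytest.approx(R2_SPHERE_AREA, rel=0.03)

    def test_single_voxel_bounded_by_its_faces(self):
        mask = np.zeros((5, 5, 5), dtype=bool)
        mask[2, 2, 2] = True
        area = surface_area(mask, (0.1, 0.1, 0.1))
        assert 0.0 < area <= 0.06  # 6 faces x 0.01 µm²

    def test_area_scales_with_square_of_voxel_size(self):
        mask, _ = make_sphere_mask(1.0, 0.1)
        a1 = surface_area(mask, (0.1, 0.1, 0.1))
        a2 = surface_area(mask, (0.2, 0.2, 0.2))
        assert a2 == pytest.approx(4.0 * a1, rel=1e-9)

    def test_empty_mask_raises(self):
        with pytest.raises(ValidationError):
            surface_area(np.zeros((3, 3, 3), dtype=bool), (0.1, 0.1, 0.1))


class TestSphericity:
    def test_analytic_sphere_is_one(self):
        assert sphericity(R2_SPHERE_VOLUME, R2_SPHERE_AREA) == pytest.approx(1.0)

    def test_prolate_spheroid_closed_form(self):
        # a=2, b=c=1: V = 8.3776 µm³, A = 21.478 µm²  → 0.929
        v = 4.0 / 3.0 * math.pi * 2.0
        a = prolate_spheroid_area(2.0, 1.0)
        assert a == pytest.approx(21.478, abs=5e-3)
        assert sphericity(v, a) == pytest.approx(0.929, abs=5e-4)

    def test_cube_closed_form(self):
        s = 1.7
        expected = math.pi ** (1 / 3) * 6 ** (2 / 3) / 6  # ≈ 0.806
        assert sphericity(s**3, 6 * s**2) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            sphericity(0.0, 1.0)
        with pytest.raises(ValidationError):
            sphericity(1.0, 0.0)

    def test_isoperimetric_bound_on_random_ellipsoids(self):
        # sphericity never exceeds 1 beyond discretization slack
        rng = np.random.default_rng(12)
        for _ in range(60):
            semi = rng.uniform(0.4, 1.5, size=3)
            mask, vox = make_ellipsoid_mask(tuple(semi), 0.05)
            s = sphericity(volume(mask, vox), surface_area(mask, vox))
            assert s <= 1.02

    def test_mesh_and_voxel_volumes_consistent(self, sphere_r2_p05):
        # smooth shape ≥ 20 voxels across: the two volume routes agree
        from skimage import measure as skm
        mask, vox = sphere_r2_p05
        verts, faces, _, _ = skm.marching_cubes(
            np.pad(mask, 1).astype(np.float32), level=0.5, spacing=vox)
        # signed tetrahedron sum over the closed mesh
        v0, v1, v2 = (verts[faces[:, i]] for i in range(3))
        mesh_vol = abs(np.einsum("ij,ij->i", v0, np.cross(v1, v2)).sum()) / 6.0
        assert mesh_vol == pytest.approx(volume(mask, vox), rel=0.05)

    def test_halving_pitch_converges_to_analytic(self):
        errs_v, errs_a = [], []
        for pitch in (0.2, 0.1):
            mask, vox = make_sphere_mask(2.0, pitch)
            errs_v.append(abs(volume(mask, vox) - R2_SPHERE_VOLUME))
            errs_a.append(abs(surface_area(mask, vox) - R2_SPHERE_AREA))
        assert errs_v[1] < errs_v[0]
        assert errs_a[1] < errs_a[0]


class TestProjectionArea:
    def test_sphere_projects_to_disc(self, sphere_r2_p05):
        mask, vox = sphere_r2_p05
        assert projection_area(mask, vox, "z") == pytest.approx(math.pi * 4.0, rel=0.02)

    def test_single_voxel_is_one_pixel(self):
        mask = np.zeros((4, 4, 4), dtype=bool)
        mask[1, 2, 3] = True
        assert projection_area(mask, (0.1, 0.2, 0.3), "z") == pytest.approx(0.02)

    def test_axially_symmetric_shape_projects_equally_in_x_and_y(self):
        mask, vox = make_sphere_mask(1.5, 0.05)
        px = projection_area(mask, vox, "x")
        py = projection_area(mask, vox, "y")
        assert px == pytest.approx(py, rel=0.01)

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValidationError):
            projection_area(np.ones((2, 2, 2), dtype=bool), (0.1, 0.1, 0.1), "w")


def homogeneous_sphere_tomo(ri_inside=1.387, medium=1.337):
    mask, vox = make_sphere_mask(2.0, 0.05)
    grid = np.full(mask.shape, medium, dtype=np.float64)
    grid[mask] = ri_inside
    return RITomogram(grid, vox, medium), mask


class TestDryMass:
    def test_homogeneous_sphere_closed_form(self):
        # ΔRI 0.05, α 0.185: m = (0.05/0.185)·V ≈ 9.057 pg at V = 33.510 µm³
        tomo, mask = homogeneous_sphere_tomo()
        m = dry_mass(tomo, mask, 0.185)
        v = volume(mask, tomo.voxel_size)
        assert m == pytest.approx((0.05 / 0.185) * v, rel=1e-9)
        assert m == pytest.approx(9.057, rel=0.02)

    def test_ri_equal_to_medium_gives_zero(self):
        tomo, mask = homogeneous_sphere_tomo(ri_inside=1.337)
        assert dry_mass(tomo, mask) == 0.0

    def test_linearity_in_ri_excess(self):
        t1, mask = homogeneous_sphere_tomo(ri_inside=1.357)
        t2, _ = homogeneous_sphere_tomo(ri_inside=1.377)
        assert dry_mass(t2, mask) == pytest.approx(2.0 * dry_mass(t1, mask), rel=1e-9)

    def test_additive_over_disjoint_masks(self):
        tomo, mask = homogeneous_sphere_tomo()
        half_a = mask.copy()
        half_a[mask.shape[0] // 2:] = False
        half_b = mask & ~half_a
        total = dry_mass(tomo, half_a) + dry_mass(tomo, half_b)
        assert total == pytest.approx(dry_mass(tomo, mask), rel=1e-12)

    def test_negative_excess_clipped(self):
        tomo, mask = homogeneous_sphere_tomo(ri_inside=1.30, medium=1.337)
        assert dry_mass(tomo, mask) == 0.0

    def test_nonpositive_alpha_rejected(self):
        tomo, mask = homogeneous_sphere_tomo()
        with pytest.raises(ValidationError):
            dry_mass(tomo, mask, 0.0)


class TestConcentration:
    def test_division_of_dry_mass_example(self):
        assert concentration(9.057, 33.510) == pytest.approx(0.2703, abs=2e-4)

    def test_homogeneous_region_independent_of_size(self):
        tomo, mask = homogeneous_sphere_tomo()
        small = mask.copy()
        small[: mask.shape[0] // 2] = False
        for m in (mask, small):
            c = concentration(dry_mass(tomo, m), volume(m, tomo.voxel_size))
            assert c == pytest.approx(0.05 / 0.185, rel=1e-9)

    def test_zero_volume_rejected(self):
        with pytest.raises(ValidationError):
            concentration(1.0, 0.0)
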