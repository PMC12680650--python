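"""Shared fixtures: digitized reference shapes and small phantoms."""

from __future__ import annotations

import numpy as np
import pytest

from cryoht import PhantomSpec, RITomogram


def make_sphere_mask(radius_um: float, pitch_um: float,
                     margin_voxels: int = 4) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Digitize a sphere: voxel centres at (i+0.5)*pitch, centre mid-grid."""
    n = int(np.ceil(2 * radius_um / pitch_um)) + 2 * margin_voxels
    coords = (np.arange(n) + 0.5) * pitch_um - n * pitch_um / 2.0
    z, y, x = np.meshgrid(coords, coords, coords, indexing="ij")
    mask = x**2 + y**2 + z**2 <= radius_um**2
    return mask, (pitch_um, pitch_um, pitch_um)


def make_ellipsoid_mask(semiaxes_xyz: tuple[float, float, float], pitch_um: float,
                        margin_voxels: int = 4) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Digitize an axis-aligned ellipsoid; semiaxes given as (x, y, z)."""
    a, b, c = semiaxes_xyz
    shape = [int(np.ceil(2 * s / pitch_um)) + 2 * margin_voxels for s in (c, b, a)]
    axes = [(np.arange(n) + 0.5) * pitch_um - n * pitch_um / 2.0 for n in shape]
    z, y, x = np.meshgrid(*axes, indexing="ij")
    mask = (x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2 <= 1.0
    return mask, (pitch_um, pitch_um, pitch_um)


@pytest.fixture(scope="session")
def sphere_r2_p05():
    """r = 2 µm sphere at 0.05 µm isotropic voxels (the geometry oracle)."""
    return make_sphere_mask(2.0, 0.05)


@pytest.fixture
def quiet_spec():
    """A noise-free default phantom."""
    return PhantomSpec(noise_sd=0.0)


@pytest.fixture
def uniform_tomogram():
    """A 16³ medium-only grid (no cell)."""
    grid = np.full((16, 16, 16), 1.337, dtype=np.float32)
    return RITomogram(grid=grid, voxel_size=(0.11, 0.11, 0.22), medium_ri=1.337)
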