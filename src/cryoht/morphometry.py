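"""Per-compartment quantitative descriptors from a mask + tomogram pair.

Descriptors follow the holotomography convention: volume (µm³), surface area
(µm²), sphericity (a.u.), projection area (µm²), dry mass (pg), concentration
(pg/µm³), plus the mean refractive index over the mask.

Volume is a voxel count times the voxel volume.  Surface area comes from a
marching-cubes iso-surface extracted at the 0.5 level of the binary mask
(voxel-face counting would overestimate smooth surfaces by up to ~50%).
Dry mass converts the RI excess over the medium to non-aqueous mass through
the specific refractive increment α (0.185 µm³/pg, the standard protein
value — exposed as a parameter):

    m = Σ_voxels (RI − RI_medium) / α · V_voxel
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from .errors import ValidationError
from .io import RITomogram
from .segmentation import CellSegmentation, RegionMask

__all__ = [
    "DEFAULT_REFRACTIVE_INCREMENT",
    "RegionMorphometry",
    "volume",
    "surface_area",
    "sphericity",
    "projection_area",
    "dry_mass",
    "concentration",
    "measure_region",
    "measure_cell",
]

logger = logging.getLogger(__name__)

#: Specific refractive increment α in µm³/pg (standard protein value).
DEFAULT_REFRACTIVE_INCREMENT = 0.185

_AXIS_INDEX = {"z": 0, "y": 1, "x": 2}  # grids are stored (z, y, x)


@dataclass(frozen=True)
class RegionMorphometry:
    """All descriptors for one compartment of one cell."""

    region: str
    volume: float            # µm³
    surface_area: float      # µm²
    sphericity: float        # a.u.
    projection_area: float   # µm²
    dry_mass: float          # pg
    concentration: float     # pg/µm³
    mean_ri: float           # a.u.
    voxel_count: int


def _mask_array(mask: RegionMask | np.ndarray) -> np.ndarray:
    arr = mask.mask if isinstance(mask, RegionMask) else np.asarray(mask)
    return arr.astype(bool)


def volume(mask: RegionMask | np.ndarray,
           voxel_size: tuple[float, float, float]) -> float:
    """Region volume in µm³: voxel count × voxel volume.  Empty mask → 0."""
    dx, dy, dz = voxel_size
    return float(_mask_array(mask).sum()) * dx * dy * dz


def surface_area(mask: RegionMask | np.ndarray,
                 voxel_size: tuple[float, float, float],
                 smoothing_sigma: float = 1.0) -> float:
    """Iso-surface area (µm²) of the mask at the 0.5 level, marching cubes.

    The binary mask is lightly Gaussian-smoothed (``smoothing_sigma`` voxels,
    default 1) before extracting the 0.5 iso-surface: a raw binary iso-surface
    carries staircase facets that overestimate a smooth surface by ~9%,
    while the smoothed field recovers a digitized sphere's area to well
    under 1%.  Objects so small that smoothing pushes the whole field under
    the level (a few voxels) fall back to the raw mask.  The volume is
    zero-padded so surfaces touching the grid boundary are closed.  Raises
    on an empty mask (no surface exists).
    """
    arr = _mask_array(mask)
    if not arr.any():
        raise ValidationError("surface area is undefined for an empty mask")
    dx, dy, dz = voxel_size
    pad = max(1, int(np.ceil(3 * smoothing_sigma)))
    field = np.pad(arr, pad).astype(np.float32)
    if smoothing_sigma > 0:
        smoothed = ndimage.gaussian_filter(field, smoothing_sigma)
        if smoothed.max() > 0.5:
            field = smoothed
    verts, faces, _, _ = measure.marching_cubes(field, level=0.5,
                                                spacing=(dz, dy, dx))
    return float(measure.mesh_surface_area(verts, faces))


def sphericity(vol: float, area: float) -> float:
    """π^(1/3)·(6V)^(2/3)/A — 1.0 for a perfect sphere, < 1 otherwise."""
    if vol <= 0:
        raise ValidationError(f"volume must be positive, got {vol}")
    if area <= 0:
        raise ValidationError(f"surface area must be positive, got {area}")
    return float(np.pi ** (1.0 / 3.0) * (6.0 * vol) ** (2.0 / 3.0) / area)


def projection_area(mask: RegionMask | np.ndarray,
                    voxel_size: tuple[float, float, float],
                    axis: str = "z") -> float:
    """Area (µm²) of the max-intensity projection along an axis.

    Defaults to the optical (z) axis, the conventional reporting plane.
    """
    if axis not in _AXIS_INDEX:
        raise ValidationError(f"axis must be one of 'x', 'y', 'z', got {axis!r}")
    arr = _mask_array(mask)
    dx, dy, dz = voxel_size
    pixel_area = {"z": dx * dy, "y": dx * dz, "x": dy * dz}[axis]
    return float(arr.any(axis=_AXIS_INDEX[axis]).sum()) * pixel_area


def dry_mass(tomogram: RITomogram, mask: RegionMask | np.ndarray,
             refractive_increment: float = DEFAULT_REFRACTIVE_INCREMENT) -> float:
    """Non-aqueous mass (pg) inside the mask via the refractive increment.

    Per-voxel contributions with RI below the medium (noise) are clipped to
    zero and logged; dry mass is therefore non-negative and exactly additive
    over disjoint masks.
    """
    if refractive_increment <= 0:
        raise ValidationError(
            f"refractive increment must be positive, got {refractive_increment}"
        )
    arr = _mask_array(mask)
    excess = tomogram.grid[arr] - tomogram.medium_ri
    n_neg = int((excess < 0).sum())
    if n_neg:
        logger.debug("%d voxels with RI below medium clipped to zero dry mass", n_neg)
        excess = np.clip(excess, 0.0, None)
    return float(excess.sum(dtype=np.float64)) / refractive_increment * tomogram.voxel_volume


def concentration(mass: float, vol: float) -> float:
    """Dry-mass concentration in pg/µm³."""
    if vol <= 0:
        raise ValidationError(f"volume must be positive for concentration, got {vol}")
    return mass / vol


def measure_region(tomogram: RITomogram, mask: RegionMask,
                   refractive_increment: float = DEFAULT_REFRACTIVE_INCREMENT,
                   projection_axis: str = "z") -> RegionMorphometry:
    """All descriptors for one non-empty compartment mask."""
    arr = _mask_array(mask)
    if not arr.any():
        raise ValidationError(f"cannot measure empty region {mask.region!r}")
    vol = volume(arr, tomogram.voxel_size)
    area = surface_area(arr, tomogram.voxel_size)
    mass = dry_mass(tomogram, arr, refractive_increment)
    return RegionMorphometry(
        region=mask.region,
        volume=vol,
        surface_area=area,
        sphericity=sphericity(vol, area),
        projection_area=projection_area(arr, tomogram.voxel_size, projection_axis),
        dry_mass=mass,
        concentration=concentration(mass, vol),
        mean_ri=float(tomogram.grid[arr].mean(dtype=np.float64)),
        voxel_count=int(arr.sum()),
    )


def measure_cell(tomogram: RITomogram, segmentation: CellSegmentation,
                 refractive_increment: float = DEFAULT_REFRACTIVE_INCREMENT
                 ) -> dict[str, RegionMorphometry]:
    """Descriptors for every non-empty region of a segmented cell."""
    out = {}
    for region, mask in segmentation.masks.items():
        if mask:
            out[region] = measure_region(tomogram, mask, refractive_increment)
    return out
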