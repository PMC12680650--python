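"""Partition an RI tomogram into sperm compartments by refractive-index windows.

Three windows define the compartments (values dimensionless):

* ``whole``    [1.348, 1.44) — the whole sperm structure;
* ``midpiece`` [1.37, 1.39)  — post-acrosomal region and midpiece;
* ``nucleus``  [1.39, 1.44)  — nuclear region.

All intervals are half-open ``[lo, hi)``.  The printed bound 1.39 appears as
both the midpiece upper and the nucleus lower limit; the half-open convention
resolves it deterministically in favour of the nucleus, so the two
sub-windows are adjacent and disjoint.  The same windows are applied to every
cell, fresh or frozen.  Voxels at or above the whole-window upper bound are
unclassified; they are counted in a QC field.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy import ndimage

from .errors import NoCellDetectedError, ValidationError
from .io import RITomogram

__all__ = [
    "RIRangeSet",
    "RegionMask",
    "CellSegmentation",
    "segment_by_ri",
    "largest_component",
    "segment_cell",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RIRangeSet:
    """The three labelled half-open RI windows defining sperm compartments."""

    whole: tuple[float, float] = (1.348, 1.44)
    midpiece: tuple[float, float] = (1.37, 1.39)
    nucleus: tuple[float, float] = (1.39, 1.44)

    def __post_init__(self) -> None:
        for name in ("whole", "midpiece", "nucleus"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValidationError(f"window {name!r} needs lo < hi, got [{lo}, {hi})")
        for name in ("midpiece", "nucleus"):
            lo, hi = getattr(self, name)
            if lo < self.whole[0] or hi > self.whole[1]:
                raise ValidationError(
                    f"window {name!r} [{lo}, {hi}) must be a subset of the whole "
                    f"window [{self.whole[0]}, {self.whole[1]})"
                )
        if self.midpiece[1] != self.nucleus[0]:
            raise ValidationError(
                "midpiece upper bound must equal nucleus lower bound "
                f"(adjacent disjoint windows), got {self.midpiece[1]} vs {self.nucleus[0]}"
            )

    def as_dict(self) -> dict[str, tuple[float, float]]:
        return {"whole": self.whole, "midpiece": self.midpiece, "nucleus": self.nucleus}


@dataclass
class RegionMask:
    """A boolean compartment mask aligned to its source tomogram."""

    region: str
    mask: np.ndarray
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValidationError("region mask must be 3D")

    @property
    def voxel_count(self) -> int:
        return int(self.mask.sum())

    def __bool__(self) -> bool:  # empty masks are legal but falsy
        return bool(self.mask.any())


def segment_by_ri(tomogram: RITomogram, ranges: RIRangeSet | None = None
                  ) -> dict[str, RegionMask]:
    """Classify each voxel into the whole/midpiece/nucleus windows.

    Membership is ``lo <= RI < hi`` per window; empty masks are legal.
    Sub-window masks are disjoint by construction and subsets of the whole
    mask whenever the windows themselves are nested.
    """
    ranges = ranges or RIRangeSet()
    grid = tomogram.grid
    masks = {}
    for region, (lo, hi) in ranges.as_dict().items():
        masks[region] = RegionMask(
            region=region, mask=(grid >= lo) & (grid < hi),
            voxel_size=tomogram.voxel_size,
        )
    return masks


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 26:
        return np.ones((3, 3, 3), dtype=bool)
    if connectivity == 6:
        return ndimage.generate_binary_structure(3, 1)
    raise ValidationError(f"connectivity must be 6 or 26, got {connectivity}")


def largest_component(mask: RegionMask, connectivity: int = 26) -> RegionMask:
    """Keep only the largest connected component of a mask.

    26-connectivity by default.  An empty mask passes through unchanged.  If
    several components tie for the largest size, the one containing the
    smallest flattened (C-order) voxel index wins — a documented,
    deterministic tie-break.
    """
    labels, n = ndimage.label(mask.mask, structure=_structure(connectivity))
    if n == 0:
        return RegionMask(mask.region, np.zeros_like(mask.mask), mask.voxel_size)
    sizes = np.bincount(labels.ravel())[1:]  # skip background
    best = sizes.max()
    candidates = np.flatnonzero(sizes == best) + 1
    if len(candidates) == 1:
        keep = candidates[0]
    else:
        flat = labels.ravel()
        keep = min(candidates, key=lambda lab: int(np.argmax(flat == lab)))
    return RegionMask(mask.region, labels == keep, mask.voxel_size)


@dataclass
class CellSegmentation(Mapping):
    """Per-region masks for one cell plus segmentation QC counters.

    Behaves as a mapping ``region -> RegionMask``.  ``n_unclassified_high``
    counts voxels at or above the whole-window upper bound (outside every
    window); ``n_removed_by_cleaning`` counts whole-mask voxels discarded as
    disconnected debris.
    """

    masks: dict[str, RegionMask]
    n_unclassified_high: int = 0
    n_removed_by_cleaning: int = 0

    def __getitem__(self, region: str) -> RegionMask:
        return self.masks[region]

    def __iter__(self):
        return iter(self.masks)

    def __len__(self) -> int:
        return len(self.masks)


def segment_cell(
    tomogram: RITomogram,
    ranges: RIRangeSet | None = None,
    clean: bool = True,
    connectivity: int = 26,
) -> CellSegmentation:
    """Segment a single-cell tomogram into whole/midpiece/nucleus masks.

    With ``clean`` (the default for single-cell fields) the whole-cell mask
    is reduced to its largest connected component — suppressing isolated
    noise voxels — and the sub-region masks are intersected with it.  Raises
    :class:`NoCellDetectedError` if the cleaned whole-cell mask is empty.
    """
    ranges = ranges or RIRangeSet()
    masks = segment_by_ri(tomogram, ranges)
    n_high = int((tomogram.grid >= ranges.whole[1]).sum())
    if n_high:
        logger.warning("%d voxels at or above the whole-cell window upper bound "
                       "left unclassified", n_high)
    removed = 0
    if clean:
        raw_whole = masks["whole"]
        cleaned = largest_component(raw_whole, connectivity=connectivity)
        removed = raw_whole.voxel_count - cleaned.voxel_count
        masks["whole"] = cleaned
        for region in ("midpiece", "nucleus"):
            masks[region] = RegionMask(
                region, masks[region].mask & cleaned.mask, cleaned.voxel_size
            )
    if not masks["whole"]:
        raise NoCellDetectedError("no cell detected: whole-cell mask is empty"
                                  + (" after cleaning" if clean else ""))
    return CellSegmentation(masks, n_unclassified_high=n_high,
                            n_removed_by_cleaning=removed)
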