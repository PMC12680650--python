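"""Read/write the formats the pipeline exchanges.

Tomograms travel as one single-channel 3D TIFF stack per cell plus a JSON
sidecar carrying the voxel geometry and the refractive index of the mounting
medium.  Masks are 8-bit (0/255) TIFF stacks.  Tracks are plain CSV.

Axis convention
---------------
Grids are stored ``(z, y, x)`` with ``z`` the optical axis; the sidecar lists
``voxel_size_um`` as ``(dx, dy, dz)``.  Physical coordinates are in µm with
the origin at the grid corner and voxel centres at ``(i + 0.5) * pitch``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import FormatError, ValidationError

__all__ = [
    "RITomogram",
    "read_tomogram",
    "write_tomogram",
    "read_mask",
    "write_mask",
    "read_tracks",
    "write_tracks",
]

#: Keys the tomogram sidecar must carry.
_REQUIRED_SIDECAR_KEYS = ("voxel_size_um", "medium_ri")


@dataclass
class RITomogram:
    """A 3D refractive-index map with its voxel geometry.

    Parameters
    ----------
    grid
        Refractive-index values (dimensionless), axis order ``(z, y, x)``.
    voxel_size
        Voxel pitch ``(dx, dy, dz)`` in µm.
    medium_ri
        Refractive index of the mounting medium (background).
    metadata
        Free-form key/value annotations (donor, extender, cell id, ...).
    """

    grid: np.ndarray
    voxel_size: tuple[float, float, float]
    medium_ri: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or self.grid.size == 0:
            raise ValidationError("tomogram grid must be a non-empty 3D array")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValidationError(
                f"voxel dimensions must be three positive lengths, got {self.voxel_size}"
            )
        low = np.argwhere(self.grid < 1.0)
        if low.size:
            idx = tuple(int(i) for i in low[0])
            raise ValidationError(
                f"refractive index below 1.0 at voxel (z,y,x)={idx}: "
                f"{float(self.grid[idx])}"
            )
        self.medium_ri = float(self.medium_ri)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in µm³."""
        dx, dy, dz = self.voxel_size
        return dx * dy * dz


def _sidecar_path(tiff_path: Path) -> Path:
    return tiff_path.with_suffix(".json")


def write_tomogram(tomo: RITomogram, path: str | Path) -> Path:
    """Write a tomogram as a float32 TIFF stack plus JSON sidecar.

    Returns the TIFF path.  The sidecar lands next to it with a ``.json``
    suffix.  Values round-trip bit-exactly at 32-bit precision.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(tomo.grid, dtype=np.float32))
    sidecar = {
        "voxel_size_um": list(tomo.voxel_size),
        "medium_ri": tomo.medium_ri,
        **tomo.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))
    return path


def read_tomogram(path: str | Path) -> RITomogram:
    """Read a TIFF stack + JSON sidecar written by :func:`write_tomogram`."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"tomogram stack not found: {path}")
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar: {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in _REQUIRED_SIDECAR_KEYS:
        if key not in sidecar:
            raise FormatError(f"sidecar {sidecar_path} lacks required key {key!r}")
    grid = tifffile.imread(path)
    metadata = {k: v for k, v in sidecar.items() if k not in _REQUIRED_SIDECAR_KEYS}
    return RITomogram(
        grid=grid,
        voxel_size=tuple(sidecar["voxel_size_um"]),
        medium_ri=sidecar["medium_ri"],
        metadata=metadata,
    )


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    """Write a boolean grid as an 8-bit 0/255 TIFF stack."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, (np.asarray(mask, dtype=bool) * np.uint8(255)))
    return path


def read_mask(path: str | Path) -> np.ndarray:
    """Read a 0/255 TIFF mask back to a boolean grid."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mask stack not found: {path}")
    return tifffile.imread(path) > 0


# ---------------------------------------------------------------------------
# tracks


def read_tracks(path: str | Path, fps: float) -> list:
    """Read CASA-style 2D tracks from CSV.

    Expects columns ``track_id, frame, x_um, y_um``.  Within each track,
    frames must be consecutive integers (uniform sampling); duplicated,
    non-monotonic or gapped frames raise :class:`FormatError` — records are
    never silently dropped or reordered.
    """
    from .kinematics import SpermTrack  # local import to avoid a cycle

    if fps <= 0:
        raise ValidationError(f"fps must be positive, got {fps}")
    path = Path(path)
    if not path.exists():
        raise FormatError(f"track file not found: {path}")
    df = pd.read_csv(path)
    required = {"track_id", "frame", "x_um", "y_um"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"track CSV lacks columns {sorted(missing)}")
    tracks = []
    for tid, sub in df.groupby("track_id", sort=False):
        frames = sub["frame"].to_numpy()
        if len(frames) != len(np.unique(frames)):
            raise FormatError(f"track {tid!r}: duplicated frame numbers")
        diffs = np.diff(frames)
        if np.any(diffs <= 0):
            raise FormatError(f"track {tid!r}: frames not strictly increasing")
        if np.any(diffs != 1):
            raise FormatError(f"track {tid!r}: gap in frame sequence")
        positions = sub[["x_um", "y_um"]].to_numpy(dtype=float)
        tracks.append(SpermTrack(positions=positions, fps=fps, track_id=tid))
    return tracks


def write_tracks(tracks: Sequence, path: str | Path) -> Path:
    """Write tracks to the CSV layout :func:`read_tracks` expects."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows = []
    for track in tracks:
        for frame, (x, y) in enumerate(track.positions):
            rows.append((track.track_id, frame, x, y))
    pd.DataFrame(rows, columns=["track_id", "frame", "x_um", "y_um"]).to_csv(
        path, index=False
    )
    return path
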