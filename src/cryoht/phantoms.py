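"""Synthetic refractive-index phantoms of spermatozoa and whole study cohorts.

A phantom is a three-compartment stand-in for a fixed spermatozoon imaged by
optical diffraction tomography: an ellipsoidal nucleus, a cylindrical
midpiece abutting it, and a thin cylindrical tail, all aligned along the
optical (z) axis and embedded in a uniform medium.  Compartment refractive
indices are chosen so each compartment falls inside exactly the RI windows
used for segmentation (the tail lies inside the whole-cell window only,
matching how the tail shows up in whole-cell renderings but in neither
sub-window).

Cryopreservation-induced dehydration is modelled as an isotropic volume
scaling per compartment: a shrinkage factor ``f`` multiplies each linear
dimension by ``f**(1/3)`` so the compartment volume scales exactly by ``f``.

:func:`simulate_study` builds an entire donor × extender cohort with
donor-specific baseline sizes, per-cell size jitter, extender-specific
shrinkage distributions, and designated "good cooler" donors whose cells
barely shrink under any extender.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import GeometryError, ValidationError
from .io import RITomogram, write_tomogram

__all__ = [
    "REGIONS",
    "PhantomSpec",
    "StudyDesign",
    "CellPlan",
    "StudySimulation",
    "render_tomogram",
    "apply_cryo_effect",
    "analytic_volumes",
    "simulate_study",
    "DEFAULT_VOXEL_SIZE",
    "DEFAULT_GRID_SHAPE",
]

#: Compartments a phantom is built from.
REGIONS = ("nucleus", "midpiece", "tail")

#: Default voxel pitch (dx, dy, dz) in µm — the instrument's lateral/axial
#: resolution (110 nm / 220 nm) used as the sampling pitch.
DEFAULT_VOXEL_SIZE = (0.11, 0.11, 0.22)

#: Default grid (nx, ny, nz): 64³ voxels, enough for one cell with margin.
DEFAULT_GRID_SHAPE = (64, 64, 64)

_MARGIN_VOXELS = 2  # minimum clearance between phantom and grid boundary


def _full_shrinkage(factors: Mapping[str, float] | None) -> dict[str, float]:
    out = {region: 1.0 for region in REGIONS}
    if factors:
        for region, f in factors.items():
            if region not in REGIONS:
                raise ValidationError(f"unknown region {region!r}; expected one of {REGIONS}")
            out[region] = float(f)
    return out


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, refractive indices and noise level of one synthetic cell.

    Linear dimensions are in µm; refractive indices are dimensionless.
    ``nucleus_semiaxes`` is ``(a, b, c)`` with ``a`` along x, ``b`` along y
    and ``c`` along the long (z) axis.  ``shrinkage`` records the cumulative
    per-region volume factors already applied to this spec.
    """

    nucleus_semiaxes: tuple[float, float, float] = (0.6, 1.6, 2.9)
    nucleus_ri: float = 1.415
    midpiece_length: float = 4.2
    midpiece_radius: float = 0.45
    midpiece_ri: float = 1.380
    tail_length: float = 1.8
    tail_radius: float = 0.18
    tail_ri: float = 1.360
    medium_ri: float = 1.337
    noise_sd: float = 0.002
    shrinkage: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        geom = (
            *self.nucleus_semiaxes,
            self.midpiece_length,
            self.midpiece_radius,
            self.tail_length,
            self.tail_radius,
        )
        if any(g <= 0 for g in geom):
            raise ValidationError("all phantom linear dimensions must be positive")
        # equality with the medium is allowed: it renders a compartment
        # optically invisible (useful for single-compartment phantoms)
        if not (self.medium_ri <= self.midpiece_ri < self.nucleus_ri):
            raise ValidationError(
                "require medium_ri <= midpiece_ri < nucleus_ri, got "
                f"{self.medium_ri}, {self.midpiece_ri}, {self.nucleus_ri}"
            )
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")
        object.__setattr__(self, "shrinkage", _full_shrinkage(self.shrinkage))
        for region, f in self.shrinkage.items():
            if not (0 < f <= 1.5):
                raise ValidationError(
                    f"shrinkage factor for {region!r} must lie in (0, 1.5], got {f}"
                )

    @property
    def total_length(self) -> float:
        """End-to-end phantom length along z (µm)."""
        return 2 * self.nucleus_semiaxes[2] + self.midpiece_length + self.tail_length

    @property
    def max_radius(self) -> float:
        """Largest transverse half-extent (µm)."""
        return max(self.nucleus_semiaxes[0], self.nucleus_semiaxes[1],
                   self.midpiece_radius, self.tail_radius)


def analytic_volumes(spec: PhantomSpec) -> dict[str, float]:
    """Closed-form compartment volumes (µm³), plus their sum as ``whole``.

    The three shapes are disjoint by construction (cylinders start where the
    ellipsoid ends), so the whole-cell volume is an exact sum.
    """
    a, b, c = spec.nucleus_semiaxes
    v = {
        "nucleus": 4.0 / 3.0 * math.pi * a * b * c,
        "midpiece": math.pi * spec.midpiece_radius**2 * spec.midpiece_length,
        "tail": math.pi * spec.tail_radius**2 * spec.tail_length,
    }
    v["whole"] = v["nucleus"] + v["midpiece"] + v["tail"]
    return v


def _scale_regions(spec: PhantomSpec, factors: Mapping[str, float],
                   record: bool = True) -> PhantomSpec:
    """Scale each region's volume by its factor (linear dims by factor^(1/3))."""
    full = {region: float(factors.get(region, 1.0)) for region in REGIONS}
    for region, f in full.items():
        if f <= 0:
            raise ValidationError(f"scale factor for {region!r} must be positive, got {f}")
    ln = {region: f ** (1.0 / 3.0) for region, f in full.items()}
    a, b, c = spec.nucleus_semiaxes
    new_shrinkage = dict(spec.shrinkage)
    if record:
        for region in REGIONS:
            new_shrinkage[region] = new_shrinkage[region] * full[region]
    return replace(
        spec,
        nucleus_semiaxes=(a * ln["nucleus"], b * ln["nucleus"], c * ln["nucleus"]),
        midpiece_length=spec.midpiece_length * ln["midpiece"],
        midpiece_radius=spec.midpiece_radius * ln["midpiece"],
        tail_length=spec.tail_length * ln["tail"],
        tail_radius=spec.tail_radius * ln["tail"],
        shrinkage=new_shrinkage,
    )


def apply_cryo_effect(spec: PhantomSpec, shrinkage: Mapping[str, float]) -> PhantomSpec:
    """Return a new spec with cryo-induced volume scaling applied per region.

    A factor ``f`` scales the region's linear dimensions by ``f**(1/3)`` so
    its volume scales exactly by ``f``.  Factors above 1 model swelling.
    The input spec is left untouched.
    """
    for region, f in shrinkage.items():
        if region not in REGIONS:
            raise ValidationError(f"unknown region {region!r}; expected one of {REGIONS}")
        if f <= 0:
            raise ValidationError(f"shrinkage factor for {region!r} must be positive, got {f}")
    return _scale_regions(spec, shrinkage, record=True)


def render_tomogram(
    spec: PhantomSpec,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
) -> RITomogram:
    """Rasterise a phantom onto a voxel grid and add Gaussian RI noise.

    Parameters
    ----------
    spec
        Phantom geometry and optical parameters.
    voxel_size
        Pitch ``(dx, dy, dz)`` in µm.
    grid_shape
        Grid extent ``(nx, ny, nz)`` in voxels; the returned array is stored
        ``(z, y, x)``.

    The phantom is centred in the grid, nucleus first along +z, then the
    midpiece, then the tail.  Rendering is deterministic for a fixed
    ``spec.seed``.  Raises :class:`GeometryError` if the phantom does not fit
    with a two-voxel margin on every side.
    """
    dx, dy, dz = (float(v) for v in voxel_size)
    if min(dx, dy, dz) <= 0:
        raise ValidationError(f"voxel dimensions must be positive, got {voxel_size}")
    nx, ny, nz = (int(n) for n in grid_shape)
    if min(nx, ny, nz) < 1:
        raise ValidationError(f"grid shape must be positive, got {grid_shape}")

    lx, ly, lz = nx * dx, ny * dy, nz * dz
    if spec.total_length + 2 * _MARGIN_VOXELS * dz > lz:
        raise GeometryError(
            f"phantom length {spec.total_length:.2f} µm exceeds z extent "
            f"{lz:.2f} µm minus margin"
        )
    if (2 * spec.max_radius + 2 * _MARGIN_VOXELS * dx > lx
            or 2 * spec.max_radius + 2 * _MARGIN_VOXELS * dy > ly):
        raise GeometryError(
            f"phantom radius {spec.max_radius:.2f} µm exceeds transverse extent"
        )

    # voxel-centre coordinates, broadcast to (z, y, x)
    z = ((np.arange(nz, dtype=np.float32) + 0.5) * dz)[:, None, None]
    y = ((np.arange(ny, dtype=np.float32) + 0.5) * dy)[None, :, None]
    x = ((np.arange(nx, dtype=np.float32) + 0.5) * dx)[None, None, :]

    rng = np.random.default_rng(spec.seed)
    # random sub-voxel placement: under a uniform translation the voxel
    # count is an unbiased volume estimator, so digitization bias (severe
    # for the few-voxel-thick midpiece) averages out across cells instead
    # of distorting volume ratios.  Deterministic for a fixed seed.
    ox, oy, oz = rng.uniform(-0.5, 0.5, 3) * (dx, dy, dz)

    xc, yc = lx / 2.0 + ox, ly / 2.0 + oy
    z0 = (lz - spec.total_length) / 2.0 + oz
    a, b, c = spec.nucleus_semiaxes

    grid = np.full((nz, ny, nx), np.float32(spec.medium_ri), dtype=np.float32)

    rad2 = (x - xc) ** 2 + (y - yc) ** 2
    z_mid0 = z0 + 2 * c
    # the midpiece gets one axial voxel of grace into the nucleus tip: the
    # ellipsoid is thinner than a voxel near its apex, and without the grace
    # the voxelized junction can break into two components.  The nucleus is
    # painted last, so nucleus voxels are untouched by the overlap.
    midpiece = (rad2 <= spec.midpiece_radius**2) & (z >= z_mid0 - dz) & (z < z_mid0 + spec.midpiece_length)
    grid[midpiece] = spec.midpiece_ri

    z_tail0 = z_mid0 + spec.midpiece_length
    tail = (rad2 <= spec.tail_radius**2) & (z >= z_tail0) & (z < z_tail0 + spec.tail_length)
    grid[tail] = spec.tail_ri

    r2 = ((x - xc) / a) ** 2 + ((y - yc) / b) ** 2
    nucleus = r2 + ((z - (z0 + c)) / c) ** 2 <= 1.0
    grid[nucleus] = spec.nucleus_ri

    if spec.noise_sd > 0:
        grid += rng.standard_normal(grid.shape, dtype=np.float32) * np.float32(spec.noise_sd)

    return RITomogram(grid=grid, voxel_size=(dx, dy, dz), medium_ri=spec.medium_ri)


# ---------------------------------------------------------------------------
# study-level simulation

#: Per-extender per-region shrinkage distributions (mean, sd) of the volume
#: factor, emulating the pattern seen across freezing media: the midpiece is
#: the most affected compartment (worst with Spectrum Duo Red, losses can
#: exceed 50%), the nucleus stays nearly stable, and slow-cooled media
#: (INRA Freeze, HF-20) preserve volume better than fast-cooled ones.
DEFAULT_EXTENDER_EFFECTS: dict[str, dict[str, tuple[float, float]]] = {
    "SpectrumDuoRed": {"midpiece": (0.55, 0.08), "nucleus": (0.95, 0.03), "tail": (0.80, 0.05)},
    "BotuCrio":       {"midpiece": (0.70, 0.08), "nucleus": (0.95, 0.03), "tail": (0.85, 0.05)},
    "INRAFreeze":     {"midpiece": (0.85, 0.06), "nucleus": (0.97, 0.02), "tail": (0.90, 0.05)},
    "HF-20":          {"midpiece": (0.80, 0.06), "nucleus": (0.97, 0.02), "tail": (0.90, 0.05)},
}


@dataclass(frozen=True)
class StudyDesign:
    """Donor × extender × cell layout of a synthetic cryotolerance study.

    Defaults reproduce the study scale: 11 donors, one fresh reference
    extender (INRA96) plus four freezing extenders, 40 cells per sample.
    Donors listed in ``good_cooler_donors`` resist freezing in every region
    (shrinkage drawn near 1 under every extender).
    """

    n_donors: int = 11
    extenders: tuple[str, ...] = (
        "INRA96", "SpectrumDuoRed", "BotuCrio", "INRAFreeze", "HF-20",
    )
    fresh_extender: str = "INRA96"
    cells_per_sample: int = 40
    donor_effects: Mapping[int, float] | None = None
    extender_effects: Mapping[str, Mapping[str, tuple[float, float]]] = field(
        default_factory=lambda: DEFAULT_EXTENDER_EFFECTS
    )
    good_cooler_donors: tuple[int, ...] = (2, 4)
    good_cooler_effect: tuple[float, float] = (0.98, 0.02)
    donor_scale_sd: float = 0.08
    cell_jitter_sd: float = 0.03
    base_spec: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_donors < 1:
            raise ValidationError("n_donors must be >= 1")
        if self.cells_per_sample < 1:
            raise ValidationError("cells_per_sample must be >= 1")
        if self.fresh_extender not in self.extenders:
            raise ValidationError(
                f"fresh extender {self.fresh_extender!r} not in extender list"
            )
        if len(set(self.extenders)) != len(self.extenders):
            raise ValidationError("extender labels must be unique")
        for ext in self.extenders:
            if ext == self.fresh_extender:
                continue
            if ext not in self.extender_effects:
                raise ValidationError(f"no shrinkage distribution for extender {ext!r}")
            for region, (mean, sd) in self.extender_effects[ext].items():
                if mean <= 0 or sd < 0:
                    raise ValidationError(
                        f"invalid shrinkage distribution for {ext!r}/{region!r}"
                    )
        if self.donor_effects is not None:
            for donor, scale in self.donor_effects.items():
                if scale <= 0:
                    raise ValidationError(f"donor {donor} effect scale must be positive")

    @property
    def frozen_extenders(self) -> tuple[str, ...]:
        return tuple(e for e in self.extenders if e != self.fresh_extender)


@dataclass(frozen=True)
class CellPlan:
    """One planned cell: who it belongs to and the spec to render."""

    donor: int
    extender: str
    cell_id: int
    spec: PhantomSpec


class StudySimulation:
    """A fully planned cohort; tomograms are rendered lazily on demand.

    ``plans`` fixes every cell's spec (and hence its analytic ground-truth
    volumes) up front; :meth:`iter_tomograms` rasterises them one at a time
    so a 2200-cell study never holds all grids in memory.
    """

    def __init__(self, design: StudyDesign, plans: Sequence[CellPlan],
                 voxel_size: tuple[float, float, float],
                 grid_shape: tuple[int, int, int]) -> None:
        self.design = design
        self.plans = list(plans)
        self.voxel_size = voxel_size
        self.grid_shape = grid_shape

    def __len__(self) -> int:
        return len(self.plans)

    @property
    def ground_truth(self) -> pd.DataFrame:
        """True (analytic) region volumes: donor, extender, cell_id, region, true_volume_um3."""
        rows = []
        for plan in self.plans:
            for region, vol in analytic_volumes(plan.spec).items():
                rows.append((plan.donor, plan.extender, plan.cell_id, region, vol))
        return pd.DataFrame(
            rows, columns=["donor", "extender", "cell_id", "region", "true_volume_um3"]
        )

    def render(self, plan: CellPlan) -> RITomogram:
        tomo = render_tomogram(plan.spec, self.voxel_size, self.grid_shape)
        tomo.metadata.update(
            donor=plan.donor, extender=plan.extender, cell_id=plan.cell_id,
            seed=plan.spec.seed,
        )
        return tomo

    def iter_tomograms(self) -> Iterator[tuple[CellPlan, RITomogram]]:
        for plan in self.plans:
            yield plan, self.render(plan)

    def write_to_dir(self, outdir: str | Path) -> Path:
        """Render the whole cohort to TIFF stacks + sidecars + truth CSV."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for plan, tomo in self.iter_tomograms():
            name = f"donor{plan.donor:02d}_{plan.extender}_cell{plan.cell_id:03d}.tif"
            write_tomogram(tomo, outdir / name)
        self.ground_truth.to_csv(outdir / "ground_truth.csv", index=False)
        return outdir


def simulate_study(
    design: StudyDesign,
    voxel_size: tuple[float, float, float] = DEFAULT_VOXEL_SIZE,
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
) -> StudySimulation:
    """Plan a donor × extender × cell cohort of phantoms.

    Per donor, a baseline size scale is drawn (log-normal around 1) and a set
    of per-cell base specs is generated with small log-normal size jitter.
    The fresh arm renders those base specs directly; each frozen arm applies
    :func:`apply_cryo_effect` to the *same* base specs with per-cell
    shrinkage factors drawn from the extender's per-region distribution
    (good-cooler donors draw from a near-1 distribution instead).  The whole
    plan, including per-cell render seeds, is reproducible from
    ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    plans: list[CellPlan] = []

    donor_ids = list(range(1, design.n_donors + 1))
    if design.donor_effects is not None:
        donor_scale = {d: float(design.donor_effects.get(d, 1.0)) for d in donor_ids}
    else:
        donor_scale = {
            d: float(np.exp(rng.normal(0.0, design.donor_scale_sd))) for d in donor_ids
        }

    for donor in donor_ids:
        base = _scale_regions(
            design.base_spec,
            {region: donor_scale[donor] for region in REGIONS},
            record=False,
        )
        cell_bases = []
        for cell_id in range(1, design.cells_per_sample + 1):
            jitter = float(np.exp(rng.normal(0.0, design.cell_jitter_sd)))
            # total baseline variation truncated at ±30% volume so every
            # cell (fresh or swollen) stays inside the default grid
            combined = float(np.clip(donor_scale[donor] * jitter, 0.7, 1.3))
            rel = combined / donor_scale[donor] if donor_scale[donor] else 1.0
            cell_bases.append(
                _scale_regions(base, {region: rel for region in REGIONS}, record=False)
            )
        for extender in design.extenders:
            fresh = extender == design.fresh_extender
            good = donor in design.good_cooler_donors
            for cell_id, cell_base in enumerate(cell_bases, start=1):
                if fresh:
                    spec = cell_base
                else:
                    factors = {}
                    for region in REGIONS:
                        if good:
                            mean, sd = design.good_cooler_effect
                        else:
                            mean, sd = design.extender_effects[extender].get(region, (1.0, 0.0))
                        f = rng.normal(mean, sd) if sd > 0 else mean
                        factors[region] = float(np.clip(f, 0.05, 1.5))
                    spec = apply_cryo_effect(cell_base, factors)
                seed = int(rng.integers(0, 2**31 - 1))
                plans.append(CellPlan(donor, extender, cell_id, replace(spec, seed=seed)))

    return StudySimulation(design, plans, voxel_size, grid_shape)
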