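"""End-to-end orchestration: simulate → segment → measure → freezability.

The study pipeline renders each planned phantom, segments it with the RI
windows, measures per-region volumes (optionally the full morphometry set)
and returns a tidy per-cell table ready for :func:`cryoht.freezability.aggregate`
and the statistics stage.  Tomograms are rendered one at a time; a full
11 × 5 × 40 cohort never resides in memory.
"""

from __future__ import annotations

import pandas as pd

from .freezability import FI_REGIONS, aggregate, records_to_frame
from .morphometry import DEFAULT_REFRACTIVE_INCREMENT, measure_cell, volume
from .phantoms import StudyDesign, StudySimulation, simulate_study
from .segmentation import RIRangeSet, segment_cell

__all__ = ["measure_study", "run_synthetic_study"]


def measure_study(sim: StudySimulation, ranges: RIRangeSet | None = None,
                  full_morphometry: bool = False,
                  refractive_increment: float = DEFAULT_REFRACTIVE_INCREMENT
                  ) -> pd.DataFrame:
    """Segment and measure every cell of a planned study.

    Returns one row per (donor, extender, cell_id, region) with
    ``volume_um3`` (and, with ``full_morphometry``, surface area, sphericity,
    projection area, dry mass, concentration and mean RI).  Regions here are
    the reported ones: whole, midpiece, nucleus.
    """
    ranges = ranges or RIRangeSet()
    rows = []
    for plan, tomo in sim.iter_tomograms():
        seg = segment_cell(tomo, ranges, clean=True)
        if full_morphometry:
            for region, m in measure_cell(tomo, seg, refractive_increment).items():
                rows.append({
                    "donor": plan.donor, "extender": plan.extender,
                    "cell_id": plan.cell_id, "region": region,
                    "volume_um3": m.volume, "surface_area_um2": m.surface_area,
                    "sphericity": m.sphericity, "projection_area_um2": m.projection_area,
                    "dry_mass_pg": m.dry_mass, "concentration_pg_um3": m.concentration,
                    "mean_ri": m.mean_ri, "voxel_count": m.voxel_count,
                })
        else:
            for region in FI_REGIONS:
                rows.append({
                    "donor": plan.donor, "extender": plan.extender,
                    "cell_id": plan.cell_id, "region": region,
                    "volume_um3": volume(seg[region], tomo.voxel_size),
                })
    return pd.DataFrame(rows)


def run_synthetic_study(design: StudyDesign | None = None,
                        ranges: RIRangeSet | None = None,
                        **measure_kwargs) -> dict[str, pd.DataFrame]:
    """Simulate a cohort and push it through the whole volumetric pipeline.

    Returns a dict with the per-cell measured table (``cells``), the
    generator's analytic ground truth (``truth``) and the per-donor ×
    extender × region freezability table (``fi``).
    """
    design = design or StudyDesign()
    sim = simulate_study(design)
    cells = measure_study(sim, ranges, **measure_kwargs)
    records = aggregate(cells, fresh_label=design.fresh_extender)
    return {
        "cells": cells,
        "truth": sim.ground_truth,
        "fi": records_to_frame(records),
    }
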