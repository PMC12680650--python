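"""The HT Freezability Index and donor cooler-phenotype classification.

The HT Freezability Index of a sperm region compares the mean volume of that
region after freezing with a given extender against the mean volume of the
same region in the donor's fresh reference sample:

    FI_HT = V_freezing_extender / V_fresh_reference × 100   (percent)

100% means no structural change; values below 100% indicate post-freeze
volume loss (dehydration, structural collapse); values above 100% are legal
and indicate swelling.  Because different spermatozoa are imaged fresh and
frozen, the index is a ratio of *sample means*, never of per-cell pairs.

A motility counterpart applies the same ratio to pre- vs post-freeze total
or progressive motility percentages.

Donors are classified as good / intermediate / poor "coolers" from their
per-region indices: good coolers keep every region near 100% (≥ 90% by
default); a donor with any region below 80% — substantial structural
shrinkage — is a poor cooler.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import pandas as pd

from .errors import ValidationError

__all__ = [
    "FreezabilityRecord",
    "CoolerCall",
    "fi_ht",
    "motility_freezability",
    "aggregate",
    "records_to_frame",
    "classify_cooler",
]

#: Regions the index is reported for.
FI_REGIONS = ("midpiece", "nucleus", "whole")


@dataclass(frozen=True)
class FreezabilityRecord:
    """FI_HT of one donor × extender × region."""

    donor: object
    extender: str
    region: str
    v_fresh: float      # µm³, mean over the donor's fresh-reference cells
    v_frozen: float     # µm³, mean over the frozen-arm cells
    fi_ht: float        # %
    n_cells_fresh: int
    n_cells_frozen: int


@dataclass(frozen=True)
class CoolerCall:
    """Cooler phenotype of one donor (optionally per extender)."""

    donor: object
    call: Literal["good", "intermediate", "poor"]
    fi_by_region: dict[str, float]
    extender: str | None = None  # None when pooled across extenders


def fi_ht(v_frozen: float, v_fresh: float) -> float:
    """HT Freezability Index (%) of a region: frozen/fresh volume × 100."""
    if v_fresh <= 0:
        raise ValidationError(f"fresh reference volume must be positive, got {v_fresh}")
    if v_frozen < 0:
        raise ValidationError(f"frozen volume must be non-negative, got {v_frozen}")
    return v_frozen / v_fresh * 100.0


def motility_freezability(post: float, pre: float,
                          mode: Literal["ratio", "delta"] = "ratio") -> float:
    """Motility freezability: post- vs pre-freeze motility percentage.

    ``ratio`` (default) mirrors the volumetric index: post/pre × 100.
    ``delta`` returns the loss in percentage points (post − pre) for workflows
    that prefer an absolute drop.  Inputs are motility percentages in
    [0, 100]; the ratio mode requires pre > 0.
    """
    for name, value in (("post", post), ("pre", pre)):
        if not 0 <= value <= 100:
            raise ValidationError(f"{name}-freeze motility must be in [0, 100], got {value}")
    if mode == "ratio":
        if pre == 0:
            raise ValidationError("pre-freeze motility must be positive for the ratio index")
        return post / pre * 100.0
    if mode == "delta":
        return post - pre
    raise ValidationError(f"mode must be 'ratio' or 'delta', got {mode!r}")


def aggregate(morph_table: pd.DataFrame, fresh_label: str = "INRA96",
              regions: Sequence[str] = FI_REGIONS,
              volume_column: str = "volume_um3") -> list[FreezabilityRecord]:
    """Compute FI_HT per (donor, frozen extender, region) from per-cell volumes.

    ``morph_table`` needs columns ``donor, extender, cell_id, region`` and a
    volume column.  For each donor and region, the fresh-arm mean volume is
    the denominator for every frozen extender.  Donors without a fresh
    reference raise a :class:`ValidationError` naming them.
    """
    required = {"donor", "extender", "region", volume_column}
    missing = required - set(morph_table.columns)
    if missing:
        raise ValidationError(f"morphometry table lacks columns {sorted(missing)}")
    donors = sorted(morph_table["donor"].unique())
    fresh = morph_table[morph_table["extender"] == fresh_label]
    lacking = [d for d in donors if d not in set(fresh["donor"])]
    if lacking:
        raise ValidationError(
            f"donors lacking a fresh reference ({fresh_label!r}): {lacking}"
        )
    frozen = morph_table[morph_table["extender"] != fresh_label]
    records = []
    for donor in donors:
        fresh_d = fresh[fresh["donor"] == donor]
        for region in regions:
            fresh_r = fresh_d[fresh_d["region"] == region][volume_column]
            if len(fresh_r) == 0:
                raise ValidationError(
                    f"donor {donor!r} has no fresh-arm cells for region {region!r}"
                )
            v_fresh = float(fresh_r.mean())
            frozen_d = frozen[frozen["donor"] == donor]
            for extender in sorted(frozen_d["extender"].unique()):
                sub = frozen_d[(frozen_d["extender"] == extender)
                               & (frozen_d["region"] == region)][volume_column]
                if len(sub) == 0:
                    continue
                v_frozen = float(sub.mean())
                records.append(FreezabilityRecord(
                    donor=donor, extender=extender, region=region,
                    v_fresh=v_fresh, v_frozen=v_frozen,
                    fi_ht=fi_ht(v_frozen, v_fresh),
                    n_cells_fresh=int(len(fresh_r)), n_cells_frozen=int(len(sub)),
                ))
    return records


def records_to_frame(records: Sequence[FreezabilityRecord]) -> pd.DataFrame:
    """Tabulate freezability records (one row per donor × extender × region)."""
    return pd.DataFrame([
        {"donor": r.donor, "extender": r.extender, "region": r.region,
         "v_fresh": r.v_fresh, "v_frozen": r.v_frozen, "fi_ht": r.fi_ht,
         "n_cells_fresh": r.n_cells_fresh, "n_cells_frozen": r.n_cells_frozen}
        for r in records
    ])


def classify_cooler(records: Sequence[FreezabilityRecord],
                    threshold_good: float = 90.0,
                    threshold_poor: float = 80.0,
                    pooled: bool = True) -> list[CoolerCall]:
    """Classify each donor as good / intermediate / poor cooler.

    A donor (or donor × extender, with ``pooled=False``) is *good* when the
    FI_HT of every region is at least ``threshold_good``, *poor* when any
    region falls below ``threshold_poor``, and *intermediate* otherwise.
    With ``pooled`` (default) the per-region index is first averaged across
    frozen extenders.
    """
    for name, t in (("threshold_good", threshold_good), ("threshold_poor", threshold_poor)):
        if not 0 < t <= 100:
            raise ValidationError(f"{name} must lie in (0, 100], got {t}")
    df = records_to_frame(records)
    if df.empty:
        return []
    group_cols = ["donor"] if pooled else ["donor", "extender"]
    calls = []
    for keys, sub in df.groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        fi = sub.groupby("region")["fi_ht"].mean().to_dict()
        values = list(fi.values())
        if any(v < threshold_poor for v in values):
            call = "poor"
        elif all(v >= threshold_good for v in values):
            call = "good"
        else:
            call = "intermediate"
        calls.append(CoolerCall(
            donor=keys[0], call=call, fi_by_region=fi,
            extender=None if pooled else keys[1],
        ))
    return calls
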