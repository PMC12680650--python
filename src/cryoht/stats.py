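"""Statistical workflow: arcsine transform, assumption checks, ANOVA,
Bonferroni pairwise comparisons, and per-donor / per-extender summary
reports.

Percentages (motility, freezability indices) are variance-stabilised with
the arcsine-square-root transform before ANOVA; volumes are analysed on
their natural scale.  Normality is assessed on model residuals with the
Shapiro–Wilk test and homogeneity of variance with Levene's test; if either
fails the ANOVA still proceeds with a logged warning (there is no documented
fallback in this workflow).  Pairwise extender contrasts use the Bonferroni
correction: raw p times the number of comparisons in the family, capped
at 1.  Significance threshold α = 0.05 throughout.

The heavy lifting (F distributions, Shapiro–Wilk, Levene, OLS fits) is
delegated to scipy/statsmodels; this module contributes the transforms,
family definitions and orchestration.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError

__all__ = [
    "StatResult",
    "arcsine_transform",
    "check_assumptions",
    "anova",
    "bonferroni_pairwise",
    "boxplot_table",
    "report",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StatResult:
    """One test outcome: statistic, p-value and provenance."""

    test: str
    factors: tuple[str, ...]
    statistic: float
    p_value: float
    transform: str | None = None
    n_per_group: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValidationError(f"p-value outside [0, 1]: {self.p_value}")


def arcsine_transform(p, clip: bool = False) -> np.ndarray | float:
    """Arcsine-square-root transform of a percentage: asin(sqrt(p/100)).

    Accepts scalars or arrays of percentages in [0, 100]; returns radians in
    [0, π/2].  Strictly increasing on its domain.  With ``clip``, values
    outside [0, 100] are clipped to the domain first (and logged) — needed
    for ratio indices like FI_HT, which may legitimately exceed 100% under
    swelling.
    """
    arr = np.asarray(p, dtype=float)
    outside = (arr < 0) | (arr > 100)
    if np.any(outside):
        if not clip:
            raise ValidationError("percentages must lie in [0, 100]")
        logger.warning("%d percentage values outside [0, 100] clipped before "
                       "the arcsine transform", int(outside.sum()))
        arr = np.clip(arr, 0.0, 100.0)
    out = np.arcsin(np.sqrt(arr / 100.0))
    return float(out) if np.isscalar(p) or out.ndim == 0 else out


def _split_groups(values: np.ndarray, groups: np.ndarray) -> dict[object, np.ndarray]:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValidationError("values and groups must have the same length")
    return {g: values[groups == g] for g in pd.unique(groups)}


def check_assumptions(values, groups) -> tuple[StatResult, StatResult]:
    """Shapiro–Wilk normality (on within-group residuals) and Levene's test.

    Requires at least 3 observations per group; a constant-valued group has
    zero variance and raises.  Failures are logged, not fatal: the ANOVA
    downstream proceeds regardless, as this workflow defines no fallback.
    """
    by_group = _split_groups(values, groups)
    for g, v in by_group.items():
        if len(v) < 3:
            raise ValidationError(f"group {g!r} has fewer than 3 observations")
        if np.ptp(v) == 0:
            raise ValidationError(f"group {g!r} is constant-valued (zero variance)")
    residuals = np.concatenate([v - v.mean() for v in by_group.values()])
    w, p_norm = sps.shapiro(residuals)
    lev, p_lev = sps.levene(*by_group.values(), center="mean")
    n = {str(g): int(len(v)) for g, v in by_group.items()}
    if p_norm < 0.05:
        logger.warning("Shapiro–Wilk rejects residual normality (p=%.3g)", p_norm)
    if p_lev < 0.05:
        logger.warning("Levene rejects variance homogeneity (p=%.3g)", p_lev)
    return (
        StatResult("shapiro-wilk", ("group",), float(w), float(p_norm), n_per_group=n),
        StatResult("levene", ("group",), float(lev), float(p_lev), n_per_group=n),
    )


def anova(data: pd.DataFrame, response: str, factors: Sequence[str],
          interaction: bool = False,
          transform: str | None = None) -> list[StatResult]:
    """Fixed-effects ANOVA of ``response`` on one or more factors.

    One factor → classic one-way ANOVA; several factors → additive two-way
    (or higher) model via OLS, with the interaction included on request.
    ``transform='arcsine'`` applies the percentage transform first.  Returns
    one :class:`StatResult` per model term.
    """
    if len(factors) == 0:
        raise ValidationError("at least one factor is required")
    missing = (set(factors) | {response}) - set(data.columns)
    if missing:
        raise ValidationError(f"data lacks columns {sorted(missing)}")
    y = data[response].to_numpy(dtype=float)
    if transform == "arcsine":
        y = arcsine_transform(y, clip=True)
    elif transform is not None:
        raise ValidationError(f"unknown transform {transform!r}")

    if len(factors) == 1:
        by_group = _split_groups(y, data[factors[0]].to_numpy())
        if len(by_group) < 2:
            raise ValidationError("ANOVA needs at least 2 groups")
        for g, v in by_group.items():
            if len(v) < 2:
                raise ValidationError(f"group {g!r} has fewer than 2 observations")
        f, p = sps.f_oneway(*by_group.values())
        n = {str(g): int(len(v)) for g, v in by_group.items()}
        return [StatResult("anova", tuple(factors), float(f), float(p),
                           transform=transform, n_per_group=n)]

    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    frame = data[list(factors)].copy()
    frame["_y"] = y
    op = " * " if interaction else " + "
    formula = "_y ~ " + op.join(f"C({f})" for f in factors)
    model = smf.ols(formula, data=frame).fit()
    table = sm.stats.anova_lm(model, typ=2)
    results = []
    for term, row in table.iterrows():
        if term == "Residual":
            continue
        results.append(StatResult(
            "anova", tuple(factors), float(row["F"]), float(row["PR(>F)"]),
            transform=transform,
            n_per_group={f: int(data[f].nunique()) for f in factors},
        ))
    return results


def bonferroni_pairwise(data: pd.DataFrame, response: str, factor: str,
                        transform: str | None = None) -> pd.DataFrame:
    """All pairwise level contrasts of one factor, Bonferroni-adjusted.

    The family is every pairwise comparison of the factor's levels for this
    response; adjusted p = min(1, raw p × family size).  Raw p comes from a
    pooled-variance two-sample t-test per pair.
    """
    y = data[response].to_numpy(dtype=float)
    if transform == "arcsine":
        y = arcsine_transform(y, clip=True)
    by_group = _split_groups(y, data[factor].to_numpy())
    levels = sorted(by_group, key=str)
    if len(levels) < 2:
        raise ValidationError("pairwise comparisons need at least 2 levels")
    pairs = list(itertools.combinations(levels, 2))
    k = len(pairs)
    rows = []
    for a, b in pairs:
        t, p_raw = sps.ttest_ind(by_group[a], by_group[b], equal_var=True)
        rows.append({
            "level_a": a, "level_b": b,
            "mean_a": float(by_group[a].mean()), "mean_b": float(by_group[b].mean()),
            "t": float(t), "p_raw": float(p_raw),
            "p_bonferroni": float(min(1.0, p_raw * k)),
            "n_comparisons": k,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# reporting


def boxplot_table(df: pd.DataFrame, value: str, by: str) -> pd.DataFrame:
    """Five-number summaries per group: median, quartiles, Tukey whiskers.

    Whiskers are the most extreme observations within 1.5 IQR of the
    quartiles (the usual box-plot rule); a single observation collapses the
    whole summary onto its value.
    """
    rows = []
    for level, sub in df.groupby(by, sort=True):
        v = sub[value].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo = v[v >= q1 - 1.5 * iqr].min()
        hi = v[v <= q3 + 1.5 * iqr].max()
        rows.append({by: level, "n": len(v), "median": med, "q1": q1, "q3": q3,
                     "whisker_low": lo, "whisker_high": hi})
    return pd.DataFrame(rows)


def report(fi_table: pd.DataFrame, outdir: str | Path,
           kin_table: pd.DataFrame | None = None,
           stat_results: Sequence[StatResult] = (),
           make_plots: bool = True) -> dict[str, Path]:
    """Write per-donor and per-extender summary tables (and box plots).

    ``fi_table`` is the freezability table (donor, extender, region, fi_ht).
    For each region, five-number summaries are written grouped by donor and
    by extender; kinematic summaries and test outcomes are appended when
    given.  Output CSVs are deterministic for identical inputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    pieces = []
    for by in ("donor", "extender"):
        for region, sub in fi_table.groupby("region", sort=True):
            t = boxplot_table(sub, "fi_ht", by)
            t.insert(0, "region", region)
            t.insert(0, "grouping", by)
            t = t.rename(columns={by: "level"})
            pieces.append(t)
    summary = pd.concat(pieces, ignore_index=True)
    path = outdir / "fi_summary.csv"
    summary.to_csv(path, index=False, float_format="%.6g")
    written["fi_summary"] = path

    if kin_table is not None:
        path = outdir / "kinematics_summary.csv"
        kin_table.to_csv(path, index=False, float_format="%.6g")
        written["kinematics_summary"] = path

    if stat_results:
        rows = [{
            "test": r.test, "factors": "*".join(r.factors),
            "statistic": r.statistic, "p_value": r.p_value,
            "transform": r.transform or "",
        } for r in stat_results]
        path = outdir / "stat_results.csv"
        pd.DataFrame(rows).to_csv(path, index=False, float_format="%.6g")
        written["stat_results"] = path

    if make_plots:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for by in ("donor", "extender"):
            regions = sorted(fi_table["region"].unique())
            fig, axes = plt.subplots(1, len(regions),
                                     figsize=(4 * len(regions), 4), squeeze=False)
            for ax, region in zip(axes[0], regions):
                sub = fi_table[fi_table["region"] == region]
                levels = sorted(sub[by].unique(), key=str)
                ax.boxplot([sub[sub[by] == lv]["fi_ht"] for lv in levels],
                           tick_labels=[str(lv) for lv in levels])
                ax.axhline(100.0, color="grey", lw=0.8, ls="--")
                ax.set_title(f"FI_HT — {region}")
                ax.set_xlabel(by)
                ax.set_ylabel("FI_HT (%)")
                ax.tick_params(axis="x", rotation=45)
            fig.tight_layout()
            path = outdir / f"fi_by_{by}.png"
            fig.savefig(path, dpi=120)
            plt.close(fig)
            written[f"fi_by_{by}"] = path
    return written
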