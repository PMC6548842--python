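"""Alignment-quality metrics and the canopy-coverage comparison.

The alignment error of a cell is the Euclidean distance between its
ground-truth displacement vector and the computed one, reported in
physical units (cm).  Error distributions are summarized with standard
box-and-whisker statistics (1.5 IQR whiskers, individually flagged
outliers, and notch half-widths for medians).

Canopy coverage -- the fraction of a cell's pixels classified as plant --
is the downstream trait used to judge what accurate plot extraction buys:
coverage is computed for a regular uniform grid, a length-trimmed grid, the
automatically refined grid, and the ground-truth grid, and the four groups
are compared with a one-way ANOVA plus Tukey HSD multiple comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict

import numpy as np
from scipy import stats

from .grid_model import DisplacementField, Grid
from .scalar_field import build_summed_area_table, rect_sums

__all__ = [
    "BoxplotSummary",
    "ErrorReport",
    "CoverageReport",
    "alignment_error",
    "boxplot_summary",
    "trim_grid",
    "canopy_coverage",
    "coverage_comparison",
]


@dataclass
class BoxplotSummary:
    """Five-number boxplot statistics with 1.5 IQR whiskers and notches."""

    median: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    outliers: np.ndarray
    notch_lo: float
    notch_hi: float
    n: int


@dataclass
class ErrorReport:
    """Per-cell alignment errors (non-negative) and their summary."""

    per_cell_errors: np.ndarray  # (P, Q), in `units`
    units: str
    summary: BoxplotSummary

    @property
    def median(self) -> float:
        return self.summary.median


@dataclass
class CoverageReport:
    """Coverage fractions per grid variant plus the ANOVA table."""

    coverage: Dict[str, np.ndarray]  # variant -> (P, Q) in [0, 1]
    anova: Dict[str, float]  # SS_between, SS_within, df_between, df_within, MS_*, F, p
    pairwise_different: list[tuple[str, str]]  # Tukey HSD at alpha = 0.05


def boxplot_summary(errors: np.ndarray) -> BoxplotSummary:
    """Boxplot statistics of a sample: median, quartiles, 1.5 IQR whiskers
    (drawn at the most extreme data points inside the fences), outliers
    beyond the fences, and 1.57 IQR / sqrt(n) median notches."""
    x = np.asarray(errors, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = x[(x >= lo_fence) & (x <= hi_fence)]
    notch = 1.57 * iqr / np.sqrt(x.size)
    return BoxplotSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(inside.min()),
        whisker_hi=float(inside.max()),
        outliers=np.sort(x[(x < lo_fence) | (x > hi_fence)]),
        notch_lo=float(med - notch),
        notch_hi=float(med + notch),
        n=int(x.size),
    )


def alignment_error(
    truth: DisplacementField,
    computed: DisplacementField,
    resolution_cm_per_px: float = 0.8,
    units: str = "cm",
) -> ErrorReport:
    """Per-cell Euclidean distance between ground-truth and computed
    displacements, converted from pixels to cm via the image resolution."""
    if truth.shape != computed.shape:
        raise ValueError(
            f"displacement shapes differ: {truth.shape} vs {computed.shape}"
        )
    err_px = np.hypot(truth.du - computed.du, truth.dv - computed.dv)
    if units == "cm":
        err = err_px * resolution_cm_per_px
    elif units == "px":
        err = err_px
    else:
        raise ValueError(f"unknown error units {units!r}")
    return ErrorReport(per_cell_errors=err, units=units, summary=boxplot_summary(err))


def trim_grid(grid: Grid, trim_fraction: float) -> Grid:
    """Shrink each cell's length (its longer dimension) to
    ``(1 - trim_fraction)`` of itself about the same center -- the common
    workaround of analyzing only the central portion of plots."""
    if not 0.0 <= trim_fraction < 1.0:
        raise ValueError("trim_fraction must lie in [0, 1)")
    if trim_fraction == 0.0:
        return replace(grid)
    keep = 1.0 - trim_fraction
    if grid.cell_h >= grid.cell_w:
        return replace(grid, cell_h=grid.cell_h * keep)
    return replace(grid, cell_w=grid.cell_w * keep)


def canopy_coverage(mask: np.ndarray, grid: Grid) -> np.ndarray:
    """Fraction of plant pixels inside each cell, denominated by the cell's
    own pixel area (clipped parts outside the image count as non-plant)."""
    mask = np.asarray(mask)
    sat = build_summed_area_table(mask.astype(float))
    w_px = round(grid.cell_w)
    h_px = round(grid.cell_h)
    x1 = np.rint(grid.centers_u - grid.cell_w / 2.0).astype(np.int64)
    y1 = np.rint(grid.centers_v - grid.cell_h / 2.0).astype(np.int64)
    counts = rect_sums(sat, x1, y1, x1 + w_px, y1 + h_px)
    return counts / float(w_px * h_px)


def _one_way_anova(groups: Dict[str, np.ndarray]) -> Dict[str, float]:
    samples = [np.asarray(v, float).ravel() for v in groups.values()]
    k = len(samples)
    n = sum(s.size for s in samples)
    grand = np.concatenate(samples).mean()
    ss_between = sum(s.size * (s.mean() - grand) ** 2 for s in samples)
    ss_within = sum(((s - s.mean()) ** 2).sum() for s in samples)
    df_b, df_w = k - 1, n - k
    ms_b = ss_between / df_b
    ms_w = ss_within / df_w if df_w > 0 else np.nan
    if ss_within == 0:
        f_stat = 0.0 if ss_between == 0 else float("inf")
        p = 1.0 if ss_between == 0 else 0.0
    else:
        f_stat = ms_b / ms_w
        p = float(stats.f.sf(f_stat, df_b, df_w))
    return {
        "SS_between": float(ss_between),
        "SS_within": float(ss_within),
        "df_between": df_b,
        "df_within": df_w,
        "MS_between": float(ms_b),
        "MS_within": float(ms_w),
        "F": float(f_stat),
        "p": p,
    }


def coverage_comparison(
    mask: np.ndarray, grids: Dict[str, Grid], alpha: float = 0.05
) -> CoverageReport:
    """Compare per-cell canopy coverage across grid variants.

    ``grids`` maps variant names (typically regular / trimmed / refined /
    truth) to same-shaped grids.  Runs a one-way ANOVA across the coverage
    groups and Tukey's HSD to flag which variant pairs differ.
    """
    if len(grids) < 2:
        raise ValueError("at least two grid variants are required")
    shapes = {(g.P, g.Q) for g in grids.values()}
    if len(shapes) != 1:
        raise ValueError("all grids must share the same P x Q layout")
    coverage = {name: canopy_coverage(mask, g) for name, g in grids.items()}
    anova = _one_way_anova(coverage)
    names = list(coverage)
    pairwise = []
    if np.isfinite(anova["F"]) and anova["SS_within"] > 0:
        res = stats.tukey_hsd(*[coverage[n].ravel() for n in names])
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if res.pvalue[i, j] < alpha:
                    pairwise.append((names[i], names[j]))
    elif anova["SS_between"] > 0:  # zero within-group variance, groups differ
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                if not np.allclose(coverage[names[i]], coverage[names[j]]):
                    pairwise.append((names[i], names[j]))
    return CoverageReport(coverage=coverage, anova=anova, pairwise_different=pairwise)
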