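"""Scripted validation studies on synthetic trials.

Each study generates misaligned synthetic trials with known ground truth,
runs the swarm alignment, and summarizes per-cell errors: robustness to
swarm initialization, adaptability over random trials, stopping-tolerance
and swarm-density sweeps, and the cost-function ablation on the hard
paired-vigor / zero-gap scenario.  Every study is reproducible from its
plan (all seeds are explicit).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .energy import _pixel_rect
from .evaluation import alignment_error
from .grid_model import DisplacementField, grid_edges
from .optimizer import SwarmConfig, align_grid
from .scalar_field import build_summed_area_table, compute_green_red_vi, segment_plants
from .synthetic import (
    TrialSimulation,
    TrialSpec,
    render_field,
    sample_displacements,
    validation_trial_spec,
)

__all__ = [
    "ExperimentPlan",
    "make_trial",
    "hard_scenario_trial",
    "run_alignment",
    "run_initialization_study",
    "run_random_trials_study",
    "run_sweep",
    "run_ablation",
    "overlap_statistics",
]

#: a run is successful when its median per-cell error is at most this
#: fraction of the smaller grid pitch
SUCCESS_PITCH_FRACTION = 0.25


@dataclass
class ExperimentPlan:
    """One study: a trial generator, an optional sweep, and replication."""

    trial_spec: TrialSpec
    swarm: SwarmConfig = field(default_factory=SwarmConfig)
    sweep: Optional[str] = None  # None | "initialization" | "tolerance" | "swarm_density" | "ablation"
    levels: Sequence = ()
    replicates: int = 5
    seed: int = 0
    displacement_fraction: float = 1.0  # true displacements as a fraction of bounds
    success_threshold_cm: Optional[float] = None  # default: pitch-fraction rule

    def success_threshold(self) -> float:
        if self.success_threshold_cm is not None:
            return self.success_threshold_cm
        pitch_cm = min(self.trial_spec.pitch_u_m, self.trial_spec.pitch_v_m) * 100.0
        return SUCCESS_PITCH_FRACTION * pitch_cm


def make_trial(
    spec: TrialSpec, seed: int, displacement_fraction: float = 1.0
) -> TrialSimulation:
    """Generate one misaligned trial: true per-plot displacements are
    i.i.d. uniform within ``displacement_fraction`` of the half-pitch
    bounds."""
    rng = np.random.default_rng(seed)
    ppm = spec.px_per_m
    bound_u = spec.pitch_u_m * ppm / 2.0
    bound_v = spec.pitch_v_m * ppm / 2.0
    disp = sample_displacements(
        spec.P,
        spec.Q,
        bound_u,
        bound_v,
        rng,
        anisotropy=(displacement_fraction, displacement_fraction),
    )
    return render_field(dc_replace(spec, seed=seed), disp)


def hard_scenario_trial(seed: int, P: int = 4, Q: int = 6) -> TrialSimulation:
    """The adversarial scenario for the cost ablation: alternate pairs of
    plot rows touch (no gap along v), each touching pair couples a vigorous
    (fertilized) row with a weak (unfertilized) one, and misalignment is
    much larger along v than along u."""
    if P % 2:
        raise ValueError("the hard scenario pairs rows; P must be even")
    vigor = np.ones((P, Q))
    vigor[1::2, :] = 0.55
    spec = validation_trial_spec(seed=seed, P=P, Q=Q, vigor_levels=vigor)
    ppm = spec.px_per_m
    gap_px = (spec.pitch_v_m - spec.plot_h_m) * ppm
    rng = np.random.default_rng(seed)
    bound_u = spec.pitch_u_m * ppm / 2.0
    bound_v = spec.pitch_v_m * ppm / 2.0
    # v-bias closes the gap inside each row pair; small jitter on top
    bias_v = np.where(np.arange(P)[:, None] % 2 == 0, gap_px / 2.0, -gap_px / 2.0)
    du = rng.uniform(-0.15, 0.15, size=(P, Q)) * bound_u
    dv = bias_v + rng.uniform(-0.05, 0.05, size=(P, Q)) * bound_v
    disp = DisplacementField(
        du=du, dv=np.clip(dv, -bound_v, bound_v), bound_u=bound_u, bound_v=bound_v
    )
    return render_field(spec, disp)


def run_alignment(
    sim: TrialSimulation,
    config: SwarmConfig,
    intra_only: bool = False,
):
    """Full pipeline on one trial: index field, summed-area table, swarm
    optimization, per-cell error report.  Returns (result, report)."""
    sfield = compute_green_red_vi(sim.image)
    sat = build_summed_area_table(sfield)
    result = align_grid(
        sat, sim.uniform_grid, config=config, intra_only=intra_only
    )
    report = alignment_error(
        sim.truth_displacements,
        result.best_displacements,
        resolution_cm_per_px=sim.image.resolution_cm_per_px,
    )
    return result, report


def run_initialization_study(plan: ExperimentPlan) -> pd.DataFrame:
    """R independent swarm initializations on one fixed trial.

    Returns one row per run with the error summary and a success flag
    (median error at or below the plan's success threshold).
    """
    sim = make_trial(plan.trial_spec, plan.seed, plan.displacement_fraction)
    rows = []
    for r in range(plan.replicates):
        cfg = dc_replace(plan.swarm, seed=int(plan.seed * 10_000 + r + 1) % 2**31)
        _, report = run_alignment(sim, cfg)
        rows.append(
            {
                "run": r + 1,
                "swarm_seed": cfg.seed,
                "median_cm": report.median,
                "q3_cm": report.summary.q3,
                "success": report.median <= plan.success_threshold(),
            }
        )
    return pd.DataFrame(rows)


def run_random_trials_study(plan: ExperimentPlan) -> tuple[pd.DataFrame, np.ndarray]:
    """One optimization on each of T independently generated random trials.

    Returns (per-trial summary table, pooled per-cell errors in cm).
    """
    rows, pooled = [], []
    for t in range(plan.replicates):
        trial_seed = int(plan.seed * 10_000 + t + 1) % 2**31
        sim = make_trial(plan.trial_spec, trial_seed, plan.displacement_fraction)
        cfg = dc_replace(plan.swarm, seed=trial_seed + 1)
        _, report = run_alignment(sim, cfg)
        pooled.append(report.per_cell_errors.ravel())
        rows.append(
            {
                "trial": t + 1,
                "trial_seed": trial_seed,
                "median_cm": report.median,
                "q1_cm": report.summary.q1,
                "q3_cm": report.summary.q3,
                "n_outliers": report.summary.outliers.size,
            }
        )
    return pd.DataFrame(rows), np.concatenate(pooled)


def run_sweep(plan: ExperimentPlan) -> pd.DataFrame:
    """Sweep the stopping tolerance or the swarm density over replicate
    random trials; one row per (level, trial)."""
    if plan.sweep not in ("tolerance", "swarm_density"):
        raise ValueError("run_sweep handles sweep='tolerance' or 'swarm_density'")
    if not plan.levels:
        raise ValueError("sweep levels must be non-empty")
    rows = []
    for t in range(plan.replicates):
        trial_seed = int(plan.seed * 10_000 + t + 1) % 2**31
        sim = make_trial(plan.trial_spec, trial_seed, plan.displacement_fraction)
        for level in plan.levels:
            cfg = dc_replace(plan.swarm, seed=trial_seed + 1, **{plan.sweep: level})
            _, report = run_alignment(sim, cfg)
            rows.append(
                {
                    "level": level,
                    "trial": t + 1,
                    "median_cm": report.median,
                    "q3_cm": report.summary.q3,
                }
            )
    return pd.DataFrame(rows)


def overlap_statistics(sim: TrialSimulation, disp: DisplacementField) -> dict:
    """Overlap geometry of a refined grid: total overlapping pixel area and
    the fraction of overlap pixels that are vegetated (above the automatic
    segmentation threshold)."""
    sfield = compute_green_red_vi(sim.image)
    mask = segment_plants(sfield, "auto")
    grid = sim.uniform_grid
    x1, y1, x2, y2 = _pixel_rect(
        grid.centers_u, grid.centers_v, grid.cell_w, grid.cell_h, disp.du, disp.dv
    )
    total_area = 0
    plant_pixels = 0
    for (p, q), (pp, qq) in grid_edges(grid.P, grid.Q):
        a = (p - 1, q - 1)
        b = (pp - 1, qq - 1)
        ox1, oy1 = max(x1[a], x1[b]), max(y1[a], y1[b])
        ox2, oy2 = min(x2[a], x2[b]), min(y2[a], y2[b])
        ox1, ox2 = max(0, ox1), min(mask.shape[1], ox2)
        oy1, oy2 = max(0, oy1), min(mask.shape[0], oy2)
        if ox1 < ox2 and oy1 < oy2:
            total_area += (ox2 - ox1) * (oy2 - oy1)
            plant_pixels += int(mask[oy1:oy2, ox1:ox2].sum())
    return {
        "overlap_area_px": int(total_area),
        "plant_fraction": plant_pixels / total_area if total_area else 0.0,
    }


def run_ablation(plan: ExperimentPlan) -> dict:
    """Paired comparison of the full cost against the intra-only cost on
    the hard scenario, from identical swarm seeds."""
    sim = hard_scenario_trial(plan.seed, P=plan.trial_spec.P, Q=plan.trial_spec.Q)
    cfg = dc_replace(plan.swarm, seed=int(plan.seed) + 1)
    res_full, rep_full = run_alignment(sim, cfg, intra_only=False)
    res_intra, rep_intra = run_alignment(sim, cfg, intra_only=True)
    return {
        "trial": sim,
        "full": {
            "report": rep_full,
            "overlap": overlap_statistics(sim, res_full.best_displacements),
        },
        "intra_only": {
            "report": rep_intra,
            "overlap": overlap_statistics(sim, res_intra.best_displacements),
        },
    }
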