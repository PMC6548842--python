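"""Particle swarm optimization of per-cell grid displacements.

The search space is the N = 2*P*Q box of displacement coordinates (all du,
then all dv), bounded per coordinate by the displacement limits.  The
swarm follows the classic bound-constrained adaptive contract:

- K = round(swarm_density * N) particles, all but one initialized i.i.d.
  uniform in the box and one *null particle* at zero displacement -- the
  unmodified uniform grid, guaranteeing the optimizer never returns
  something worse than its starting layout;
- velocity update v <- w*v + c1*r1.*(pbest - x) + c2*r2.*(nbest - x) with
  fresh uniform r1, r2 per element, where nbest is the best personal best
  in a random neighborhood re-drawn each iteration (dynamic neighborhood);
- inertia w adapts within ``inertia_range``: it grows while the global
  best keeps improving and shrinks during stagnation, while stalled
  iterations also enlarge the neighborhoods;
- positions are clamped to the box (velocity zeroed on clamped
  coordinates); velocities are clamped per coordinate to
  ``velocity_clamp_fraction`` of the box span, which keeps late-stage
  moves on the scale of a plot rather than the whole search box;
- termination when the relative drop of the best cost over the last
  ``stall_iterations`` iterations is below ``tolerance``, or at
  ``max_iterations``.

Everything is driven by one seeded generator, so runs are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .energy import GridCostFunction
from .grid_model import DisplacementField, Grid
from .scalar_field import SummedAreaTable

__all__ = [
    "SwarmConfig",
    "Swarm",
    "AlignmentResult",
    "initialize_swarm",
    "step",
    "optimize",
    "align_grid",
]


@dataclass
class SwarmConfig:
    """Tunable optimizer parameters.

    Defaults follow the standard adaptive PSO: swarm density K/N of 8
    (inside the 6-12 band where alignment errors are lowest), stopping
    tolerance 1e-4 over a 20-iteration stall window, acceleration
    coefficients 1.49 and inertia adapting in [0.1, 1.1].
    """

    swarm_density: float = 8.0
    tolerance: float = 1e-4
    stall_iterations: int = 20
    max_iterations: Optional[int] = None  # defaults to 200 * N
    inertia_range: tuple[float, float] = (0.1, 1.1)
    cognitive_coeff: float = 1.49
    social_coeff: float = 1.49
    min_neighborhood_fraction: float = 0.25
    velocity_clamp_fraction: float = 0.1
    seed: Optional[int] = None

    def __post_init__(self):
        if self.swarm_density <= 0:
            raise ValueError("swarm_density must be positive")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.cognitive_coeff <= 0 or self.social_coeff <= 0:
            raise ValueError("acceleration coefficients must be positive")
        if not 0 < self.min_neighborhood_fraction <= 1:
            raise ValueError("min_neighborhood_fraction must be in (0, 1]")
        if not 0 < self.velocity_clamp_fraction <= 1:
            raise ValueError("velocity_clamp_fraction must be in (0, 1]")


@dataclass
class Swarm:
    """Swarm state: positions/velocities are (K, N); personal bests are
    carried along with the adaptive inertia/neighborhood state."""

    positions: np.ndarray
    velocities: np.ndarray
    pbest_positions: np.ndarray
    pbest_costs: np.ndarray
    lb: np.ndarray
    ub: np.ndarray
    inertia: float
    neighborhood_size: int
    adaptive_counter: int = 0

    @property
    def K(self) -> int:
        return self.positions.shape[0]

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.pbest_costs))

    @property
    def best_cost(self) -> float:
        return float(self.pbest_costs[self.best_index])

    @property
    def best_position(self) -> np.ndarray:
        return self.pbest_positions[self.best_index].copy()


@dataclass
class AlignmentResult:
    """Outcome of one optimization run."""

    best_position: np.ndarray
    best_cost: float
    cost_trace: np.ndarray  # best cost after each iteration (non-increasing)
    iterations: int
    terminated_by: str  # "tolerance" | "max_iterations"
    best_displacements: Optional[DisplacementField] = None


def _as_bounds(bounds, n_dims: int) -> tuple[np.ndarray, np.ndarray]:
    b = np.broadcast_to(np.asarray(bounds, dtype=float), (n_dims,)).copy()
    if np.any(b < 0):
        raise ValueError("displacement bounds must be non-negative")
    return -b, b


def initialize_swarm(
    config: SwarmConfig,
    n_dims: int,
    bounds,
    cost_fn: Callable[[np.ndarray], np.ndarray],
    rng: np.random.Generator,
) -> Swarm:
    """Create the initial swarm: K-1 uniform random particles plus the null
    particle at zero displacement, with personal bests evaluated."""
    if n_dims < 2:
        raise ValueError("at least two displacement coordinates are required")
    lb, ub = _as_bounds(bounds, n_dims)
    K = int(round(config.swarm_density * n_dims))
    if K < 2:
        raise ValueError(f"swarm of K={K} particles is too small (need >= 2)")
    span = ub - lb
    positions = lb + rng.uniform(size=(K, n_dims)) * span
    positions[0] = 0.0  # the null particle: the unmodified uniform grid
    vmax = span * config.velocity_clamp_fraction
    velocities = rng.uniform(-1.0, 1.0, size=(K, n_dims)) * vmax
    costs = _evaluate(cost_fn, positions)
    min_nbr = max(2, int(np.floor(config.min_neighborhood_fraction * K)))
    return Swarm(
        positions=positions,
        velocities=velocities,
        pbest_positions=positions.copy(),
        pbest_costs=costs,
        lb=lb,
        ub=ub,
        inertia=config.inertia_range[1],
        neighborhood_size=min(min_nbr, K),
    )


def _evaluate(cost_fn, positions) -> np.ndarray:
    costs = np.asarray(cost_fn(positions), dtype=float).reshape(-1)
    if costs.shape[0] != positions.shape[0]:
        raise ValueError("cost function must return one cost per particle")
    if not np.all(np.isfinite(costs)):
        raise RuntimeError(
            "cost function returned a non-finite value; aborting optimization"
        )
    return costs


def step(
    swarm: Swarm,
    cost_fn: Callable[[np.ndarray], np.ndarray],
    rng: np.random.Generator,
    config: SwarmConfig,
) -> Swarm:
    """Advance the swarm one iteration in place (returns the same object).

    Personal and global bests can only improve, so the reported best cost
    is non-increasing across steps.
    """
    K, n = swarm.positions.shape
    prev_best = swarm.best_cost

    # dynamic neighborhoods: each particle consults itself plus a fresh
    # random subset, and is attracted to the best personal best among them
    nbr = rng.integers(0, K, size=(K, swarm.neighborhood_size))
    nbr_costs = swarm.pbest_costs[nbr]
    self_better = swarm.pbest_costs[:, None] <= nbr_costs.min(axis=1, keepdims=True)
    nbest_idx = np.where(
        self_better[:, 0], np.arange(K), nbr[np.arange(K), np.argmin(nbr_costs, axis=1)]
    )
    nbest = swarm.pbest_positions[nbest_idx]

    r1 = rng.uniform(size=(K, n))
    r2 = rng.uniform(size=(K, n))
    v = (
        swarm.inertia * swarm.velocities
        + config.cognitive_coeff * r1 * (swarm.pbest_positions - swarm.positions)
        + config.social_coeff * r2 * (nbest - swarm.positions)
    )
    vmax = (swarm.ub - swarm.lb) * config.velocity_clamp_fraction
    np.clip(v, -vmax, vmax, out=v)
    x = swarm.positions + v
    clamped = (x < swarm.lb) | (x > swarm.ub)
    np.clip(x, swarm.lb, swarm.ub, out=x)
    v[clamped] = 0.0
    swarm.positions = x
    swarm.velocities = v

    costs = _evaluate(cost_fn, x)
    improved = costs < swarm.pbest_costs
    swarm.pbest_positions[improved] = x[improved]
    swarm.pbest_costs[improved] = costs[improved]

    # adaptive inertia / neighborhood growth
    w_lo, w_hi = config.inertia_range
    min_nbr = max(2, int(np.floor(config.min_neighborhood_fraction * K)))
    if swarm.best_cost < prev_best:
        swarm.adaptive_counter = max(0, swarm.adaptive_counter - 1)
        swarm.neighborhood_size = min(min_nbr, K)
        if swarm.adaptive_counter < 2:
            swarm.inertia = min(2.0 * swarm.inertia, w_hi)
        elif swarm.adaptive_counter > 5:
            swarm.inertia = max(swarm.inertia / 2.0, w_lo)
    else:
        swarm.adaptive_counter += 1
        swarm.neighborhood_size = min(swarm.neighborhood_size + min_nbr, K)
        if swarm.adaptive_counter > 5:
            swarm.inertia = max(swarm.inertia / 2.0, w_lo)
    return swarm


def optimize(
    cost_fn: Callable[[np.ndarray], np.ndarray],
    n_dims: int,
    bounds,
    config: Optional[SwarmConfig] = None,
) -> AlignmentResult:
    """Minimize a batch cost function over the bounded displacement box.

    ``cost_fn`` maps a (K, N) position array to (K,) costs.  ``bounds`` is
    the per-coordinate half-width of the symmetric box (scalar or length-N).
    The run is deterministic given ``config.seed``.
    """
    config = config or SwarmConfig()
    rng = np.random.default_rng(config.seed)
    max_iter = config.max_iterations or 200 * n_dims

    swarm = initialize_swarm(config, n_dims, bounds, cost_fn, rng)
    trace = [swarm.best_cost]
    terminated_by = "max_iterations"
    it = 0
    for it in range(1, max_iter + 1):
        step(swarm, cost_fn, rng, config)
        trace.append(swarm.best_cost)
        if len(trace) > config.stall_iterations:
            old = trace[-1 - config.stall_iterations]
            if (old - trace[-1]) <= config.tolerance * max(1.0, abs(trace[-1])):
                terminated_by = "tolerance"
                break
    return AlignmentResult(
        best_position=swarm.best_position,
        best_cost=swarm.best_cost,
        cost_trace=np.asarray(trace),
        iterations=it,
        terminated_by=terminated_by,
    )


def default_bounds(grid: Grid) -> tuple[float, float]:
    """Default displacement bounds: half the grid pitch per direction (a
    cell may not jump past a neighboring plot); falls back to half the cell
    size on degenerate pitch."""
    bu = grid.pitch_u / 2.0 if grid.pitch_u > 0 else grid.cell_w / 2.0
    bv = grid.pitch_v / 2.0 if grid.pitch_v > 0 else grid.cell_h / 2.0
    return bu, bv


def align_grid(
    sat: SummedAreaTable,
    grid: Grid,
    bounds: Optional[tuple[float, float]] = None,
    config: Optional[SwarmConfig] = None,
    intra_only: bool = False,
) -> AlignmentResult:
    """Optimize the grid's per-cell displacements against a scalar field.

    Returns the swarm's best candidate reshaped into a
    :class:`DisplacementField` (du/dv bounded by ``bounds``, default half
    the grid pitch).
    """
    bu, bv = bounds if bounds is not None else default_bounds(grid)
    n = grid.P * grid.Q
    per_coord = np.concatenate([np.full(n, float(bu)), np.full(n, float(bv))])
    cost_fn = GridCostFunction(sat, grid, intra_only=intra_only)
    result = optimize(cost_fn, 2 * n, per_coord, config)
    result.best_displacements = DisplacementField.from_flat(
        result.best_position, grid.P, grid.Q, bu, bv
    )
    return result
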