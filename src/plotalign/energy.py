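"""Grid alignment energies and the cost function.

For a grid of fixed-size cells over a vegetation-index field S, each cell
at its displaced position accrues:

- an intra-cell energy ``d_pq``: the index mass inside the cell, rewarding
  placement over vegetation;
- an inter-cell energy ``g_pq``: the index mass shared with overlapping von
  Neumann neighbors, attributed to each cell of an overlapping pair in
  proportion to the *other* cell's intra energy, penalizing overlap;
- a net energy per unit area ``f_pq = (d_pq - g_pq) / (W * H)``.

The grid cost is ``f = exp(-mean(f_pq))`` -- strictly positive, lower is
better, with the exponential keeping the optimizer's objective numerically
stable.  All sums are evaluated exactly on the integer pixel lattice via a
summed-area table: a displaced cell is discretized to the W x H pixel
rectangle nearest its continuous position, so every cell contributes
exactly round(W) * round(H) samples (clipped at field borders, where
outside pixels contribute zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid_model import DisplacementField, Grid, neighbors
from .scalar_field import SummedAreaTable, rect_sums

__all__ = [
    "CellEnergy",
    "OverlapRect",
    "intra_cell_energy",
    "overlap_region",
    "inter_cell_energy",
    "net_cell_energy",
    "cell_energies",
    "grid_cost",
    "grid_cost_intra_only",
    "grid_cost_hard_limited",
    "GridCostFunction",
]


@dataclass(frozen=True)
class CellEnergy:
    """Per-cell energy budget: intra d, inter g, and net f = (d - g)/(W*H)."""

    d: float
    g: float
    f_cell: float


@dataclass(frozen=True)
class OverlapRect:
    """Half-open overlap rectangle [x1, x2) x [y1, y2) of two displaced
    cells on the pixel lattice; empty iff x1 >= x2 or y1 >= y2."""

    x1: int
    y1: int
    x2: int
    y2: int

    @property
    def empty(self) -> bool:
        return self.x1 >= self.x2 or self.y1 >= self.y2

    @property
    def area(self) -> int:
        return 0 if self.empty else (self.x2 - self.x1) * (self.y2 - self.y1)


def _pixel_rect(u, v, W, H, du, dv):
    """Integer sampling rectangle of a displaced cell.

    The continuous rectangle centered at (u + du, v + dv) is snapped to the
    nearest lattice position, keeping exactly round(W) x round(H) samples.
    """
    w_px = int(round(W))
    h_px = int(round(H))
    x1 = np.rint(np.asarray(u) + np.asarray(du) - W / 2.0).astype(np.int64)
    y1 = np.rint(np.asarray(v) + np.asarray(dv) - H / 2.0).astype(np.int64)
    return x1, y1, x1 + w_px, y1 + h_px


def intra_cell_energy(sat: SummedAreaTable, cell, delta=(0.0, 0.0)) -> float:
    """Index mass of S inside the cell displaced by ``delta = (du, dv)``.

    Portions outside the field contribute zero (soft clipping), so border
    plots partially off the mosaic are allowed.
    """
    x1, y1, x2, y2 = _pixel_rect(cell.u, cell.v, cell.W, cell.H, delta[0], delta[1])
    return float(rect_sums(sat, x1, y1, x2, y2))


def overlap_region(cellA, deltaA, cellB, deltaB) -> OverlapRect:
    """Overlap rectangle of two displaced cells.

    Edges are the max of the displaced left/top edges and the min of the
    displaced right/bottom edges, on the discretized pixel lattice.
    """
    ax1, ay1, ax2, ay2 = _pixel_rect(cellA.u, cellA.v, cellA.W, cellA.H, *deltaA)
    bx1, by1, bx2, by2 = _pixel_rect(cellB.u, cellB.v, cellB.W, cellB.H, *deltaB)
    return OverlapRect(
        x1=int(max(ax1, bx1)),
        y1=int(max(ay1, by1)),
        x2=int(min(ax2, bx2)),
        y2=int(min(ay2, by2)),
    )


def inter_cell_energy(
    sat: SummedAreaTable,
    grid: Grid,
    disp: DisplacementField,
    p: int,
    q: int,
    intra_energies: np.ndarray,
) -> float:
    """Inter-cell energy g_pq of cell (p, q): over its von Neumann
    neighbors, the index mass of each non-empty overlap weighted by
    d_neighbor / (d_cell + d_neighbor).

    A cell with no overlapping neighbor has g_pq = 0; a pair with zero
    total intra energy (bare soil) contributes 0 -- there is no vegetation
    energy to attribute.
    """
    cell = grid.cell(p, q)
    delta = (disp.du[p - 1, q - 1], disp.dv[p - 1, q - 1])
    d_self = intra_energies[p - 1, q - 1]
    g = 0.0
    for (pp, qq) in neighbors(p, q, grid.P, grid.Q):
        nb = grid.cell(pp, qq)
        nb_delta = (disp.du[pp - 1, qq - 1], disp.dv[pp - 1, qq - 1])
        ov = overlap_region(cell, delta, nb, nb_delta)
        if ov.empty:
            continue
        d_nb = intra_energies[pp - 1, qq - 1]
        denom = d_self + d_nb
        if denom == 0:
            continue
        shared = float(rect_sums(sat, ov.x1, ov.y1, ov.x2, ov.y2))
        g += (d_nb / denom) * shared
    return g


def net_cell_energy(d: float, g: float, W: float, H: float) -> float:
    """Net energy per unit area, f = (d - g) / (W * H)."""
    area = W * H
    if area <= 0:
        raise ValueError("cell area must be positive")
    return (d - g) / area


def _batch_energies(sat, grid, du, dv, include_inter=True):
    """Per-cell d, g for displacement arrays of shape (..., P, Q)."""
    x1, y1, x2, y2 = _pixel_rect(
        grid.centers_u, grid.centers_v, grid.cell_w, grid.cell_h, du, dv
    )
    d = rect_sums(sat, x1, y1, x2, y2)
    g = np.zeros_like(d)
    if include_inter:
        for axis in (-1, -2):  # horizontal then vertical neighbor pairs
            sl_a = (Ellipsis, slice(None, -1)) if axis == -1 else (Ellipsis, slice(None, -1), slice(None))
            sl_b = (Ellipsis, slice(1, None)) if axis == -1 else (Ellipsis, slice(1, None), slice(None))
            ox1 = np.maximum(x1[sl_a], x1[sl_b])
            oy1 = np.maximum(y1[sl_a], y1[sl_b])
            ox2 = np.minimum(x2[sl_a], x2[sl_b])
            oy2 = np.minimum(y2[sl_a], y2[sl_b])
            valid = (ox1 < ox2) & (oy1 < oy2)
            shared = np.where(valid, rect_sums(sat, ox1, oy1, ox2, oy2), 0.0)
            da, db = d[sl_a], d[sl_b]
            denom = da + db
            with np.errstate(divide="ignore", invalid="ignore"):
                share_a = np.where(denom != 0, db / np.where(denom == 0, 1, denom), 0.0)
            g[sl_a] += share_a * shared
            g[sl_b] += (1.0 - share_a) * np.where(denom != 0, 1.0, 0.0) * shared
    return d, g


def cell_energies(sat: SummedAreaTable, grid: Grid, disp: DisplacementField):
    """All per-cell energies at once: (d, g, f) arrays of shape (P, Q)."""
    d, g = _batch_energies(sat, grid, disp.du, disp.dv)
    area = round(grid.cell_w) * round(grid.cell_h)
    return d, g, (d - g) / area


def grid_cost(sat: SummedAreaTable, grid: Grid, disp: DisplacementField) -> float:
    """Grid cost f = exp(-mean(f_pq)); strictly positive, lower is better."""
    _, _, f = cell_energies(sat, grid, disp)
    return float(np.exp(-f.mean()))


def grid_cost_intra_only(
    sat: SummedAreaTable, grid: Grid, disp: DisplacementField
) -> float:
    """Ablated cost with all inter-cell penalties g_pq forced to zero."""
    d, _ = _batch_energies(sat, grid, disp.du, disp.dv, include_inter=False)
    area = round(grid.cell_w) * round(grid.cell_h)
    return float(np.exp(-(d / area).mean()))


def grid_cost_hard_limited(
    sat: SummedAreaTable, grid: Grid, disp: DisplacementField
) -> float:
    """Hard-limited reference variant: any cell overlap carries infinite
    penalty, so the cost is +inf for overlapping configurations and the
    intra-only cost otherwise.  Provided as a comparison oracle, not a
    user-facing optimization mode."""
    x1, y1, x2, y2 = _pixel_rect(
        grid.centers_u, grid.centers_v, grid.cell_w, grid.cell_h, disp.du, disp.dv
    )
    for sl_a, sl_b in (
        ((Ellipsis, slice(None, -1)), (Ellipsis, slice(1, None))),
        ((Ellipsis, slice(None, -1), slice(None)), (Ellipsis, slice(1, None), slice(None))),
    ):
        ox1 = np.maximum(x1[sl_a], x1[sl_b])
        oy1 = np.maximum(y1[sl_a], y1[sl_b])
        ox2 = np.minimum(x2[sl_a], x2[sl_b])
        oy2 = np.minimum(y2[sl_a], y2[sl_b])
        if np.any((ox1 < ox2) & (oy1 < oy2)):
            return float("inf")
    return grid_cost_intra_only(sat, grid, disp)


class GridCostFunction:
    """Vectorized grid cost over flattened displacement vectors.

    Evaluates the cost for a whole swarm at once: the input is a (K, N)
    array with N = 2*P*Q (all du row-major, then all dv) and the output a
    (K,) cost vector.  This is the objective handed to the particle swarm
    optimizer.
    """

    def __init__(self, sat: SummedAreaTable, grid: Grid, intra_only: bool = False):
        self.sat = sat
        self.grid = grid
        self.intra_only = intra_only
        self.n_dims = 2 * grid.P * grid.Q
        self._area = round(grid.cell_w) * round(grid.cell_h)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_dims:
            raise ValueError(f"expected vectors of length {self.n_dims}")
        P, Q = self.grid.P, self.grid.Q
        n = P * Q
        du = x[:, :n].reshape(-1, P, Q)
        dv = x[:, n:].reshape(-1, P, Q)
        d, g = _batch_energies(
            self.sat, self.grid, du, dv, include_inter=not self.intra_only
        )
        f = (d - g) / self._area
        return np.exp(-f.mean(axis=(-1, -2)))
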