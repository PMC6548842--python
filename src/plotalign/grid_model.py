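"""The P x Q plot grid: layout, transforms, neighborhoods, displacement
fields, and shapefile exchange.

A grid cell represents one field plot: a fixed-size W x H rectangle whose
center may move but whose dimensions never change.  Indices follow trial
notation: ``p`` is the row (range) index and ``q`` the column index, both
1-based in the public API.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import ndimage

from .scalar_field import GeoTransform, ScalarField
from .shapefile_io import read_polygon_shapefile, write_polygon_shapefile

__all__ = [
    "Cell",
    "Grid",
    "DisplacementField",
    "make_uniform_grid",
    "transform_grid",
    "neighbors",
    "grid_edges",
    "apply_displacements",
    "assign_plot_sequence",
    "resample_to_grid_frame",
    "export_shapefile",
    "import_grid",
]


@dataclass(frozen=True)
class Cell:
    """One grid cell: 1-based lattice indices, center (pixels, grid frame)
    and fixed width/height in pixels."""

    p: int
    q: int
    u: float
    v: float
    W: float
    H: float
    plot_id: Optional[str] = None

    def __post_init__(self):
        if self.W <= 0 or self.H <= 0:
            raise ValueError("cell dimensions must be positive")


@dataclass
class Grid:
    """P x Q lattice of fixed-size cells.

    Centers are stored in grid-frame pixel coordinates; when
    ``rotation_deg`` is nonzero the grid frame is rotated by that angle
    about the grid centroid relative to the image frame.
    """

    P: int
    Q: int
    centers_u: np.ndarray  # (P, Q)
    centers_v: np.ndarray  # (P, Q)
    cell_w: float
    cell_h: float
    pitch_u: float = 0.0
    pitch_v: float = 0.0
    rotation_deg: float = 0.0
    plot_ids: Optional[np.ndarray] = None  # (P, Q) object array of labels

    def __post_init__(self):
        if self.P < 1 or self.Q < 1:
            raise ValueError("grid must have P >= 1 rows and Q >= 1 columns")
        if self.cell_w <= 0 or self.cell_h <= 0:
            raise ValueError("cell dimensions must be positive")
        self.centers_u = np.asarray(self.centers_u, dtype=float)
        self.centers_v = np.asarray(self.centers_v, dtype=float)
        if self.centers_u.shape != (self.P, self.Q) or self.centers_v.shape != (
            self.P,
            self.Q,
        ):
            raise ValueError("center arrays must have shape (P, Q)")

    @property
    def n_cells(self) -> int:
        return self.P * self.Q

    def cell(self, p: int, q: int) -> Cell:
        """Cell at 1-based lattice position (p, q)."""
        _check_index(p, q, self.P, self.Q)
        pid = None if self.plot_ids is None else self.plot_ids[p - 1, q - 1]
        return Cell(
            p=p,
            q=q,
            u=float(self.centers_u[p - 1, q - 1]),
            v=float(self.centers_v[p - 1, q - 1]),
            W=self.cell_w,
            H=self.cell_h,
            plot_id=pid,
        )

    def cells(self):
        for p in range(1, self.P + 1):
            for q in range(1, self.Q + 1):
                yield self.cell(p, q)

    def centroid(self) -> tuple[float, float]:
        return float(self.centers_u.mean()), float(self.centers_v.mean())

    def grid_to_image(self, u, v):
        """Map grid-frame pixel coordinates to image-frame coordinates."""
        if self.rotation_deg == 0.0:
            return np.asarray(u, float), np.asarray(v, float)
        cu, cv = self.centroid()
        th = math.radians(self.rotation_deg)
        du, dv = np.asarray(u, float) - cu, np.asarray(v, float) - cv
        return (
            cu + du * math.cos(th) - dv * math.sin(th),
            cv + du * math.sin(th) + dv * math.cos(th),
        )


@dataclass
class DisplacementField:
    """Per-cell 2D displacements with component-wise bounds |du| <= bound_u,
    |dv| <= bound_v (pixels)."""

    du: np.ndarray
    dv: np.ndarray
    bound_u: float
    bound_v: float

    def __post_init__(self):
        self.du = np.asarray(self.du, dtype=float)
        self.dv = np.asarray(self.dv, dtype=float)
        if self.du.shape != self.dv.shape:
            raise ValueError("du and dv must share a shape")
        if self.bound_u < 0 or self.bound_v < 0:
            raise ValueError("displacement bounds must be non-negative")
        tol = 1e-9
        if np.any(np.abs(self.du) > self.bound_u + tol) or np.any(
            np.abs(self.dv) > self.bound_v + tol
        ):
            raise ValueError("displacements exceed their bounds")

    @property
    def shape(self):
        return self.du.shape

    @staticmethod
    def zeros(P: int, Q: int, bound_u: float = 0.0, bound_v: float = 0.0):
        return DisplacementField(
            du=np.zeros((P, Q)), dv=np.zeros((P, Q)), bound_u=bound_u, bound_v=bound_v
        )

    def flatten(self) -> np.ndarray:
        """Flatten to the optimizer's N = 2*P*Q vector: all du row-major,
        then all dv."""
        return np.concatenate([self.du.ravel(), self.dv.ravel()])

    @staticmethod
    def from_flat(x: np.ndarray, P: int, Q: int, bound_u: float, bound_v: float):
        x = np.asarray(x, dtype=float)
        n = P * Q
        if x.size != 2 * n:
            raise ValueError(f"expected a vector of length {2 * n}, got {x.size}")
        return DisplacementField(
            du=x[:n].reshape(P, Q),
            dv=x[n:].reshape(P, Q),
            bound_u=bound_u,
            bound_v=bound_v,
        )


def _check_index(p: int, q: int, P: int, Q: int) -> None:
    if not (1 <= p <= P and 1 <= q <= Q):
        raise IndexError(f"cell index ({p}, {q}) outside 1..{P} x 1..{Q}")


def make_uniform_grid(
    P: int,
    Q: int,
    cell_w: float,
    cell_h: float,
    origin: tuple[float, float] = (0.0, 0.0),
    pitch_u: float = 0.0,
    pitch_v: float = 0.0,
    rotation_deg: float = 0.0,
) -> Grid:
    """Regularly spaced grid: cell (p, q) centered at
    ``origin + ((q-1) * pitch_u, (p-1) * pitch_v)`` in the grid frame."""
    if P < 1 or Q < 1:
        raise ValueError("P and Q must be >= 1")
    if cell_w <= 0 or cell_h <= 0:
        raise ValueError("cell dimensions must be positive")
    if pitch_u < 0 or pitch_v < 0:
        raise ValueError("pitch must be non-negative")
    qq, pp = np.meshgrid(np.arange(Q), np.arange(P))
    return Grid(
        P=P,
        Q=Q,
        centers_u=origin[0] + qq * pitch_u,
        centers_v=origin[1] + pp * pitch_v,
        cell_w=cell_w,
        cell_h=cell_h,
        pitch_u=pitch_u,
        pitch_v=pitch_v,
        rotation_deg=rotation_deg,
    )


def transform_grid(grid: Grid, op: str, **params) -> Grid:
    """Apply one interactive layout transform; returns a new grid.

    Supported ops (composable in any order, any number of times):

    - ``translate(du, dv)`` -- displace the whole grid.
    - ``rotate(angle_deg)`` -- orient the grid at an angle (about its
      centroid).
    - ``scale(cell_w, cell_h)`` -- resize cells to the given dimensions.
    - ``shift_margin(pitch_u, pitch_v)`` -- change the cell spacing without
      changing cell size, keeping the first cell's center fixed.
    """
    if op == "translate":
        du, dv = params["du"], params["dv"]
        return replace(
            grid, centers_u=grid.centers_u + du, centers_v=grid.centers_v + dv
        )
    if op == "rotate":
        return replace(grid, rotation_deg=grid.rotation_deg + params["angle_deg"])
    if op == "scale":
        w, h = params["cell_w"], params["cell_h"]
        if w <= 0 or h <= 0:
            raise ValueError("cannot scale cells to non-positive dimensions")
        return replace(grid, cell_w=float(w), cell_h=float(h))
    if op == "shift_margin":
        pu = params.get("pitch_u", grid.pitch_u)
        pv = params.get("pitch_v", grid.pitch_v)
        if pu < 0 or pv < 0:
            raise ValueError("pitch must be non-negative")
        origin = (grid.centers_u[0, 0], grid.centers_v[0, 0])
        qq, pp = np.meshgrid(np.arange(grid.Q), np.arange(grid.P))
        return replace(
            grid,
            centers_u=origin[0] + qq * pu,
            centers_v=origin[1] + pp * pv,
            pitch_u=float(pu),
            pitch_v=float(pv),
        )
    raise ValueError(f"unknown grid transform {op!r}")


def neighbors(p: int, q: int, P: int, Q: int) -> set[tuple[int, int]]:
    """Von Neumann neighborhood of cell (p, q): the valid subset of
    {(p-1,q), (p,q-1), (p+1,q), (p,q+1)} -- 2, 3 or 4 cells depending on
    corner/side/interior position."""
    _check_index(p, q, P, Q)
    cand = [(p - 1, q), (p, q - 1), (p + 1, q), (p, q + 1)]
    return {(a, b) for a, b in cand if 1 <= a <= P and 1 <= b <= Q}


def grid_edges(P: int, Q: int) -> list[tuple[tuple[int, int], tuple[int, int]]]:
    """All neighbor pairs of the grid graph, each listed once:
    P*(Q-1) horizontal + Q*(P-1) vertical edges."""
    edges = []
    for p in range(1, P + 1):
        for q in range(1, Q):
            edges.append(((p, q), (p, q + 1)))
    for p in range(1, P):
        for q in range(1, Q + 1):
            edges.append(((p, q), (p + 1, q)))
    return edges


def apply_displacements(grid: Grid, disp: DisplacementField) -> Grid:
    """Move each cell center by its displacement; dimensions unchanged."""
    if disp.shape != (grid.P, grid.Q):
        raise ValueError(
            f"displacement field shape {disp.shape} does not match grid "
            f"({grid.P}, {grid.Q})"
        )
    return replace(
        grid, centers_u=grid.centers_u + disp.du, centers_v=grid.centers_v + disp.dv
    )


def assign_plot_sequence(grid: Grid, order: str = "row_major", start: int = 1) -> Grid:
    """Label cells with a trial plot sequence.

    ``row_major`` numbers along each row left-to-right; ``serpentine``
    alternates direction every row (the common harvester path).
    """
    ids = np.empty((grid.P, grid.Q), dtype=object)
    n = start
    for p in range(grid.P):
        cols = range(grid.Q)
        if order == "serpentine" and p % 2 == 1:
            cols = reversed(cols)
        elif order not in ("row_major", "serpentine"):
            raise ValueError(f"unknown plot sequence order {order!r}")
        for q in cols:
            ids[p, q] = str(n)
            n += 1
    return replace(grid, plot_ids=ids)


def resample_to_grid_frame(field: ScalarField, grid: Grid) -> tuple[ScalarField, Grid]:
    """Rotate the scalar field into the grid frame so that all downstream
    energies can use axis-aligned rectangles.

    Returns the resampled field (bilinear interpolation, zero fill) and the
    same grid with ``rotation_deg = 0``.  A no-op for unrotated grids.
    """
    if grid.rotation_deg == 0.0:
        return field, grid
    th = math.radians(grid.rotation_deg)
    cu, cv = grid.centroid()
    # output pixel (grid frame) -> input pixel (image frame): rotate by +th
    cos_t, sin_t = math.cos(th), math.sin(th)
    matrix = np.array([[cos_t, sin_t], [-sin_t, cos_t]])  # acts on (v, u)
    center = np.array([cv, cu])
    offset = center - matrix @ center
    values = ndimage.affine_transform(
        field.values, matrix, offset=offset, order=1, mode="constant", cval=0.0
    )
    out_field = ScalarField(
        values=values,
        resolution_cm_per_px=field.resolution_cm_per_px,
        geotransform=field.geotransform,
    )
    return out_field, replace(grid, rotation_deg=0.0)


def _cell_polygons(grid: Grid, geotransform: Optional[GeoTransform]):
    """Corner rings of all cells, mapped to image frame then (optionally)
    world coordinates."""
    hw, hh = grid.cell_w / 2.0, grid.cell_h / 2.0
    polys = []
    for cell in grid.cells():
        corners_u = np.array([cell.u - hw, cell.u + hw, cell.u + hw, cell.u - hw, cell.u - hw])
        corners_v = np.array([cell.v - hh, cell.v - hh, cell.v + hh, cell.v + hh, cell.v - hh])
        iu, iv = grid.grid_to_image(corners_u, corners_v)
        if geotransform is not None:
            iu, iv = geotransform.pixel_to_world(iu, iv)
        polys.append(np.column_stack([iu, iv]))
    return polys


def export_shapefile(
    grid: Grid, path: str | Path, geotransform: Optional[GeoTransform] = None
) -> None:
    """Export one rectangle polygon per cell with ROW, COL, PLOT_ID
    attributes.  World coordinates are written when a geotransform is given,
    else pixel coordinates."""
    polys = _cell_polygons(grid, geotransform)
    records = []
    for cell in grid.cells():
        records.append(
            {"ROW": cell.p, "COL": cell.q, "PLOT_ID": cell.plot_id or ""}
        )
    fields = [("ROW", "N", 9, 0), ("COL", "N", 9, 0), ("PLOT_ID", "C", 32, 0)]
    write_polygon_shapefile(path, polys, records, fields)


def import_grid(path: str | Path, geotransform: Optional[GeoTransform] = None) -> Grid:
    """Rebuild a grid from an exported shapefile (axis-aligned cells).

    Inverts :func:`export_shapefile` for unrotated grids; centers round-trip
    to within 1e-6 px.
    """
    polys, records = read_polygon_shapefile(path)
    if not records or "ROW" not in records[0] or "COL" not in records[0]:
        raise ValueError(f"{path}: not a plot-grid shapefile (missing ROW/COL)")
    P = max(int(r["ROW"]) for r in records)
    Q = max(int(r["COL"]) for r in records)
    centers_u = np.full((P, Q), np.nan)
    centers_v = np.full((P, Q), np.nan)
    plot_ids = np.empty((P, Q), dtype=object)
    widths, heights = [], []
    for poly, rec in zip(polys, records):
        x, y = poly[:, 0], poly[:, 1]
        if geotransform is not None:
            x, y = geotransform.world_to_pixel(x, y)
        p, q = int(rec["ROW"]), int(rec["COL"])
        centers_u[p - 1, q - 1] = (x.min() + x.max()) / 2.0
        centers_v[p - 1, q - 1] = (y.min() + y.max()) / 2.0
        plot_ids[p - 1, q - 1] = rec.get("PLOT_ID", "") or None
        widths.append(x.max() - x.min())
        heights.append(y.max() - y.min())
    if np.any(np.isnan(centers_u)):
        raise ValueError(f"{path}: missing cells in the shapefile grid")
    pitch_u = float(np.mean(np.diff(centers_u, axis=1))) if Q > 1 else 0.0
    pitch_v = float(np.mean(np.diff(centers_v, axis=0))) if P > 1 else 0.0
    return Grid(
        P=P,
        Q=Q,
        centers_u=centers_u,
        centers_v=centers_v,
        cell_w=float(np.mean(widths)),
        cell_h=float(np.mean(heights)),
        pitch_u=pitch_u,
        pitch_v=pitch_v,
        plot_ids=plot_ids if any(plot_ids.ravel()) else None,
    )
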