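"""Synthetic agronomic trial images with known ground truth.

Real trial orthomosaics are rarely shareable, so validation runs on
generated look-alikes: a soil-textured background with plant-colored pixel
clusters arranged in sown rows inside each plot, every plot drawn at a
known displaced position.  Only the statistics of the vegetation-index
field matter to the alignment algorithm -- not photorealism -- so plants
are overlapping green-dominant ellipses and soil is low-frequency brown
noise.

Two trial geometries are bundled as defaults: a fertilizer-response style
validation layout (5 x 12 grid of 1.2 x 4 m plots, 6 plant rows at 0.2 m
spacing) and a breeding style test layout (48 x 12 grid of single-row
0.3 x 5 m plots), both at 0.8 cm/px.

The module also provides the reflection trick for misaligning plots in an
*existing* mosaic: enlarged plot regions are translated to their displaced
position and the vacated band is filled with the region's mirror image, so
the modified mosaic contains no voids and seams fall in low-texture soil.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage.draw import ellipse as draw_ellipse

from .grid_model import DisplacementField, Grid, apply_displacements, make_uniform_grid
from .scalar_field import RGBImage

__all__ = [
    "TrialSpec",
    "TrialSimulation",
    "validation_trial_spec",
    "test_trial_spec",
    "sample_displacements",
    "render_field",
    "displace_plots_reflect",
    "displace_plots_linear",
]

SOIL_COLOR = (125.0, 100.0, 72.0)  # dry loam, red-dominant
PLANT_COLOR = (55.0, 128.0, 48.0)  # wheat canopy, green-dominant


@dataclass
class TrialSpec:
    """Geometry and appearance of a synthetic trial."""

    P: int
    Q: int
    plot_w_m: float
    plot_h_m: float
    pitch_u_m: float
    pitch_v_m: float
    resolution_cm_per_px: float = 0.8
    n_plant_rows_per_plot: int = 6
    row_spacing_m: float = 0.2
    emergence_rate: float = 1.0
    end_taper: float = 0.0  # fraction of each row over which the stand thins
    vigor_levels: Optional[np.ndarray] = None  # (P, Q) greenness multipliers
    soil_color: tuple[float, float, float] = SOIL_COLOR
    plant_color: tuple[float, float, float] = PLANT_COLOR
    noise_sd: float = 8.0
    margin_m: float = 1.0  # soil border around the grid
    seed: Optional[int] = None

    def __post_init__(self):
        for name in ("plot_w_m", "plot_h_m", "pitch_u_m", "pitch_v_m", "resolution_cm_per_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.emergence_rate <= 1.0:
            raise ValueError("emergence_rate must lie in [0, 1]")

    @property
    def px_per_m(self) -> float:
        return 100.0 / self.resolution_cm_per_px


@dataclass
class TrialSimulation:
    """A rendered trial: the image, the uniform starting grid, the ground
    truth grid, and the displacements linking them."""

    image: RGBImage
    uniform_grid: Grid
    truth_grid: Grid
    truth_displacements: DisplacementField


def validation_trial_spec(seed: Optional[int] = None, **overrides) -> TrialSpec:
    """Fertilizer-response style layout: 5 x 12 plots of 1.2 x 4 m with six
    sown rows spaced 0.2 m, at 0.8 cm/px."""
    params = dict(
        P=5, Q=12, plot_w_m=1.2, plot_h_m=4.0, pitch_u_m=1.6, pitch_v_m=4.8,
        n_plant_rows_per_plot=6, row_spacing_m=0.2, seed=seed,
    )
    params.update(overrides)
    return TrialSpec(**params)


def test_trial_spec(seed: Optional[int] = None, **overrides) -> TrialSpec:
    """Breeding style layout: 48 x 12 single-row plots of 0.3 x 5 m."""
    params = dict(
        P=48, Q=12, plot_w_m=0.3, plot_h_m=5.0, pitch_u_m=0.5, pitch_v_m=5.5,
        n_plant_rows_per_plot=1, row_spacing_m=0.0, end_taper=0.15, seed=seed,
    )
    params.update(overrides)
    return TrialSpec(**params)


def sample_displacements(
    P: int,
    Q: int,
    bound_u: float,
    bound_v: float,
    rng: np.random.Generator,
    anisotropy: tuple[float, float] = (1.0, 1.0),
) -> DisplacementField:
    """I.i.d. uniform per-cell displacements within the given pixel bounds.

    ``anisotropy`` scales the sampled (not the declared) range per axis, to
    bias misalignment toward one direction.
    """
    if bound_u < 0 or bound_v < 0:
        raise ValueError("bounds must be non-negative")
    du = rng.uniform(-bound_u * anisotropy[0], bound_u * anisotropy[0], size=(P, Q))
    dv = rng.uniform(-bound_v * anisotropy[1], bound_v * anisotropy[1], size=(P, Q))
    return DisplacementField(du=du, dv=dv, bound_u=bound_u, bound_v=bound_v)


def _soil_background(shape, spec: TrialSpec, rng) -> np.ndarray:
    h, w = shape
    img = np.empty((h, w, 3), dtype=float)
    # low-frequency mottling: coarse noise upsampled to full resolution
    coarse = rng.normal(0.0, 10.0, size=(max(2, h // 64), max(2, w // 64)))
    reps_v = -(-h // coarse.shape[0])
    reps_u = -(-w // coarse.shape[1])
    mottle = np.kron(coarse, np.ones((reps_v, reps_u)))[:h, :w]
    for c in range(3):
        img[:, :, c] = spec.soil_color[c] + mottle
    img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    return img


def _draw_plot(img, spec: TrialSpec, cx: float, cy: float, vigor: float, rng) -> None:
    """Stamp one plot's plant rows (ellipse clusters) centered at (cx, cy)."""
    ppm = spec.px_per_m
    h_px = spec.plot_h_m * ppm
    n_rows = spec.n_plant_rows_per_plot
    if n_rows <= 1:
        row_offsets = [0.0]
    else:
        half = spec.row_spacing_m * (n_rows - 1) / 2.0
        row_offsets = [(-half + i * spec.row_spacing_m) * ppm for i in range(n_rows)]
    plant_step = 0.10 * ppm  # one plant every ~10 cm along the row
    r_minor = 0.045 * ppm
    r_major = 0.075 * ppm
    color = np.array(spec.plant_color)
    color = np.array([color[0], color[1] * vigor, color[2]])
    n_plants = max(1, int(round(h_px / plant_step)))
    taper = max(1.0, spec.end_taper * n_plants) if spec.end_taper > 0 else 0.0
    H, W = img.shape[:2]
    for off in row_offsets:
        u0 = cx + off
        for i in range(n_plants):
            if taper:
                ramp = min(1.0, (i + 0.5) / taper, (n_plants - i - 0.5) / taper)
            else:
                ramp = 1.0
            if rng.uniform() > spec.emergence_rate * (0.5 + 0.5 * ramp):
                continue
            v0 = cy - h_px / 2.0 + (i + 0.5) * plant_step + rng.normal(0, 0.3 * r_minor)
            u_j = u0 + rng.normal(0, 0.4 * r_minor)
            size = 0.7 + 0.3 * ramp
            rr, cc = draw_ellipse(
                v0, u_j,
                size * r_major * rng.uniform(0.7, 1.3),
                size * r_minor * rng.uniform(0.7, 1.3),
                shape=(H, W),
            )
            jitter = rng.normal(1.0, 0.08, size=3)
            img[rr, cc] = np.clip(color * jitter, 0, 255)


def render_field(spec: TrialSpec, displacements: DisplacementField) -> TrialSimulation:
    """Render a trial image with plots drawn at their displaced positions.

    The returned simulation bundles the image, the uniform grid (the
    optimizer's starting point), the displaced ground-truth grid and the
    displacement field between them.
    """
    rng = np.random.default_rng(spec.seed)
    ppm = spec.px_per_m
    plot_w = spec.plot_w_m * ppm
    plot_h = spec.plot_h_m * ppm
    pitch_u = spec.pitch_u_m * ppm
    pitch_v = spec.pitch_v_m * ppm
    if plot_w > pitch_u or plot_h > pitch_v:
        warnings.warn("plots exceed the grid pitch; plots may touch", stacklevel=2)
    margin = spec.margin_m * ppm
    width = int(round(2 * margin + (spec.Q - 1) * pitch_u + plot_w))
    height = int(round(2 * margin + (spec.P - 1) * pitch_v + plot_h))
    origin = (margin + plot_w / 2.0, margin + plot_h / 2.0)

    uniform = make_uniform_grid(
        spec.P, spec.Q, plot_w, plot_h, origin=origin, pitch_u=pitch_u, pitch_v=pitch_v
    )
    if displacements.shape != (spec.P, spec.Q):
        raise ValueError("displacement field shape must match the trial grid")
    truth = apply_displacements(uniform, displacements)

    img = _soil_background((height, width), spec, rng)
    vigor = spec.vigor_levels
    if vigor is None:
        vigor = np.ones((spec.P, spec.Q))
    for p in range(spec.P):
        for q in range(spec.Q):
            _draw_plot(
                img,
                spec,
                float(truth.centers_u[p, q]),
                float(truth.centers_v[p, q]),
                float(vigor[p, q]),
                rng,
            )
    image = RGBImage(
        pixels=np.clip(img, 0, 255).astype(np.uint8),
        resolution_cm_per_px=spec.resolution_cm_per_px,
    )
    return TrialSimulation(
        image=image,
        uniform_grid=uniform,
        truth_grid=truth,
        truth_displacements=displacements,
    )


def _shift_region_reflect(region: np.ndarray, du: int, dv: int) -> np.ndarray:
    """Translate region content by (du, dv), mirror-filling exposed bands."""
    pad_v, pad_u = abs(dv), abs(du)
    if pad_v == 0 and pad_u == 0:
        return region.copy()
    pad = ((pad_v, pad_v), (pad_u, pad_u)) + ((0, 0),) * (region.ndim - 2)
    padded = np.pad(region, pad, mode="reflect")
    v0 = pad_v - dv
    u0 = pad_u - du
    return padded[v0 : v0 + region.shape[0], u0 : u0 + region.shape[1]]


def _region_slices(grid: Grid, p: int, q: int, margin: float, shape):
    cell = grid.cell(p, q)
    x1 = int(round(cell.u - cell.W / 2 - margin))
    x2 = int(round(cell.u + cell.W / 2 + margin))
    y1 = int(round(cell.v - cell.H / 2 - margin))
    y2 = int(round(cell.v + cell.H / 2 + margin))
    x1, x2 = max(0, x1), min(shape[1], x2)
    y1, y2 = max(0, y1), min(shape[0], y2)
    return slice(y1, y2), slice(x1, x2)


def displace_plots_reflect(
    image: RGBImage,
    truth_grid_before: Grid,
    displacements: DisplacementField,
    margin: float,
) -> RGBImage:
    """Misalign the plots of an existing mosaic without leaving voids.

    For each plot, a region grown by ``margin`` pixels is remapped so the
    plot content lands at its displaced position; the band exposed by the
    translation is filled with the region's mirror reflection about its
    trailing edge.  Every pixel of the region stays covered, and with a
    soil-sized margin the reflection seams fall in low-texture soil.
    """
    max_du = float(np.max(np.abs(displacements.du))) if displacements.du.size else 0.0
    max_dv = float(np.max(np.abs(displacements.dv))) if displacements.dv.size else 0.0
    if margin < max(max_du, max_dv):
        raise ValueError(
            f"margin {margin} px is smaller than the largest requested "
            f"displacement ({max(max_du, max_dv):.1f} px)"
        )
    src = np.asarray(image.pixels)
    out = src.copy()
    for p in range(1, truth_grid_before.P + 1):
        for q in range(1, truth_grid_before.Q + 1):
            du = int(round(displacements.du[p - 1, q - 1]))
            dv = int(round(displacements.dv[p - 1, q - 1]))
            sl_v, sl_u = _region_slices(truth_grid_before, p, q, margin, src.shape)
            region = src[sl_v, sl_u]
            if region.size == 0:
                continue
            out[sl_v, sl_u] = _shift_region_reflect(region, du, dv)
    return RGBImage(
        pixels=out,
        resolution_cm_per_px=image.resolution_cm_per_px,
        geotransform=image.geotransform,
        nodata_mask=image.nodata_mask,
    )


def displace_plots_linear(
    image: RGBImage,
    truth_grid_before: Grid,
    displacements: DisplacementField,
    fill: Sequence[float] = (0, 0, 0),
) -> RGBImage:
    """Naive cut-and-paste misalignment: each plot rectangle is moved to
    its displaced position and the vacated area is painted with ``fill``.
    Kept as the contrast case -- it leaves voids at the plots' original
    positions."""
    src = np.asarray(image.pixels)
    out = src.copy()
    fill_arr = np.asarray(fill, dtype=src.dtype)
    for p in range(1, truth_grid_before.P + 1):
        for q in range(1, truth_grid_before.Q + 1):
            du = int(round(displacements.du[p - 1, q - 1]))
            dv = int(round(displacements.dv[p - 1, q - 1]))
            sl_v, sl_u = _region_slices(truth_grid_before, p, q, 0.0, src.shape)
            patch = src[sl_v, sl_u].copy()
            out[sl_v, sl_u] = fill_arr
            H, W = src.shape[:2]
            y1, y2 = sl_v.start + dv, sl_v.stop + dv
            x1, x2 = sl_u.start + du, sl_u.stop + du
            py1, py2 = max(0, -y1), patch.shape[0] - max(0, y2 - H)
            px1, px2 = max(0, -x1), patch.shape[1] - max(0, x2 - W)
            out[max(0, y1) : min(H, y2), max(0, x1) : min(W, x2)] = patch[
                py1:py2, px1:px2
            ]
    return RGBImage(
        pixels=out,
        resolution_cm_per_px=image.resolution_cm_per_px,
        geotransform=image.geotransform,
        nodata_mask=image.nodata_mask,
    )
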