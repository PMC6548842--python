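"""Vegetation-index scalar fields and constant-time rectangle sums.

The alignment energies all reduce to sums of a per-pixel vegetation index
over axis-aligned rectangles.  This module converts an RGB orthomosaic into
that scalar field S (the green-red difference index), builds a summed-area
table over it, and answers clipped rectangle-sum queries in O(1).

Coordinate convention (used package-wide): ``u`` is the column / x
coordinate, ``v`` the row / y coordinate, both 0-based with the origin at
the top-left pixel.  Arrays are stored numpy-style as ``(height, width)``
i.e. indexed ``[v, u]``.  Rectangles are half-open ``[x1, x2) x [y1, y2)``
in pixel units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "RGBImage",
    "ScalarField",
    "SummedAreaTable",
    "compute_green_red_vi",
    "build_summed_area_table",
    "rect_sum",
    "rect_sums",
    "segment_plants",
]


@dataclass
class GeoTransform:
    """Affine pixel -> world map with axis-aligned scaling.

    ``world = origin + (u * scale_x, v * scale_y)``; ``scale_y`` is
    typically negative (north-up raster, origin at the top-left corner).
    """

    origin_x: float
    origin_y: float
    scale_x: float
    scale_y: float

    def pixel_to_world(self, u, v):
        return (
            self.origin_x + np.asarray(u, dtype=float) * self.scale_x,
            self.origin_y + np.asarray(v, dtype=float) * self.scale_y,
        )

    def world_to_pixel(self, x, y):
        return (
            (np.asarray(x, dtype=float) - self.origin_x) / self.scale_x,
            (np.asarray(y, dtype=float) - self.origin_y) / self.scale_y,
        )


@dataclass
class RGBImage:
    """An RGB orthomosaic: ``(height, width, 3)`` non-negative intensities."""

    pixels: np.ndarray
    resolution_cm_per_px: float = 0.8
    geotransform: Optional[GeoTransform] = None
    nodata_mask: Optional[np.ndarray] = None  # True where pixel is nodata

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(
                f"expected a (height, width, 3) RGB array, got shape {self.pixels.shape}"
            )
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("image must contain at least one pixel")
        if np.any(self.pixels < 0):
            raise ValueError("channel intensities must be non-negative")
        if self.resolution_cm_per_px <= 0:
            raise ValueError("resolution_cm_per_px must be positive")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass
class ScalarField:
    """Discrete scalar field S over the pixel lattice, values in [-1, 1]."""

    values: np.ndarray
    resolution_cm_per_px: float = 0.8
    geotransform: Optional[GeoTransform] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("scalar field must be a 2D array")
        if self.values.size == 0:
            raise ValueError("scalar field must be non-empty")
        if self.resolution_cm_per_px <= 0:
            raise ValueError("resolution_cm_per_px must be positive")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]


@dataclass
class SummedAreaTable:
    """Prefix sums of a scalar field: ``cumulative[v, u]`` is the sum of the
    field over ``[0, u) x [0, v)``, so any rectangle sum is four lookups."""

    cumulative: np.ndarray

    @property
    def height(self) -> int:
        return self.cumulative.shape[0] - 1

    @property
    def width(self) -> int:
        return self.cumulative.shape[1] - 1


def compute_green_red_vi(image: RGBImage) -> ScalarField:
    """Green-red difference vegetation index, S = (G - R) / (G + R).

    The index is scale-free (invariant to uniform scaling of R and G), so
    channels are used at native integer scale.  Pixels with G + R = 0
    (pure black / pure blue, nodata borders) map to 0 -- a neutral value
    that neither attracts nor repels grid cells; nodata pixels likewise.
    """
    pix = np.asarray(image.pixels, dtype=float)
    if pix.ndim != 3 or pix.shape[2] != 3:
        raise ValueError("green-red index requires a 3-channel RGB image")
    r = pix[:, :, 0]
    g = pix[:, :, 1]
    denom = g + r
    values = np.zeros(denom.shape, dtype=float)
    ok = denom > 0
    values[ok] = (g[ok] - r[ok]) / denom[ok]
    if image.nodata_mask is not None:
        values[image.nodata_mask] = 0.0
    return ScalarField(
        values=values,
        resolution_cm_per_px=image.resolution_cm_per_px,
        geotransform=image.geotransform,
    )


def build_summed_area_table(field: ScalarField | np.ndarray) -> SummedAreaTable:
    """Build the (H+1) x (W+1) prefix-sum table of a field."""
    values = field.values if isinstance(field, ScalarField) else np.asarray(field, float)
    if values.size == 0:
        raise ValueError("cannot build a summed-area table of an empty field")
    cum = np.zeros((values.shape[0] + 1, values.shape[1] + 1), dtype=float)
    np.cumsum(values, axis=0, out=cum[1:, 1:])
    np.cumsum(cum[1:, 1:], axis=1, out=cum[1:, 1:])
    return SummedAreaTable(cumulative=cum)


def rect_sum(sat: SummedAreaTable, x1: int, y1: int, x2: int, y2: int) -> float:
    """Sum of the field over ``[x1, x2) x [y1, y2)``, clipped to bounds.

    Empty or fully-outside rectangles return 0.
    """
    return float(rect_sums(sat, np.array([x1]), np.array([y1]), np.array([x2]), np.array([y2]))[0])


def rect_sums(sat: SummedAreaTable, x1, y1, x2, y2) -> np.ndarray:
    """Vectorized :func:`rect_sum` over arrays of rectangles (any shape)."""
    w, h = sat.width, sat.height
    x1c = np.clip(np.asarray(x1), 0, w)
    x2c = np.clip(np.asarray(x2), 0, w)
    y1c = np.clip(np.asarray(y1), 0, h)
    y2c = np.clip(np.asarray(y2), 0, h)
    # degenerate (empty after clipping) rectangles collapse to zero area
    x2c = np.maximum(x1c, x2c)
    y2c = np.maximum(y1c, y2c)
    c = sat.cumulative
    return c[y2c, x2c] - c[y1c, x2c] - c[y2c, x1c] + c[y1c, x1c]


def segment_plants(field: ScalarField, threshold: float | str = "auto") -> np.ndarray:
    """Binary plant mask: 1 where S strictly exceeds the threshold.

    ``threshold="auto"`` picks Otsu's threshold on the S histogram, a
    reproducible stand-in for a manually tuned cut between the soil and
    canopy modes of the index distribution.
    """
    if isinstance(threshold, str):
        if threshold != "auto":
            raise ValueError(f"unknown threshold mode {threshold!r}")
        threshold = float(threshold_otsu(field.values))
    else:
        threshold = float(threshold)
        if not -1.0 <= threshold <= 1.0:
            raise ValueError("threshold must lie in [-1, 1]")
    return (field.values > threshold).astype(np.uint8)
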