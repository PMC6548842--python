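"""Raster I/O: TIFF/GeoTIFF and PNG/JPEG readers, GeoTIFF writers.

GeoTIFF georeferencing is handled at the tag level (ModelPixelScale 33550,
ModelTiepoint 33922, GDAL_NODATA 42113): enough to round-trip the
axis-aligned pixel->world map of a north-up orthomosaic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import imageio.v3 as iio
import numpy as np
import tifffile

from .scalar_field import GeoTransform, RGBImage, ScalarField

__all__ = ["read_image", "write_geotiff_rgb", "write_geotiff_field"]

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_NODATA = 42113


def _geotags_from_page(page) -> Optional[GeoTransform]:
    tags = page.tags
    if _TAG_PIXEL_SCALE in tags and _TAG_TIEPOINT in tags:
        sx, sy = tags[_TAG_PIXEL_SCALE].value[:2]
        tp = tags[_TAG_TIEPOINT].value
        # tiepoint: (i, j, k, x, y, z) -- pixel (i, j) maps to world (x, y)
        i, j, _, x, y, _ = tp[:6]
        return GeoTransform(
            origin_x=x - i * sx, origin_y=y + j * sy, scale_x=sx, scale_y=-sy
        )
    return None


def read_image(path: str | Path, resolution_cm_per_px: float = 0.8) -> RGBImage:
    """Read a TIFF/GeoTIFF/PNG/JPEG orthomosaic into an :class:`RGBImage`.

    A GeoTIFF geotransform and nodata value are honored when present; a
    4-band (RGBA) raster's alpha band becomes the nodata mask.
    """
    path = Path(path)
    geotransform = None
    nodata_value = None
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tif:
            page = tif.pages[0]
            data = page.asarray()
            geotransform = _geotags_from_page(page)
            if _TAG_NODATA in page.tags:
                try:
                    nodata_value = float(page.tags[_TAG_NODATA].value)
                except (TypeError, ValueError):
                    nodata_value = None
    else:
        data = iio.imread(path)

    data = np.asarray(data)
    nodata_mask = None
    if data.ndim == 2:
        raise ValueError(
            f"{path.name}: single-band raster; an RGB image with 3 channels is required"
        )
    if data.ndim != 3 or data.shape[2] < 3:
        raise ValueError(f"{path.name}: expected 3 (or 4) bands, got shape {data.shape}")
    if data.shape[2] >= 4:
        nodata_mask = data[:, :, 3] == 0
    rgb = data[:, :, :3]
    if nodata_value is not None:
        mask = np.all(rgb == nodata_value, axis=2)
        nodata_mask = mask if nodata_mask is None else (nodata_mask | mask)
    return RGBImage(
        pixels=rgb,
        resolution_cm_per_px=resolution_cm_per_px,
        geotransform=geotransform,
        nodata_mask=nodata_mask,
    )


def _geo_extratags(gt: GeoTransform):
    scale = (float(gt.scale_x), float(-gt.scale_y), 0.0)
    tiepoint = (0.0, 0.0, 0.0, float(gt.origin_x), float(gt.origin_y), 0.0)
    return [
        (_TAG_PIXEL_SCALE, "d", 3, scale, True),
        (_TAG_TIEPOINT, "d", 6, tiepoint, True),
    ]


def write_geotiff_rgb(path: str | Path, image: RGBImage) -> None:
    """Write an RGB image as (Geo)TIFF, embedding the geotransform if any."""
    extratags = _geo_extratags(image.geotransform) if image.geotransform else []
    tifffile.imwrite(
        Path(path),
        np.asarray(image.pixels, dtype=np.uint8),
        photometric="rgb",
        extratags=extratags,
    )


def write_geotiff_field(path: str | Path, field: ScalarField) -> None:
    """Write a scalar field as a single-band float32 GeoTIFF for inspection."""
    extratags = _geo_extratags(field.geotransform) if field.geotransform else []
    tifffile.imwrite(
        Path(path),
        field.values.astype(np.float32),
        photometric="minisblack",
        extratags=extratags,
    )
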