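"""Minimal ESRI shapefile (polygon) writer/reader.

Only the subset needed to exchange plot-boundary grids with GIS software is
implemented: one shapefile of simple 5-point closed rings (type 5, POLYGON)
with a .shx index and a .dbf attribute table of numeric/character fields.
"""

from __future__ import annotations

import struct
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = ["write_polygon_shapefile", "read_polygon_shapefile"]


def write_polygon_shapefile(
    path: str | Path,
    polygons: Sequence[np.ndarray],
    records: Sequence[dict],
    fields: Sequence[tuple[str, str, int, int]],
) -> None:
    """Write polygons (each an (n, 2) array of x, y vertices forming a closed
    ring) plus per-polygon attribute records.

    ``fields`` is a sequence of ``(name, type, length, decimals)`` with type
    ``"N"`` (numeric) or ``"C"`` (character).  Writes ``path`` with .shp,
    .shx and .dbf suffixes.
    """
    path = Path(path)
    base = path.with_suffix("")
    if len(polygons) != len(records):
        raise ValueError("one attribute record per polygon is required")

    shp_records = []
    for ring in polygons:
        ring = np.asarray(ring, dtype=float)
        if ring.ndim != 2 or ring.shape[1] != 2 or ring.shape[0] < 4:
            raise ValueError("each polygon must be an (n>=4, 2) closed ring")
        if not np.allclose(ring[0], ring[-1]):
            ring = np.vstack([ring, ring[0]])
        # shapefile spec: outer rings are clockwise (in a y-up frame)
        area2 = np.sum(ring[:-1, 0] * ring[1:, 1] - ring[1:, 0] * ring[:-1, 1])
        if area2 > 0:
            ring = ring[::-1]
        bbox = (ring[:, 0].min(), ring[:, 1].min(), ring[:, 0].max(), ring[:, 1].max())
        content = struct.pack("<i", 5)
        content += struct.pack("<4d", *bbox)
        content += struct.pack("<2i", 1, len(ring))  # one part
        content += struct.pack("<i", 0)  # part start index
        content += ring.astype("<f8").tobytes()
        shp_records.append((content, bbox))

    all_x = [b for _, bb in shp_records for b in (bb[0], bb[2])] or [0.0]
    all_y = [b for _, bb in shp_records for b in (bb[1], bb[3])] or [0.0]
    global_bbox = (min(all_x), min(all_y), max(all_x), max(all_y))

    def file_header(total_words: int) -> bytes:
        head = struct.pack(">i20xi", 9994, total_words)
        head += struct.pack("<2i", 1000, 5)
        head += struct.pack("<4d", *global_bbox)
        head += struct.pack("<4d", 0.0, 0.0, 0.0, 0.0)
        return head

    shp_len = 50 + sum(4 + len(c) // 2 for c, _ in shp_records)
    shx_len = 50 + 4 * len(shp_records)

    with open(base.with_suffix(".shp"), "wb") as shp, open(
        base.with_suffix(".shx"), "wb"
    ) as shx:
        shp.write(file_header(shp_len))
        shx.write(file_header(shx_len))
        offset = 50
        for i, (content, _) in enumerate(shp_records):
            words = len(content) // 2
            shp.write(struct.pack(">2i", i + 1, words))
            shp.write(content)
            shx.write(struct.pack(">2i", offset, words))
            offset += 4 + words

    _write_dbf(base.with_suffix(".dbf"), records, fields)


def _write_dbf(path: Path, records, fields) -> None:
    n_fields = len(fields)
    record_size = 1 + sum(length for _, _, length, _ in fields)
    header_size = 32 + 32 * n_fields + 1
    with open(path, "wb") as f:
        f.write(struct.pack("<B3Bihh20x", 0x03, 24, 1, 1, len(records), header_size, record_size))
        for name, ftype, length, decimals in fields:
            f.write(struct.pack("<11sc4xBB14x", name.encode()[:11], ftype.encode(), length, decimals))
        f.write(b"\x0d")
        for rec in records:
            f.write(b" ")
            for name, ftype, length, decimals in fields:
                val = rec.get(name, "")
                if ftype == "N":
                    text = f"{float(val):.{decimals}f}" if decimals else str(int(val))
                    f.write(text.rjust(length)[:length].encode())
                else:
                    f.write(str(val).ljust(length)[:length].encode())
        f.write(b"\x1a")


def read_polygon_shapefile(path: str | Path):
    """Read a polygon shapefile written by :func:`write_polygon_shapefile`.

    Returns ``(polygons, records)``: a list of (n, 2) vertex arrays (first
    ring of each shape) and a list of attribute dicts with numeric fields
    parsed to int/float and character fields stripped.
    """
    base = Path(path).with_suffix("")
    data = base.with_suffix(".shp").read_bytes()
    (magic,) = struct.unpack(">i", data[:4])
    if magic != 9994:
        raise ValueError(f"{base}.shp is not a shapefile")
    (shape_type,) = struct.unpack("<i", data[32:36])
    if shape_type != 5:
        raise ValueError(f"expected polygon shapefile (type 5), got type {shape_type}")

    polygons = []
    pos = 100
    while pos < len(data):
        _, words = struct.unpack(">2i", data[pos : pos + 8])
        content = data[pos + 8 : pos + 8 + 2 * words]
        pos += 8 + 2 * words
        (stype,) = struct.unpack("<i", content[:4])
        if stype == 0:  # null shape
            polygons.append(np.empty((0, 2)))
            continue
        n_parts, n_points = struct.unpack("<2i", content[36:44])
        parts = struct.unpack(f"<{n_parts}i", content[44 : 44 + 4 * n_parts])
        pts_off = 44 + 4 * n_parts
        pts = np.frombuffer(content, dtype="<f8", count=2 * n_points, offset=pts_off)
        pts = pts.reshape(n_points, 2)
        end = parts[1] if n_parts > 1 else n_points
        polygons.append(np.array(pts[parts[0] : end]))

    records = _read_dbf(base.with_suffix(".dbf"))
    return polygons, records


def _read_dbf(path: Path):
    data = path.read_bytes()
    n_records, header_size, record_size = struct.unpack("<ihh", data[4:12])
    fields = []
    pos = 32
    while data[pos] != 0x0D:
        name = data[pos : pos + 11].split(b"\x00")[0].decode()
        ftype = chr(data[pos + 11])
        length = data[pos + 16]
        decimals = data[pos + 17]
        fields.append((name, ftype, length, decimals))
        pos += 32
    records = []
    for i in range(n_records):
        start = header_size + i * record_size + 1  # skip deletion flag
        rec = {}
        off = start
        for name, ftype, length, decimals in fields:
            raw = data[off : off + length].decode().strip()
            off += length
            if ftype == "N" and raw:
                rec[name] = float(raw) if decimals else int(raw)
            else:
                rec[name] = raw
        records.append(rec)
    return records
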