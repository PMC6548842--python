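"""Independent brute-force reference implementations used as test oracles.

Everything here is written with plain nested loops over pixels and cells,
deliberately sharing no code path with the package's summed-area-table /
vectorized implementations.
"""

from __future__ import annotations

import math

import numpy as np


def rect_sum_loops(values: np.ndarray, x1: int, y1: int, x2: int, y2: int) -> float:
    """Direct double-loop sum of a field over [x1, x2) x [y1, y2), clipped."""
    total = 0.0
    for v in range(max(0, y1), min(values.shape[0], y2)):
        for u in range(max(0, x1), min(values.shape[1], x2)):
            total += values[v, u]
    return total


def cell_rect(u, v, W, H, du, dv):
    w_px = int(round(W))
    h_px = int(round(H))
    x1 = int(np.rint(u + du - W / 2.0))
    y1 = int(np.rint(v + dv - H / 2.0))
    return x1, y1, x1 + w_px, y1 + h_px


def oracle_energies(values, grid, du, dv):
    """Per-cell (d, g, f) computed term by term with loops."""
    P, Q = grid.P, grid.Q
    d = np.zeros((P, Q))
    rects = {}
    for p in range(P):
        for q in range(Q):
            r = cell_rect(
                grid.centers_u[p, q], grid.centers_v[p, q],
                grid.cell_w, grid.cell_h, du[p, q], dv[p, q],
            )
            rects[(p, q)] = r
            d[p, q] = rect_sum_loops(values, *r)
    g = np.zeros((P, Q))
    for p in range(P):
        for q in range(Q):
            for pp, qq in ((p - 1, q), (p, q - 1), (p + 1, q), (p, q + 1)):
                if not (0 <= pp < P and 0 <= qq < Q):
                    continue
                ax1, ay1, ax2, ay2 = rects[(p, q)]
                bx1, by1, bx2, by2 = rects[(pp, qq)]
                ox1, oy1 = max(ax1, bx1), max(ay1, by1)
                ox2, oy2 = min(ax2, bx2), min(ay2, by2)
                if ox1 >= ox2 or oy1 >= oy2:
                    continue
                denom = d[p, q] + d[pp, qq]
                if denom == 0:
                    continue
                shared = rect_sum_loops(values, ox1, oy1, ox2, oy2)
                g[p, q] += (d[pp, qq] / denom) * shared
    area = round(grid.cell_w) * round(grid.cell_h)
    f = (d - g) / area
    return d, g, f


def oracle_grid_cost(values, grid, du, dv, intra_only: bool = False) -> float:
    d, g, f = oracle_energies(values, grid, du, dv)
    if intra_only:
        area = round(grid.cell_w) * round(grid.cell_h)
        f = d / area
    return math.exp(-float(np.mean(f)))
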