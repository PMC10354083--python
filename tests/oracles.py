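"""Independent brute-force oracles shared across test modules.

These deliberately avoid the package's own code paths: plain loops,
sorting and enumeration only.
"""

import numpy as np


def brute_force_buffer_median(raster, point, radius):
    """Enumerate every pixel centre, keep those within radius, sort, median."""
    vals = []
    for j in range(raster.nrows):
        for i in range(raster.ncols):
            cx = raster.x0 + (i + 0.5) * raster.pixel
            cy = raster.y0 + (j + 0.5) * raster.pixel
            if (cx - point[0]) ** 2 + (cy - point[1]) ** 2 <= radius**2:
                v = raster.values[j, i]
                if not np.isnan(v):
                    vals.append(v)
    if not vals:
        return None
    vals = sorted(vals)
    n = len(vals)
    return vals[n // 2] if n % 2 else 0.5 * (vals[n // 2 - 1] + vals[n // 2])


def nearest_center_oracle(grid, x, y):
    """The containing flat-top hexagon is the one with the nearest centre."""
    s = grid.size
    q0 = int(round(x / (1.5 * s)))
    best, best_d = None, np.inf
    for q in range(q0 - 3, q0 + 4):
        r0 = int(round(y / (np.sqrt(3) * s) - q / 2.0))
        for r in range(r0 - 3, r0 + 4):
            cx, cy = grid.cell_center(q, r)
            d = (cx - x) ** 2 + (cy - y) ** 2
            if d < best_d - 1e-12:
                best, best_d = (q, r), d
    return best
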