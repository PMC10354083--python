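"""Flat-top hexagonal lattice for spatiotemporal subsampling strata.

The lattice tiles the metric plane with regular flat-top hexagons addressed
by axial coordinates ``(q, r)``.  ``width_km`` is the across-flats diameter,
which equals the centre-to-centre distance of adjacent cells; the default
5 km matches the gridding convention of the checklist-thinning workflow.

Points in lon/lat are projected with the same local equirectangular mapping
used for rasters before cell assignment, so one grid instance serves both
planar synthetic worlds and geographic data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ConfigurationError
from .raster import EARTH_RADIUS_KM

SQRT3 = np.sqrt(3.0)


@dataclass(frozen=True)
class HexGrid:
    """A planar flat-top hexagonal grid.

    Parameters
    ----------
    width_km
        Across-flats cell diameter (= adjacent centre spacing), > 0.
    origin
        Metric-km coordinates of cell (0, 0)'s centre.
    crs
        ``"planar-km"``: input points are already km.  ``"wgs84"``: points
        are lon/lat degrees, projected about ``lonlat_center`` first.
    lonlat_center
        Projection centre (lon, lat) used when ``crs == "wgs84"``.
    """

    width_km: float = 5.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str = "planar-km"
    lonlat_center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.width_km <= 0:
            raise ConfigurationError("hex width must be > 0")
        if self.crs not in ("planar-km", "wgs84"):
            raise ConfigurationError(f"unknown CRS tag {self.crs!r}")

    @property
    def size(self) -> float:
        """Circumradius of each hexagon."""
        return self.width_km / SQRT3

    def _to_metric(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        if self.crs == "planar-km":
            return np.asarray(x, float), np.asarray(y, float)
        lat0 = np.deg2rad(self.lonlat_center[1])
        kx = EARTH_RADIUS_KM * np.cos(lat0) * np.pi / 180.0
        ky = EARTH_RADIUS_KM * np.pi / 180.0
        return np.asarray(x, float) * kx, np.asarray(y, float) * ky

    def cell_center(self, q: np.ndarray, r: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Metric-km centre of cell(s) (q, r)."""
        q = np.asarray(q, float)
        r = np.asarray(r, float)
        s = self.size
        cx = self.origin[0] + 1.5 * s * q
        cy = self.origin[1] + SQRT3 * s * (r + q / 2.0)
        return cx, cy

    def assign_cells(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Axial (q, r) of the cell containing each point.

        Uses fractional axial coordinates followed by cube rounding, which
        returns the nearest cell centre; the rounding rule makes boundary
        assignment deterministic.
        """
        x = np.atleast_1d(np.asarray(x, float))
        y = np.atleast_1d(np.asarray(y, float))
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("non-finite coordinates in cell assignment")
        mx, my = self._to_metric(x, y)
        mx = mx - self.origin[0]
        my = my - self.origin[1]
        s = self.size
        qf = (2.0 / 3.0) * mx / s
        rf = (-mx / 3.0 + SQRT3 / 3.0 * my) / s
        return _cube_round(qf, rf)

    def assign_cell(self, x: float, y: float) -> tuple[int, int]:
        q, r = self.assign_cells([x], [y])
        return int(q[0]), int(r[0])


def _cube_round(qf: np.ndarray, rf: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sf = -qf - rf
    q = np.round(qf)
    r = np.round(rf)
    s = np.round(sf)
    dq = np.abs(q - qf)
    dr = np.abs(r - rf)
    ds = np.abs(s - sf)
    fix_q = (dq > dr) & (dq > ds)
    fix_r = ~fix_q & (dr > ds)
    q = np.where(fix_q, -r - s, q)
    r = np.where(fix_r, -q - s, r)
    return q.astype(np.int64), r.astype(np.int64)
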