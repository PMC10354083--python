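"""Single-band radiance rasters: plain-text grid I/O, median compositing and
buffer-median extraction.

The raster container holds upward radiance (nW cm^-2 sr^-1) on a regular
grid.  Two coordinate reference tags are supported:

``planar-km``
    x/y are kilometres on a plane; all distances are Euclidean.
``wgs84``
    x/y are longitude/latitude degrees; for metric operations points are
    projected with a local equirectangular projection about the raster
    centre (adequate at the few-km buffer scale this pipeline uses).

The on-disk format is a small self-describing text grid (header lines then
``nrows`` rows of ``ncols`` values, southernmost row first)::

    URBANTOL-RASTER 1
    crs: planar-km
    x0: 0.0
    y0: 0.0
    pixel: 1.0
    ncols: 120
    nrows: 80
    nodata: -1.0
    <values...>
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import (
    AlignmentError,
    ConfigurationError,
    CoverageError,
    ExtentError,
)

EARTH_RADIUS_KM = 6371.0088

_MAGIC = "URBANTOL-RASTER 1"


@dataclass
class RadianceRaster:
    """A single-band non-negative radiance grid.

    Parameters
    ----------
    x0, y0
        Coordinates of the lower-left *corner* of the grid (km or degrees).
    pixel
        Pixel edge length (km or degrees), > 0.
    values
        2-D float array, shape ``(nrows, ncols)``; row 0 is the southernmost
        row.  ``NaN`` marks nodata.
    crs
        ``"planar-km"`` or ``"wgs84"``.
    """

    x0: float
    y0: float
    pixel: float
    values: np.ndarray
    crs: str = "planar-km"
    nodata: float = -1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ConfigurationError("raster values must be a 2-D array")
        if self.pixel <= 0:
            raise ConfigurationError("pixel size must be > 0")
        if self.crs not in ("planar-km", "wgs84"):
            raise ConfigurationError(f"unknown CRS tag {self.crs!r}")
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ConfigurationError("radiance values must be >= 0 or nodata")

    # -- geometry -----------------------------------------------------------

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the grid outline."""
        return (
            self.x0,
            self.y0,
            self.x0 + self.ncols * self.pixel,
            self.y0 + self.nrows * self.pixel,
        )

    def same_geometry(self, other: "RadianceRaster") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.isclose(self.x0, other.x0)
            and np.isclose(self.y0, other.y0)
            and np.isclose(self.pixel, other.pixel)
            and self.crs == other.crs
        )

    def contains(self, x: float, y: float) -> bool:
        xmin, ymin, xmax, ymax = self.extent
        return xmin <= x <= xmax and ymin <= y <= ymax

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Native-coordinate centre arrays (cx of shape ncols, cy of nrows)."""
        cx = self.x0 + (np.arange(self.ncols) + 0.5) * self.pixel
        cy = self.y0 + (np.arange(self.nrows) + 0.5) * self.pixel
        return cx, cy

    # -- projection ---------------------------------------------------------

    def _project(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map native coordinates to a metric (km) plane.

        Identity for planar rasters; local equirectangular about the raster
        centre for lon/lat rasters.
        """
        if self.crs == "planar-km":
            return np.asarray(x, float), np.asarray(y, float)
        xmin, ymin, xmax, ymax = self.extent
        lat0 = np.deg2rad(0.5 * (ymin + ymax))
        kx = EARTH_RADIUS_KM * np.cos(lat0) * np.pi / 180.0
        ky = EARTH_RADIUS_KM * np.pi / 180.0
        return np.asarray(x, float) * kx, np.asarray(y, float) * ky

    def metric_pixel_centers(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """All pixel centres in metric km, flattened, plus their values."""
        cx, cy = self.pixel_centers()
        gx, gy = np.meshgrid(cx, cy)
        px, py = self._project(gx.ravel(), gy.ravel())
        return px, py, self.values.ravel()

    # -- I/O ----------------------------------------------------------------

    def write_text(self, path: str | Path) -> None:
        path = Path(path)
        vals = np.where(np.isnan(self.values), self.nodata, self.values)
        with path.open("w") as fh:
            fh.write(f"{_MAGIC}\n")
            fh.write(f"crs: {self.crs}\n")
            fh.write(f"x0: {self.x0:.17g}\n")
            fh.write(f"y0: {self.y0:.17g}\n")
            fh.write(f"pixel: {self.pixel:.17g}\n")
            fh.write(f"ncols: {self.ncols}\n")
            fh.write(f"nrows: {self.nrows}\n")
            fh.write(f"nodata: {self.nodata:.17g}\n")
            for row in vals:
                fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")

    @classmethod
    def read_text(cls, path: str | Path) -> "RadianceRaster":
        path = Path(path)
        with path.open() as fh:
            magic = fh.readline().strip()
            if magic != _MAGIC:
                raise ConfigurationError(f"{path}: not a radiance-raster text grid")
            hdr: dict[str, str] = {}
            for _ in range(7):
                key, _, val = fh.readline().partition(":")
                hdr[key.strip()] = val.strip()
            ncols, nrows = int(hdr["ncols"]), int(hdr["nrows"])
            nodata = float(hdr["nodata"])
            data = np.loadtxt(fh, dtype=float, ndmin=2)
        if data.shape != (nrows, ncols):
            raise ConfigurationError(
                f"{path}: expected {nrows}x{ncols} values, got {data.shape}"
            )
        data = np.where(data == nodata, np.nan, data)
        return cls(
            x0=float(hdr["x0"]),
            y0=float(hdr["y0"]),
            pixel=float(hdr["pixel"]),
            values=data,
            crs=hdr["crs"],
            nodata=nodata,
        )


def composite_median_raster(monthly: Sequence[RadianceRaster]) -> RadianceRaster:
    """Per-pixel median across a stack of co-registered monthly rasters.

    Nodata pixels are ignored month-wise; a pixel that is nodata in every
    month stays nodata.  This condenses a multi-year monthly night-lights
    series into the single urbanisation surface used downstream.
    """
    monthly = list(monthly)
    if not monthly:
        raise AlignmentError("empty raster stack")
    ref = monthly[0]
    for r in monthly[1:]:
        if not ref.same_geometry(r):
            raise AlignmentError("raster stack members differ in grid geometry")
    stack = np.stack([r.values for r in monthly])
    with np.errstate(invalid="ignore"):
        all_nan = np.all(np.isnan(stack), axis=0)
        med = np.full(ref.values.shape, np.nan)
        if not all_nan.all():
            med[~all_nan] = np.nanmedian(stack[:, ~all_nan], axis=0)
    return RadianceRaster(ref.x0, ref.y0, ref.pixel, med, ref.crs, ref.nodata)


def median_radiance_in_buffer(
    raster: RadianceRaster, point: tuple[float, float], radius_km: float = 5.0
) -> float:
    """Median radiance over pixels whose centres fall within ``radius_km``.

    A pixel belongs to the buffer when its centre lies within Euclidean
    (metric) distance ``radius_km`` of the point, boundary inclusive.  For
    an even pixel count the median is the mean of the two middle values.
    """
    x, y = float(point[0]), float(point[1])
    if not raster.contains(x, y):
        raise ExtentError(f"point ({x}, {y}) outside raster extent {raster.extent}")
    px, py, vals = raster.metric_pixel_centers()
    qx, qy = raster._project(np.array([x]), np.array([y]))
    d2 = (px - qx[0]) ** 2 + (py - qy[0]) ** 2
    sel = d2 <= radius_km**2
    chosen = vals[sel]
    chosen = chosen[~np.isnan(chosen)]
    if chosen.size == 0:
        raise CoverageError(
            f"no usable pixels within {radius_km} km of ({x}, {y})"
        )
    return float(np.median(chosen))


def median_radiance_at_points(
    raster: RadianceRaster,
    xs: np.ndarray,
    ys: np.ndarray,
    radius_km: float = 5.0,
) -> np.ndarray:
    """Vectorised buffer-median for many points (KD-tree accelerated).

    Semantics are identical to :func:`median_radiance_in_buffer`; points
    outside the extent or with empty buffers receive ``NaN`` instead of
    raising, so bulk extraction over a checklist table never aborts.
    """
    xs = np.asarray(xs, float)
    ys = np.asarray(ys, float)
    px, py, vals = raster.metric_pixel_centers()
    tree = cKDTree(np.column_stack([px, py]))
    qx, qy = raster._project(xs, ys)
    out = np.full(xs.shape, np.nan)
    xmin, ymin, xmax, ymax = raster.extent
    inside = (xs >= xmin) & (xs <= xmax) & (ys >= ymin) & (ys <= ymax)
    idx_lists = tree.query_ball_point(
        np.column_stack([qx, qy]), r=radius_km * (1 + 1e-12)
    )
    r2 = radius_km**2
    for i, idx in enumerate(idx_lists):
        if not inside[i] or not idx:
            continue
        idx = np.asarray(idx)
        d2 = (px[idx] - qx[i]) ** 2 + (py[idx] - qy[i]) ** 2
        chosen = vals[idx[d2 <= r2]]
        chosen = chosen[~np.isnan(chosen)]
        if chosen.size:
            out[i] = np.median(chosen)
    return out
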