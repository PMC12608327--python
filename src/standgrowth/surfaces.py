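"""Raster surfaces: Delaunay-TIN rasterization, DSM/DTM/CHM, smoothing, masking.

Grid convention: top-left origin, row index grows southward, column index
grows eastward.  Cell (i, j) covers the half-open square
``[ox + j*r, ox + (j+1)*r) x (oy - (i+1)*r, oy - i*r]`` and is sampled at its
center.  Rasters are float arrays with NaN as the NA value.  On disk they are
written as ESRI ASCII grids so that every intermediate stays plain text.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.interpolate import LinearNDInterpolator
from scipy.spatial import QhullError

logger = logging.getLogger(__name__)

DEFAULT_RESOLUTION = 0.5
DEFAULT_MASK_THRESHOLD = 7.0

#: 3x3 smoothing kernel; weights sum to 1 and are 90-degree symmetric.
SMOOTHING_KERNEL = np.array([
    [0.0625, 0.125, 0.0625],
    [0.125, 0.25, 0.125],
    [0.0625, 0.125, 0.0625],
])


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster: top-left origin, resolution, shape."""

    origin_x: float
    origin_y: float
    resolution: float
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one cell")

    @classmethod
    def from_bounds(cls, xmin: float, ymin: float, xmax: float, ymax: float,
                    resolution: float) -> "GridSpec":
        """Build a spec covering the bounds, origin snapped to a multiple of
        the resolution so that grids from different epochs align cellwise."""
        if xmax <= xmin or ymax <= ymin:
            raise ValueError("bounds must have positive extent")
        ox = math.floor(xmin / resolution) * resolution
        oy = math.ceil(ymax / resolution) * resolution
        n_cols = int(math.ceil((xmax - ox) / resolution))
        n_rows = int(math.ceil((oy - ymin) / resolution))
        return cls(ox, oy, resolution, n_rows, n_cols)

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of shape (n_rows, n_cols) with cell-center coords."""
        r = self.resolution
        xs = self.origin_x + (np.arange(self.n_cols) + 0.5) * r
        ys = self.origin_y - (np.arange(self.n_rows) + 0.5) * r
        return np.meshgrid(xs, ys)


@dataclass
class RasterGrid:
    """Single-band georeferenced grid with NaN as NA."""

    spec: GridSpec
    values: np.ndarray
    crs: str = "local"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (self.spec.n_rows, self.spec.n_cols):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"({self.spec.n_rows}, {self.spec.n_cols})")

    @property
    def resolution(self) -> float:
        return self.spec.resolution

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def same_geometry(self, other: "RasterGrid") -> bool:
        a, b = self.spec, other.spec
        return (a.n_rows == b.n_rows and a.n_cols == b.n_cols
                and math.isclose(a.origin_x, b.origin_x, abs_tol=1e-9)
                and math.isclose(a.origin_y, b.origin_y, abs_tol=1e-9)
                and math.isclose(a.resolution, b.resolution, abs_tol=1e-12))

    def cell_center(self, i: int, j: int) -> tuple[float, float]:
        r = self.spec.resolution
        return (self.spec.origin_x + (j + 0.5) * r,
                self.spec.origin_y - (i + 0.5) * r)

    def copy_with(self, values: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.spec, values, crs=self.crs)


# ---------------------------------------------------------------------------
# ASCII grid IO (plain-text intermediates)

def write_ascii_grid(raster: RasterGrid, path: str | Path,
                     nodata: float = -9999.0) -> None:
    spec = raster.spec
    vals = np.where(np.isnan(raster.values), nodata, raster.values)
    header = (
        f"ncols {spec.n_cols}\n"
        f"nrows {spec.n_rows}\n"
        f"xllcorner {spec.origin_x:.6f}\n"
        f"yllcorner {spec.origin_y - spec.n_rows * spec.resolution:.6f}\n"
        f"cellsize {spec.resolution:.6f}\n"
        f"NODATA_value {nodata}\n"
    )
    with Path(path).open("w") as fh:
        fh.write(header)
        np.savetxt(fh, vals, fmt="%.4f")


def read_ascii_grid(path: str | Path, crs: str = "local") -> RasterGrid:
    path = Path(path)
    header: dict[str, float] = {}
    with path.open() as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        vals = np.loadtxt(fh, ndmin=2)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    r = header["cellsize"]
    spec = GridSpec(header["xllcorner"], header["yllcorner"] + n_rows * r,
                    r, n_rows, n_cols)
    vals = np.where(vals == header["nodata_value"], np.nan, vals)
    return RasterGrid(spec, vals, crs=crs)


# ---------------------------------------------------------------------------
# TIN rasterization

def build_tin_raster(points: np.ndarray, spec: GridSpec,
                     crs: str = "local") -> RasterGrid:
    """Rasterize scattered (x, y, z) points via a Delaunay TIN.

    Each cell center inside the convex hull of the points receives the value
    of the linear (barycentric) interpolant of its containing triangle; cells
    outside the hull are NA.

    Parameters
    ----------
    points : ndarray of shape (n, 3)
        Scattered x, y, z samples; at least three non-collinear points.
    """
    points = np.asarray(points, dtype=np.float64)
    if points.ndim != 2 or points.shape[1] != 3:
        raise ValueError("points must be an (n, 3) array of x, y, z")
    if len(points) < 3:
        raise ValueError("TIN interpolation requires at least 3 points")
    try:
        interp = LinearNDInterpolator(points[:, :2], points[:, 2])
    except QhullError as exc:
        raise ValueError(f"degenerate point set (collinear?): {exc}") from exc
    X, Y = spec.cell_centers()
    values = interp(X, Y)
    return RasterGrid(spec, values, crs=crs)


def _require_spec(cloud, resolution: float, spec: GridSpec | None) -> GridSpec:
    if spec is not None:
        return spec
    xmin, ymin, xmax, ymax = cloud.bounds
    return GridSpec.from_bounds(xmin, ymin, xmax, ymax, resolution)


def make_dsm(cloud, resolution: float = DEFAULT_RESOLUTION,
             spec: GridSpec | None = None) -> RasterGrid:
    """Digital surface model from first returns."""
    first = cloud.select(cloud.return_number == 1)
    if len(first) < 3:
        raise ValueError("not enough first returns to build a DSM")
    spec = _require_spec(cloud, resolution, spec)
    pts = np.column_stack([first.x, first.y, first.z])
    return build_tin_raster(pts, spec, crs=cloud.crs)


def make_dtm(cloud, resolution: float = DEFAULT_RESOLUTION,
             spec: GridSpec | None = None) -> RasterGrid:
    """Digital terrain model from ground returns.

    Classified ground points (class 2) are preferred; when the cloud carries
    no class-2 points the farthest returns (return_number == number_of_returns)
    are used instead, with a logged warning.
    """
    ground = cloud.select(cloud.class_code == 2)
    if len(ground) < 3:
        logger.warning("no classified ground points; falling back to last returns")
        ground = cloud.select(cloud.return_number == cloud.number_of_returns)
    if len(ground) < 3:
        raise ValueError("not enough ground/last returns to build a DTM")
    spec = _require_spec(cloud, resolution, spec)
    pts = np.column_stack([ground.x, ground.y, ground.z])
    return build_tin_raster(pts, spec, crs=cloud.crs)


def compute_chm(dsm: RasterGrid, dtm: RasterGrid,
                clamp_negative: bool = True) -> RasterGrid:
    """Canopy height model: cellwise DSM - DTM on an identical grid.

    NA in either input propagates.  Negative differences (vertical noise on
    open ground) are clamped to 0 by default.
    """
    if not dsm.same_geometry(dtm):
        raise ValueError("DSM and DTM grid geometries differ")
    chm = dsm.values - dtm.values
    if clamp_negative:
        chm = np.where(chm < 0, 0.0, chm)
    return dsm.copy_with(chm)


def gaussian_smooth(raster: RasterGrid,
                    kernel: np.ndarray = SMOOTHING_KERNEL) -> RasterGrid:
    """Centered 3x3 smoothing convolution, NA-aware.

    At borders and next to NA cells the kernel weights are renormalized over
    the valid neighbors, so a constant raster stays exactly constant.  A cell
    whose whole neighborhood (itself included) is NA stays NA.
    """
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.shape != (3, 3):
        raise ValueError("kernel must be 3x3")
    vals = raster.values
    valid = ~np.isnan(vals)
    filled = np.where(valid, vals, 0.0)
    acc = np.zeros_like(filled)
    wsum = np.zeros_like(filled)
    n_rows, n_cols = vals.shape
    for dm in (-1, 0, 1):
        for dn in (-1, 0, 1):
            w = kernel[dm + 1, dn + 1]
            src_r = slice(max(dm, 0), n_rows + min(dm, 0))
            src_c = slice(max(dn, 0), n_cols + min(dn, 0))
            dst_r = slice(max(-dm, 0), n_rows + min(-dm, 0))
            dst_c = slice(max(-dn, 0), n_cols + min(-dn, 0))
            acc[dst_r, dst_c] += w * filled[src_r, src_c]
            wsum[dst_r, dst_c] += w * valid[src_r, src_c]
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(wsum > 0, acc / wsum, np.nan)
    return raster.copy_with(out)


def mask_below(raster: RasterGrid,
               threshold: float = DEFAULT_MASK_THRESHOLD) -> RasterGrid:
    """Replace cells strictly below ``threshold`` with NA; cells >= threshold
    are kept unchanged (7 m default: low vegetation is cut out of the CHM)."""
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    vals = raster.values
    out = np.where(np.isnan(vals) | (vals >= threshold), vals, np.nan)
    return raster.copy_with(out)
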