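"""Variable-window local-maxima tree-top detection and spatial filtering.

A cell of the smoothed, masked CHM is a tree top when its value is >= every
other non-NA cell whose center lies within a circular search window centered
on it.  The window radius depends on the candidate's own height through a
linear crown-size relation (0.16 * height + 0.8 meters by default); taller
trees get wider windows.  Equal-valued plateaus are broken deterministically:
the lexicographically smallest (row, col) cell wins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import Point
from shapely.prepared import prep

from standgrowth.surfaces import RasterGrid

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_SLOPE = 0.16
DEFAULT_WINDOW_INTERCEPT = 0.8
DEFAULT_NEA_BUFFER = 2.0


@dataclass
class TreeTop:
    """Detected apex: cell-center position, CHM height, search radius."""

    id: int
    x: float
    y: float
    height: float
    search_radius: float
    forest_address: str | None = None
    epoch: str | None = None


def window_radius(height: float | np.ndarray,
                  slope: float = DEFAULT_WINDOW_SLOPE,
                  intercept: float = DEFAULT_WINDOW_INTERCEPT) -> float | np.ndarray:
    """Search-window radius (m) for a candidate of the given height (m)."""
    h = np.asarray(height, dtype=np.float64)
    if (h < 0).any():
        raise ValueError("height must be non-negative")
    out = slope * h + intercept
    return float(out) if np.isscalar(height) or out.ndim == 0 else out


def _disk_offsets(radius_m: float, resolution: float) -> np.ndarray:
    """(di, dj) offsets whose cell-center distance is within radius_m."""
    k = int(math.floor(radius_m / resolution + 1e-12))
    offs = []
    for di in range(-k, k + 1):
        for dj in range(-k, k + 1):
            if math.hypot(di, dj) * resolution <= radius_m + 1e-12:
                offs.append((di, dj))
    return np.array(offs, dtype=np.int64)


def detect_treetops(chm: RasterGrid,
                    slope: float = DEFAULT_WINDOW_SLOPE,
                    intercept: float = DEFAULT_WINDOW_INTERCEPT,
                    epoch: str | None = None) -> list[TreeTop]:
    """Detect tree tops on a smoothed, masked CHM.

    Returns tops sorted by (row, col).  An all-NA raster yields an empty
    list.  The footprint radius is evaluated per candidate from its own CHM
    value, so the window grows with tree height.
    """
    vals = chm.values
    valid = ~np.isnan(vals)
    if not valid.any():
        return []
    r = chm.resolution
    neg_inf = np.where(valid, vals, -np.inf)

    radius = np.where(valid, slope * np.maximum(vals, 0.0) + intercept, np.nan)
    # Distinct circular footprints are bounded by the distinct cell-center
    # distances below the max radius; group cells by footprint to use one
    # maximum_filter call per group instead of a per-cell scan.
    max_rad = np.nanmax(radius)
    kmax = int(math.floor(max_rad / r + 1e-12))
    dists = sorted({math.hypot(di, dj) * r
                    for di in range(kmax + 1) for dj in range(kmax + 1)
                    if math.hypot(di, dj) * r <= max_rad + 1e-12})
    candidates: list[tuple[int, int]] = []
    thresholds = dists + [np.inf]
    for lo, hi in zip(thresholds[:-1], thresholds[1:]):
        group = valid & (radius >= lo - 1e-12) & (radius < hi - 1e-12)
        if not group.any():
            continue
        size = int(math.floor(lo / r + 1e-12))
        fp = np.zeros((2 * size + 1, 2 * size + 1), dtype=bool)
        for di in range(-size, size + 1):
            for dj in range(-size, size + 1):
                if math.hypot(di, dj) * r <= lo + 1e-12:
                    fp[di + size, dj + size] = True
        local_max = ndimage.maximum_filter(neg_inf, footprint=fp,
                                           mode="constant", cval=-np.inf)
        hits = group & (vals >= local_max)
        candidates.extend(zip(*np.nonzero(hits)))

    n_rows, n_cols = vals.shape
    tops: list[TreeTop] = []
    for i, j in sorted(candidates):
        v = vals[i, j]
        rad = slope * v + intercept
        k = int(math.floor(rad / r + 1e-12))
        keep = True
        for di in range(-k, k + 1):
            p = i + di
            if p < 0 or p >= n_rows:
                continue
            for dj in range(-k, k + 1):
                q = j + dj
                if q < 0 or q >= n_cols or (di == 0 and dj == 0):
                    continue
                if math.hypot(di, dj) * r > rad + 1e-12:
                    continue
                w = vals[p, q]
                if np.isnan(w):
                    continue
                # plateau tie-break: smallest (row, col) wins
                if w > v or (w == v and (p, q) < (i, j)):
                    keep = False
                    break
            if not keep:
                break
        if keep:
            x, y = chm.cell_center(i, j)
            tops.append(TreeTop(id=len(tops), x=x, y=y, height=float(v),
                                search_radius=float(rad), epoch=epoch))
    return tops


def filter_treetops(tops: list[TreeTop], units, neas=(),
                    nea_buffer: float = DEFAULT_NEA_BUFFER) -> list[TreeTop]:
    """Keep tops inside forest-stand unit polygons, outside buffered NEAs.

    ``units`` is an iterable of objects with ``geometry``, ``forest_address``
    and ``land_kind`` attributes (see :mod:`standgrowth.geoprep`); units whose
    ``land_kind`` is not ``"stand"`` reject their tops (marshes, meadows...).
    ``neas`` is an iterable of shapely geometries, each dilated by
    ``nea_buffer`` meters before the point-in-polygon test.  Survivors gain
    the forest address of their containing unit.
    """
    unit_list = [(u, prep(u.geometry)) for u in units]
    nea_prepped = [prep(g.buffer(nea_buffer, join_style="round")) for g in neas]
    kept: list[TreeTop] = []
    dropped_outside = dropped_nea = dropped_nonstand = 0
    for top in tops:
        pt = Point(top.x, top.y)
        if any(p.intersects(pt) for p in nea_prepped):
            dropped_nea += 1
            continue
        owner = None
        for unit, prepared in unit_list:
            if prepared.intersects(pt):
                owner = unit
                break
        if owner is None:
            dropped_outside += 1
            continue
        if getattr(owner, "land_kind", "stand") != "stand":
            dropped_nonstand += 1
            continue
        kept.append(TreeTop(id=top.id, x=top.x, y=top.y, height=top.height,
                            search_radius=top.search_radius,
                            forest_address=owner.forest_address,
                            epoch=top.epoch))
    logger.info("treetop filter: kept %d, dropped %d outside units, "
                "%d in buffered NEAs, %d in non-stand units",
                len(kept), dropped_outside, dropped_nea, dropped_nonstand)
    return kept


def write_treetops_geojson(tops: list[TreeTop], path) -> None:
    """Write tops as a GeoJSON point layer (id, height, radius, address, epoch)."""
    import json

    features = [{
        "type": "Feature",
        "geometry": {"type": "Point", "coordinates": [top.x, top.y]},
        "properties": {
            "id": top.id, "height": top.height, "radius": top.search_radius,
            "address": top.forest_address, "epoch": top.epoch,
        },
    } for top in tops]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
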