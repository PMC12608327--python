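"""Classified LiDAR point clouds: reading, merging and class filtering.

Clouds are held as column arrays (x, y, z, return_number, number_of_returns,
class_code).  On disk the package uses a plain-text dialect, one point per
line, whitespace-separated::

    x y z return_number number_of_returns class_code

Lines starting with ``#`` are comments.  Record order carries no meaning
anywhere downstream; clouds are treated as unordered multisets of points.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

#: ASPRS class codes accepted in input clouds.
VALID_CLASS_CODES = frozenset({0, 2, 3, 4, 5, 6, 7, 8, 12})

#: Classes rejected by default: unclassified, noise, water, overlap.
DEFAULT_DROP_CODES = frozenset({0, 7, 8, 12})

GROUND_CLASS = 2
NOISE_CLASS = 7


class CloudParseError(ValueError):
    """Raised when a point-cloud file cannot be parsed."""


@dataclass
class PointCloud:
    """Unordered collection of classified LiDAR returns in one projected CRS."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    return_number: np.ndarray
    number_of_returns: np.ndarray
    class_code: np.ndarray
    crs: str = "local"
    epoch: str | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.z = np.asarray(self.z, dtype=np.float64)
        self.return_number = np.asarray(self.return_number, dtype=np.int64)
        self.number_of_returns = np.asarray(self.number_of_returns, dtype=np.int64)
        self.class_code = np.asarray(self.class_code, dtype=np.int64)
        n = len(self.x)
        for name in ("y", "z", "return_number", "number_of_returns", "class_code"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name!r} has length != {n}")
        if n and ((self.return_number < 1).any() or
                  (self.return_number > self.number_of_returns).any()):
            raise ValueError("return_number must satisfy 1 <= rn <= number_of_returns")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax); raises on an empty cloud."""
        if len(self) == 0:
            raise ValueError("empty cloud has no bounds")
        return (float(self.x.min()), float(self.y.min()),
                float(self.x.max()), float(self.y.max()))

    def select(self, mask: np.ndarray) -> "PointCloud":
        return PointCloud(
            self.x[mask], self.y[mask], self.z[mask],
            self.return_number[mask], self.number_of_returns[mask],
            self.class_code[mask], crs=self.crs, epoch=self.epoch,
        )

    @classmethod
    def empty(cls, crs: str = "local", epoch: str | None = None) -> "PointCloud":
        z = np.empty(0)
        zi = np.empty(0, dtype=np.int64)
        return cls(z, z.copy(), z.copy(), zi, zi.copy(), zi.copy(), crs=crs, epoch=epoch)


def read_cloud(path: str | Path, crs: str = "local",
               epoch: str | None = None) -> PointCloud:
    """Read a plain-text point cloud.

    Missing classification column (5-column lines) is tolerated: points get
    class 0 and a warning is emitted.  An empty file yields an empty cloud.
    """
    path = Path(path)
    rows: list[tuple[float, float, float, int, int, int]] = []
    missing_class = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (5, 6):
                raise CloudParseError(
                    f"{path}:{lineno}: expected 5 or 6 columns, got {len(parts)}")
            try:
                x, y, z = float(parts[0]), float(parts[1]), float(parts[2])
                rn, nr = int(parts[3]), int(parts[4])
                cc = int(parts[5]) if len(parts) == 6 else 0
            except ValueError as exc:
                raise CloudParseError(f"{path}:{lineno}: {exc}") from exc
            if len(parts) == 5:
                missing_class += 1
            rows.append((x, y, z, rn, nr, cc))
    if missing_class:
        warnings.warn(
            f"{path}: {missing_class} points lacked a classification; assigned class 0",
            stacklevel=2)
    if not rows:
        return PointCloud.empty(crs=crs, epoch=epoch)
    arr = np.array(rows, dtype=np.float64)
    return PointCloud(arr[:, 0], arr[:, 1], arr[:, 2],
                      arr[:, 3].astype(np.int64), arr[:, 4].astype(np.int64),
                      arr[:, 5].astype(np.int64), crs=crs, epoch=epoch)


def write_cloud(cloud: PointCloud, path: str | Path) -> None:
    """Write a cloud in the plain-text dialect read by :func:`read_cloud`."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# x y z return_number number_of_returns class_code\n")
        for i in range(len(cloud)):
            fh.write(f"{cloud.x[i]:.3f} {cloud.y[i]:.3f} {cloud.z[i]:.3f} "
                     f"{cloud.return_number[i]} {cloud.number_of_returns[i]} "
                     f"{cloud.class_code[i]}\n")


def merge_tiles(clouds: list[PointCloud]) -> PointCloud:
    """Concatenate tiles into one cloud.  All tiles must share a CRS.

    Duplicate points from tile-overlap areas are retained; overlap handling
    is a class-filter concern (class 12), not a merge concern.
    """
    if not clouds:
        return PointCloud.empty()
    crs_set = {c.crs for c in clouds}
    if len(crs_set) > 1:
        raise ValueError(f"cannot merge tiles with mixed CRS: {sorted(crs_set)}")
    epochs = {c.epoch for c in clouds}
    epoch = epochs.pop() if len(epochs) == 1 else None
    return PointCloud(
        np.concatenate([c.x for c in clouds]),
        np.concatenate([c.y for c in clouds]),
        np.concatenate([c.z for c in clouds]),
        np.concatenate([c.return_number for c in clouds]),
        np.concatenate([c.number_of_returns for c in clouds]),
        np.concatenate([c.class_code for c in clouds]),
        crs=clouds[0].crs, epoch=epoch,
    )


def filter_classes(cloud: PointCloud,
                   drop_codes: frozenset[int] | set[int] = DEFAULT_DROP_CODES
                   ) -> PointCloud:
    """Remove points whose class code is in ``drop_codes``.

    The default drop set rejects unclassified points (0), noise (7),
    water (8) and overlap-area points (12).  Idempotent; an empty result is
    allowed (a warning is emitted when everything is dropped).
    """
    keep = ~np.isin(cloud.class_code, list(drop_codes))
    out = cloud.select(keep)
    if len(cloud) and len(out) == 0:
        warnings.warn("class filter removed every point", stacklevel=2)
    return out
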