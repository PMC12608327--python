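"""Per-unit stand heights, difference classes, increments and error flags.

Stand height mimics what a surveyor records: individual top heights are
rounded to whole meters first, a histogram of rounded heights is built, and
the stand height is the occurrence-weighted mean of the distinct rounded
heights — which is algebraically the plain mean of the rounded heights.
The weighted form is kept because the histogram is also the unit's height
profile output.

Heights difference classes: (LiDAR - inventory) in whole meters, with
classes -8..-6 pooled into one label and -5..6 kept as unit-width classes.
Differences of +8 m and above are gross errors and are excluded from the
agreement statistics.
"""

from __future__ import annotations

import enum
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

POOLED_CLASS_LABEL = "-8..-6"
GROSS_ERROR_MIN_DIFF = 8
YOUNG_STAND_MAX_AGE = 15


class ErrorFlag(enum.Enum):
    OK = "ok"
    GROSS_POSITIVE = "gross_positive"
    SUSPECT_NEA = "suspect_nea"
    SUSPECT_CONTOUR = "suspect_contour"
    RESIDUAL_TREES = "residual_trees"
    MULTI_TIER = "multi_tier"


@dataclass
class StandHeightRecord:
    forest_address: str
    epoch: str | None
    mean_height: float          # weighted mean of rounded heights, unrounded
    reported_height: int        # mean rounded to whole meters
    n_tops: int
    height_histogram: dict[int, int]


@dataclass
class IncrementPair:
    forest_address: str
    lidar_increment: int
    inventory_increment: int
    diff_a: int | None = None   # LiDAR - inventory, historic epoch
    diff_b: int | None = None   # LiDAR - inventory, current epoch
    error_flag: ErrorFlag = ErrorFlag.OK


def round_half_up(value: float) -> int:
    """Round to the nearest integer, ties away from zero upward (2.5 -> 3)."""
    return int(math.floor(value + 0.5))


def round_heights(value: float, mode: str = "half_up") -> int:
    """Round a height to whole meters.  Modes: ``half_up`` (default) or
    ``ceil`` for a strict reading of rounding heights upward."""
    if mode == "half_up":
        return round_half_up(value)
    if mode == "ceil":
        return int(math.ceil(value))
    raise ValueError(f"unknown rounding mode {mode!r}")


def stand_height(heights, forest_address: str = "", epoch: str | None = None,
                 rounding: str = "half_up") -> StandHeightRecord:
    """Occurrence-weighted stand height from individual top heights.

    ``h_bar = sum(w_i * h_i) / sum(w_i)`` over distinct rounded heights
    ``h_i`` with occurrence counts ``w_i``.
    """
    heights = list(heights)
    if not heights:
        raise ValueError(f"unit {forest_address!r} has no tree tops")
    rounded = [round_heights(h, rounding) for h in heights]
    hist = Counter(rounded)
    total_w = sum(hist.values())
    h_bar = sum(w * h for h, w in hist.items()) / total_w
    return StandHeightRecord(
        forest_address=forest_address, epoch=epoch,
        mean_height=h_bar, reported_height=round_half_up(h_bar),
        n_tops=len(heights), height_histogram=dict(sorted(hist.items())),
    )


def height_difference(lidar_height: float, inventory_height: float
                      ) -> tuple[int, str | None]:
    """(LiDAR - inventory) in whole meters and its class label.

    Class labels: ``"-8..-6"`` pooled, ``"-5"`` ... ``"6"`` unit classes.
    Differences outside [-8, 6] get no class (``None``) — positive ones are
    gross-error territory.
    """
    diff = round_half_up(lidar_height) - round_half_up(inventory_height)
    if -8 <= diff <= -6:
        return diff, POOLED_CLASS_LABEL
    if -5 <= diff <= 6:
        return diff, str(diff)
    return diff, None


def flag_gross_errors(diff: int, n_tops: int | None = None,
                      age: float | None = None,
                      age_threshold: float = YOUNG_STAND_MAX_AGE) -> ErrorFlag:
    """Flag units whose LiDAR-inventory difference cannot be real growth.

    A positive difference of 8 m or more is a gross error outright.  A young
    stand (age <= ``age_threshold``) with detected heights at or above the
    7 m mask floor is also impossible and flagged; with a suspiciously low
    crown count this points at residual trees from an older stand, otherwise
    at a misplaced NEA.  Flagged units are excluded from agreement statistics.
    """
    if diff >= GROSS_ERROR_MIN_DIFF:
        return ErrorFlag.GROSS_POSITIVE
    if age is not None and age <= age_threshold:
        if n_tops is not None and n_tops < 60:
            return ErrorFlag.RESIDUAL_TREES
        return ErrorFlag.SUSPECT_NEA
    return ErrorFlag.OK


def increments(forest_address: str,
               lidar_a: StandHeightRecord, lidar_b: StandHeightRecord,
               inventory_a: float, inventory_b: float) -> IncrementPair:
    """Whole-meter height increments from both sources for one matched unit.

    LiDAR increment uses the reported (rounded) stand heights so that both
    sources live on the same whole-meter scale.  Negative increments are
    legitimate (dieback, storm damage, inventory corrections).
    """
    inv_a = round_half_up(inventory_a)
    inv_b = round_half_up(inventory_b)
    diff_a, _ = height_difference(lidar_a.reported_height, inv_a)
    diff_b, _ = height_difference(lidar_b.reported_height, inv_b)
    return IncrementPair(
        forest_address=forest_address,
        lidar_increment=lidar_b.reported_height - lidar_a.reported_height,
        inventory_increment=inv_b - inv_a,
        diff_a=diff_a, diff_b=diff_b,
    )


def class_labels() -> list[str]:
    """All difference-class labels in order, pooled class first."""
    return [POOLED_CLASS_LABEL] + [str(c) for c in range(-5, 7)]


def heights_by_unit(tops) -> dict[str, list[float]]:
    """Group tree-top heights by forest address (unassigned tops skipped)."""
    out: dict[str, list[float]] = {}
    for top in tops:
        if top.forest_address is None:
            continue
        out.setdefault(top.forest_address, []).append(top.height)
    return out


def stand_heights_for_units(tops, epoch: str | None = None,
                            rounding: str = "half_up"
                            ) -> dict[str, StandHeightRecord]:
    """Stand-height records for every unit that received at least one top."""
    return {
        addr: stand_height(heights, forest_address=addr, epoch=epoch,
                           rounding=rounding)
        for addr, heights in sorted(heights_by_unit(tops).items())
    }
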