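"""Forest-unit vector preparation and cross-epoch matching.

Two epochs of inventory vectors arrive with different schemas (current data
carry heights inline, historic data need a height-table join) and drifted
unit addresses.  This module harmonizes both into one schema and matches
units across epochs spatially: polygon intersection fragments are kept only
when they contain the pole of inaccessibility of the current-epoch unit,
which discards sliver fragments without an arbitrary area cutoff.

All vector IO is GeoJSON; coordinates must be in a projected CRS (meters).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import pandas as pd
from shapely.geometry import MultiPolygon, Point, Polygon, mapping, shape
from shapely.ops import polylabel
from shapely.validation import make_valid

logger = logging.getLogger(__name__)

SITE_TYPES = ("FPF", "FMCF", "FMHF", "TASF", "AAF", "MMF", "BMF", "MMCF")

#: Trees/stands at or below this inventory height carry no merchantable
#: volume in the growth tables and are excluded from the analysis set.
MIN_ANALYSIS_HEIGHT = 6.0


@dataclass
class ForestUnit:
    """Addressed forest polygon with the inventory attributes used downstream."""

    forest_address: str
    geometry: Polygon | MultiPolygon
    epoch: str
    dominant_species: str | None = None
    age: float | None = None
    inventory_height: float | None = None
    site_type: str | None = None
    area_ha: float | None = None
    land_kind: str = "stand"

    def __post_init__(self) -> None:
        if self.area_ha is None and self.geometry is not None:
            self.area_ha = self.geometry.area / 10_000.0


@dataclass
class MatchedUnit:
    """A cross-epoch unit pair with its principal overlap fragment."""

    unit_a: ForestUnit
    unit_b: ForestUnit
    overlap: Polygon | MultiPolygon
    overlap_area_ha: float


# ---------------------------------------------------------------------------
# harmonization

def harmonize_layers(units: list[ForestUnit], height_table: pd.DataFrame,
                     min_height: float = MIN_ANALYSIS_HEIGHT
                     ) -> tuple[list[ForestUnit], pd.DataFrame]:
    """Attach dominant-species top-layer heights to units; filter the rest.

    ``height_table`` needs columns ``forest_address``, ``species``,
    ``height`` and optionally ``layer`` (rows with layer != 1 are dropped:
    only the tallest stand layer is analysed).  Non-dominant species rows
    are discarded.  Units without a qualifying height row, and units whose
    height is <= ``min_height``, go to the rejects report instead of being
    silently dropped.

    Returns (harmonized units, rejects DataFrame with columns
    forest_address, reason).
    """
    table = height_table.copy()
    if "layer" in table.columns:
        table = table[table["layer"].astype(int) == 1]
    kept: list[ForestUnit] = []
    rejects: list[dict] = []
    for unit in units:
        if unit.land_kind != "stand":
            rejects.append({"forest_address": unit.forest_address,
                            "reason": "non_stand"})
            continue
        rows = table[table["forest_address"] == unit.forest_address]
        if unit.dominant_species is not None:
            rows = rows[rows["species"] == unit.dominant_species]
        if rows.empty:
            rejects.append({"forest_address": unit.forest_address,
                            "reason": "no_height_row"})
            continue
        height = float(rows.iloc[0]["height"])
        species = str(rows.iloc[0]["species"])
        if height <= min_height:
            rejects.append({"forest_address": unit.forest_address,
                            "reason": f"height_le_{min_height:g}"})
            continue
        kept.append(replace(unit, inventory_height=height,
                            dominant_species=species))
    return kept, pd.DataFrame(rejects, columns=["forest_address", "reason"])


def buffer_neas(geometries, width: float = 2.0) -> list:
    """Dilate NEA polygons by ``width`` meters with round joins.

    Invalid polygons are repaired (``make_valid``) with a warning before
    buffering.  Width 0 is the identity (modulo repair).
    """
    if width < 0:
        raise ValueError("buffer width must be non-negative")
    out = []
    for geom in geometries:
        if not geom.is_valid:
            warnings.warn("repairing invalid NEA polygon", stacklevel=2)
            geom = make_valid(geom)
        out.append(geom.buffer(width, join_style="round") if width > 0 else geom)
    return out


# ---------------------------------------------------------------------------
# cross-epoch matching

def pole_of_inaccessibility(geom, tolerance: float = 0.1) -> Point:
    """Interior point farthest from the boundary (iterative grid refinement).

    For multi-part geometries the largest part is used.
    """
    if isinstance(geom, MultiPolygon):
        geom = max(geom.geoms, key=lambda g: g.area)
    return polylabel(geom, tolerance)


def match_units(layer_a: list[ForestUnit], layer_b: list[ForestUnit],
                pole_tolerance: float = 0.1) -> list[MatchedUnit]:
    """Match epoch-b (current) units to epoch-a (historic) units spatially.

    Every pairwise intersection fragment is a candidate; a fragment survives
    only when it contains the pole of inaccessibility of the epoch-b unit.
    Addresses are never compared — unit addresses drift between management
    plan revisions.  Deterministic: units are processed in address order.
    """
    matches: list[MatchedUnit] = []
    unmatched = 0
    for unit_b in sorted(layer_b, key=lambda u: u.forest_address):
        pole = pole_of_inaccessibility(unit_b.geometry, pole_tolerance)
        found = None
        for unit_a in sorted(layer_a, key=lambda u: u.forest_address):
            overlap = unit_b.geometry.intersection(unit_a.geometry)
            if overlap.is_empty or overlap.area <= 0:
                continue
            overlap = make_valid(overlap)
            if overlap.geom_type not in ("Polygon", "MultiPolygon"):
                continue
            if overlap.contains(pole) or overlap.touches(pole):
                found = MatchedUnit(unit_a=unit_a, unit_b=unit_b,
                                    overlap=overlap,
                                    overlap_area_ha=overlap.area / 10_000.0)
                break
        if found is None:
            unmatched += 1
            logger.info("unit %s: no overlap fragment contains its pole",
                        unit_b.forest_address)
        else:
            matches.append(found)
    if unmatched:
        logger.info("match_units: %d units left unmatched", unmatched)
    return matches


def filter_matched(matches: list[MatchedUnit]
                   ) -> tuple[list[MatchedUnit], pd.DataFrame]:
    """Drop cross-epoch pairs that cannot represent growth.

    Removed: pairs with a negative age difference (stand was cut and
    replanted between epochs), pairs treeless in the historic epoch (no
    inventory height), and pairs with missing age attributes.
    """
    kept: list[MatchedUnit] = []
    rejects: list[dict] = []
    for m in matches:
        addr = m.unit_b.forest_address
        if m.unit_a.age is None or m.unit_b.age is None:
            rejects.append({"forest_address": addr, "reason": "missing_age"})
        elif m.unit_b.age - m.unit_a.age < 0:
            rejects.append({"forest_address": addr, "reason": "negative_age_diff"})
        elif m.unit_a.inventory_height is None:
            rejects.append({"forest_address": addr, "reason": "treeless_historic"})
        else:
            kept.append(m)
    return kept, pd.DataFrame(rejects, columns=["forest_address", "reason"])


# ---------------------------------------------------------------------------
# GeoJSON IO

_GEOGRAPHIC_HINTS = ("4326", "CRS84", "WGS84", "WGS 84")


def _check_projected(crs: str | None) -> None:
    if crs and any(hint in str(crs) for hint in _GEOGRAPHIC_HINTS):
        raise ValueError(
            f"geographic CRS {crs!r} refused: a projected CRS in meters is required")


def read_units_geojson(path: str | Path, epoch: str) -> list[ForestUnit]:
    with Path(path).open() as fh:
        data = json.load(fh)
    _check_projected(data.get("crs", {}).get("properties", {}).get("name")
                     if isinstance(data.get("crs"), dict) else data.get("crs"))
    units = []
    for feat in data.get("features", []):
        props = feat.get("properties", {})
        units.append(ForestUnit(
            forest_address=str(props["forest_address"]),
            geometry=shape(feat["geometry"]),
            epoch=epoch,
            dominant_species=props.get("dominant_species"),
            age=props.get("age"),
            inventory_height=props.get("inventory_height"),
            site_type=props.get("site_type"),
            area_ha=props.get("area_ha"),
            land_kind=props.get("land_kind", "stand"),
        ))
    return units


def write_units_geojson(units: list[ForestUnit], path: str | Path) -> None:
    features = [{
        "type": "Feature",
        "geometry": mapping(u.geometry),
        "properties": {
            "forest_address": u.forest_address,
            "epoch": u.epoch,
            "dominant_species": u.dominant_species,
            "age": u.age,
            "inventory_height": u.inventory_height,
            "site_type": u.site_type,
            "area_ha": u.area_ha,
            "land_kind": u.land_kind,
        },
    } for u in units]
    with Path(path).open("w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geometries_geojson(path: str | Path) -> list:
    """Read a bare geometry layer (e.g. NEAs) from GeoJSON."""
    with Path(path).open() as fh:
        data = json.load(fh)
    return [shape(feat["geometry"]) for feat in data.get("features", [])]


def write_geometries_geojson(geometries, path: str | Path) -> None:
    features = [{"type": "Feature", "geometry": mapping(g), "properties": {}}
                for g in geometries]
    with Path(path).open("w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)
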