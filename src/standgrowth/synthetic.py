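"""Synthetic two-epoch forest scenes: terrain, trees, point clouds, inventory.

Everything downstream of the LAS reader can be exercised without external
data: the generator emulates pine-dominated stands with minority deciduous
species, per-unit stem densities, simple crown solids (cones for conifers,
paraboloids for deciduous trees), between-epoch growth, ALS sampling on a
jittered pulse grid, and a field inventory that measures ~10 representative
trees per unit and rounds to whole meters.

All randomness flows from a single ``numpy`` Generator seeded by the scene
config, so a fixed seed reproduces clouds, vectors and tables byte for byte.
Per-unit true mean apex heights are recorded alongside the outputs as ground
truth for parameter-recovery tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import Point, Polygon, box

from standgrowth.geoprep import ForestUnit
from standgrowth.pointcloud import PointCloud

CONIFERS = frozenset({"pine", "spruce", "larch"})
DECIDUOUS = frozenset({"alder", "birch"})

#: Default species mix mirroring a pine-dominated range with minority
#: alder/birch (shares by dominant-species area).
DEFAULT_SPECIES_MIX = {"pine": 0.967, "alder": 0.017, "birch": 0.007,
                       "spruce": 0.005, "larch": 0.004}

#: Height above ground where the live crown starts, as a fraction of apex height.
CROWN_BASE_FRACTION = 0.4


@dataclass
class SyntheticTree:
    id: int
    x: float
    y: float
    apex_height: float
    crown_radius: float
    species: str
    unit_id: str


@dataclass
class SceneConfig:
    """Knobs for one synthetic study area."""

    extent: tuple[float, float, float, float] = (0.0, 0.0, 100.0, 100.0)
    pulse_density: float = 4.0
    vertical_noise_sd: float = 0.2
    seed: int = 0
    stem_density: float = 400.0          # trees / ha
    relief_amplitude: float = 3.0        # m, bound on |terrain - mean|
    relief_scale: float = 60.0           # m, correlation length
    species_mix: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_MIX))
    noise_fraction: float = 0.0          # share of extra class-7 points
    leafoff_bias: float = 0.0            # m subtracted from deciduous first returns

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.extent
        if x1 <= x0 or y1 <= y0:
            raise ValueError("extent must have positive width and height")
        if self.pulse_density <= 0:
            raise ValueError("pulse_density must be positive")
        if not (0.0 <= self.vertical_noise_sd <= 0.5):
            raise ValueError("vertical_noise_sd must lie in [0, 0.5]")
        if self.stem_density < 0:
            raise ValueError("stem_density must be non-negative")
        total = sum(self.species_mix.values())
        if total <= 0:
            raise ValueError("species_mix must have positive total weight")
        self.species_mix = {k: v / total for k, v in self.species_mix.items()}

    @property
    def area_m2(self) -> float:
        x0, y0, x1, y1 = self.extent
        return (x1 - x0) * (y1 - y0)


# ---------------------------------------------------------------------------
# terrain

def generate_terrain(config: SceneConfig, n_waves: int = 8):
    """Smooth deterministic elevation field as a callable z(x, y).

    A sum of random cosine waves with wavelengths around ``relief_scale``,
    centered and rescaled on a probe grid so that the deviation from the
    field mean stays within ``relief_amplitude`` (up to interpolation of the
    probe grid).  Zero amplitude gives a flat plane at elevation 0.
    """
    amp = config.relief_amplitude
    if amp == 0:
        return lambda x, y: np.zeros_like(np.asarray(x, dtype=np.float64))
    rng = np.random.default_rng(config.seed ^ 0x7E44A1)
    coeff = rng.uniform(0.3, 1.0, n_waves)
    wavelen = config.relief_scale * rng.uniform(0.5, 2.0, n_waves)
    theta = rng.uniform(0, 2 * math.pi, n_waves)
    phase = rng.uniform(0, 2 * math.pi, n_waves)
    ux, uy = np.cos(theta), np.sin(theta)

    def raw(x, y):
        x = np.asarray(x, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64)
        z = np.zeros(np.broadcast(x, y).shape)
        for a, lam, cx, cy, ph in zip(coeff, wavelen, ux, uy, phase):
            z = z + a * np.cos(2 * math.pi * (x * cx + y * cy) / lam + ph)
        return z

    x0, y0, x1, y1 = config.extent
    px, py = np.meshgrid(np.linspace(x0, x1, 201), np.linspace(y0, y1, 201))
    probe = raw(px, py)
    center = probe.mean()
    scale = np.abs(probe - center).max()
    if scale == 0:
        return lambda x, y: np.zeros_like(np.asarray(x, dtype=np.float64))

    def terrain(x, y):
        return amp * (raw(x, y) - center) / scale

    return terrain


# ---------------------------------------------------------------------------
# trees

def _crown_radius(height: float, rng: np.random.Generator) -> float:
    # crown size grows roughly linearly with height
    return max(0.5, 0.16 * height + 0.8 + rng.normal(0.0, 0.2))


def generate_stand(polygon: Polygon, unit_id: str, config: SceneConfig,
                   rng: np.random.Generator,
                   mean_height: float = 18.0, height_sd: float = 1.5,
                   stem_density: float | None = None,
                   species_mix: dict[str, float] | None = None,
                   id_offset: int = 0) -> list[SyntheticTree]:
    """Poisson-populated stand inside one unit polygon.

    Tree count ~ Poisson(stem_density * area_ha); positions uniform in the
    polygon (rejection sampling); heights ~ N(mean_height, height_sd^2)
    truncated above 1 m.  A degenerate polygon yields an empty list with a
    warning.
    """
    density = config.stem_density if stem_density is None else stem_density
    mix = config.species_mix if species_mix is None else species_mix
    area_ha = polygon.area / 10_000.0
    if area_ha <= 0:
        warnings.warn(f"unit {unit_id}: degenerate polygon, no trees generated",
                      stacklevel=2)
        return []
    n = int(rng.poisson(density * area_ha))
    if n == 0:
        return []
    names = sorted(mix)
    probs = np.array([mix[s] for s in names])
    species = rng.choice(names, size=n, p=probs / probs.sum())
    heights = np.maximum(rng.normal(mean_height, height_sd, n), 1.0)
    minx, miny, maxx, maxy = polygon.bounds
    trees: list[SyntheticTree] = []
    placed = 0
    while placed < n:
        m = (n - placed) * 2 + 8
        xs = rng.uniform(minx, maxx, m)
        ys = rng.uniform(miny, maxy, m)
        for x, y in zip(xs, ys):
            if placed >= n:
                break
            if polygon.contains(Point(x, y)):
                h = float(heights[placed])
                trees.append(SyntheticTree(
                    id=id_offset + placed, x=float(x), y=float(y),
                    apex_height=h, crown_radius=_crown_radius(h, rng),
                    species=str(species[placed]), unit_id=unit_id))
                placed += 1
    return trees


def grow_stand(trees: list[SyntheticTree], years: float,
               rates: dict[str, float], jitter_sd: float = 0.0,
               rng: np.random.Generator | None = None) -> list[SyntheticTree]:
    """Advance apex heights by ``years * rates[species]`` (+ optional jitter).

    Positions and crown assignments are kept; heights are clamped at 0
    (dieback scenarios with negative rates never go below ground).
    """
    if years < 0:
        raise ValueError("years must be non-negative")
    if jitter_sd > 0 and rng is None:
        raise ValueError("jitter requires an rng")
    out = []
    for tree in trees:
        dh = years * rates.get(tree.species, 0.0)
        if jitter_sd > 0:
            dh += rng.normal(0.0, jitter_sd)
        out.append(replace(tree, apex_height=max(tree.apex_height + dh, 0.0)))
    return out


# ---------------------------------------------------------------------------
# ALS sampling

def _crown_surface_height(tree: SyntheticTree, dist: np.ndarray) -> np.ndarray:
    """Crown surface height above ground at horizontal distance from the stem.

    Cone for conifers (linear taper from apex to crown base), paraboloid for
    deciduous species (quadratic taper); NaN outside the crown radius.
    """
    h = tree.apex_height
    base = CROWN_BASE_FRACTION * h
    frac = dist / tree.crown_radius
    power = 1.0 if tree.species in CONIFERS else 2.0
    surf = h - (h - base) * frac ** power
    return np.where(frac <= 1.0, surf, np.nan)


def simulate_point_cloud(trees: list[SyntheticTree], terrain, config: SceneConfig,
                         rng: np.random.Generator,
                         epoch: str | None = None) -> PointCloud:
    """ALS sampling of the scene on a jittered square pulse grid.

    Each pulse hitting a crown emits a first return near the crown surface
    (class 3/4/5 by height above ground: <=0.4 m, 0.4-2 m, >2 m) and a last
    return on the ground (class 2); open-ground pulses emit a single class-2
    return.  Gaussian vertical noise with sd ``vertical_noise_sd`` applies to
    every return; a ``noise_fraction`` share of additional class-7 points is
    scattered through the air column.
    """
    x0, y0, x1, y1 = config.extent
    spacing = 1.0 / math.sqrt(config.pulse_density)
    nx = max(int(round((x1 - x0) / spacing)), 1)
    ny = max(int(round((y1 - y0) / spacing)), 1)
    gx, gy = np.meshgrid(x0 + (np.arange(nx) + 0.5) * (x1 - x0) / nx,
                         y0 + (np.arange(ny) + 0.5) * (y1 - y0) / ny)
    px = (gx + rng.uniform(-spacing / 2, spacing / 2, gx.shape)).ravel()
    py = (gy + rng.uniform(-spacing / 2, spacing / 2, gy.shape)).ravel()
    n_pulses = px.size
    ground = np.asarray(terrain(px, py), dtype=np.float64)

    canopy = np.full(n_pulses, np.nan)
    is_deciduous = np.zeros(n_pulses, dtype=bool)
    if trees:
        tree_xy = np.array([(t.x, t.y) for t in trees])
        kd = cKDTree(np.column_stack([px, py]))
        for idx, tree in enumerate(trees):
            hits = kd.query_ball_point(tree_xy[idx], tree.crown_radius)
            if not hits:
                continue
            hits = np.asarray(hits)
            dist = np.hypot(px[hits] - tree.x, py[hits] - tree.y)
            surf = _crown_surface_height(tree, dist)
            better = ~np.isnan(surf) & (np.isnan(canopy[hits]) | (surf > canopy[hits]))
            sel = hits[better]
            canopy[sel] = surf[better]
            is_deciduous[sel] = tree.species in DECIDUOUS

    sd = config.vertical_noise_sd
    noise = (rng.normal(0.0, sd, n_pulses) if sd > 0 else np.zeros(n_pulses))
    noise2 = (rng.normal(0.0, sd, n_pulses) if sd > 0 else np.zeros(n_pulses))

    hit = ~np.isnan(canopy) & (canopy > 0)
    first_h = np.where(hit, canopy, 0.0)
    if config.leafoff_bias:
        first_h = np.where(hit & is_deciduous,
                           np.maximum(first_h - config.leafoff_bias, 0.0), first_h)

    xs, ys, zs, rn, nr, cc = [], [], [], [], [], []
    # canopy pulses: first return on the crown, last return on the ground
    xs.append(px[hit]); ys.append(py[hit])
    zs.append(ground[hit] + first_h[hit] + noise[hit])
    rn.append(np.ones(hit.sum(), dtype=np.int64))
    nr.append(np.full(hit.sum(), 2, dtype=np.int64))
    band = np.where(first_h[hit] <= 0.4, 3,
                    np.where(first_h[hit] <= 2.0, 4, 5))
    cc.append(band.astype(np.int64))

    xs.append(px[hit]); ys.append(py[hit])
    zs.append(ground[hit] + noise2[hit])
    rn.append(np.full(hit.sum(), 2, dtype=np.int64))
    nr.append(np.full(hit.sum(), 2, dtype=np.int64))
    cc.append(np.full(hit.sum(), 2, dtype=np.int64))

    # open-ground pulses: single ground return
    open_ = ~hit
    xs.append(px[open_]); ys.append(py[open_])
    zs.append(ground[open_] + noise[open_])
    rn.append(np.ones(open_.sum(), dtype=np.int64))
    nr.append(np.ones(open_.sum(), dtype=np.int64))
    cc.append(np.full(open_.sum(), 2, dtype=np.int64))

    n_noise = int(config.noise_fraction * n_pulses)
    if n_noise:
        xs.append(rng.uniform(x0, x1, n_noise))
        ys.append(rng.uniform(y0, y1, n_noise))
        zs.append(rng.uniform(-5.0, 60.0, n_noise))
        rn.append(np.ones(n_noise, dtype=np.int64))
        nr.append(np.ones(n_noise, dtype=np.int64))
        cc.append(np.full(n_noise, 7, dtype=np.int64))

    return PointCloud(np.concatenate(xs), np.concatenate(ys), np.concatenate(zs),
                      np.concatenate(rn), np.concatenate(nr), np.concatenate(cc),
                      crs="local", epoch=epoch)


# ---------------------------------------------------------------------------
# inventory

def generate_inventory(trees: list[SyntheticTree], unit_ids,
                       n_sample: int = 10, height_noise_sd: float = 0.3,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Field inventory table: per unit, the mean height of ~``n_sample``
    measured trees of the dominant species, rounded to whole meters.

    Units without trees get a missing height (not 0).  Columns:
    forest_address, species, height, height_raw, n_trees.
    """
    if n_sample < 1:
        raise ValueError("n_sample must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    by_unit: dict[str, list[SyntheticTree]] = {str(u): [] for u in unit_ids}
    for tree in trees:
        by_unit.setdefault(tree.unit_id, []).append(tree)
    rows = []
    for unit_id in sorted(by_unit):
        members = by_unit[unit_id]
        if not members:
            rows.append({"forest_address": unit_id, "species": None,
                         "height": np.nan, "height_raw": np.nan, "n_trees": 0})
            continue
        counts: dict[str, int] = {}
        for t in members:
            counts[t.species] = counts.get(t.species, 0) + 1
        dominant = max(sorted(counts), key=counts.get)
        pool = [t.apex_height for t in members if t.species == dominant]
        k = min(n_sample, len(pool))
        sample = rng.choice(np.asarray(pool), size=k, replace=False)
        measured = sample + (rng.normal(0.0, height_noise_sd, k)
                             if height_noise_sd > 0 else 0.0)
        raw = float(measured.mean())
        rows.append({"forest_address": unit_id, "species": dominant,
                     "height": float(math.floor(raw + 0.5)),
                     "height_raw": raw, "n_trees": len(members)})
    return pd.DataFrame(rows)


def true_stand_heights(trees: list[SyntheticTree]) -> pd.DataFrame:
    """Ground-truth per-unit mean apex heights (sidecar for recovery tests)."""
    by_unit: dict[str, list[float]] = {}
    for tree in trees:
        by_unit.setdefault(tree.unit_id, []).append(tree.apex_height)
    rows = [{"forest_address": u, "true_mean_height": float(np.mean(hs)),
             "n_trees": len(hs)} for u, hs in sorted(by_unit.items())]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# whole scenes

@dataclass
class SyntheticScene:
    """Everything the pipeline needs for two epochs, plus ground truth."""

    config: SceneConfig
    terrain: object
    units_a: list[ForestUnit]
    units_b: list[ForestUnit]
    neas: list
    trees_a: list[SyntheticTree]
    trees_b: list[SyntheticTree]
    cloud_a: PointCloud
    cloud_b: PointCloud
    inventory_a: pd.DataFrame
    inventory_b: pd.DataFrame
    truth: pd.DataFrame          # per-unit true means and growth


def build_scene(config: SceneConfig, units_nx: int = 2, units_ny: int = 2,
                margin: float = 10.0, years: float = 9.0,
                mean_height_range: tuple[float, float] = (14.0, 24.0),
                growth_range: tuple[float, float] = (0.05, 0.45),
                growth_rates: list[float] | None = None,
                inventory_noise_sd: float = 0.3, n_sample: int = 10,
                height_sd: float = 1.5) -> SyntheticScene:
    """Generate a full two-epoch study area on a grid of rectangular units.

    Each unit draws its own mean height and annual growth rate (uniform in
    ``growth_range`` over ``years`` years this spans roughly 0-4 m of true
    growth, with negative rates possible if the range allows).  All trees in
    a unit grow at the unit rate, so the unit's true increment is exactly
    ``years * rate``.
    """
    rng = np.random.default_rng(config.seed)
    x0, y0, x1, y1 = config.extent
    ux = (x1 - x0 - 2 * margin) / units_nx
    uy = (y1 - y0 - 2 * margin) / units_ny
    if ux <= 0 or uy <= 0:
        raise ValueError("extent too small for the requested unit grid and margin")

    terrain = generate_terrain(config)
    units_a: list[ForestUnit] = []
    trees_a: list[SyntheticTree] = []
    unit_meta: list[tuple[str, float, float]] = []  # (address, mean_h, rate)
    idx = 0
    for iy in range(units_ny):
        for ix in range(units_nx):
            address = f"U{iy:02d}{ix:02d}"
            poly = box(x0 + margin + ix * ux, y0 + margin + iy * uy,
                       x0 + margin + (ix + 1) * ux, y0 + margin + (iy + 1) * uy)
            mean_h = rng.uniform(*mean_height_range)
            rate = (growth_rates[iy * units_nx + ix] if growth_rates is not None
                    else rng.uniform(*growth_range))
            stand = generate_stand(poly, address, config, rng,
                                   mean_height=mean_h, height_sd=height_sd,
                                   id_offset=len(trees_a))
            trees_a.extend(stand)
            age = float(rng.integers(30, 80))
            units_a.append(ForestUnit(forest_address=address, geometry=poly,
                                      epoch="a", age=age))
            unit_meta.append((address, mean_h, rate))
            idx += 1

    rates_by_unit = {addr: rate for addr, _, rate in unit_meta}
    trees_b = []
    for tree in trees_a:
        rate = rates_by_unit[tree.unit_id]
        trees_b.append(replace(tree,
                               apex_height=max(tree.apex_height + years * rate, 0.0)))

    cloud_a = simulate_point_cloud(trees_a, terrain, config, rng, epoch="a")
    cloud_b = simulate_point_cloud(trees_b, terrain, config, rng, epoch="b")

    unit_ids = [u.forest_address for u in units_a]
    inventory_a = generate_inventory(trees_a, unit_ids, n_sample=n_sample,
                                     height_noise_sd=inventory_noise_sd, rng=rng)
    inventory_b = generate_inventory(trees_b, unit_ids, n_sample=n_sample,
                                     height_noise_sd=inventory_noise_sd, rng=rng)

    units_b = [ForestUnit(forest_address=u.forest_address, geometry=u.geometry,
                          epoch="b", age=(u.age or 0) + years)
               for u in units_a]
    # attach inventory heights and species to the unit layers
    for units, inv in ((units_a, inventory_a), (units_b, inventory_b)):
        lookup = inv.set_index("forest_address")
        for u in units:
            row = lookup.loc[u.forest_address]
            u.inventory_height = (None if pd.isna(row["height"])
                                  else float(row["height"]))
            u.dominant_species = row["species"]
            u.site_type = "FPF" if u.dominant_species == "pine" else "TASF"

    ta = true_stand_heights(trees_a).set_index("forest_address")
    tb = true_stand_heights(trees_b).set_index("forest_address")
    truth = pd.DataFrame({
        "forest_address": unit_ids,
        "true_mean_a": [ta["true_mean_height"].get(u, np.nan) for u in unit_ids],
        "true_mean_b": [tb["true_mean_height"].get(u, np.nan) for u in unit_ids],
        "growth_rate": [rates_by_unit[u] for u in unit_ids],
        "true_growth": [rates_by_unit[u] * years for u in unit_ids],
    })
    return SyntheticScene(config=config, terrain=terrain, units_a=units_a,
                          units_b=units_b, neas=[], trees_a=trees_a,
                          trees_b=trees_b, cloud_a=cloud_a, cloud_b=cloud_b,
                          inventory_a=inventory_a, inventory_b=inventory_b,
                          truth=truth)


def write_scene(scene: SyntheticScene, outdir: str | Path) -> dict[str, Path]:
    """Serialize a scene to plain-text files; returns the path map."""
    from standgrowth.geoprep import write_geometries_geojson, write_units_geojson
    from standgrowth.pointcloud import write_cloud

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cloud_a": outdir / "cloud_a.xyz", "cloud_b": outdir / "cloud_b.xyz",
        "units_a": outdir / "units_a.geojson", "units_b": outdir / "units_b.geojson",
        "neas_a": outdir / "neas_a.geojson", "neas_b": outdir / "neas_b.geojson",
        "inventory_a": outdir / "inventory_a.csv",
        "inventory_b": outdir / "inventory_b.csv",
        "truth": outdir / "truth.csv",
    }
    write_cloud(scene.cloud_a, paths["cloud_a"])
    write_cloud(scene.cloud_b, paths["cloud_b"])
    write_units_geojson(scene.units_a, paths["units_a"])
    write_units_geojson(scene.units_b, paths["units_b"])
    write_geometries_geojson(scene.neas, paths["neas_a"])
    write_geometries_geojson(scene.neas, paths["neas_b"])
    scene.inventory_a.to_csv(paths["inventory_a"], index=False)
    scene.inventory_b.to_csv(paths["inventory_b"], index=False)
    scene.truth.to_csv(paths["truth"], index=False)
    return paths
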