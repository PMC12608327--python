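"""End-to-end orchestration: two epochs of clouds and vectors in, agreement out.

Every stage is a pure function of its inputs plus the run config; the run
report keeps per-stage unit/point counts so that every filtering step is
auditable.  Intermediates (grids, top layers, per-unit tables) are written
as plain-text files under the output directory.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from standgrowth import agreement as agr
from standgrowth import geoprep, standmetrics, surfaces, treetops
from standgrowth.pointcloud import (DEFAULT_DROP_CODES, filter_classes,
                                    merge_tiles, read_cloud)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of a pipeline run; defaults match the reference workflow
    (0.5 m grids, 7 m mask, 0.16x+0.8 search window, 2 m NEA buffer,
    drop classes {0, 7, 8, 12})."""

    clouds_a: list[str] = field(default_factory=list)
    clouds_b: list[str] = field(default_factory=list)
    units_a: str = ""
    units_b: str = ""
    neas_a: str | None = None
    neas_b: str | None = None
    inventory_a: str | None = None
    inventory_b: str | None = None
    resolution: float = 0.5
    mask_threshold: float = 7.0
    window_slope: float = 0.16
    window_intercept: float = 0.8
    nea_buffer: float = 2.0
    drop_classes: list[int] = field(
        default_factory=lambda: sorted(DEFAULT_DROP_CODES))
    rounding: str = "half_up"
    min_inventory_height: float = 6.0
    seed: int = 0
    output_dir: str = "standgrowth_run"

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        with path.open() as fh:
            data = (yaml.safe_load(fh) if path.suffix in (".yml", ".yaml")
                    else json.load(fh))
        return cls(**data)


def _load_units(path: str, epoch: str, inventory_path: str | None,
                min_height: float):
    units = geoprep.read_units_geojson(path, epoch=epoch)
    if inventory_path:
        table = pd.read_csv(inventory_path)
        units, rejects = geoprep.harmonize_layers(units, table,
                                                  min_height=min_height)
    else:
        rejects = pd.DataFrame(columns=["forest_address", "reason"])
        units = [u for u in units if u.inventory_height is not None
                 and u.inventory_height > min_height]
    return units, rejects


def process_epoch(cloud_paths: list[str], config: RunConfig, epoch: str,
                  spec: surfaces.GridSpec | None = None):
    """filter -> DSM/DTM -> CHM -> smooth -> mask -> detect for one epoch."""
    clouds = [read_cloud(p, epoch=epoch) for p in cloud_paths]
    merged = merge_tiles(clouds)
    filtered = filter_classes(merged, set(config.drop_classes))
    if spec is None:
        xmin, ymin, xmax, ymax = filtered.bounds
        spec = surfaces.GridSpec.from_bounds(xmin, ymin, xmax, ymax,
                                             config.resolution)
    dsm = surfaces.make_dsm(filtered, spec=spec)
    dtm = surfaces.make_dtm(filtered, spec=spec)
    chm = surfaces.compute_chm(dsm, dtm)
    smooth = surfaces.gaussian_smooth(chm)
    masked = surfaces.mask_below(smooth, config.mask_threshold)
    tops = treetops.detect_treetops(masked, slope=config.window_slope,
                                    intercept=config.window_intercept,
                                    epoch=epoch)
    counts = {"points_raw": len(merged), "points_filtered": len(filtered),
              "tops_detected": len(tops)}
    return {"spec": spec, "dsm": dsm, "dtm": dtm, "chm": masked,
            "tops": tops, "counts": counts}


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full two-epoch chain and write a run report.

    Returns the report dict: per-stage counts, per-unit increments, and the
    agreement statistics between LiDAR and inventory increments.
    """
    t0 = time.time()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}, "config": asdict(config)}

    # --- load vectors -----------------------------------------------------
    units_a, rejects_a = _load_units(config.units_a, "a", config.inventory_a,
                                     config.min_inventory_height)
    units_b, rejects_b = _load_units(config.units_b, "b", config.inventory_b,
                                     config.min_inventory_height)
    neas_a = (geoprep.read_geometries_geojson(config.neas_a)
              if config.neas_a else [])
    neas_b = (geoprep.read_geometries_geojson(config.neas_b)
              if config.neas_b else [])
    report["stages"]["units"] = {
        "a_loaded": len(units_a) + len(rejects_a),
        "a_harmonized": len(units_a),
        "b_loaded": len(units_b) + len(rejects_b),
        "b_harmonized": len(units_b),
    }
    pd.concat([rejects_a.assign(epoch="a"), rejects_b.assign(epoch="b")]
              ).to_csv(outdir / "harmonize_rejects.csv", index=False)

    # --- per-epoch raster/tops chain on one shared grid -------------------
    ep_a = process_epoch(config.clouds_a, config, "a")
    ep_b = process_epoch(config.clouds_b, config, "b", spec=ep_a["spec"])
    for tag, ep in (("a", ep_a), ("b", ep_b)):
        report["stages"][f"epoch_{tag}"] = ep["counts"]
        surfaces.write_ascii_grid(ep["chm"], outdir / f"chm_{tag}.asc")

    tops_a = treetops.filter_treetops(ep_a["tops"], units_a, neas_a,
                                      config.nea_buffer)
    tops_b = treetops.filter_treetops(ep_b["tops"], units_b, neas_b,
                                      config.nea_buffer)
    report["stages"]["tops_filtered"] = {"a": len(tops_a), "b": len(tops_b)}
    treetops.write_treetops_geojson(tops_a, outdir / "tops_a.geojson")
    treetops.write_treetops_geojson(tops_b, outdir / "tops_b.geojson")

    # --- cross-epoch unit matching ----------------------------------------
    matches = geoprep.match_units(units_a, units_b)
    kept, match_rejects = geoprep.filter_matched(matches)
    match_rejects.to_csv(outdir / "match_rejects.csv", index=False)
    report["stages"]["matching"] = {
        "matched": len(matches), "after_age_filter": len(kept),
    }

    # --- stand heights, error flags, increments ---------------------------
    heights_a = standmetrics.stand_heights_for_units(tops_a, epoch="a",
                                                     rounding=config.rounding)
    heights_b = standmetrics.stand_heights_for_units(tops_b, epoch="b",
                                                     rounding=config.rounding)
    pairs = []
    skipped = {"no_tops": 0, "gross_error": 0}
    unit_rows = []
    for m in kept:
        addr_a, addr_b = m.unit_a.forest_address, m.unit_b.forest_address
        rec_a, rec_b = heights_a.get(addr_a), heights_b.get(addr_b)
        if rec_a is None or rec_b is None:
            skipped["no_tops"] += 1
            continue
        diff_a, _ = standmetrics.height_difference(rec_a.reported_height,
                                                   m.unit_a.inventory_height)
        diff_b, _ = standmetrics.height_difference(rec_b.reported_height,
                                                   m.unit_b.inventory_height)
        flag_a = standmetrics.flag_gross_errors(diff_a, rec_a.n_tops,
                                                m.unit_a.age)
        flag_b = standmetrics.flag_gross_errors(diff_b, rec_b.n_tops,
                                                m.unit_b.age)
        if (flag_a is not standmetrics.ErrorFlag.OK
                or flag_b is not standmetrics.ErrorFlag.OK):
            skipped["gross_error"] += 1
            continue
        pair = standmetrics.increments(addr_b, rec_a, rec_b,
                                       m.unit_a.inventory_height,
                                       m.unit_b.inventory_height)
        pairs.append(pair)
        unit_rows.append({
            "forest_address": addr_b,
            "lidar_height_a": rec_a.reported_height,
            "lidar_height_b": rec_b.reported_height,
            "inventory_height_a": m.unit_a.inventory_height,
            "inventory_height_b": m.unit_b.inventory_height,
            "lidar_increment": pair.lidar_increment,
            "inventory_increment": pair.inventory_increment,
            "diff_a": pair.diff_a, "diff_b": pair.diff_b,
            "n_tops_a": rec_a.n_tops, "n_tops_b": rec_b.n_tops,
        })
    report["stages"]["increments"] = {"pairs": len(pairs), **skipped}
    increments_df = pd.DataFrame(unit_rows)
    increments_df.to_csv(outdir / "increments.csv", index=False)

    # --- agreement --------------------------------------------------------
    if len(pairs) >= 2:
        x = [p.lidar_increment for p in pairs]
        y = [p.inventory_increment for p in pairs]
        try:
            stats = agr.agreement_stats(x, y)
            report["agreement"] = {
                "r_xy": stats.r_xy, "bias": stats.bias, "rmse": stats.rmse,
                "r2_pearson": stats.r2_pearson, "r2_identity": stats.r2_identity,
                "rbias_pct": stats.rbias_pct, "n": stats.n,
            }
        except ValueError as exc:
            report["agreement"] = {"error": str(exc)}
        crosstab = agr.crosstab_increments(pairs)
        crosstab.to_csv(outdir / "increment_crosstab.csv")
    else:
        report["agreement"] = {"error": "fewer than 2 increment pairs"}

    # timing goes to the log, not the report: reports must be byte-identical
    # for a fixed config and seed
    logger.info("pipeline finished in %.3f s", time.time() - t0)
    with (outdir / "report.json").open("w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
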