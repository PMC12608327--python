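# standgrowth

Forest-stand height increments from two-epoch airborne laser scanning (ALS),
with agreement statistics against field-inventory heights and a synthetic
forest generator so the whole pipeline runs without external data.

The processing chain per epoch: class-filter the classified point cloud →
Delaunay-TIN rasterization of first returns (DSM) and ground returns (DTM)
at 0.5 m → CHM = DSM − DTM → 3×3 Gaussian smoothing → mask everything below
7 m → variable-window local-maxima tree-top detection (search radius
0.16·height + 0.8 m) → spatial filtering against forest-unit and buffered
non-exclusive-area (NEA) polygons → occurrence-weighted stand height per
unit in whole meters. Units are matched across epochs spatially (polygon
intersection + pole of inaccessibility), increments are differenced per
source, and agreement is quantified with weighted Pearson correlation,
bias/RMSE/R²/rBias, difference-class tabulations, Jenks natural-breaks
classification, detection precision/recall/F1, and Monte Carlo propagation
of per-tree measurement error.

## Layout

| module | role |
| --- | --- |
| `standgrowth.pointcloud` | plain-text cloud IO, tile merging, class filtering |
| `standgrowth.surfaces` | TIN rasterization, DSM/DTM/CHM, smoothing, masking, ASCII-grid IO |
| `standgrowth.treetops` | variable-window local-maxima detection, unit/NEA filtering |
| `standgrowth.geoprep` | layer harmonization, NEA buffering, cross-epoch unit matching |
| `standgrowth.standmetrics` | weighted stand heights, difference classes, increments, gross-error flags |
| `standgrowth.agreement` | correlation, agreement stats, cross-tabs, Jenks, detection metrics, Monte Carlo SE |
| `standgrowth.synthetic` | two-epoch synthetic scenes (terrain, stands, ALS sampling, inventory) |
| `standgrowth.pipeline` / `standgrowth.cli` | end-to-end orchestration and the `standgrowth` CLI |
| `standgrowth.refdata` | published reference tabulations used as regression fixtures |

Point clouds are stored as whitespace-separated text
(`x y z return_number number_of_returns class_code`), rasters as ESRI ASCII
grids, vectors as GeoJSON (projected CRS in meters required) — every
intermediate stays plain text.

## CLI

```sh
# generate a synthetic two-epoch study area + ready-to-run config
standgrowth simulate --seed 1 --extent 120 --units 2 --out scene/

# run the full chain: filter -> surfaces -> tops -> match -> heights -> agreement
standgrowth all scene/run_config.json

# individual stages
standgrowth surfaces scene/cloud_a.xyz --resolution 0.5 --out surf/
standgrowth tops surf/chm.asc --slope 0.16 --intercept 0.8 --out tops.geojson
```

The run report (`report.json`) lists unit and point counts surviving every
filter stage, the per-unit increment table, and the agreement statistics.
Reports are byte-identical for a fixed config and seed.

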