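"""Published reference tabulations from a two-epoch pine-forest comparison.

These tables summarize an operational comparison of LiDAR-derived and
field-inventory stand heights over a pine-dominated forest range (two ALS
epochs nine years apart, 4 pts/m^2).  They serve as fixed regression inputs:
the aggregation and correlation routines in :mod:`standgrowth.agreement`
must reproduce the summary figures published alongside them.

Area tables: rows are forest site types or dominant species, columns are
height-difference classes (LiDAR minus inventory, whole meters), cells are
summed unit areas in hectares.  The increment cross-tabulation counts forest
units by (inventory increment, LiDAR increment) in meters.
"""

from __future__ import annotations

import pandas as pd

#: Area (ha) of units excluded as gross errors in the historic epoch —
#: enters the denominator of the historic percent-of-area figures.
EXCLUDED_ERROR_AREA_HA = 19.01

_EPOCH1_SITE_CLASSES = [-5, -4, -3, -2, -1, 0, 1, 2, 3, 4, 5, 6]

#: Historic-epoch unit areas (ha) by site type and difference class.
EPOCH1_AREA_BY_SITE = pd.DataFrame(
    {
        "FPF":  [0, 0, 1.45, 85.3, 194.08, 204.45, 129.91, 9.26, 1.74, 0, 0, 0],
        "BMF":  [0, 0, 0, 0, 0.55, 0.92, 0, 0, 0, 0, 0, 0],
        "MMCF": [0, 0, 0, 0, 1.94, 0, 0, 0, 0, 0, 0, 0],
        "FMCF": [0, 0, 2.59, 22.23, 49.46, 122.27, 123.51, 52.87, 17.72, 10.04, 0, 0],
        "FMHF": [1.12, 0, 6.18, 5.93, 2.33, 5.79, 11.61, 1.16, 1.22, 0.8, 0.26, 0.65],
        "MMF":  [0, 0, 0, 0.54, 0, 0, 0, 0, 0, 0, 0, 0],
        "TASF": [5.19, 1.03, 7.54, 1.8, 1.69, 2.34, 1.86, 0, 0, 0, 0, 0],
        "AAF":  [1.21, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    },
    index=_EPOCH1_SITE_CLASSES,
).T

#: Historic-epoch unit areas (ha) by dominant species and difference class.
EPOCH1_AREA_BY_SPECIES = pd.DataFrame(
    {
        "birch":  [3.66, 0, 2.23, 1.16, 0, 1.05, 0, 0, 0, 0, 0, 0],
        "alder":  [2.74, 1.03, 5.94, 2.34, 1.69, 2.34, 1.86, 0, 0, 0, 0, 0],
        "larch":  [0, 0, 0.99, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        "spruce": [0, 0, 2.96, 2.36, 0, 0, 0, 0, 0, 0, 0, 0.65],
        "pine":   [1.12, 0, 8.6, 109.34, 248.36, 332.38, 265.03, 63.29,
                   20.68, 10.84, 0.26, 0],
    },
    index=_EPOCH1_SITE_CLASSES,
).T

_EPOCH2_CLASSES = ["-8..-6", -5, -4, -3, -2, -1, 0, 1, 2, 3, 4, 5, 6]

#: Current-epoch unit areas (ha) by site type and difference class
#: (classes -8..-6 pooled).
EPOCH2_AREA_BY_SITE = pd.DataFrame(
    {
        "FPF":  [0, 0, 0.45, 0, 51.91, 61.87, 186.03, 179.34, 80.04, 18.54,
                 0, 1.76, 2.91],
        "BMF":  [0, 0, 0, 0, 0, 0.55, 0.99, 0, 0, 0, 0, 0, 0],
        "MMCF": [0, 0.77, 0, 0, 0.76, 0, 0, 1.23, 0, 0, 0, 0, 0],
        "FMCF": [0, 0, 0, 0, 8.67, 40.59, 72.51, 130.92, 116.6, 28.25,
                 12.93, 0.74, 3.87],
        "FMHF": [3.81, 3.11, 0, 0, 1.82, 5.08, 9.91, 3.07, 2.81, 1.94, 0.8, 0, 0],
        "MMF":  [0, 0, 0, 0.54, 0, 0, 0, 0, 0, 0, 0, 0, 0],
        "TASF": [11.08, 3.42, 2.83, 2.34, 2.19, 0, 0, 0, 0, 0, 0, 0, 0],
        "AAF":  [1.21, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0],
    },
    index=_EPOCH2_CLASSES,
).T

#: Current-epoch unit areas (ha) by dominant species and difference class.
EPOCH2_AREA_BY_SPECIES = pd.DataFrame(
    {
        "birch":  [5.92, 0, 0, 0, 1.22, 0, 1.05, 0, 0, 0, 0, 0, 0],
        "alder":  [6.99, 3.42, 2.83, 2.88, 2.19, 0, 0, 0, 0, 0, 0, 0, 0],
        "larch":  [0, 0.99, 0, 0, 0, 0, 0, 0, 0, 0, 0.5, 0, 0],
        "spruce": [2.36, 0, 0, 0, 0.6, 0, 0, 0, 0, 0.72, 0, 0, 0],
        "pine":   [0.83, 2.89, 0.45, 0, 61.34, 108.09, 268.39, 314.56,
                   199.45, 48.01, 13.23, 2.5, 6.87],
    },
    index=_EPOCH2_CLASSES,
).T

#: Forest-unit counts by (inventory increment, LiDAR increment) in meters.
#: Rows: inventory-based increment; columns: LiDAR-based increment.
INCREMENT_CROSSTAB = pd.DataFrame(
    {
        -5: {-1: 0, 0: 0, 1: 1, 2: 0, 3: 0, 4: 0, 8: 0},
        -4: {-1: 0, 0: 0, 1: 1, 2: 0, 3: 0, 4: 0, 8: 0},
        -3: {-1: 0, 0: 0, 1: 2, 2: 0, 3: 0, 4: 0, 8: 0},
        -2: {-1: 1, 0: 1, 1: 1, 2: 0, 3: 0, 4: 0, 8: 0},
        -1: {-1: 0, 0: 2, 1: 2, 2: 0, 3: 0, 4: 0, 8: 0},
        0:  {-1: 0, 0: 4, 1: 1, 2: 3, 3: 0, 4: 0, 8: 0},
        1:  {-1: 1, 0: 8, 1: 9, 2: 7, 3: 0, 4: 0, 8: 0},
        2:  {-1: 0, 0: 20, 1: 35, 2: 31, 3: 2, 4: 2, 8: 0},
        3:  {-1: 0, 0: 1, 1: 6, 2: 29, 3: 18, 4: 5, 8: 0},
        4:  {-1: 0, 0: 0, 1: 0, 2: 6, 3: 11, 4: 2, 8: 0},
        5:  {-1: 0, 0: 0, 1: 0, 2: 0, 3: 3, 4: 0, 8: 1},
    },
)

INCREMENT_CROSSTAB.index.name = "inventory_increment"
INCREMENT_CROSSTAB.columns.name = "lidar_increment"
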