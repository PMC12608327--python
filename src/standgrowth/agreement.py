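"""Agreement statistics between LiDAR and inventory stand heights.

Implements weighted product-moment correlation (so that contingency-table
counts can be used directly as pair multiplicities), bias/RMSE/R^2/rBias,
difference-class tabulations by site type or species, increment
cross-tabulations, 1-D Fisher-Jenks natural-breaks classification, tree-top
detection metrics, and Monte Carlo propagation of per-tree measurement error
into the stand mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class AgreementStats:
    r_xy: float
    bias: float
    rmse: float
    r2_pearson: float      # squared correlation
    r2_identity: float     # 1 - SS_res/SS_tot about the line x == y
    rbias_pct: float | None
    n: int


def pearson(x, y, weights=None) -> float:
    """Weighted product-moment correlation coefficient.

    ``weights`` are pair multiplicities (e.g. cell counts of a
    cross-tabulation); omitted weights mean unit weight per pair.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length with n >= 2")
    w = np.ones_like(x) if weights is None else np.asarray(weights, dtype=np.float64)
    if w.shape != x.shape or (w < 0).any() or w.sum() <= 0:
        raise ValueError("weights must be non-negative with a positive sum")
    xbar = np.average(x, weights=w)
    ybar = np.average(y, weights=w)
    cov = np.sum(w * (x - xbar) * (y - ybar))
    vx = np.sum(w * (x - xbar) ** 2)
    vy = np.sum(w * (y - ybar) ** 2)
    if vx <= 0 or vy <= 0:
        raise ValueError("correlation undefined: zero variance in x or y")
    return float(cov / math.sqrt(vx * vy))


def agreement_stats(x, y) -> AgreementStats:
    """Agreement measures for predictions x against reference y.

    bias = mean(x - y); rmse = sqrt(mean((x - y)^2));
    rbias = 100 * bias / mean(y) (None when mean(y) == 0).
    Two R^2 variants are reported: the squared Pearson correlation, and the
    coefficient of determination about the identity line x == y.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length with n >= 2")
    resid = x - y
    bias = float(resid.mean())
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    try:
        r = pearson(x, y)
    except ValueError:
        r = float("nan")
    r2_id = 1.0 - float(np.sum(resid ** 2)) / ss_tot if ss_tot > 0 else float("nan")
    ybar = float(y.mean())
    rbias = 100.0 * bias / ybar if ybar != 0 else None
    return AgreementStats(
        r_xy=r, bias=bias, rmse=rmse, r2_pearson=r * r, r2_identity=r2_id,
        rbias_pct=rbias, n=int(x.size),
    )


def class_tabulate(records: pd.DataFrame, grouping: str,
                   measure: str = "count",
                   class_order: list[str] | None = None) -> pd.DataFrame:
    """Tabulate units by difference class.

    ``records`` needs columns ``diff_class``, the grouping column
    (``site_type`` or ``dominant_species``) and, for ``measure="area"``,
    ``area_ha``.  Rows are group levels, columns difference classes, plus a
    TOTAL row.  Area cells are rounded to 2 decimals.
    """
    if measure not in ("count", "area"):
        raise ValueError("measure must be 'count' or 'area'")
    if class_order is None:
        from standgrowth.standmetrics import class_labels
        class_order = class_labels()
    if records.empty:
        table = pd.DataFrame(0.0 if measure == "area" else 0,
                             index=["TOTAL"], columns=class_order)
        return table
    if measure == "count":
        table = records.pivot_table(index=grouping, columns="diff_class",
                                    aggfunc="size", fill_value=0)
    else:
        table = records.pivot_table(index=grouping, columns="diff_class",
                                    values="area_ha", aggfunc="sum", fill_value=0.0)
    table = table.reindex(columns=class_order, fill_value=0).fillna(0)
    table.loc["TOTAL"] = table.sum(axis=0)
    if measure == "area":
        table = table.round(2)
    else:
        table = table.astype(int)
    return table


def crosstab_increments(pairs) -> pd.DataFrame:
    """Cross-tabulate unit counts by (inventory increment, LiDAR increment).

    Accepts IncrementPair objects or anything with ``inventory_increment``
    and ``lidar_increment`` attributes.  Rows are inventory increments,
    columns LiDAR increments, cells counts.
    """
    inv = [p.inventory_increment for p in pairs]
    lid = [p.lidar_increment for p in pairs]
    if not inv:
        return pd.DataFrame()
    table = pd.crosstab(pd.Series(inv, name="inventory_increment"),
                        pd.Series(lid, name="lidar_increment"))
    return table.sort_index().sort_index(axis=1)


def restricted_pearson_from_crosstab(table: pd.DataFrame,
                                     max_abs_diff: float | None = None) -> float:
    """Weighted Pearson over a cross-tab, optionally restricted to cells
    whose two increments differ by at most ``max_abs_diff`` meters."""
    xs, ys, ws = [], [], []
    for inv in table.index:
        for lid in table.columns:
            count = int(table.loc[inv, lid])
            if count == 0:
                continue
            if max_abs_diff is not None and abs(lid - inv) > max_abs_diff:
                continue
            xs.append(lid)
            ys.append(inv)
            ws.append(count)
    return pearson(xs, ys, weights=ws)


# ---------------------------------------------------------------------------
# Jenks natural breaks

def jenks_breaks(values, k: int) -> list[float]:
    """Optimal 1-D classification into ``k`` classes (Fisher-Jenks).

    Minimizes the total within-class sum of squared deviations by dynamic
    programming; O(k n^2).  Returns k+1 break points: the minimum, the k-1
    inner class maxima, and the maximum.  Deterministic and invariant to
    input order.
    """
    data = np.sort(np.asarray(values, dtype=np.float64))
    n = data.size
    if k < 2:
        raise ValueError("k must be >= 2")
    if np.unique(data).size < k:
        raise ValueError("need at least k distinct values")
    # prefix sums for O(1) within-class SSD of data[i..j]
    csum = np.concatenate([[0.0], np.cumsum(data)])
    csq = np.concatenate([[0.0], np.cumsum(data ** 2)])

    def ssd(i: int, j: int) -> float:
        # inclusive 0-based range [i, j]
        m = j - i + 1
        s = csum[j + 1] - csum[i]
        q = csq[j + 1] - csq[i]
        return max(q - s * s / m, 0.0)

    INF = float("inf")
    cost = np.full((k + 1, n + 1), INF)
    split = np.zeros((k + 1, n + 1), dtype=np.int64)
    cost[0, 0] = 0.0
    for c in range(1, k + 1):
        for j in range(c, n + 1):
            best, arg = INF, c - 1
            for i in range(c - 1, j):
                val = cost[c - 1, i] + ssd(i, j - 1)
                if val < best:
                    best, arg = val, i
            cost[c, j] = best
            split[c, j] = arg
    breaks = [float(data[-1])]
    j = n
    for c in range(k, 0, -1):
        i = split[c, j]
        breaks.append(float(data[i - 1]) if i > 0 else float(data[0]))
        j = i
    breaks.reverse()
    breaks[0] = float(data[0])
    return breaks


def classify_jenks(values, breaks: list[float]) -> np.ndarray:
    """Class index (0-based) of each value under Jenks breaks."""
    values = np.asarray(values, dtype=np.float64)
    inner = np.asarray(breaks[1:-1])
    return np.searchsorted(inner, values, side="left")


# ---------------------------------------------------------------------------
# detection metrics

@dataclass
class DetectionMetrics:
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int


def detection_metrics(detected, reference, match_radius: float = 2.0
                      ) -> DetectionMetrics:
    """Greedy one-to-one nearest matching of detected vs reference points.

    Candidate pairs within ``match_radius`` are matched in ascending distance
    order, each point used at most once.  With no detections precision is
    reported as 0 by convention (documented degenerate case).
    """
    det = np.asarray([(p.x, p.y) if hasattr(p, "x") else tuple(p)
                      for p in detected], dtype=np.float64).reshape(-1, 2)
    ref = np.asarray([(p.x, p.y) if hasattr(p, "x") else tuple(p)
                      for p in reference], dtype=np.float64).reshape(-1, 2)
    if len(ref) == 0:
        raise ValueError("empty reference set: metrics undefined")
    pairs = []
    for i in range(len(det)):
        d = np.hypot(ref[:, 0] - det[i, 0], ref[:, 1] - det[i, 1])
        for j in np.nonzero(d <= match_radius)[0]:
            pairs.append((float(d[j]), i, int(j)))
    pairs.sort()
    used_det: set[int] = set()
    used_ref: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_det or j in used_ref:
            continue
        used_det.add(i)
        used_ref.add(j)
        tp += 1
    fp = len(det) - tp
    fn = len(ref) - tp
    precision = tp / (tp + fp) if (tp + fp) > 0 else 0.0
    recall = tp / (tp + fn)
    f1 = (2 * precision * recall / (precision + recall)
          if (precision + recall) > 0 else 0.0)
    return DetectionMetrics(precision=precision, recall=recall, f1=f1,
                            tp=tp, fp=fp, fn=fn)


def count_rmse(detected_counts, reference_counts) -> float:
    """RMSE of per-plot detected vs reference tree counts."""
    d = np.asarray(detected_counts, dtype=np.float64)
    r = np.asarray(reference_counts, dtype=np.float64)
    if d.shape != r.shape or d.size == 0:
        raise ValueError("count vectors must be equal-length and non-empty")
    return float(np.sqrt(np.mean((d - r) ** 2)))


# ---------------------------------------------------------------------------
# Monte Carlo uncertainty of the stand mean

@dataclass
class UncertaintySpec:
    sigma: float = 0.3
    n_trees: int = 1000
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.n_reps < 100:
            raise ValueError("n_reps must be >= 100")

    @property
    def analytic_se(self) -> float:
        """Closed-form standard error sigma / sqrt(n)."""
        return self.sigma / math.sqrt(self.n_trees)


def mc_height_uncertainty(spec: UncertaintySpec,
                          base_heights=None) -> float:
    """Monte Carlo standard error of the stand mean height.

    Draws ``n_reps`` replicate stands of ``n_trees`` heights with independent
    N(0, sigma^2) measurement errors and returns the standard deviation of
    the replicate means; converges to sigma / sqrt(n).
    """
    rng = np.random.default_rng(spec.seed)
    if base_heights is None:
        base = np.zeros(spec.n_trees)
    else:
        base = np.asarray(base_heights, dtype=np.float64)
        if base.size != spec.n_trees:
            raise ValueError("base_heights length must equal n_trees")
    errors = rng.normal(0.0, spec.sigma, size=(spec.n_reps, spec.n_trees))
    means = (base[None, :] + errors).mean(axis=1)
    return float(means.std(ddof=1))
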