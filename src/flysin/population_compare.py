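"""Population-level comparison of social interaction networks.

Group comparisons use independent-samples t-tests with Welch correction
(unequal variances, Welch-Satterthwaite degrees of freedom), significant at
p < 0.05 per measure without multiple-testing correction; an optional
Benjamini-Hochberg adjustment is available.  The unit of analysis for local
measures is the per-network median (mean available), for global and middle
measures the per-network value.  Also provides the pooled-node Pearson
correlation matrix of local measures and arena occupancy histograms.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from flysin.errors import DegenerateInputError, ParameterError
from flysin.community_mid import community_stats, louvain_partition
from flysin.measures_global import global_summary
from flysin.measures_local import MEASURE_COLUMNS, local_measure_table
from flysin.trajectory_io import TrajectoryTable

COMPARE_LEVELS = ("local-medians", "local-means", "global", "middle")


def welch_t_test(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test.

    Returns ``(t, df, p)`` with the Welch-Satterthwaite degrees of freedom
    and the two-sided p-value.  Each sample needs at least two finite
    values, and at least one sample must have positive variance.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError(
            f"Welch test needs >= 2 finite values per sample, got {a.size} and {b.size}"
        )
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise DegenerateInputError("both samples have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def _bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = pvals.size
    order = np.argsort(pvals)
    ranked = pvals[order] * n / (np.arange(n) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.clip(ranked, 0, 1)
    return out


def _per_network_values(sins, level: str, statistic: str, seed: int) -> pd.DataFrame:
    rows = []
    for g in sins:
        if level in ("local-medians", "local-means"):
            tbl = local_measure_table(g)
            rows.append(tbl.median() if level == "local-medians" else tbl.mean())
        elif level == "global":
            rows.append(pd.Series(global_summary(g).as_dict()))
        elif level == "middle":
            part = louvain_partition(g, weight="duration", seed=seed)
            rows.append(pd.Series(community_stats(g, part).as_dict()))
        else:
            raise ParameterError(
                f"unknown level '{level}'; expected one of {COMPARE_LEVELS}"
            )
    return pd.DataFrame(rows).astype(float)


def compare_measures(
    networks_a,
    networks_b,
    level: str = "global",
    alpha: float = 0.05,
    bh_correction: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Measure-by-measure Welch comparison of two populations of networks.

    One row per measure: group means and SDs, Welch t, df, two-sided p and
    a significance flag at ``alpha``.  Non-finite per-network values
    (undefined measures) are dropped per measure with a ``n_dropped``
    count.  Degenerate measures (zero variance in both groups, or fewer
    than two finite values in a group) yield NaN statistics.
    """
    if len(networks_a) < 2 or len(networks_b) < 2:
        raise DegenerateInputError("need at least 2 networks per group")
    va = _per_network_values(networks_a, level, "median", seed)
    vb = _per_network_values(networks_b, level, "median", seed)
    rows = []
    for measure in va.columns:
        xa = va[measure].to_numpy()
        xb = vb[measure].to_numpy()
        n_drop = int(np.sum(~np.isfinite(xa)) + np.sum(~np.isfinite(xb)))
        xa, xb = xa[np.isfinite(xa)], xb[np.isfinite(xb)]
        try:
            t, df, p = welch_t_test(xa, xb)
        except DegenerateInputError:
            if (
                xa.size >= 2
                and xb.size >= 2
                and np.allclose(xa, xa[0])
                and np.allclose(xb, xb[0])
                and math.isclose(xa[0], xb[0])
            ):
                t, df, p = 0.0, float(xa.size + xb.size - 2), 1.0
            else:
                t, df, p = math.nan, math.nan, math.nan
        rows.append(
            {
                "measure": measure,
                "mean_a": xa.mean() if xa.size else math.nan,
                "sd_a": xa.std(ddof=1) if xa.size > 1 else math.nan,
                "mean_b": xb.mean() if xb.size else math.nan,
                "sd_b": xb.std(ddof=1) if xb.size > 1 else math.nan,
                "t": t,
                "df": df,
                "p": p,
                "n_dropped": n_drop,
            }
        )
    table = pd.DataFrame(rows)
    if bh_correction:
        finite = np.isfinite(table["p"].to_numpy())
        adj = np.full(len(table), math.nan)
        adj[finite] = _bh_adjust(table.loc[finite, "p"].to_numpy())
        table["p_adjusted"] = adj
        table["significant"] = table["p_adjusted"] < alpha
    else:
        table["significant"] = table["p"] < alpha
    return table


def measure_correlations(networks) -> pd.DataFrame:
    """Pearson correlation matrix of local measures, pooling flies across
    networks; constant measures give NaN rows/columns."""
    tables = [local_measure_table(g) for g in networks]
    pooled = pd.concat(tables, ignore_index=True)
    if len(pooled) < 3:
        raise DegenerateInputError("need at least 3 pooled flies")
    return pooled[MEASURE_COLUMNS].corr(method="pearson")


def occupancy_heatmap(
    trajs: list[TrajectoryTable], grid_cells: int = 32
) -> np.ndarray:
    """Arena occupancy histogram: frames spent per spatial cell.

    The arena's bounding square is divided into ``grid_cells`` bins per
    axis; entry [i, j] counts fly-frames whose position falls in that cell
    (rows follow y, columns x).  Cells lying entirely outside the arena
    disc are NaN-masked; finite entries sum to the total number of observed
    fly-frames.
    """
    if grid_cells < 2:
        raise ParameterError("grid_cells must be >= 2")
    if trajs:
        radius = trajs[0].arena.radius
    else:
        radius = 1.0
    edges = np.linspace(-radius, radius, grid_cells + 1)
    h = np.zeros((grid_cells, grid_cells))
    for traj in trajs:
        df = traj.data
        x = df["x"].to_numpy(dtype=float)
        y = df["y"].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        hist, _, _ = np.histogram2d(
            y[ok], x[ok], bins=[edges, edges]
        )
        h += hist
    # mask cells whose nearest point to the centre is outside the disc
    centers = (edges[:-1] + edges[1:]) / 2.0
    half = (edges[1] - edges[0]) / 2.0
    cy, cx = np.meshgrid(centers, centers, indexing="ij")
    nearest = np.hypot(
        np.maximum(np.abs(cx) - half, 0.0), np.maximum(np.abs(cy) - half, 0.0)
    )
    h[nearest > radius] = np.nan
    return h
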