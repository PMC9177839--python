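"""Per-individual path metrics and their group comparisons.

Three movement summaries per bird, computed on the daily-regularized
track: maximum great-circle displacement from the deployment colony, path
length from the colony to the point of maximum displacement (sum of
great-circle distances between consecutive daily positions), and the
individual core area (UD isopleth area at the cohort core isopleth).

Group differences are assessed by permutational ANOVA (the F statistic
with group labels permuted; no normality assumption) followed, where the
omnibus test is significant, by Dunn's rank-sum pairwise tests with
Bonferroni correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geo import AzimuthalEquidistant, great_circle_distance
from .homerange import DEFAULT_CELL_KM, DEFAULT_H_KM, isopleth_region, kde_ud

N_PERM_ANOVA = 5000
ALPHA = 0.05


def _daily_positions(track_daily: pd.DataFrame) -> pd.DataFrame:
    out = track_daily.dropna(subset=["lon", "lat"])
    if out.empty:
        raise ValueError("empty daily track")
    return out


def max_distance(track_daily: pd.DataFrame, colony_lonlat) -> float:
    """Maximum great-circle distance (km) from the deployment colony."""
    sub = _daily_positions(track_daily)
    d = great_circle_distance(sub["lon"].to_numpy(), sub["lat"].to_numpy(),
                              colony_lonlat[0], colony_lonlat[1])
    return float(np.max(d))


def path_length_to_max(track_daily: pd.DataFrame, colony_lonlat) -> float:
    """Cumulative great-circle path length (km) from the deployment colony
    through the daily position attaining the maximum displacement."""
    sub = _daily_positions(track_daily)
    lon = np.concatenate([[colony_lonlat[0]], sub["lon"].to_numpy()])
    lat = np.concatenate([[colony_lonlat[1]], sub["lat"].to_numpy()])
    d = great_circle_distance(lon, lat, colony_lonlat[0], colony_lonlat[1])
    k = int(np.argmax(d))
    seg = great_circle_distance(lon[:k], lat[:k], lon[1:k + 1], lat[1:k + 1])
    return float(np.sum(seg))


def individual_core_area(track_daily: pd.DataFrame,
                         projection: AzimuthalEquidistant,
                         core_isopleth_pct: float, h: float = DEFAULT_H_KM,
                         cell: float = DEFAULT_CELL_KM) -> float:
    """Area (km^2) of the individual's UD at the cohort core isopleth."""
    sub = _daily_positions(track_daily)
    x, y = projection.forward(sub["lon"].to_numpy(), sub["lat"].to_numpy())
    ud = kde_ud(np.column_stack([x, y]), h=h, cell=cell)
    return isopleth_region(ud, core_isopleth_pct / 100.0).area


def path_metrics_table(clean_tracks: dict, colony_positions: dict,
                       projection: AzimuthalEquidistant,
                       core_isopleth_pct: float, h: float = DEFAULT_H_KM,
                       cell: float = DEFAULT_CELL_KM) -> pd.DataFrame:
    """All three metrics for every retained individual, long-format ready
    for group comparisons and box plots."""
    rows = []
    for iid, ct in clean_tracks.items():
        daily = ct.daily
        meta = daily.iloc[0]
        colony = colony_positions[meta["colony"]]
        try:
            core = individual_core_area(daily, projection, core_isopleth_pct,
                                        h=h, cell=cell)
        except ValueError:
            core = float("nan")
        rows.append({"individual_id": iid, "colony": meta["colony"],
                     "stage": meta["stage"], "year": meta["year"],
                     "max_distance_km": max_distance(daily, colony),
                     "path_length_km": path_length_to_max(daily, colony),
                     "core_area_km2": core})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Permutational ANOVA and Dunn's post hoc


def _f_statistic(values: np.ndarray, onehot: np.ndarray) -> float:
    n = len(values)
    k = onehot.shape[1]
    counts = onehot.sum(axis=0)
    means = values @ onehot / counts
    grand = values.mean()
    ssb = float(np.sum(counts * (means - grand) ** 2))
    ssw = float(np.sum((values - onehot @ means) ** 2))
    if ssw == 0:
        return np.inf if ssb > 0 else 0.0
    return (ssb / (k - 1)) / (ssw / (n - k))


def peranova(values, labels, n_perm: int = N_PERM_ANOVA, seed: int = 0):
    """One-way permutational ANOVA.

    The observed F statistic is compared with its distribution under
    ``n_perm`` random permutations of the raw group labels; the p-value is
    the (+1-smoothed) proportion of permuted F at least as large as the
    observed, so p lies in [1/(B+1), 1].

    Returns ``(F, p)``.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups, inv = np.unique(labels, return_inverse=True)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    onehot = np.zeros((len(values), len(groups)))
    onehot[np.arange(len(values)), inv] = 1.0
    f_obs = _f_statistic(values, onehot)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        count += _f_statistic(rng.permutation(values), onehot) >= f_obs
    p = (count + 1) / (n_perm + 1)
    return float(f_obs), float(p)


def dunn_test(values, labels) -> pd.DataFrame:
    """Dunn's (1964) rank-sum pairwise z tests with tie-corrected variance
    and Bonferroni-multiplied two-sided p-values (capped at 1)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    n = len(values)
    ranks = stats.rankdata(values)
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    mean_rank = {g: ranks[labels == g].mean() for g in groups}
    sizes = {g: int(np.sum(labels == g)) for g in groups}
    m = len(groups) * (len(groups) - 1) // 2
    rows = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            g1, g2 = groups[a], groups[b]
            se = np.sqrt(var_base * (1.0 / sizes[g1] + 1.0 / sizes[g2]))
            z = (mean_rank[g1] - mean_rank[g2]) / se
            p_raw = 2.0 * stats.norm.sf(abs(z))
            rows.append({"group1": g1, "group2": g2, "z": float(z),
                         "p_raw": float(p_raw),
                         "p_bonferroni": float(min(1.0, p_raw * m))})
    return pd.DataFrame(rows)


@dataclass
class MetricComparison:
    omnibus: pd.DataFrame     # metric, F, p
    pairwise: pd.DataFrame    # metric, group1, group2, z, p_raw, p_bonferroni


def compare_metrics(metrics: pd.DataFrame, group_col: str,
                    metric_cols=("max_distance_km", "path_length_km",
                                 "core_area_km2"),
                    n_perm: int = N_PERM_ANOVA, seed: int = 0,
                    alpha: float = ALPHA) -> MetricComparison:
    """perANOVA per metric across the ``group_col`` cohorts; Dunn-Bonferroni
    pairwise tests wherever the omnibus permutation p is significant.

    Groups with fewer than two individuals are excluded with a warning.
    """
    counts = metrics[group_col].value_counts()
    small = counts[counts < 2].index.tolist()
    if small:
        warnings.warn(f"excluding group(s) with < 2 individuals: {small}")
        metrics = metrics[~metrics[group_col].isin(small)]
    omnibus_rows, pairwise_frames = [], []
    for mi, col in enumerate(metric_cols):
        sub = metrics.dropna(subset=[col])
        f, p = peranova(sub[col], sub[group_col], n_perm=n_perm,
                        seed=seed + mi)
        omnibus_rows.append({"metric": col, "F": f, "p": p,
                             "n_perm": n_perm})
        if p <= alpha and sub[group_col].nunique() >= 2:
            pw = dunn_test(sub[col].to_numpy(), sub[group_col].to_numpy())
            pw.insert(0, "metric", col)
            pairwise_frames.append(pw)
    pairwise = (pd.concat(pairwise_frames, ignore_index=True)
                if pairwise_frames else
                pd.DataFrame(columns=["metric", "group1", "group2", "z",
                                      "p_raw", "p_bonferroni"]))
    return MetricComparison(omnibus=pd.DataFrame(omnibus_rows),
                            pairwise=pairwise)
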