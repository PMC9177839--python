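"""Marine Important Bird Area (IBA) delineation from individual core areas.

For each data group with more than 10 tracked individuals: (1) the
fraction of individuals whose core range covers each grid cell is
computed; (2) cells where more than 10% of individuals' cores overlap
form the candidate site; (3) a bootstrap "representativeness" score asks
whether the tracked sample adequately captures the population's space use
(inclusion of left-out individuals' positions in cores built from
subsamples, extrapolated with a Michaelis-Menten curve; > 70% is deemed
representative); (4) candidate polygons are tidied by 5% rules (drop
isolated slivers, fill small holes, merge near-centroid pairs) and the
final site boundary is their minimum convex polygon.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .homerange import (DEFAULT_CELL_KM, DEFAULT_H_KM, GridSpec, UDGrid,
                        individual_ud_stack, isopleth_region,
                        mask_to_polygons)

MIN_IBA_INDIVIDUALS = 10       # site requires strictly more than this
CORE_OVERLAP_THRESHOLD = 0.10  # strictly more than 10% of cores overlap
REPRESENTATIVENESS_THRESHOLD = 70.0
AGGREGATION_FRACTION = 0.05


def individual_core_masks(points_by_individual, core_isopleth_pct: float,
                          h: float = DEFAULT_H_KM,
                          grid: GridSpec | None = None,
                          cell: float = DEFAULT_CELL_KM,
                          min_points: int = 5):
    """Boolean core-region masks for each individual on one common grid."""
    stack, grid = individual_ud_stack(points_by_individual, h=h, grid=grid,
                                      cell=cell, min_points=min_points)
    v = core_isopleth_pct / 100.0
    masks = np.zeros(stack.shape, dtype=bool)
    for i, dens in enumerate(stack):
        masks[i] = isopleth_region(UDGrid(grid=grid, density=dens, h=h),
                                   v).mask
    return masks, grid


def core_overlap_surface(core_masks: np.ndarray) -> np.ndarray:
    """Per-cell fraction of individuals whose core region covers the cell."""
    if core_masks.ndim != 3 or core_masks.shape[0] < 2:
        raise ValueError("need core masks of >= 2 individuals")
    return core_masks.mean(axis=0)


def candidate_site(surface: np.ndarray, grid: GridSpec,
                   threshold: float = CORE_OVERLAP_THRESHOLD):
    """Union of cells where the overlap fraction strictly exceeds the
    threshold, dissolved into polygons (plane km).  May be empty."""
    mask = surface > threshold
    return mask_to_polygons(mask, grid), mask


# ---------------------------------------------------------------------------
# Representativeness (bootstrap inclusion curve)


@dataclass
class RepresentativenessResult:
    score: float                  # percent, <= 100 by construction; NaN on failure
    n_individuals: int
    asymptote: float              # fitted Michaelis-Menten a
    half_saturation: float        # fitted Michaelis-Menten b
    inclusion_means: dict         # k -> mean inclusion rate
    diagnostic: str = ""

    @property
    def representative(self) -> bool:
        return self.score > REPRESENTATIVENESS_THRESHOLD


def representativeness(points_by_individual, core_isopleth_pct: float,
                       n_boot: int = 50, seed: int = 0,
                       h: float = DEFAULT_H_KM, cell: float = DEFAULT_CELL_KM,
                       k_values=None, min_points: int = 5,
                       min_individuals: int = MIN_IBA_INDIVIDUALS
                       ) -> RepresentativenessResult:
    """Bootstrap representativeness of a tracked sample.

    For each sample size k, ``n_boot`` random subsets of k individuals are
    pooled into a core region (at the cohort core isopleth) and scored by
    the fraction of the left-out individuals' positions falling inside
    it.  Mean inclusion versus k is fit with a saturating
    Michaelis-Menten curve y = a*k/(b+k); the score is
    100 * y(N)/a = 100 * N/(b+N) — the fraction of asymptotic space-use
    coverage achieved at the actual sample size N.

    Each individual carries equal weight regardless of track length, so
    unequal tracking durations are not accounted for (a known limitation
    of this procedure).
    """
    pts_list = [np.atleast_2d(np.asarray(p, float)) for p in points_by_individual]
    n = len(pts_list)
    if n <= min_individuals:
        raise ValueError(f"representativeness requires > {min_individuals} "
                         f"individuals (got {n})")
    stack, grid = individual_ud_stack(pts_list, h=h, cell=cell,
                                      min_points=min_points)
    cell_area = grid.cell_area
    v = core_isopleth_pct / 100.0
    # precompute each individual's positions as cell indices
    pos_cells = []
    for p in pts_list:
        iy, ix = grid.cell_index(p[:, 0], p[:, 1])
        pos_cells.append((iy, ix))
    rng = np.random.default_rng(seed)
    if k_values is None:
        k_values = range(1, n)
    inclusion_means = {}
    for k in k_values:
        vals = np.empty(n_boot)
        for b in range(n_boot):
            sample = rng.choice(n, size=k, replace=False)
            rest = np.setdiff1d(np.arange(n), sample)
            dens = stack[sample].mean(axis=0)
            flat = dens.ravel()
            order = np.argsort(-flat, kind="stable")
            cum = np.cumsum(flat[order]) * cell_area
            kk = int(np.searchsorted(cum, v * cum[-1], side="left")) + 1
            mask = np.zeros(flat.size, dtype=bool)
            mask[order[:kk]] = True
            mask = mask.reshape(dens.shape)
            inc = [mask[iy[iy >= 0], ix[iy >= 0]]
                   for iy, ix in (pos_cells[r] for r in rest)]
            vals[b] = float(np.mean(np.concatenate(inc)))
        inclusion_means[int(k)] = float(vals.mean())
    ks = np.array(sorted(inclusion_means), dtype=float)
    ys = np.array([inclusion_means[int(k)] for k in ks])
    try:
        (a, bmm), _ = curve_fit(lambda k, a, b: a * k / (b + k), ks, ys,
                                p0=[max(ys.max(), 1e-3), 1.0],
                                bounds=([1e-6, 1e-6], [2.0, 1e4]),
                                maxfev=10000)
        score = 100.0 * n / (bmm + n)
        diag = ""
    except RuntimeError as exc:  # fit failure
        a = bmm = float("nan")
        score = float("nan")
        diag = f"saturating-curve fit failed: {exc}"
    return RepresentativenessResult(score=float(score), n_individuals=n,
                                    asymptote=float(a),
                                    half_saturation=float(bmm),
                                    inclusion_means=inclusion_means,
                                    diagnostic=diag)


# ---------------------------------------------------------------------------
# Polygon aggregation and the final site


def _component_polygons(geom):
    if geom.is_empty:
        return []
    if isinstance(geom, Polygon):
        return [geom]
    return [g for g in geom.geoms if isinstance(g, Polygon)]


def aggregate_polygons(polygons, fraction: float = AGGREGATION_FRACTION):
    """Tidy candidate polygons by the 5% rules.

    Relative to the total area identified (the summed area of the input
    polygons): isolated polygons smaller than the fraction are dropped,
    holes smaller than the fraction are filled, and pairs of polygons
    whose centroid separation is below the fraction of the largest
    pairwise centroid distance are merged (replaced by their joint convex
    hull), iterating merges to closure.
    """
    polys = []
    for g in polygons:
        polys.extend(_component_polygons(g))
    if not polys:
        return []
    total = sum(p.area for p in polys)
    # 1) drop small isolated polygons
    kept = [p for p in polys if p.area >= fraction * total]
    if not kept:  # degenerate: nothing reaches the threshold, keep largest
        kept = [max(polys, key=lambda p: p.area)]
    # 2) fill small holes
    filled = []
    for p in kept:
        rings = [r for r in p.interiors
                 if Polygon(r).area >= fraction * total]
        filled.append(Polygon(p.exterior, rings))
    # 3) iterative merge of near-centroid pairs
    if len(filled) >= 2:
        cents = [p.centroid for p in filled]
        maxd = max(cents[i].distance(cents[j])
                   for i in range(len(cents)) for j in range(i + 1, len(cents)))
        thresh = fraction * maxd
        changed = True
        while changed and len(filled) >= 2:
            changed = False
            best = None
            for i in range(len(filled)):
                for j in range(i + 1, len(filled)):
                    d = filled[i].centroid.distance(filled[j].centroid)
                    if d < thresh and (best is None or d < best[0]):
                        best = (d, i, j)
            if best is not None:
                _, i, j = best
                merged = unary_union([filled[i], filled[j]]).convex_hull
                filled = [p for k, p in enumerate(filled) if k not in (i, j)]
                filled.append(merged)
                changed = True
    return filled


@dataclass
class IBASite:
    """A delineated site with its provenance."""
    colony: str
    stage: str
    polygon: object               # minimum convex polygon, plane km
    component_polygons: list      # aggregated polygons inside the MCP
    representativeness: float
    n_individuals: int
    thresholds: dict = field(default_factory=dict)
    polygon_lonlat: object = None

    @property
    def representative(self) -> bool:
        return (not np.isnan(self.representativeness)
                and self.representativeness > REPRESENTATIVENESS_THRESHOLD)

    @property
    def empty(self) -> bool:
        return self.polygon is None or self.polygon.is_empty


def final_site(polygons, representativeness_score: float, colony: str,
               stage: str, n_individuals: int, thresholds: dict | None = None,
               projection=None) -> IBASite:
    """Delimit the final site by the minimum convex polygon over the
    aggregated polygons' vertices.  A site failing the representativeness
    threshold is still emitted, flagged not-representative."""
    polys = list(polygons)
    mcp = unary_union(polys).convex_hull if polys else Polygon()
    lonlat = (projection.unproject_geometry(mcp)
              if projection is not None and not mcp.is_empty else None)
    site = IBASite(colony=colony, stage=stage, polygon=mcp,
                   component_polygons=polys,
                   representativeness=float(representativeness_score),
                   n_individuals=n_individuals,
                   thresholds=dict(thresholds or {}), polygon_lonlat=lonlat)
    if not site.representative:
        warnings.warn(f"site {colony}/{stage}: representativeness "
                      f"{representativeness_score:.1f}% <= "
                      f"{REPRESENTATIVENESS_THRESHOLD}%; flagged")
    return site


def delineate_iba(points_by_individual, colony: str, stage: str,
                  core_isopleth_pct: float, h: float = DEFAULT_H_KM,
                  cell: float = DEFAULT_CELL_KM,
                  overlap_threshold: float = CORE_OVERLAP_THRESHOLD,
                  n_boot: int = 50, seed: int = 0, k_values=None,
                  projection=None,
                  min_individuals: int = MIN_IBA_INDIVIDUALS) -> IBASite | None:
    """Full delineation for one data group; None if the group has too few
    individuals (strictly more than ``min_individuals`` required)."""
    n = len(points_by_individual)
    if n <= min_individuals:
        warnings.warn(f"group {colony}/{stage}: {n} individuals <= "
                      f"{min_individuals}; IBA not estimated")
        return None
    masks, grid = individual_core_masks(points_by_individual,
                                        core_isopleth_pct, h=h, cell=cell)
    surface = core_overlap_surface(masks)
    region, _ = candidate_site(surface, grid, threshold=overlap_threshold)
    rep = representativeness(points_by_individual, core_isopleth_pct,
                             n_boot=n_boot, seed=seed, h=h, cell=cell,
                             k_values=k_values,
                             min_individuals=min_individuals)
    polys = aggregate_polygons(_component_polygons(region))
    return final_site(polys, rep.score, colony, stage, n,
                      thresholds={"core_isopleth_pct": core_isopleth_pct,
                                  "overlap_threshold": overlap_threshold,
                                  "h_km": h, "cell_km": cell,
                                  "n_boot": n_boot},
                      projection=projection)
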