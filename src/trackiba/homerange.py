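"""Kernel utilisation distributions, isopleth regions and optimal-isopleth
value selection (OIVS).

A utilisation distribution (UD) is a probability surface over space; here
it is the fixed-bandwidth bivariate Gaussian kernel density of an
individual's daily at-sea positions, evaluated on a regular grid in the
shared projected plane with a smoothing factor h = 7 km.  The x% isopleth
is the smallest-area set of cells holding x% of the probability mass; the
core range is taken at the cohort-mean OIVS isopleth and the
distributional range at 90%.

OIVS picks the core isopleth from the shape of the area-versus-volume
curve: with both axes rescaled to [0, 1], the isopleth where the curve's
slope first drops to 1 (scanning from the 99% isopleth downward)
separates intensively used cells — which add mass faster than area — from
the diffuse tail.

Group (pooled) UDs weight each individual equally regardless of track
length, implemented as the arithmetic mean of the individuals' UDs on a
common grid, which is exactly the per-individual-weighted pooled kernel
density.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import shapely
from shapely.ops import unary_union

DEFAULT_H_KM = 7.0
DEFAULT_CELL_KM = 2.0
CORE_ISOPLETH_DEFAULT = 54  # cohort-mean OIVS reported for the reference study
DISTRIBUTION_ISOPLETH = 90


@dataclass(frozen=True)
class GridSpec:
    """Regular grid in the projected plane (km); origin is the lower-left
    cell edge and cells are squares of side ``cell``."""
    x0: float
    y0: float
    cell: float
    nx: int
    ny: int

    @property
    def cell_area(self) -> float:
        return self.cell * self.cell

    @property
    def x_centers(self) -> np.ndarray:
        return self.x0 + (np.arange(self.nx) + 0.5) * self.cell

    @property
    def y_centers(self) -> np.ndarray:
        return self.y0 + (np.arange(self.ny) + 0.5) * self.cell

    def cell_index(self, x, y):
        """Map plane coordinates to (iy, ix); -1 where outside the grid."""
        ix = np.floor((np.asarray(x, float) - self.x0) / self.cell).astype(int)
        iy = np.floor((np.asarray(y, float) - self.y0) / self.cell).astype(int)
        ok = (ix >= 0) & (ix < self.nx) & (iy >= 0) & (iy < self.ny)
        return np.where(ok, iy, -1), np.where(ok, ix, -1)


def make_grid(points, h: float = DEFAULT_H_KM, cell: float = DEFAULT_CELL_KM,
              pad_factor: float = 3.0) -> GridSpec:
    """Grid covering the points padded by ``pad_factor * h`` on every side,
    with the origin snapped to a multiple of ``cell`` so grids built from
    overlapping point sets align."""
    pts = np.asarray(points, dtype=float)
    pad = pad_factor * h
    x0 = np.floor((pts[:, 0].min() - pad) / cell) * cell
    y0 = np.floor((pts[:, 1].min() - pad) / cell) * cell
    nx = int(np.ceil((pts[:, 0].max() + pad - x0) / cell))
    ny = int(np.ceil((pts[:, 1].max() + pad - y0) / cell))
    return GridSpec(float(x0), float(y0), float(cell), nx, ny)


@dataclass
class UDGrid:
    """A gridded utilisation distribution (probability mass per km^2)."""
    grid: GridSpec
    density: np.ndarray          # (ny, nx), integrates to 1 over the grid
    h: float
    source: str = ""

    @property
    def total_mass(self) -> float:
        return float(self.density.sum() * self.grid.cell_area)

    def _mass_order(self):
        """Cells by descending density (stable tie-break on cell order) and
        the cumulative mass along that ordering."""
        flat = self.density.ravel()
        order = np.argsort(-flat, kind="stable")
        cum = np.cumsum(flat[order]) * self.grid.cell_area
        return order, cum


def kde_ud(points, h: float = DEFAULT_H_KM, grid: GridSpec | None = None,
           cell: float = DEFAULT_CELL_KM, pad_factor: float = 3.0,
           weights=None, min_points: int = 5, source: str = "") -> UDGrid:
    """Fixed-bandwidth bivariate Gaussian kernel UD on a regular grid.

    ``points`` are (x, y) km in the projected plane.  The density is
    evaluated at cell centres (the Gaussian kernel separates, so this is
    two small matrix products) and renormalized to unit mass over the
    grid.  Fewer than ``min_points`` positions is an error: a kernel
    home range from a handful of fixes is not meaningful.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if len(pts) < min_points:
        raise ValueError(f"need at least {min_points} positions, got {len(pts)}")
    if grid is None:
        grid = make_grid(pts, h=h, cell=cell, pad_factor=pad_factor)
    if weights is None:
        w = np.full(len(pts), 1.0 / len(pts))
    else:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
    # separable Gaussian: K((x,y)) = Kx(x) * Ky(y)
    dx = grid.x_centers[None, :] - pts[:, 0][:, None]      # (n, nx)
    dy = grid.y_centers[None, :] - pts[:, 1][:, None]      # (n, ny)
    kx = np.exp(-0.5 * (dx / h) ** 2)
    ky = np.exp(-0.5 * (dy / h) ** 2)
    density = (w[:, None] * ky).T @ kx                     # (ny, nx)
    density /= 2.0 * np.pi * h * h
    density /= density.sum() * grid.cell_area              # unit mass on grid
    return UDGrid(grid=grid, density=density, h=h, source=source)


@dataclass
class IsoplethRegion:
    """Smallest-area cell set containing a fraction ``v`` of the UD mass."""
    v: float
    ud: UDGrid
    mask: np.ndarray             # (ny, nx) bool
    area: float                  # km^2

    def contains_points(self, points) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        iy, ix = self.ud.grid.cell_index(pts[:, 0], pts[:, 1])
        inside = (iy >= 0)
        out = np.zeros(len(pts), dtype=bool)
        out[inside] = self.mask[iy[inside], ix[inside]]
        return out

    @cached_property
    def polygons(self):
        """Member cells dissolved into a shapely (Multi)Polygon (plane km)."""
        return mask_to_polygons(self.mask, self.ud.grid)


def mask_to_polygons(mask: np.ndarray, grid: GridSpec):
    iy, ix = np.nonzero(mask)
    if len(iy) == 0:
        return shapely.Polygon()
    boxes = shapely.box(grid.x0 + ix * grid.cell, grid.y0 + iy * grid.cell,
                        grid.x0 + (ix + 1) * grid.cell,
                        grid.y0 + (iy + 1) * grid.cell)
    return unary_union(boxes)


def isopleth_region(ud: UDGrid, v: float) -> IsoplethRegion:
    """The ``v`` (0 < v < 1) isopleth: cells sorted by density descending,
    accumulated until at least ``v`` of the mass is enclosed."""
    if not 0.0 < v < 1.0:
        raise ValueError("isopleth volume must be in (0, 1)")
    order, cum = ud._mass_order()
    k = int(np.searchsorted(cum, v * ud.total_mass, side="left")) + 1
    k = min(k, len(order))
    mask = np.zeros(ud.density.size, dtype=bool)
    mask[order[:k]] = True
    return IsoplethRegion(v=v, ud=ud, mask=mask.reshape(ud.density.shape),
                          area=k * ud.grid.cell_area)


def area_curve(ud: UDGrid, vs) -> np.ndarray:
    """Isopleth area (km^2) for each volume in ``vs`` in one sorted pass."""
    vs = np.asarray(vs, dtype=float)
    _, cum = ud._mass_order()
    ks = np.searchsorted(cum, vs * ud.total_mass, side="left") + 1
    ks = np.minimum(ks, len(cum))
    return ks * ud.grid.cell_area


def oivs(ud: UDGrid, vs=None) -> int:
    """Optimal isopleth value selection: integer percent in (0, 99].

    The empirical area-vs-volume curve for v = 0.01..0.99 is rescaled to
    [0, 1] on both axes (area by area(0.99), volume by 0.99); its slope is
    taken by central finite differences and scanned from v = 0.99
    downward; the largest v at which the slope first reaches 1 is the
    optimal isopleth.  Above it, area grows faster than mass (diffuse
    use); below it, mass accumulates faster than area (maximal use).
    """
    if vs is None:
        vs = np.arange(0.01, 0.995, 0.01)
    vs = np.asarray(vs, dtype=float)
    areas = area_curve(ud, vs)
    if np.any(np.diff(areas) < 0):
        raise ValueError("non-monotone isopleth area curve (grid pathology)")
    return _oivs_from_curve(vs, areas)


def _oivs_from_curve(vs: np.ndarray, areas: np.ndarray) -> int:
    """Slope-1 scan on a rescaled area-vs-volume curve (shared by the
    empirical path and any externally supplied analytic curve)."""
    a = areas / areas[-1]
    u = vs / vs[-1]
    slope = np.gradient(a, u)  # 3-point central differences
    for i in range(len(vs) - 1, -1, -1):
        if slope[i] <= 1.0:
            return int(round(vs[i] * 100))
    return int(round(vs[0] * 100))


def mean_core_isopleth(oivs_values) -> int:
    """Cohort core isopleth: arithmetic mean of per-individual OIVS values,
    rounded to the nearest integer percent; applied uniformly to every
    individual core area and group core range."""
    vals = np.asarray(list(oivs_values), dtype=float)
    if vals.size == 0:
        raise ValueError("no OIVS values supplied")
    return int(np.floor(vals.mean() + 0.5))


def individual_ud_stack(points_by_individual, h: float = DEFAULT_H_KM,
                        grid: GridSpec | None = None,
                        cell: float = DEFAULT_CELL_KM,
                        min_points: int = 5):
    """Per-individual UDs on one common grid.

    Returns ``(stack (n, ny, nx), grid)``; the common grid covers all
    individuals' points (padded by 3h) unless supplied.
    """
    pts_list = [np.atleast_2d(np.asarray(p, float)) for p in points_by_individual]
    if grid is None:
        grid = make_grid(np.vstack(pts_list), h=h, cell=cell)
    stack = np.stack([kde_ud(p, h=h, grid=grid, min_points=min_points).density
                      for p in pts_list])
    return stack, grid


def group_ud(points_by_individual, h: float = DEFAULT_H_KM,
             grid: GridSpec | None = None, cell: float = DEFAULT_CELL_KM,
             min_individuals: int = 5, source: str = "") -> UDGrid:
    """Pooled UD of a data group, each individual contributing equal mass.

    Requires at least ``min_individuals`` individuals — groups smaller
    than five birds are not pooled in this analysis.
    """
    pts_list = list(points_by_individual)
    if len(pts_list) < min_individuals:
        raise ValueError(f"data group has {len(pts_list)} individuals; "
                         f"need >= {min_individuals}")
    stack, grid = individual_ud_stack(pts_list, h=h, grid=grid, cell=cell)
    density = stack.mean(axis=0)
    density /= density.sum() * grid.cell_area
    return UDGrid(grid=grid, density=density, h=h, source=source)


def ud_to_ascii_grid(ud: UDGrid, path) -> None:
    """Write a UD as an ESRI ASCII grid (row order: north to south)."""
    g = ud.grid
    header = (f"ncols {g.nx}\nnrows {g.ny}\nxllcorner {g.x0}\n"
              f"yllcorner {g.y0}\ncellsize {g.cell}\nNODATA_value -9999\n")
    with open(path, "w") as fh:
        fh.write(header)
        for row in ud.density[::-1]:
            fh.write(" ".join(f"{v:.8e}" for v in row) + "\n")
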