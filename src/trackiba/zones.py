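"""Spatial-management overlays: zone overlap, colony-radius residency and
gridded fishing pressure.

Answers the management questions: how much of a delineated site falls
inside existing or proposed no-take zones, what fraction of a bird's time
is spent within 20/50 km of its colony, and where seasonal purse-seine
catch concentrates on a 0.16 degree grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import mapping, shape
from shapely.ops import unary_union

from .geo import AzimuthalEquidistant, great_circle_distance


@dataclass
class ZoneSet:
    """Named polygon layers in lon/lat degrees."""
    coastline: object = None          # shapely polygon (land)
    existing: list = field(default_factory=list)    # existing no-take zones
    proposed: list = field(default_factory=list)    # 20 km closure circles
    colony_names: list = field(default_factory=list)

    def to_geojson(self, path) -> None:
        import json
        feats = []
        if self.coastline is not None:
            feats.append({"type": "Feature", "geometry": mapping(self.coastline),
                          "properties": {"layer": "coastline"}})
        for g in self.existing:
            feats.append({"type": "Feature", "geometry": mapping(g),
                          "properties": {"layer": "existing_no_take"}})
        for name, g in zip(self.colony_names, self.proposed):
            feats.append({"type": "Feature", "geometry": mapping(g),
                          "properties": {"layer": "proposed_closure",
                                         "colony": name}})
        with open(path, "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh,
                      sort_keys=True)

    @classmethod
    def from_geojson(cls, path) -> "ZoneSet":
        import json
        with open(path) as fh:
            doc = json.load(fh)
        zs = cls()
        for feat in doc["features"]:
            layer = feat["properties"].get("layer")
            geom = shape(feat["geometry"])
            if layer == "coastline":
                zs.coastline = geom
            elif layer == "existing_no_take":
                zs.existing.append(geom)
            elif layer == "proposed_closure":
                zs.proposed.append(geom)
                zs.colony_names.append(feat["properties"].get("colony"))
        return zs


def iba_zone_overlap(site_polygon, zones: ZoneSet,
                     projection: AzimuthalEquidistant) -> dict:
    """Percentage of a site's area inside no-take zones.

    Reports overlap with the existing zones alone and with existing plus
    proposed closures combined.  ``site_polygon`` is lon/lat; areas are
    measured in the shared planar projection.  An empty site yields NaN.
    """
    if site_polygon is None or site_polygon.is_empty:
        return {"existing_pct": float("nan"), "existing_plus_proposed_pct": float("nan")}
    site = projection.project_geometry(site_polygon)
    out = {}
    for key, layers in (("existing_pct", zones.existing),
                        ("existing_plus_proposed_pct",
                         list(zones.existing) + list(zones.proposed))):
        if layers:
            zone = unary_union([projection.project_geometry(g) for g in layers])
            out[key] = 100.0 * site.intersection(zone).area / site.area
        else:
            out[key] = 0.0
    return out


def time_within_radius(trackset, colony_lonlat, radius_km: float,
                       include_land: bool) -> pd.DataFrame:
    """Per-bird percentage of fixes within ``radius_km`` of the colony.

    The denominator is all fixes (``include_land=True``) or at-sea fixes
    only; the numerator counts denominator fixes within the radius
    (great-circle).  Birds with an empty denominator are excluded.
    Returns one row per bird plus ``mean``/``sd`` attributes in
    ``DataFrame.attrs``.
    """
    lon0, lat0 = colony_lonlat
    rows = []
    for iid, track in trackset.itertracks():
        sub = track if include_land else track[~track["on_land"].astype(bool)]
        if len(sub) == 0:
            continue
        d = great_circle_distance(sub["lon"].to_numpy(), sub["lat"].to_numpy(),
                                  lon0, lat0)
        rows.append({"individual_id": iid,
                     "pct_within": 100.0 * float(np.mean(d <= radius_km)),
                     "n_fixes": len(sub)})
    out = pd.DataFrame(rows, columns=["individual_id", "pct_within", "n_fixes"])
    out.attrs["mean"] = float(out["pct_within"].mean()) if len(out) else float("nan")
    out.attrs["sd"] = float(out["pct_within"].std(ddof=1)) if len(out) > 1 else float("nan")
    out.attrs["radius_km"] = radius_km
    out.attrs["include_land"] = include_land
    return out


@dataclass
class CatchGrid:
    """Season-mean catch tonnage on a regular lon/lat grid."""
    resolution_deg: float
    origin: tuple                      # (lon0, lat0), integer degrees
    cells: pd.DataFrame                # ilon, ilat, mean_tonnage
    per_year: pd.DataFrame             # year, ilon, ilat, tonnage
    years: list

    def cell_bounds(self, ilon: int, ilat: int):
        res = self.resolution_deg
        lon0, lat0 = self.origin
        return (lon0 + ilon * res, lat0 + ilat * res,
                lon0 + (ilon + 1) * res, lat0 + (ilat + 1) * res)

    def to_csv(self, path) -> None:
        self.cells.to_csv(path, index=False)


def grid_catches(records: pd.DataFrame, years, months=range(9, 13),
                 resolution_deg: float = 0.16, excluded_years=()) -> CatchGrid:
    """Aggregate haul records into a seasonal catch grid.

    Per year, tonnage of hauls in ``months`` is summed into half-open
    ``resolution_deg`` cells anchored at integer degrees, then averaged
    across the retained years (a year with no hauls contributes zero).
    Hauls outside ``months`` or in ``excluded_years`` are skipped.
    """
    months = set(months)
    years = [y for y in years if y not in set(excluded_years)]
    if not years:
        raise ValueError("no years retained")
    df = records.copy()
    df["date"] = pd.to_datetime(df["date"], utc=True)
    df = df[df["date"].dt.year.isin(years) & df["date"].dt.month.isin(months)]
    lon0 = float(np.floor(df["lon"].min())) if len(df) else 0.0
    lat0 = float(np.floor(df["lat"].min())) if len(df) else 0.0
    df["ilon"] = np.floor((df["lon"] - lon0) / resolution_deg).astype(int)
    df["ilat"] = np.floor((df["lat"] - lat0) / resolution_deg).astype(int)
    df["year"] = df["date"].dt.year
    per_year = (df.groupby(["year", "ilon", "ilat"], as_index=False)["tonnage"]
                .sum())
    cells = (per_year.groupby(["ilon", "ilat"], as_index=False)["tonnage"]
             .sum())
    cells["mean_tonnage"] = cells["tonnage"] / len(years)
    cells = cells.drop(columns="tonnage").sort_values(["ilon", "ilat"],
                                                      ignore_index=True)
    return CatchGrid(resolution_deg=resolution_deg, origin=(lon0, lat0),
                     cells=cells, per_year=per_year, years=years)
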