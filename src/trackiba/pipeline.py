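"""End-to-end orchestration: simulate -> preprocess -> path metrics ->
UDs -> overlap inference -> IBA delineation -> management overlays ->
report.

Every stage's thresholds live in one :class:`RunConfig` with the analysis
defaults (12.4 km/h speed filter, h = 7 km, > 20 tracking days, > 48 h
moult rule, 90% distributional isopleth with the core isopleth taken as
the cohort-mean OIVS, > 10% core overlap, > 70% representativeness, 5%
aggregation rules, 20/50 km colony radii, 0.16 degree catch grid, 1000
overlap permutations, 5000 perANOVA permutations).  All randomness
derives from the configured seeds, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import homerange, iba, metrics, overlap, preprocess, zones
from .geo import region_projection, write_geojson
from .io import TrackSet
from .simulate import (SimulationConfig, demo_config, make_toy_layers,
                       simulate_catches, simulate_dataset)

STAGES = ("simulate", "preprocess", "metrics", "ud", "compare", "iba",
          "zones", "report")


@dataclass
class RunConfig:
    sim: SimulationConfig = None
    vmax_kmh: float = 12.4
    h_km: float = 7.0
    cell_km: float = 2.0
    min_days: int = 20
    moult_threshold_h: float = 48.0
    core_isopleth_pct: float | None = None   # None: cohort-mean OIVS
    distribution_isopleth_pct: float = 90.0
    overlap_threshold: float = 0.10
    aggregation_fraction: float = 0.05
    radii_km: tuple = (20.0, 50.0)
    catch_resolution_deg: float = 0.16
    catch_years: tuple = (2012, 2013, 2014, 2015, 2017, 2018, 2019)
    n_perm_overlap: int = 1000
    n_perm_anova: int = 5000
    n_boot_representativeness: int = 50
    min_group_individuals: int = 5
    min_iba_individuals: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.sim is None:
            self.sim = demo_config(seed=self.seed)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        sim_doc = doc.pop("sim", None)
        cfg = cls(**doc)
        if sim_doc is not None:
            from .simulate import (Colony, ErrorParams, GroupSpec,
                                   MoultParams, MovementParams, SamplingParams)
            for key, klass in (("movement", MovementParams),
                               ("sampling", SamplingParams),
                               ("error", ErrorParams), ("moult", MoultParams)):
                if key in sim_doc:
                    sim_doc[key] = klass(**sim_doc[key])
            if "colonies" in sim_doc:
                sim_doc["colonies"] = tuple(tuple(c) for c in sim_doc["colonies"])
            if "groups" in sim_doc:
                sim_doc["groups"] = tuple(tuple(g) for g in sim_doc["groups"])
            cfg.sim = SimulationConfig(**sim_doc)
        return cfg


def _config_dict(cfg) -> dict:
    def enc(obj):
        if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
            return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, (tuple, list)):
            return [enc(v) for v in obj]
        return obj
    return enc(cfg)


def _daily_xy(clean: preprocess.CleanTrack, projection) -> np.ndarray:
    sub = clean.daily.dropna(subset=["lon", "lat"])
    x, y = projection.forward(sub["lon"].to_numpy(), sub["lat"].to_numpy())
    return np.column_stack([x, y])


def run(config: RunConfig, outdir, until: str = "report") -> dict:
    """Execute the pipeline up to stage ``until``; write artifacts to
    ``outdir``; return the run report (also written as report.json)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stop = STAGES.index(until)
    report = {"seed": config.seed, "stages": {}, "config": _config_dict(config)}
    sim = config.sim
    proj = region_projection([(c.lon, c.lat) for c in sim.colonies])
    colony_positions = {c.name: (c.lon, c.lat) for c in sim.colonies}

    # -- simulate ----------------------------------------------------------
    trackset, truths = simulate_dataset(sim)
    layers = make_toy_layers(sim)
    lons = [c.lon for c in sim.colonies]
    lats = [c.lat for c in sim.colonies]
    bounds = (min(lons) - 3, min(lats) - 3, max(lons) + 3, max(lats) + 1)
    catches = simulate_catches(config.catch_years, 600, bounds,
                               seed=config.seed + 1)
    trackset.to_csv(outdir / "tracks.csv")
    layers.to_geojson(outdir / "zones.geojson")
    out_catches = catches.copy()
    out_catches["date"] = out_catches["date"].dt.strftime("%Y-%m-%d")
    out_catches.to_csv(outdir / "catches.csv", index=False)
    report["stages"]["simulate"] = {
        "n_individuals": len(trackset),
        "n_fixes": int(len(trackset.fixes)),
        "n_moulters_true": sum(t.moult_interval is not None
                               for t in truths.values()),
        "n_teleports_injected": sum(len(t.teleport_timestamps)
                                    for t in truths.values()),
    }
    if stop == 0:
        return _finish(report, outdir)

    # -- preprocess --------------------------------------------------------
    clean, prep_report = preprocess.preprocess_trackset(
        trackset, layers.coastline, colony_positions, proj,
        min_days=config.min_days, vmax=config.vmax_kmh,
        moult_threshold_h=config.moult_threshold_h)
    report["stages"]["preprocess"] = prep_report
    if stop == 1 or not clean:
        return _finish(report, outdir)

    # cohort core isopleth from per-individual OIVS
    xy_by_id = {iid: _daily_xy(ct, proj) for iid, ct in clean.items()}
    oivs_values = {}
    for iid, xy in xy_by_id.items():
        if len(xy) >= 5:
            ud = homerange.kde_ud(xy, h=config.h_km, cell=config.cell_km)
            oivs_values[iid] = homerange.oivs(ud)
    core_pct = (config.core_isopleth_pct if config.core_isopleth_pct
                is not None else homerange.mean_core_isopleth(
                    oivs_values.values()))
    report["stages"]["ud"] = {"oivs_by_individual": oivs_values,
                              "core_isopleth_pct": core_pct}

    # -- path metrics ------------------------------------------------------
    table = metrics.path_metrics_table(clean, colony_positions, proj,
                                       core_pct, h=config.h_km,
                                       cell=config.cell_km)
    table.to_csv(outdir / "path_metrics.csv", index=False)
    comparisons = {}
    pre = table[table["stage"] == "pre_moult"]
    if pre["colony"].nunique() >= 2:
        comparisons["pre_moult_colonies"] = metrics.compare_metrics(
            pre, "colony", n_perm=config.n_perm_anova, seed=config.seed + 11)
    for colony in sorted(table["colony"].unique()):
        sub = table[table["colony"] == colony]
        if sub["stage"].nunique() >= 2:
            comparisons[f"stages_at_{colony}"] = metrics.compare_metrics(
                sub, "stage", n_perm=config.n_perm_anova,
                seed=config.seed + 13)
    omnibus = pd.concat([c.omnibus.assign(contrast=name)
                         for name, c in comparisons.items()],
                        ignore_index=True) if comparisons else pd.DataFrame()
    pairwise = pd.concat([c.pairwise.assign(contrast=name)
                          for name, c in comparisons.items()],
                         ignore_index=True) if comparisons else pd.DataFrame()
    omnibus.to_csv(outdir / "metric_tests.csv", index=False)
    pairwise.to_csv(outdir / "metric_posthoc.csv", index=False)
    report["stages"]["metrics"] = {
        "n_individuals": int(len(table)),
        "contrasts": list(comparisons)}
    if stop == 2:
        return _finish(report, outdir)

    # -- group UDs ---------------------------------------------------------
    meta = {iid: clean[iid].daily.iloc[0] for iid in clean}
    data_groups = {}
    for iid in clean:
        key = (meta[iid]["colony"], meta[iid]["stage"], int(meta[iid]["year"]))
        data_groups.setdefault(key, []).append(iid)
    ud_rows = []
    for key in sorted(data_groups):
        ids = data_groups[key]
        if len(ids) < config.min_group_individuals:
            warnings.warn(f"data group {key}: {len(ids)} individuals < "
                          f"{config.min_group_individuals}; skipped")
            continue
        gud = homerange.group_ud([xy_by_id[i] for i in ids], h=config.h_km,
                                 cell=config.cell_km,
                                 min_individuals=config.min_group_individuals,
                                 source="/".join(map(str, key)))
        core_area = homerange.area_curve(gud, [core_pct / 100.0])[0]
        dist_area = homerange.area_curve(
            gud, [config.distribution_isopleth_pct / 100.0])[0]
        ud_rows.append({"colony": key[0], "stage": key[1], "year": key[2],
                        "n_individuals": len(ids),
                        "core_area_km2": core_area,
                        "distribution_area_km2": dist_area})
        homerange.ud_to_ascii_grid(
            gud, outdir / f"ud_{key[0].replace(' ', '_')}_{key[1]}_{key[2]}.asc")
    pd.DataFrame(ud_rows).to_csv(outdir / "group_uds.csv", index=False)
    if stop == 3:
        return _finish(report, outdir)

    # -- overlap comparisons ----------------------------------------------
    isopleths = (core_pct, config.distribution_isopleth_pct)
    overlap_rows = []
    eligible = {k: v for k, v in data_groups.items()
                if len(v) >= config.min_group_individuals}
    colonies_present = sorted({k[0] for k in eligible})
    contrasts = []
    for colony in colonies_present:  # stage contrasts within colony
        pre_keys = [k for k in eligible if k[0] == colony and k[1] == "pre_moult"]
        post_keys = [k for k in eligible if k[0] == colony and k[1] == "post_moult"]
        if pre_keys and post_keys:
            ids_a = sum((eligible[k] for k in pre_keys), [])
            ids_b = sum((eligible[k] for k in post_keys), [])
            contrasts.append((f"{colony}: pre vs post moult", ids_a, ids_b))
    for colony in colonies_present:  # year contrasts within colony+stage
        for stage in ("pre_moult", "post_moult"):
            keys = sorted(k for k in eligible
                          if k[0] == colony and k[1] == stage)
            for i in range(len(keys)):
                for j in range(i + 1, len(keys)):
                    contrasts.append((
                        f"{colony} {stage}: {keys[i][2]} vs {keys[j][2]}",
                        eligible[keys[i]], eligible[keys[j]]))
    for ci, (name, ids_a, ids_b) in enumerate(contrasts):
        for iso in isopleths:
            res = overlap.permutation_overlap_test(
                [xy_by_id[i] for i in ids_a], [xy_by_id[i] for i in ids_b],
                isopleth_pct=iso, n_perm=config.n_perm_overlap,
                seed=config.seed + 100 + ci, h=config.h_km,
                cell=config.cell_km,
                min_individuals=config.min_group_individuals)
            row = {"contrast": name, **res.as_dict(),
                   "significant": res.significant}
            overlap_rows.append(row)
    pd.DataFrame(overlap_rows).to_csv(outdir / "overlap_tests.csv", index=False)
    report["stages"]["compare"] = {"n_contrasts": len(contrasts)}
    if stop == 4:
        return _finish(report, outdir)

    # -- IBA delineation ---------------------------------------------------
    sites = []
    iba_groups = {}
    for iid in clean:
        key = (meta[iid]["colony"], meta[iid]["stage"])
        iba_groups.setdefault(key, []).append(iid)
    for gi, key in enumerate(sorted(iba_groups)):
        ids = iba_groups[key]
        if len(ids) <= config.min_iba_individuals:
            warnings.warn(f"IBA group {key}: {len(ids)} individuals <= "
                          f"{config.min_iba_individuals}; not estimated")
            continue
        site = iba.delineate_iba(
            [xy_by_id[i] for i in ids], colony=key[0], stage=key[1],
            core_isopleth_pct=core_pct, h=config.h_km, cell=config.cell_km,
            overlap_threshold=config.overlap_threshold,
            n_boot=config.n_boot_representativeness,
            seed=config.seed + 200 + gi, projection=proj,
            min_individuals=config.min_iba_individuals)
        if site is not None:
            sites.append(site)
    geoms = [s.polygon_lonlat for s in sites if s.polygon_lonlat is not None]
    props = [{"colony": s.colony, "stage": s.stage,
              "representativeness_pct": round(s.representativeness, 2),
              "n_individuals": s.n_individuals,
              "representative": s.representative, **s.thresholds}
             for s in sites if s.polygon_lonlat is not None]
    write_geojson(outdir / "iba_sites.geojson", geoms, props)
    report["stages"]["iba"] = {
        "sites": [{"colony": s.colony, "stage": s.stage,
                   "representativeness_pct": round(s.representativeness, 2),
                   "area_km2": round(s.polygon.area, 1),
                   "representative": s.representative} for s in sites]}
    if stop == 5:
        return _finish(report, outdir)

    # -- management overlays ----------------------------------------------
    zone_rows = []
    for s in sites:
        ov = zones.iba_zone_overlap(s.polygon_lonlat, layers, proj)
        zone_rows.append({"colony": s.colony, "stage": s.stage, **ov})
    pd.DataFrame(zone_rows).to_csv(outdir / "iba_zone_overlap.csv", index=False)
    resid_rows = []
    for key in sorted(iba_groups):
        ids = iba_groups[key]
        frames = [clean[i].daily_with_land.dropna(subset=["lon", "lat"])
                  for i in ids]
        ts = TrackSet(pd.concat(frames, ignore_index=True))
        for radius in config.radii_km:
            for include_land in (False, True):
                res = zones.time_within_radius(
                    ts, colony_positions[key[0]], radius, include_land)
                resid_rows.append({
                    "colony": key[0], "stage": key[1], "radius_km": radius,
                    "include_land": include_land,
                    "mean_pct": res.attrs["mean"], "sd_pct": res.attrs["sd"],
                    "n_birds": int(len(res))})
    pd.DataFrame(resid_rows).to_csv(outdir / "time_within_radius.csv",
                                    index=False)
    cg = zones.grid_catches(catches, config.catch_years,
                            resolution_deg=config.catch_resolution_deg,
                            excluded_years=(2016,))
    cg.to_csv(outdir / "catch_grid.csv")
    report["stages"]["zones"] = {
        "n_sites": len(zone_rows),
        "catch_cells": int(len(cg.cells)),
        "catch_total_mean_tonnage": float(cg.cells["mean_tonnage"].sum())}
    return _finish(report, outdir)


def _finish(report: dict, outdir: Path) -> dict:
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
    return report
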