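"""Synthetic central-place foraging tracks and toy spatial layers.

The generator emulates the statistical structure of non-breeding penguin
tracking data: multi-day foraging trips from one or more coastal colonies,
a biased correlated random walk at sea (gamma step lengths, von Mises
turning angles, homing bias that strengthens toward the end of the trip),
overnight roosts ashore, an optional terminal moult haul-out of more than
48 h, two device sampling regimes (hourly GPS fixes versus one fix per
night window for PTT-class tags), and occasional erroneous "teleport"
fixes whose implied transit speed violates the 12.4 km/h plausibility
bound.  Every injected artefact is logged in a :class:`TruthRecord` so
downstream cleaning stages can be scored against ground truth.

Land is a toy half-plane: everything at latitude >= ``coast_lat`` is land
and colonies sit on the coastline.  Real bathymetry, prey fields and
behavioural state switching are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import Point, box

from .geo import region_projection
from .zones import ZoneSet

HOUR = pd.Timedelta(hours=1)


@dataclass(frozen=True)
class Colony:
    name: str
    lon: float
    lat: float


@dataclass(frozen=True)
class GroupSpec:
    """A (colony, stage, year) cohort of simulated individuals."""
    colony: str
    stage: str  # "pre_moult" | "post_moult"
    year: int
    n_individuals: int
    range_scale: float = 1.0  # multiplies mean step length for this group

    def __post_init__(self):
        if self.stage not in ("pre_moult", "post_moult"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")


@dataclass(frozen=True)
class MovementParams:
    """Biased correlated random walk parameters.

    African-penguin travel speeds at sea are a few km/h; the per-step cap
    stays well below the 12.4 km/h error threshold so that clean tracks
    never trigger the speed filter.
    """
    step_speed_mean_kmh: float = 2.2
    step_speed_max_kmh: float = 8.0
    turn_concentration: float = 4.0   # von Mises kappa
    homing_bias: float = 0.25         # directional bias weight
    trip_duration_mean_days: float = 32.0
    trip_duration_sd_days: float = 7.0


@dataclass(frozen=True)
class SamplingParams:
    regime: str = "hourly"            # "hourly" | "night_only"
    window: tuple = (21, 22)          # [start, end) hour GMT for night_only

    def __post_init__(self):
        if self.regime not in ("hourly", "night_only"):
            raise ValueError(f"unknown sampling regime {self.regime!r}")


@dataclass(frozen=True)
class ErrorParams:
    teleport_rate: float = 0.0
    teleport_displacement_km: float = 300.0


@dataclass(frozen=True)
class MoultParams:
    p_haulout: float = 0.5            # probability of a terminal >48 h haul-out
    duration_h: tuple = (60.0, 96.0)
    p_home_colony: float = 0.75       # moult at deployment colony vs another


@dataclass(frozen=True)
class SimulationConfig:
    colonies: tuple
    groups: tuple
    movement: MovementParams = MovementParams()
    sampling: SamplingParams = SamplingParams()
    error: ErrorParams = ErrorParams()
    moult: MoultParams = MoultParams()
    coast_lat: float = -33.3          # land is lat >= coast_lat
    roost_radius_km: float = 15.0
    p_roost: float = 0.25
    existing_zones: tuple = ()        # (lonmin, latmin, lonmax, latmax) rects
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "colonies",
                           tuple(Colony(*c) if not isinstance(c, Colony) else c
                                 for c in self.colonies))
        object.__setattr__(self, "groups",
                           tuple(GroupSpec(*g) if not isinstance(g, GroupSpec) else g
                                 for g in self.groups))
        names = {c.name for c in self.colonies}
        for g in self.groups:
            if g.colony not in names:
                raise ValueError(f"group colony {g.colony!r} not in colonies")
        if self.movement.step_speed_max_kmh >= 12.4:
            raise ValueError("step speed bound must stay below 12.4 km/h")

    def colony(self, name: str) -> Colony:
        for c in self.colonies:
            if c.name == name:
                return c
        raise KeyError(name)

    def individual_ids(self):
        """Deterministic id -> (group, index-in-group) mapping."""
        out = {}
        for gi, g in enumerate(self.groups):
            for i in range(g.n_individuals):
                iid = f"{g.colony}_{g.stage}_{g.year}_{i:02d}"
                out[iid] = (gi, i)
        return out


@dataclass
class TruthRecord:
    """Ground truth for one simulated individual, for scoring cleaning stages."""
    individual_id: str
    group: GroupSpec
    trip_intervals: list = field(default_factory=list)   # (start, end) at sea
    moult_interval: tuple | None = None                  # (start, end) ashore
    moult_colony: str | None = None
    teleport_timestamps: list = field(default_factory=list)
    params: dict = field(default_factory=dict)


def _deployment_start(group: GroupSpec) -> pd.Timestamp:
    # pre-moult tags go out Aug-Oct, post-moult tags in November
    month, day = (9, 15) if group.stage == "pre_moult" else (11, 15)
    return pd.Timestamp(year=group.year, month=month, day=day, hour=6, tz="UTC")


def _simulate_raw(config: SimulationConfig, group: GroupSpec, rng):
    """Hourly ground-truth path before sampling thinning or error injection.

    Returns (timestamps, x, y, on_land, truth fields) in the region plane.
    """
    proj = region_projection([(c.lon, c.lat) for c in config.colonies])
    mv = config.movement
    home = config.colony(group.colony)
    hx, hy = proj.forward(home.lon, home.lat)
    colony_xy = {c.name: proj.forward(c.lon, c.lat) for c in config.colonies}
    # coastline in the plane: land where projected latitude >= coast_lat
    _, y_coast = proj.forward(home.lon, config.coast_lat)

    sd = max(mv.trip_duration_sd_days, 1e-6)
    shape_k = (mv.trip_duration_mean_days / sd) ** 2
    scale = mv.trip_duration_mean_days / shape_k
    n_hours = int(round(max(3.0, rng.gamma(shape_k, scale)) * 24))

    step_mean = mv.step_speed_mean_kmh * group.range_scale
    # gamma(shape 2) hourly steps, clipped to the plausibility cap
    steps = np.minimum(rng.gamma(2.0, step_mean / 2.0, size=n_hours),
                       mv.step_speed_max_kmh)
    turns = rng.vonmises(0.0, mv.turn_concentration, size=n_hours)
    outbound_heading = rng.uniform(np.pi, 2 * np.pi)  # seaward (dy < 0)

    t0 = _deployment_start(group)
    times = [t0]
    xs, ys, land = [float(hx)], [float(hy)], [True]
    heading = outbound_heading
    trips, trip_start = [], None
    at_sea = False
    t = t0
    i = 0
    while i < n_hours:
        t = t + HOUR
        frac = i / n_hours
        # homing bias ramps up over the final third of the trip
        if frac > 2 / 3:
            w = mv.homing_bias + (1 - mv.homing_bias) * (3 * frac - 2) ** 2
            target = np.arctan2(hy - ys[-1], hx - xs[-1])
        else:
            w = mv.homing_bias * 0.5
            target = outbound_heading
        vx = (1 - w) * np.cos(heading) + w * np.cos(target)
        vy = (1 - w) * np.sin(heading) + w * np.sin(target)
        heading = np.arctan2(vy, vx) + turns[i]
        nx = xs[-1] + steps[i] * np.cos(heading)
        ny = ys[-1] + steps[i] * np.sin(heading)
        if ny >= y_coast:  # bounce off the coastline
            ny = ys[-1] - abs(steps[i] * np.sin(heading))
            heading = np.arctan2(ny - ys[-1], nx - xs[-1])
        times.append(t)
        xs.append(float(nx))
        ys.append(float(ny))
        land.append(False)
        if not at_sea:
            at_sea, trip_start = True, t
        i += 1
        # overnight roost ashore when near a colony at 22:00 GMT; the snap
        # to the colony point must stay within one hour's plausible travel
        snap_km = min(config.roost_radius_km, 0.9 * mv.step_speed_max_kmh)
        if t.hour == 22 and i < n_hours:
            near = [(name, xy) for name, xy in colony_xy.items()
                    if np.hypot(xy[0] - nx, xy[1] - ny) <= snap_km]
            if near and rng.random() < config.p_roost:
                name, (cx, cy) = near[rng.integers(len(near))]
                if at_sea:
                    trips.append((trip_start, t))
                    at_sea = False
                for _ in range(int(rng.integers(5, 9))):
                    if i >= n_hours:
                        break
                    t = t + HOUR
                    times.append(t)
                    xs.append(float(cx))
                    ys.append(float(cy))
                    land.append(True)
                    i += 1
                xs[-1], ys[-1] = float(cx), float(cy)
    if at_sea:
        trips.append((trip_start, times[-1]))

    # terminal moult haul-out (> 48 h continuously ashore); the bird swims
    # to the moult colony first, so no implausible transit speed appears
    moult_interval = moult_colony = None
    if rng.random() < config.moult.p_haulout:
        if rng.random() < config.moult.p_home_colony or len(config.colonies) == 1:
            moult_colony = group.colony
        else:
            others = [c.name for c in config.colonies if c.name != group.colony]
            moult_colony = others[rng.integers(len(others))]
        mx, my = colony_xy[moult_colony]
        v_transit = 0.8 * mv.step_speed_max_kmh
        while np.hypot(mx - xs[-1], my - ys[-1]) > v_transit:
            d = np.hypot(mx - xs[-1], my - ys[-1])
            t = t + HOUR
            times.append(t)
            xs.append(float(xs[-1] + v_transit * (mx - xs[-1]) / d))
            ys.append(float(ys[-1] + v_transit * (my - ys[-1]) / d))
            land.append(False)
        if trips and at_sea:
            trips[-1] = (trips[-1][0], times[-1])
        dur = rng.uniform(*config.moult.duration_h)
        n_moult = int(np.ceil(dur)) + 1
        start = times[-1] + HOUR
        for k in range(n_moult):
            times.append(start + k * HOUR)
            xs.append(float(mx))
            ys.append(float(my))
            land.append(True)
        # a roost directly before the haul-out keeps the bird continuously
        # ashore: the true interval starts with that contiguous land run
        first = len(land) - n_moult
        while first > 0 and land[first - 1]:
            first -= 1
        moult_interval = (times[first], times[-1])

    lon, lat = proj.inverse(np.array(xs), np.array(ys))
    return (pd.DatetimeIndex(times), lon, lat, np.array(land),
            trips, moult_interval, moult_colony, proj)


def _apply_sampling(df: pd.DataFrame, sampling: SamplingParams) -> pd.DataFrame:
    if sampling.regime == "hourly":
        return df
    lo, hi = sampling.window
    hours = df["timestamp"].dt.hour
    in_window = (hours >= lo) & (hours < hi)
    sub = df[in_window]
    # at most one fix per night window: keep the first fix of each window
    night = sub["timestamp"].dt.floor("D")
    return sub.groupby(night, sort=False).head(1).reset_index(drop=True)


def _inject_teleports(df, truth, error: ErrorParams, proj, y_coast, rng):
    n = len(df)
    if error.teleport_rate <= 0 or n < 3:
        return df
    candidates = np.flatnonzero(~df["on_land"].to_numpy()[1:-1]) + 1
    n_tel = rng.binomial(len(candidates), error.teleport_rate)
    if n_tel == 0:
        return df
    chosen = np.sort(rng.choice(candidates, size=n_tel, replace=False))
    # keep at least two genuine fixes between errors, so every injected
    # fix is isolated and violates against both of its true neighbours
    keep = [chosen[0]]
    for c in chosen[1:]:
        if c - keep[-1] > 2:
            keep.append(c)
    df = df.copy()
    x, y = proj.forward(df["lon"].to_numpy(), df["lat"].to_numpy())
    ts = df["timestamp"].to_numpy()
    for idx in keep:
        dt_prev = (ts[idx] - ts[idx - 1]) / np.timedelta64(1, "h")
        dt_next = (ts[idx + 1] - ts[idx]) / np.timedelta64(1, "h")
        d_prev = np.hypot(x[idx] - x[idx - 1], y[idx] - y[idx - 1])
        d_next = np.hypot(x[idx + 1] - x[idx], y[idx + 1] - y[idx])
        need = 12.4 * max(dt_prev, dt_next) * 1.5 + max(d_prev, d_next) + 50.0
        disp = max(error.teleport_displacement_km, need)
        ang = rng.uniform(np.pi, 2 * np.pi)  # displace seaward
        tx = x[idx] + disp * np.cos(ang)
        ty = min(y[idx] + disp * np.sin(ang), y_coast - 1.0)
        lon_t, lat_t = proj.inverse(tx, ty)
        df.iloc[idx, df.columns.get_loc("lon")] = float(lon_t)
        df.iloc[idx, df.columns.get_loc("lat")] = float(lat_t)
        truth.teleport_timestamps.append(pd.Timestamp(ts[idx]))
    return df


def simulate_track(config: SimulationConfig, individual_id: str):
    """Simulate one individual's track.

    Returns ``(fixes DataFrame, TruthRecord)``.  The frame has the standard
    track columns plus an ``on_land`` ground-truth flag.  Deterministic for
    a fixed config seed, independent of simulation order.
    """
    ids = config.individual_ids()
    if individual_id not in ids:
        raise KeyError(f"unknown individual_id {individual_id!r}")
    gi, i = ids[individual_id]
    group = config.groups[gi]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, gi, i]))

    (times, lon, lat, land, trips, moult_interval, moult_colony,
     proj) = _simulate_raw(config, group, rng)
    device = "GPS-GSM" if config.sampling.regime == "hourly" else "PTT"
    df = pd.DataFrame({
        "individual_id": individual_id,
        "timestamp": times,
        "lon": lon,
        "lat": lat,
        "colony": group.colony,
        "stage": group.stage,
        "year": group.year,
        "device": device,
        "on_land": land,
    })
    truth = TruthRecord(
        individual_id=individual_id, group=group,
        trip_intervals=trips, moult_interval=moult_interval,
        moult_colony=moult_colony,
        params={"step_speed_mean_kmh":
                config.movement.step_speed_mean_kmh * group.range_scale})
    df = _apply_sampling(df, config.sampling)
    _, y_coast = proj.forward(config.colony(group.colony).lon, config.coast_lat)
    df = _inject_teleports(df, truth, config.error, proj, y_coast, rng)
    return df.reset_index(drop=True), truth


def simulate_dataset(config: SimulationConfig):
    """Simulate every configured individual.

    Returns ``(TrackSet, dict of TruthRecord by individual id)``.
    """
    from .io import TrackSet
    frames, truths = [], {}
    for iid in config.individual_ids():
        df, truth = simulate_track(config, iid)
        frames.append(df)
        truths[iid] = truth
    return TrackSet(pd.concat(frames, ignore_index=True)), truths


def make_toy_layers(config: SimulationConfig) -> ZoneSet:
    """Toy coastline, existing no-take rectangles and proposed 20 km closures.

    The closures are 20-km-radius circles around each colony, constructed in
    the region plane and inverse-projected to lon/lat.
    """
    proj = region_projection([(c.lon, c.lat) for c in config.colonies])
    lons = [c.lon for c in config.colonies]
    coastline = box(min(lons) - 10.0, config.coast_lat,
                    max(lons) + 10.0, config.coast_lat + 5.0)
    existing = [box(*rect) for rect in config.existing_zones]
    proposed = []
    for c in config.colonies:
        cx, cy = proj.forward(c.lon, c.lat)
        circle = Point(cx, cy).buffer(20.0, quad_segs=90)
        proposed.append(proj.unproject_geometry(circle))
    return ZoneSet(coastline=coastline, existing=existing, proposed=proposed,
                   colony_names=[c.name for c in config.colonies])


def simulate_catches(years, n_hauls, bounds, seed, n_clusters=3):
    """Synthetic purse-seine haul records.

    ``bounds`` is (lonmin, latmin, lonmax, latmax).  Hauls fall in the
    September-December season, clustered around ``n_clusters`` random
    centres (pass 0 for uniform), with lognormal tonnage and a random
    sardine/anchovy label.
    """
    lonmin, latmin, lonmax, latmax = bounds
    if not (lonmax > lonmin and latmax > latmin):
        raise ValueError("degenerate bounds")
    rng = np.random.default_rng(seed)
    years = list(years)
    yr = rng.choice(years, size=n_hauls)
    month = rng.integers(9, 13, size=n_hauls)
    day = rng.integers(1, 29, size=n_hauls)
    dates = pd.to_datetime({"year": yr, "month": month, "day": day}, utc=True)
    if n_clusters and n_clusters > 0:
        centres = np.column_stack([rng.uniform(lonmin, lonmax, n_clusters),
                                   rng.uniform(latmin, latmax, n_clusters)])
        which = rng.integers(n_clusters, size=n_hauls)
        spread = 0.15 * min(lonmax - lonmin, latmax - latmin)
        lon = np.clip(centres[which, 0] + rng.normal(0, spread, n_hauls),
                      lonmin, lonmax)
        lat = np.clip(centres[which, 1] + rng.normal(0, spread, n_hauls),
                      latmin, latmax)
    else:
        lon = rng.uniform(lonmin, lonmax, n_hauls)
        lat = rng.uniform(latmin, latmax, n_hauls)
    tonnage = rng.lognormal(mean=1.5, sigma=1.0, size=n_hauls)
    species = rng.choice(["sardine", "anchovy"], size=n_hauls)
    return pd.DataFrame({"date": dates, "lon": lon, "lat": lat,
                         "tonnage": tonnage, "species": species})


def demo_config(seed=0, **overrides) -> SimulationConfig:
    """Reference two-colony demonstration study: 2 colonies x 2 stages,
    12 birds per data group, hourly sampling, one existing no-take rectangle."""
    cfg = dict(
        colonies=(Colony("West Island", 18.1, -33.3),
                  Colony("East Island", 21.5, -33.3)),
        groups=(GroupSpec("West Island", "pre_moult", 2018, 12, 1.0),
                GroupSpec("West Island", "post_moult", 2018, 12, 0.8),
                GroupSpec("East Island", "pre_moult", 2018, 12, 0.7),
                GroupSpec("East Island", "post_moult", 2018, 12, 0.9)),
        sampling=SamplingParams("hourly"),
        error=ErrorParams(teleport_rate=0.005),
        existing_zones=((17.6, -34.1, 18.4, -33.5),),
        seed=seed,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)
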