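"""Track cleaning: speed filter, land flagging, trip segmentation, moult
detection, tracking-day inclusion rule and daily regularization.

The stages mirror the standard cleaning sequence for PTT/GPS seabird
tracks: implausible fixes are removed on a 12.4 km/h transit-speed
criterion, fixes ashore are flagged and excluded from at-sea analyses,
tracks are split into trips between land-based events, a continuous spell
of more than 48 h ashore is read as the start of moult, tracks followed
for more than 20 full calendar days are retained, and every track is
down-sampled / linearly interpolated to one position per day so hourly
GPS and night-only PTT regimes are comparable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely

from .geo import AzimuthalEquidistant, great_circle_distance

VMAX_KMH = 12.4
MOULT_THRESHOLD_H = 48.0
MIN_TRACKING_DAYS = 20
DAILY_REF_HOUR = 12
MAX_INTERP_GAP_DAYS = 3.0
COLONY_RADIUS_M = 500.0


@dataclass
class Trip:
    """A maximal run of consecutive at-sea fixes."""
    individual_id: str
    fixes: pd.DataFrame
    start: pd.Timestamp
    end: pd.Timestamp
    complete: bool = False  # ended by a detected moult


@dataclass
class MoultEvent:
    start: pd.Timestamp
    end: pd.Timestamp
    colony: str | None = None

    @property
    def duration_h(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)


def _implied_speeds(track: pd.DataFrame) -> np.ndarray:
    """Speed (km/h) between consecutive fixes; length len(track)-1."""
    lon = track["lon"].to_numpy()
    lat = track["lat"].to_numpy()
    ts = track["timestamp"].to_numpy()
    d = great_circle_distance(lon[:-1], lat[:-1], lon[1:], lat[1:])
    dt = (ts[1:] - ts[:-1]) / np.timedelta64(1, "h")
    with np.errstate(divide="ignore"):
        return np.where(dt > 0, d / np.where(dt > 0, dt, 1.0), np.inf)


def speed_filter(track: pd.DataFrame, vmax: float = VMAX_KMH):
    """Remove fixes implying transit speeds above ``vmax``.

    Iterative worst-violator removal: while any consecutive pair implies a
    speed over the threshold, the pair with the largest speed is located
    and the endpoint whose removal best eliminates the violation is
    deleted.  A genuinely erroneous fix violates against both neighbours,
    so removing it "bridges" its neighbours at a plausible speed, whereas
    removing its victim does not; if both (or neither) removal resolves
    the bridge, the one leaving the smaller residual local violation is
    preferred.  This removes exactly the bad fixes even when two
    erroneous fixes flank one good fix, or when the error sits at a track
    end.

    Returns ``(filtered track, removed fixes)``.  A track reduced below
    two fixes triggers a degenerate-track warning and is returned empty.
    """
    track = track.reset_index(drop=True)
    keep = track.copy()
    removed_idx = []

    def bridged_speed(frame, k):
        """Implied speed between fix k's neighbours once k is removed;
        removing a terminal fix creates no new pair (speed 0)."""
        if k == 0 or k == len(frame) - 1:
            return 0.0
        a, b = frame.iloc[k - 1], frame.iloc[k + 1]
        d = float(great_circle_distance(a["lon"], a["lat"], b["lon"], b["lat"]))
        dt = (b["timestamp"] - a["timestamp"]) / pd.Timedelta(hours=1)
        return d / dt if dt > 0 else np.inf

    while len(keep) >= 2:
        speeds = _implied_speeds(keep)
        worst = int(np.argmax(speeds))
        if speeds[worst] <= vmax:
            break
        i, j = worst, worst + 1
        bridge_i, bridge_j = bridged_speed(keep, i), bridged_speed(keep, j)
        if (bridge_i <= vmax) != (bridge_j <= vmax):
            # exactly one removal resolves the violation in place
            drop = i if bridge_i <= vmax else j
        else:
            # residual local violation left behind by each removal
            cost_i = max(bridge_i, speeds[j] if j < len(speeds) else 0.0)
            cost_j = max(bridge_j, speeds[i - 1] if i - 1 >= 0 else 0.0)
            drop = i if cost_i < cost_j else j
        removed_idx.append(keep.index[drop])
        keep = keep.drop(keep.index[drop])
    removed = track.loc[removed_idx]
    if len(keep) < 2:
        warnings.warn(f"track {track['individual_id'].iat[0] if len(track) else '?'} "
                      "degenerate after speed filtering; dropped")
        keep = keep.iloc[0:0]
    return keep.reset_index(drop=True), removed.reset_index(drop=True)


def flag_land(track: pd.DataFrame, coastline, colony_positions,
              radius_m: float = COLONY_RADIUS_M) -> pd.DataFrame:
    """Set the ``on_land`` flag: inside the land polygon, or within
    ``radius_m`` of a colony point (GPS scatter around haul-outs)."""
    if coastline is None:
        raise ValueError("coastline polygon is required for land flagging")
    pts = shapely.points(track["lon"].to_numpy(), track["lat"].to_numpy())
    on_land = shapely.covers(coastline, pts)
    for lon0, lat0 in colony_positions:
        d = great_circle_distance(track["lon"].to_numpy(),
                                  track["lat"].to_numpy(), lon0, lat0)
        on_land |= d <= radius_m / 1000.0
    out = track.copy()
    out["on_land"] = on_land
    return out


def split_trips(track: pd.DataFrame, min_fixes: int = 2):
    """Split a land-flagged track into trips between land-based events.

    Returns ``(trips, n_discarded)`` where trips are maximal runs of
    consecutive at-sea fixes and runs shorter than ``min_fixes`` are
    discarded.
    """
    at_sea = ~track["on_land"].to_numpy(dtype=bool)
    trips, discarded = [], 0
    if len(track) == 0:
        return trips, discarded
    boundaries = np.flatnonzero(np.diff(at_sea.astype(int)) != 0) + 1
    segments = np.split(np.arange(len(track)), boundaries)
    iid = track["individual_id"].iat[0]
    for seg in segments:
        if len(seg) == 0 or not at_sea[seg[0]]:
            continue
        if len(seg) < min_fixes:
            discarded += 1
            continue
        fixes = track.iloc[seg].reset_index(drop=True)
        trips.append(Trip(individual_id=iid, fixes=fixes,
                          start=fixes["timestamp"].iat[0],
                          end=fixes["timestamp"].iat[-1]))
    return trips, discarded


def detect_moult(track: pd.DataFrame, colony_positions=None,
                 threshold_h: float = MOULT_THRESHOLD_H):
    """First maximal on-land interval longer than ``threshold_h`` (48 h).

    Interprets a continuous spell ashore of more than two days as the
    catastrophic moult haul-out.  Returns a :class:`MoultEvent` (with the
    nearest colony if ``colony_positions`` is a name -> (lon, lat)
    mapping) or None.  A land run broken by any at-sea fix does not
    qualify, so moult is not detectable under sparse night-only sampling.
    """
    on_land = track["on_land"].to_numpy(dtype=bool)
    if not on_land.any():
        return None
    boundaries = np.flatnonzero(np.diff(on_land.astype(int)) != 0) + 1
    for seg in np.split(np.arange(len(track)), boundaries):
        if len(seg) == 0 or not on_land[seg[0]]:
            continue
        start = track["timestamp"].iloc[seg[0]]
        end = track["timestamp"].iloc[seg[-1]]
        if (end - start) > pd.Timedelta(hours=threshold_h):
            colony = None
            if colony_positions:
                mlon = track["lon"].iloc[seg].mean()
                mlat = track["lat"].iloc[seg].mean()
                colony = min(colony_positions,
                             key=lambda n: float(great_circle_distance(
                                 mlon, mlat, *colony_positions[n])))
            return MoultEvent(start=start, end=end, colony=colony)
    return None


def tracking_days(track: pd.DataFrame, moult: MoultEvent | None = None) -> int:
    """Number of full calendar dates tracked.

    Counted from the first at-sea fix to the last at-sea fix before the
    moult haul-out (if one was detected) or the last transmitted fix.  A
    date counts only if its full 24 h lie inside that interval.
    """
    at_sea = track[~track["on_land"].astype(bool)]
    if at_sea.empty:
        return 0
    start = at_sea["timestamp"].iat[0]
    if moult is not None:
        before = at_sea[at_sea["timestamp"] < moult.start]
        if before.empty:
            return 0
        end = before["timestamp"].iat[-1]
    else:
        end = track["timestamp"].iat[-1]
    first_full = start.ceil("D")
    last_full = (end - pd.Timedelta(days=1)).floor("D")
    return max(0, (last_full - first_full).days + 1)


def select_tracks(trackset, n_days_by_id: dict, min_days: int = MIN_TRACKING_DAYS):
    """Keep tracks followed for strictly more than ``min_days`` full days.

    Returns ``(selected TrackSet, excluded ids)``.
    """
    keep = [iid for iid in trackset.ids if n_days_by_id.get(iid, 0) > min_days]
    excluded = [iid for iid in trackset.ids if iid not in set(keep)]
    if not keep:
        warnings.warn("no tracks exceed the minimum tracking duration")
    return trackset.subset(keep) if keep else None, excluded


def regularize_daily(track: pd.DataFrame, projection: AzimuthalEquidistant,
                     include_land: bool = False,
                     ref_hour: int = DAILY_REF_HOUR,
                     max_gap_days: float = MAX_INTERP_GAP_DAYS) -> pd.DataFrame:
    """Down-sample / linearly interpolate to one position per calendar day.

    Positions are interpolated in the shared projected plane at a fixed
    daily reference instant (``ref_hour``:00 UTC, midpoint between the
    night-only and hourly regimes); the reference instants before the
    first or after the last fix clamp to that endpoint fix.  Days whose
    bracketing fixes straddle a gap longer than ``max_gap_days`` are
    emitted with ``gap=True`` and NaN coordinates rather than invented
    straight-line transits.  When ``include_land`` is set, all fixes feed
    the interpolation and each day carries the land flag of the fix
    nearest its reference instant.
    """
    sub = track if include_land else track[~track["on_land"].astype(bool)]
    sub = sub.reset_index(drop=True)
    if sub.empty:
        return sub.iloc[0:0]
    first, last = sub["timestamp"].iat[0], sub["timestamp"].iat[-1]
    if last.normalize() == first.normalize():
        return sub.iloc[0:0]  # degenerate: spans < 2 calendar days

    x, y = projection.forward(sub["lon"].to_numpy(), sub["lat"].to_numpy())
    t = sub["timestamp"].astype("int64").to_numpy() // 10 ** 9  # epoch s
    days = pd.date_range(first.normalize(), last.normalize(), freq="D")
    refs = days + pd.Timedelta(hours=ref_hour)
    tr = refs.asi8 // 10 ** 9

    idx = np.searchsorted(t, tr, side="right")  # first fix strictly after ref
    xo = np.empty(len(tr))
    yo = np.empty(len(tr))
    gap = np.zeros(len(tr), dtype=bool)
    land = np.zeros(len(tr), dtype=bool)
    has_land = "on_land" in sub.columns
    land_arr = sub["on_land"].to_numpy(dtype=bool) if has_land else np.zeros(len(sub), bool)
    max_gap_s = max_gap_days * 86400.0
    for k in range(len(tr)):
        j = idx[k]
        if j == 0:
            xo[k], yo[k] = x[0], y[0]
            land[k] = land_arr[0]
        elif j >= len(t):
            xo[k], yo[k] = x[-1], y[-1]
            land[k] = land_arr[-1]
        else:
            i = j - 1
            if (t[j] - t[i]) > max_gap_s:
                gap[k] = True
                xo[k] = yo[k] = np.nan
                continue
            w = (tr[k] - t[i]) / (t[j] - t[i]) if t[j] > t[i] else 0.0
            xo[k] = x[i] + w * (x[j] - x[i])
            yo[k] = y[i] + w * (y[j] - y[i])
            land[k] = land_arr[i] if (tr[k] - t[i]) <= (t[j] - tr[k]) else land_arr[j]

    lon, lat = projection.inverse(xo, yo)
    lon = np.where(gap, np.nan, lon)
    lat = np.where(gap, np.nan, lat)
    meta ={c: sub[c].iat[0] for c in ("individual_id", "colony", "stage",
                                       "year", "device") if c in sub.columns}
    out = pd.DataFrame({"timestamp": refs, "lon": lon, "lat": lat,
                        "gap": gap, "on_land": land})
    for c, v in meta.items():
        out[c] = v
    return out


@dataclass
class CleanTrack:
    """Everything preprocessing derives for one individual."""
    individual_id: str
    fixes: pd.DataFrame              # speed-filtered, land-flagged
    removed_fixes: pd.DataFrame
    trips: list
    n_trips_discarded: int
    moult: MoultEvent | None
    n_days: int
    daily: pd.DataFrame              # at-sea daily positions
    daily_with_land: pd.DataFrame    # daily positions incl. land, flagged


def preprocess_track(track: pd.DataFrame, coastline, colony_positions: dict,
                     projection: AzimuthalEquidistant,
                     vmax: float = VMAX_KMH,
                     moult_threshold_h: float = MOULT_THRESHOLD_H,
                     colony_radius_m: float = COLONY_RADIUS_M) -> CleanTrack:
    """Run the full cleaning sequence on one track."""
    iid = track["individual_id"].iat[0]
    filtered, removed = speed_filter(track, vmax=vmax)
    flagged = flag_land(filtered, coastline, list(colony_positions.values()),
                        radius_m=colony_radius_m)
    moult = detect_moult(flagged, colony_positions, threshold_h=moult_threshold_h)
    trips, n_disc = split_trips(flagged)
    if moult is not None and trips:
        if trips[-1].end <= moult.start:
            trips[-1].complete = True
    n_days = tracking_days(flagged, moult)
    # moult haul-out fixes are not foraging: cut the track at moult onset
    pre_moult = (flagged[flagged["timestamp"] < moult.start]
                 if moult is not None else flagged)
    daily = regularize_daily(pre_moult, projection, include_land=False)
    daily_land = regularize_daily(pre_moult, projection, include_land=True)
    return CleanTrack(individual_id=iid, fixes=flagged, removed_fixes=removed,
                      trips=trips, n_trips_discarded=n_disc, moult=moult,
                      n_days=n_days, daily=daily, daily_with_land=daily_land)


def preprocess_trackset(trackset, coastline, colony_positions: dict,
                        projection: AzimuthalEquidistant,
                        min_days: int = MIN_TRACKING_DAYS, **kwargs):
    """Clean every track and apply the >``min_days`` inclusion rule.

    Returns ``(dict of CleanTrack for retained ids, report dict)``.
    """
    clean, report_tracks = {}, {}
    for iid, track in trackset.itertracks():
        ct = preprocess_track(track, coastline, colony_positions, projection,
                              **kwargs)
        clean[iid] = ct
        report_tracks[iid] = {
            "n_fixes_in": int(len(track)),
            "n_fixes_removed_speed": int(len(ct.removed_fixes)),
            "n_trips": len(ct.trips),
            "n_trips_discarded": ct.n_trips_discarded,
            "moult_detected": ct.moult is not None,
            "moult_colony": ct.moult.colony if ct.moult else None,
            "tracking_days": ct.n_days,
        }
    retained = {iid: ct for iid, ct in clean.items()
                if ct.n_days > min_days and len(ct.daily) > 0}
    excluded = {iid: f"tracking days {clean[iid].n_days} <= {min_days}"
                for iid in clean if iid not in retained}
    report = {"tracks": report_tracks,
              "n_tracks_in": len(clean),
              "n_tracks_retained": len(retained),
              "excluded": excluded,
              "min_days": min_days}
    return retained, report
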