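"""Track table I/O.

Tracks are held as a single tidy :class:`pandas.DataFrame` of fixes with
columns ``individual_id, timestamp, lon, lat, colony, stage, year, device``
(plus an ``on_land`` flag once preprocessing has run), wrapped in a thin
:class:`TrackSet` that enforces per-track time ordering and metadata
completeness.  CSV is the on-disk format; timestamps are ISO-8601 UTC.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("individual_id", "timestamp", "lon", "lat",
                    "colony", "stage", "year", "device")

META_COLUMNS = ("colony", "stage", "year", "device")


class TrackFormatError(ValueError):
    """Raised when a track file is missing columns or has bad rows."""


@dataclass
class TrackSet:
    """A collection of tracks keyed by individual id.

    ``fixes`` is a tidy frame sorted by (individual_id, timestamp) with
    strictly increasing timestamps within each track.
    """

    fixes: pd.DataFrame
    log: dict = field(default_factory=dict)

    def __post_init__(self):
        df = self.fixes
        missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
        if missing:
            raise TrackFormatError(f"missing required column(s): {', '.join(missing)}")
        df = df.copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True)
        bad_lon = ~df["lon"].between(-180, 180)
        bad_lat = ~df["lat"].between(-90, 90)
        if bad_lon.any() or bad_lat.any():
            raise TrackFormatError("coordinates out of range")
        df = df.sort_values(["individual_id", "timestamp"], kind="mergesort")
        dup = df.duplicated(subset=["individual_id", "timestamp"])
        if dup.any():
            self.log["duplicate_timestamps_dropped"] = int(dup.sum())
            df = df[~dup]
        self.fixes = df.reset_index(drop=True)

    # -- accessors ---------------------------------------------------------

    @property
    def ids(self) -> list:
        return list(dict.fromkeys(self.fixes["individual_id"]))

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, individual_id) -> pd.DataFrame:
        track = self.fixes[self.fixes["individual_id"] == individual_id]
        if track.empty:
            raise KeyError(individual_id)
        return track.reset_index(drop=True)

    def itertracks(self):
        for iid, track in self.fixes.groupby("individual_id", sort=False):
            yield iid, track.reset_index(drop=True)

    @property
    def metadata(self) -> pd.DataFrame:
        """One row per individual with its (colony, stage, year, device)."""
        return (self.fixes.groupby("individual_id", sort=False)[list(META_COLUMNS)]
                .first().reset_index())

    def subset(self, ids) -> "TrackSet":
        ids = set(ids)
        return TrackSet(self.fixes[self.fixes["individual_id"].isin(ids)])

    def groups(self):
        """Iterate (colony, stage, year) data groups as (key, TrackSet)."""
        meta = self.metadata
        for key, sub in meta.groupby(["colony", "stage", "year"], sort=True):
            yield key, self.subset(sub["individual_id"])

    # -- I/O ---------------------------------------------------------------

    def to_csv(self, path) -> None:
        out = self.fixes.copy()
        out["timestamp"] = out["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%SZ")
        out.to_csv(path, index=False)


def read_tracks(path) -> TrackSet:
    """Read a track CSV written by this package (or an equivalent dialect).

    Fixes are time-sorted per individual; duplicate timestamps collapse to
    the first occurrence (count recorded in ``TrackSet.log``).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise TrackFormatError(
            f"{path}: missing required column(s): {', '.join(missing)}")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True, format="ISO8601")
    except (ValueError, TypeError):
        parsed = pd.to_datetime(df["timestamp"], utc=True, errors="coerce",
                                format="mixed")
        if parsed.isna().any():
            row = int(np.flatnonzero(parsed.isna())[0])
            raise TrackFormatError(
                f"{path}: unparseable timestamp at data row {row + 1}: "
                f"{df['timestamp'].iloc[row]!r}") from None
        df["timestamp"] = parsed
    return TrackSet(df)


def write_tracks(trackset: TrackSet, path) -> None:
    trackset.to_csv(path)
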