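"""Reading, validating and filtering Argos fix tables, and daily averaging.

The filtering ladder mirrors standard turtle-telemetry practice: reject
implausible class-Z fixes, drop fixes on land, remove fixes whose implied
swim speed from the last retained fix exceeds 5 kph (single forward pass),
and drop fixes over water deeper than the -200 m neritic cutoff. Retained
fixes are averaged per UTC calendar day to damp autocorrelation before
home-range estimation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely.prepared import prep

from ._geo import haversine_km

LC_ORDER = {"3": 6, "2": 5, "1": 4, "0": 3, "A": 2, "B": 1, "Z": 0}
REQUIRED_COLUMNS = ("animal_id", "timestamp", "lon", "lat", "lc")


def read_fixes(path) -> pd.DataFrame:
    """Read a fix CSV (animal_id, timestamp, lon, lat, lc) and validate it.

    Rows are sorted chronologically per animal; duplicate (animal, timestamp)
    rows collapse to the best location class (3 > 2 > 1 > 0 > A > B > Z).
    Unknown classes or unparseable timestamps raise with the offending row.
    """
    df = pd.read_csv(path, dtype={"lc": str, "animal_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"fix table missing column(s): {', '.join(missing)}")
    ts = pd.to_datetime(df["timestamp"], utc=True, errors="coerce", format="ISO8601")
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna())[0])
        raise ValueError(f"unparseable timestamp {df['timestamp'].iloc[row]!r} at row {row}")
    df = df.assign(timestamp=ts)
    bad = ~df["lc"].isin(LC_ORDER)
    if bad.any():
        row = int(np.flatnonzero(bad)[0])
        raise ValueError(f"unknown location class {df['lc'].iloc[row]!r} at row {row}")
    if (df["lat"].abs() > 90).any() or (df["lon"].abs() > 180).any():
        row = int(np.flatnonzero((df["lat"].abs() > 90) | (df["lon"].abs() > 180))[0])
        raise ValueError(f"coordinate out of range at row {row}")
    df["_rank"] = df["lc"].map(LC_ORDER)
    df = (
        df.sort_values(["animal_id", "timestamp", "_rank"])
        .drop_duplicates(["animal_id", "timestamp"], keep="last")
        .drop(columns="_rank")
        .reset_index(drop=True)
    )
    return df


def filter_fixes(
    fixes: pd.DataFrame,
    habitat=None,
    max_speed_kph: float = 5.0,
    depth_cutoff_m: float = -200.0,
) -> pd.DataFrame:
    """Flag fixes in the order lc_z -> on_land -> speed -> deep.

    Returns a copy with a ``rejection_reason`` column ('' for retained fixes;
    first failing rule otherwise). A ``manual`` column of truthy values, if
    present, marks expert removals and is honoured before everything else.
    The speed rule compares each candidate against the last *retained* fix of
    the same animal (great-circle distance over elapsed time) and flags the
    later fix of a violating pair. Habitat may be None to skip the land and
    depth rules.
    """
    df = fixes.copy().reset_index(drop=True)
    reason = np.full(len(df), "", dtype=object)

    if "manual" in df.columns:
        reason[df["manual"].fillna(0).astype(bool).to_numpy()] = "manual"
    reason[(df["lc"] == "Z").to_numpy() & (reason == "")] = "lc_z"

    if habitat is not None:
        pts = shapely.points(np.column_stack([df["lon"].to_numpy(), df["lat"].to_numpy()]))
        on_land = shapely.contains(habitat.coast, pts) | shapely.intersects(
            shapely.boundary(habitat.coast), pts
        )
        reason[on_land & (reason == "")] = "on_land"

    # forward-pass speed filter per animal
    for _, idx in df.groupby("animal_id", sort=False).indices.items():
        idx = np.asarray(idx)
        last = -1
        for i in idx:
            if reason[i]:
                continue
            if last >= 0:
                dt_h = (df["timestamp"].iloc[i] - df["timestamp"].iloc[last]).total_seconds() / 3600.0
                dist = haversine_km(
                    df["lon"].iloc[last], df["lat"].iloc[last], df["lon"].iloc[i], df["lat"].iloc[i]
                )
                if dt_h <= 0:
                    if dist > 1e-9:
                        reason[i] = "speed"
                        continue
                elif dist / dt_h > max_speed_kph:
                    reason[i] = "speed"
                    continue
            last = i

    if habitat is not None:
        open_idx = np.flatnonzero(reason == "")
        if len(open_idx):
            depth = np.atleast_1d(
                habitat.depth_at(df["lon"].to_numpy()[open_idx], df["lat"].to_numpy()[open_idx])
            )
            reason[open_idx[depth < depth_cutoff_m]] = "deep"

    df["rejection_reason"] = reason
    return df


def retained(flagged: pd.DataFrame) -> pd.DataFrame:
    """Subset of fixes that passed every filter (NaN after a CSV round-trip
    counts as an empty reason)."""
    reason = flagged["rejection_reason"].fillna("")
    return flagged[reason == ""].reset_index(drop=True)


def mean_daily_locations(fixes: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of lon/lat per (animal, UTC day) over retained fixes.

    Averaging is done in raw lon/lat: foraging clusters span well under two
    degrees, where the curvature error is negligible.
    """
    if "rejection_reason" in fixes.columns:
        fixes = retained(fixes)
    if fixes.empty:
        return pd.DataFrame(columns=["animal_id", "date", "lon", "lat", "n_fixes"])
    g = fixes.assign(date=fixes["timestamp"].dt.floor("D")).groupby(
        ["animal_id", "date"], as_index=False
    )
    out = g.agg(lon=("lon", "mean"), lat=("lat", "mean"), n_fixes=("lon", "size"))
    return out.sort_values(["animal_id", "date"]).reset_index(drop=True)
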