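"""Spatial annotation of foraging centroids and turtle-day occupancy grids.

Centroids get depth (bilinear bathymetry sample), great-circle distance to
the nearest land, geographic region (exactly one of five), trawl effort from
the containing statistical zone, platform proximity (10 km), oil-footprint
membership, and jurisdiction (state submerged lands, else EEZ country).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point

from ._geo import haversine_km

PLATFORM_RADIUS_KM = 10.0


@dataclass
class CentroidAnnotation:
    animal_id: str
    period_ref: str
    estimator: str                  # "KDE" or "MCP"
    depth_m: float
    dist_to_land_km: float
    region: str
    trawl_days_fished: float | None  # None where no zone covers the centroid
    within_10km_platform: bool
    in_oil_footprint: bool
    jurisdiction: str


def _point_region(pt: Point, regions) -> str:
    hits = [props["region_name"] for geom, props in regions if geom.covers(pt)]
    if not hits:
        raise ValueError(f"centroid {pt.wkt} falls outside every region polygon")
    return hits[0]


def distance_to_land_km(lon: float, lat: float, coast_line) -> float:
    """Minimum great-circle distance from a point to the (unbuffered)
    coastline, via densified boundary vertices."""
    seg = coast_line.segmentize(0.01)  # ~1 km vertex spacing
    coords = np.asarray(seg.coords)
    return float(haversine_km(lon, lat, coords[:, 0], coords[:, 1]).min())


def annotate_centroid(
    lonlat: tuple,
    habitat,
    threats,
    animal_id: str = "",
    period_ref: str = "",
    estimator: str = "KDE",
) -> CentroidAnnotation:
    lon, lat = float(lonlat[0]), float(lonlat[1])
    pt = Point(lon, lat)
    depth = float(habitat.depth_at(lon, lat))
    dist = distance_to_land_km(lon, lat, habitat.coast_line)
    region = _point_region(pt, threats.regions)

    trawl = None
    for geom, props in threats.trawl_zones:
        if geom.covers(pt):
            trawl = float(props["days_fished"])
            break

    near_platform = any(
        haversine_km(lon, lat, p.x, p.y) <= PLATFORM_RADIUS_KM for p in threats.platforms
    )
    in_oil = bool(threats.oil_footprint.covers(pt))

    jurisdiction = None
    for geom, props in threats.ssl:
        if geom.covers(pt):
            jurisdiction = props["state"]
            break
    if jurisdiction is None:
        for geom, props in threats.eez:
            if geom.covers(pt):
                jurisdiction = props["country"]
                break
    if jurisdiction is None:
        jurisdiction = "international"

    return CentroidAnnotation(
        animal_id=animal_id,
        period_ref=period_ref,
        estimator=estimator,
        depth_m=depth,
        dist_to_land_km=dist,
        region=region,
        trawl_days_fished=trawl,
        within_10km_platform=near_platform,
        in_oil_footprint=in_oil,
        jurisdiction=jurisdiction,
    )


@dataclass
class TurtleDaysGrid:
    x0: float
    y0: float
    cell_km: float
    counts: dict                    # (i, j) -> turtle-days

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def to_frame(self) -> pd.DataFrame:
        rows = [{"i": i, "j": j, "count": c} for (i, j), c in sorted(self.counts.items())]
        return pd.DataFrame(rows, columns=["i", "j", "count"])


def turtle_days_grid(
    fixes: pd.DataFrame,
    proj,
    cell_km: float = 10.0,
    origin: tuple | None = None,
) -> TurtleDaysGrid:
    """Turtle-days per half-open grid cell [x0+i·w, x0+(i+1)·w) × [y0+j·w, …).

    For each (animal, UTC day), every distinct cell holding at least one fix
    that day gains one turtle-day; LC Z fixes must be excluded upstream (A
    and B are kept). The fix order within a day is irrelevant.
    """
    df = fixes.copy()
    if "lc" in df.columns and (df["lc"] == "Z").any():
        df = df[df["lc"] != "Z"]
    x, y = proj.forward(df["lon"].to_numpy(), df["lat"].to_numpy())
    if origin is None:
        origin = (float(np.floor(x.min() / cell_km) * cell_km),
                  float(np.floor(y.min() / cell_km) * cell_km))
    x0, y0 = origin
    i = np.floor((x - x0) / cell_km).astype(int)
    j = np.floor((y - y0) / cell_km).astype(int)
    day = df["timestamp"].dt.floor("D")
    triples = pd.DataFrame({"animal_id": df["animal_id"].to_numpy(), "day": day.to_numpy(),
                            "i": i, "j": j}).drop_duplicates()
    counts: dict = {}
    for (ci, cj), grp in triples.groupby(["i", "j"]):
        counts[(int(ci), int(cj))] = len(grp)
    return TurtleDaysGrid(x0=x0, y0=y0, cell_km=cell_km, counts=counts)


def oiled_foraging_days(fixes: pd.DataFrame, oil_polygon) -> tuple:
    """(days inside, total foraging days, fraction): a turtle-day counts as
    oiled when at least one of that animal's fixes that day lies inside the
    oil polygon."""
    import shapely

    if fixes.empty:
        return 0, 0, float("nan")
    df = fixes.assign(day=fixes["timestamp"].dt.floor("D"))
    pts = shapely.points(np.column_stack([df["lon"].to_numpy(), df["lat"].to_numpy()]))
    df = df.assign(inside=shapely.intersects(oil_polygon, pts))
    per_day = df.groupby(["animal_id", "day"])["inside"].any()
    days_total = int(len(per_day))
    days_in = int(per_day.sum())
    return days_in, days_total, days_in / days_total
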