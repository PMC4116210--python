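"""Estimate foraging areas per period: LSCV-bandwidth KDE (50/95% isopleths)
for KDE-eligible periods, 100% MCP otherwise; test site fidelity against
habitat-constrained random walks.

Writes results/homeranges.csv (one row per foraging period, mirroring the
KDE/MCP summary-table layout).
"""

import pathlib

import numpy as np
import pandas as pd

from gulftrack.argos import retained
from gulftrack.fidelity import generate_constrained_walks, site_fidelity_test
from gulftrack.homerange import isopleth, kde_utilization, lscv_bandwidth, mcp
from gulftrack.synthetic import build_habitat

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 7) -> None:
    habitat = build_habitat(seed=seed)
    proj = habitat.proj
    water_km = proj.project_geom(habitat.water_poly)
    flagged = pd.read_csv(ROOT / "filtered.csv", parse_dates=["timestamp"])
    daily = pd.read_csv(ROOT / "daily.csv", parse_dates=["date"])
    segments = pd.read_csv(ROOT / "segments.csv", parse_dates=["start", "end"])

    rows = []
    for _, s in segments[segments["period"].str.startswith("F", na=False)].iterrows():
        fx = retained(flagged[(flagged.animal_id == s.animal_id)
                              & (flagged.timestamp >= s.start) & (flagged.timestamp <= s.end)])
        dl = daily[(daily.animal_id == s.animal_id)
                   & (daily.date >= s.start.floor("D")) & (daily.date <= s.end.floor("D"))]
        if len(fx) < 10:
            continue
        x, y = proj.forward(fx.lon.to_numpy(), fx.lat.to_numpy())
        track_km = np.column_stack([x, y])
        walks = generate_constrained_walks(track_km, water_km, m=100, seed=seed)
        fid = site_fidelity_test(track_km, walks)

        row = {"animal_id": s.animal_id, "period": s.period,
               "first_date": s.start.date(), "last_date": s.end.date(), "days": s.days,
               "filtered_locations": len(fx), "daily_locations": len(dl),
               "fidelity_p": round(fid.p_percent, 4), "fidelity_passed": fid.passed}
        if s.eligibility == "kde" and len(dl) >= 20:
            dx, dy = proj.forward(dl.lon.to_numpy(), dl.lat.to_numpy())
            pts = np.column_stack([dx, dy])
            bw = lscv_bandwidth(pts)
            ud = kde_utilization(pts, bw, cell_km=1.0)
            hr50 = isopleth(ud, 0.50, water_km, n_inputs=len(pts), proj=proj)
            hr95 = isopleth(ud, 0.95, water_km, n_inputs=len(pts), proj=proj)
            lon_c, lat_c = hr50.centroid_lonlat()
            row.update(estimator="KDE", kde50_km2=round(hr50.area_water_km2, 1),
                       kde95_km2=round(hr95.area_water_km2, 1),
                       centroid_lon=round(lon_c, 4), centroid_lat=round(lat_c, 4))
        elif s.days >= 6 and len(track_km) >= 3:
            hr = mcp(track_km, water_km, proj=proj)
            lon_c, lat_c = hr.centroid_lonlat()
            row.update(estimator="MCP", mcp_km2=round(hr.area_water_km2, 1),
                       centroid_lon=round(lon_c, 4), centroid_lat=round(lat_c, 4))
        else:
            row.update(estimator="last_point")
        rows.append(row)

    out = pd.DataFrame(rows)
    out.to_csv(ROOT / "homeranges.csv", index=False)
    kde = out[out.estimator == "KDE"]
    print(f"{len(out)} foraging periods: {len(kde)} KDE, "
          f"{(out.estimator == 'MCP').sum()} MCP, {(out.estimator == 'last_point').sum()} last-point")
    if len(kde):
        print(f"KDE50 area: mean {kde.kde50_km2.mean():.1f} km^2, "
              f"KDE95 mean {kde.kde95_km2.mean():.1f} km^2")
    print(f"site fidelity passed: {out.fidelity_passed.sum()}/{len(out)}")


if __name__ == "__main__":
    main()
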