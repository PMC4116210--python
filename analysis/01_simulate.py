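"""Simulate the study system: shelf habitat, threat layers, and a cohort of
post-nesting loggerhead tracks observed through Argos-class error.

Writes results/sim/: fixes.csv, truth.csv, bathymetry.asc, and one GeoJSON
per habitat/threat layer.
"""

import pathlib
import sys

import pandas as pd

from gulftrack._geo import write_geojson
from gulftrack.synthetic import SimParams, build_habitat, build_threat_layers, simulate_tracks

OUT = pathlib.Path(__file__).resolve().parents[1] / "results" / "sim"


def main(seed: int = 7, n_turtles: int = 6) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    habitat = build_habitat(seed=seed)
    threats = build_threat_layers(habitat, seed=seed + 1)
    tracks = simulate_tracks(SimParams(n_turtles=n_turtles, seed=seed + 2), habitat)

    pd.concat([f for _, f in tracks]).to_csv(OUT / "fixes.csv", index=False)
    pd.concat(
        [t.assign(animal_id=f"sim{i:03d}") for i, (t, _) in enumerate(tracks)]
    ).to_csv(OUT / "truth.csv", index=False)

    habitat.bathymetry.write(OUT / "bathymetry.asc")
    write_geojson(OUT / "coast.geojson", [habitat.coast])
    write_geojson(OUT / "water.geojson", [habitat.water_poly])
    write_geojson(OUT / "trawl_zones.geojson", *zip(*threats.trawl_zones))
    write_geojson(OUT / "platforms.geojson", threats.platforms)
    write_geojson(OUT / "oil_footprint.geojson", [threats.oil_footprint])
    write_geojson(OUT / "eez.geojson", *zip(*threats.eez))
    write_geojson(OUT / "ssl.geojson", *zip(*threats.ssl))
    write_geojson(OUT / "regions.geojson", *zip(*threats.regions))

    n_fixes = sum(len(f) for _, f in tracks)
    print(f"simulated {n_turtles} turtles, {n_fixes} Argos fixes -> {OUT}")


if __name__ == "__main__":
    main(*(int(a) for a in sys.argv[1:]))
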