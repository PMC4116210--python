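"""Small geodesy helpers: local equal-area projection, great-circle distance,
ESRI ASCII grid I/O with bilinear sampling, and GeoJSON round-tripping.

All projected coordinates are kilometres; lon/lat are decimal degrees WGS84.
The Gulf-of-Mexico extent (~18 km of spread in the azimuthal scale factor over
1500 km) keeps the equal-area distortion well below the Argos error scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import transform as shp_transform

EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between points given in decimal degrees.

    Accepts scalars or arrays (broadcast).
    """
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(x, dtype=float)) for x in (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class LocalEqualArea:
    """Lambert azimuthal equal-area projection centred on (lon0, lat0).

    Forward maps lon/lat (deg) to (x, y) km; inverse maps back. Equal-area,
    so polygon areas in the projected frame are true areas.
    """

    lon0: float
    lat0: float

    def forward(self, lon, lat):
        lon = np.radians(np.asarray(lon, dtype=float))
        lat = np.radians(np.asarray(lat, dtype=float))
        lon0 = np.radians(self.lon0)
        lat0 = np.radians(self.lat0)
        dlon = lon - lon0
        denom = 1.0 + np.sin(lat0) * np.sin(lat) + np.cos(lat0) * np.cos(lat) * np.cos(dlon)
        k = np.sqrt(2.0 / np.maximum(denom, 1e-12))
        x = EARTH_RADIUS_KM * k * np.cos(lat) * np.sin(dlon)
        y = EARTH_RADIUS_KM * k * (np.cos(lat0) * np.sin(lat) - np.sin(lat0) * np.cos(lat) * np.cos(dlon))
        return x, y

    def inverse(self, x, y):
        x = np.asarray(x, dtype=float) / EARTH_RADIUS_KM
        y = np.asarray(y, dtype=float) / EARTH_RADIUS_KM
        lat0 = np.radians(self.lat0)
        rho = np.hypot(x, y)
        c = 2.0 * np.arcsin(np.clip(rho / 2.0, 0.0, 1.0))
        with np.errstate(invalid="ignore"):
            lat = np.where(
                rho > 1e-12,
                np.arcsin(np.clip(np.cos(c) * np.sin(lat0) + y * np.sin(c) * np.cos(lat0) / np.maximum(rho, 1e-12), -1, 1)),
                lat0,
            )
            lon = np.radians(self.lon0) + np.where(
                rho > 1e-12,
                np.arctan2(x * np.sin(c), rho * np.cos(lat0) * np.cos(c) - y * np.sin(lat0) * np.sin(c)),
                0.0,
            )
        return np.degrees(lon), np.degrees(lat)

    def project_geom(self, geom: BaseGeometry) -> BaseGeometry:
        return shp_transform(lambda lon, lat: self.forward(lon, lat), geom)

    def unproject_geom(self, geom: BaseGeometry) -> BaseGeometry:
        return shp_transform(lambda x, y: self.inverse(x, y), geom)


@dataclass
class AsciiGrid:
    """Regular raster in ESRI ASCII grid layout.

    ``values[0, 0]`` is the *top-left* (north-west) cell, matching the file
    layout. ``xll, yll`` are the lower-left corner coordinates and ``cell``
    the cell size, in whatever CRS the grid was built in (lon/lat here).
    """

    values: np.ndarray
    xll: float
    yll: float
    cell: float
    nodata: float = -9999.0

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def x_centers(self) -> np.ndarray:
        return self.xll + (np.arange(self.ncols) + 0.5) * self.cell

    def y_centers(self) -> np.ndarray:
        # top row first, to match the values array
        return self.yll + (self.nrows - np.arange(self.nrows) - 0.5) * self.cell

    def sample_bilinear(self, x, y):
        """Bilinear interpolation at (x, y); nearest-edge beyond the border."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        # fractional column/row in cell-center coordinates
        fc = (x - self.xll) / self.cell - 0.5
        fr = (self.yll + self.nrows * self.cell - y) / self.cell - 0.5
        fc = np.clip(fc, 0.0, self.ncols - 1.0)
        fr = np.clip(fr, 0.0, self.nrows - 1.0)
        c0 = np.floor(fc).astype(int)
        r0 = np.floor(fr).astype(int)
        c1 = np.minimum(c0 + 1, self.ncols - 1)
        r1 = np.minimum(r0 + 1, self.nrows - 1)
        wc = fc - c0
        wr = fr - r0
        v = self.values
        top = v[r0, c0] * (1 - wc) + v[r0, c1] * wc
        bot = v[r1, c0] * (1 - wc) + v[r1, c1] * wc
        out = top * (1 - wr) + bot * wr
        return out if out.shape else float(out)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"ncols {self.ncols}\n")
            fh.write(f"nrows {self.nrows}\n")
            fh.write(f"xllcorner {self.xll!r}\n")
            fh.write(f"yllcorner {self.yll!r}\n")
            fh.write(f"cellsize {self.cell!r}\n")
            fh.write(f"NODATA_value {self.nodata!r}\n")
            for row in self.values:
                fh.write(" ".join(f"{v:.4f}" for v in row) + "\n")

    @classmethod
    def read(cls, path) -> "AsciiGrid":
        header: dict[str, float] = {}
        rows: list[np.ndarray] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                key = parts[0].lower()
                if key in {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                    header[key] = float(parts[1])
                else:
                    rows.append(np.array(parts, dtype=float))
        values = np.vstack(rows)
        if values.shape != (int(header["nrows"]), int(header["ncols"])):
            raise ValueError("ASCII grid data shape does not match header")
        return cls(
            values=values,
            xll=header["xllcorner"],
            yll=header["yllcorner"],
            cell=header["cellsize"],
            nodata=header.get("nodata_value", -9999.0),
        )


def write_geojson(path, geoms, properties=None) -> None:
    """Write shapely geometries as a GeoJSON FeatureCollection (WGS84 lon/lat)."""
    if properties is None:
        properties = [{} for _ in geoms]
    features = [
        {"type": "Feature", "geometry": mapping(g), "properties": props}
        for g, props in zip(geoms, properties)
    ]
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh)


def read_geojson(path):
    """Read a GeoJSON FeatureCollection; returns (geometries, properties) lists."""
    with open(path) as fh:
        obj = json.load(fh)
    geoms = [shape(f["geometry"]) for f in obj["features"]]
    props = [f.get("properties", {}) or {} for f in obj["features"]]
    return geoms, props
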