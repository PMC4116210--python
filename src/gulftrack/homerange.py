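"""Foraging-area estimation: fixed-kernel KDE with least-squares
cross-validated bandwidth, 50/95% isopleths clipped to water, 100% minimum
convex polygons, and the largest-activity-center centroid rule.

All computation happens in a local equal-area km frame; geometries are
returned in that frame together with the projection used, so areas are true
km² and centroids can be reported in lon/lat.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.spatial import ConvexHull
from scipy.spatial.distance import pdist, squareform
from shapely.geometry import MultiPolygon, Polygon, box
from shapely.ops import unary_union

from ._geo import LocalEqualArea


@dataclass
class Bandwidth:
    """LSCV bandwidth: scalar optimum ``h`` on standardized coordinates and
    the per-axis back-scaled bandwidths in km."""

    h: float
    h_x: float
    h_y: float
    cv_grid: np.ndarray          # evaluated h values (standardized scale)
    cv_scores: np.ndarray
    clamped: bool = False


@dataclass
class UtilizationDistribution:
    density: np.ndarray          # (nrows, ncols), row 0 = max y (north)
    x_edges: np.ndarray
    y_edges: np.ndarray
    cell_km: float

    @property
    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_km**2)


@dataclass
class HomeRange:
    estimator: str               # "KDE50", "KDE95", "MCP100"
    geometry: MultiPolygon       # unclipped, km frame
    area_water_km2: float
    centroid_xy: tuple           # km frame, largest-activity-center rule
    n_inputs: int
    proj: LocalEqualArea | None = None

    @property
    def area_km2(self) -> float:
        return float(self.geometry.area)

    def centroid_lonlat(self):
        if self.proj is None:
            raise ValueError("no projection attached")
        lon, lat = self.proj.inverse(self.centroid_xy[0], self.centroid_xy[1])
        return float(lon), float(lat)


def lscv_score(points: np.ndarray, h: float, pair_d2: np.ndarray | None = None) -> float:
    """Least-squares CV score for a 2-D Gaussian kernel with scalar bandwidth
    ``h``: estimated integrated squared error up to a data-independent term,

        ∫ f̂² − (2/n) Σ_i f̂_{−i}(x_i)
        = Σ_ij e^{−r²/4h²} / (4π h² n²) − 2 Σ_{i≠j} e^{−r²/2h²} / (2π h² n(n−1)).
    """
    n = len(points)
    if pair_d2 is None:
        pair_d2 = squareform(pdist(points)) ** 2
    term1 = np.exp(-pair_d2 / (4.0 * h * h)).sum() / (4.0 * np.pi * h * h * n * n)
    off = np.exp(-pair_d2 / (2.0 * h * h)).sum() - n  # remove the i==j diagonal (e^0)
    term2 = off / (np.pi * h * h * n * (n - 1))
    return float(term1 - term2)


def lscv_bandwidth(points_km: np.ndarray, min_points: int = 20) -> Bandwidth:
    """Scalar LSCV optimum on per-axis standardized coordinates.

    The search runs over 50 log-spaced values of h in [0.05, 2] times the
    Gaussian reference bandwidth, refined by bounded scalar minimization; a
    monotone CV curve hitting the lower bound is clamped with a warning.
    Ties break toward the smaller h.
    """
    pts = np.asarray(points_km, dtype=float)
    if len(pts) < min_points:
        raise ValueError(f"KDE needs at least {min_points} points, got {len(pts)}")
    sd = pts.std(axis=0, ddof=1)
    if np.any(sd <= 0):
        raise ValueError("zero variance: all points identical along an axis")
    z = (pts - pts.mean(axis=0)) / sd
    n = len(z)
    h_ref = n ** (-1.0 / 6.0)  # Gaussian reference rule for unit-variance 2-D data
    grid = np.geomspace(0.05 * h_ref, 2.0 * h_ref, 50)
    d2 = squareform(pdist(z)) ** 2
    scores = np.array([lscv_score(z, h, d2) for h in grid])
    i = int(np.argmin(scores))  # argmin takes the first (smallest h) on ties
    clamped = False
    if i == 0:
        warnings.warn("LSCV curve decreasing to the lower search bound; h clamped")
        clamped = True
        h_opt = grid[0]
    else:
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(
            lambda h: lscv_score(z, h, d2), bounds=(lo, hi), method="bounded",
            options={"xatol": 1e-5 * h_ref},
        )
        h_opt = float(res.x)
        if lscv_score(z, grid[i], d2) < res.fun:
            h_opt = float(grid[i])
    return Bandwidth(
        h=h_opt, h_x=h_opt * sd[0], h_y=h_opt * sd[1],
        cv_grid=grid, cv_scores=scores, clamped=clamped,
    )


def kde_utilization(points_km: np.ndarray, bw: Bandwidth, cell_km: float = 1.0,
                    pad_bandwidths: float = 4.0) -> UtilizationDistribution:
    """Gaussian product-kernel KDE on a regular grid padded ``pad_bandwidths``
    bandwidths beyond the point extent, normalized to unit mass."""
    if cell_km <= 0:
        raise ValueError("cell_km must be positive")
    pts = np.asarray(points_km, dtype=float)
    hx, hy = bw.h_x, bw.h_y
    x0 = pts[:, 0].min() - pad_bandwidths * hx
    x1 = pts[:, 0].max() + pad_bandwidths * hx
    y0 = pts[:, 1].min() - pad_bandwidths * hy
    y1 = pts[:, 1].max() + pad_bandwidths * hy
    x_edges = np.arange(x0, x1 + cell_km, cell_km)
    y_edges = np.arange(y0, y1 + cell_km, cell_km)
    xc = (x_edges[:-1] + x_edges[1:]) / 2.0
    yc = ((y_edges[:-1] + y_edges[1:]) / 2.0)[::-1]  # row 0 = north
    # separable evaluation: density = (Gy @ Gx^T) / n with per-axis kernels
    gx = np.exp(-((xc[:, None] - pts[None, :, 0]) ** 2) / (2 * hx * hx)) / (np.sqrt(2 * np.pi) * hx)
    gy = np.exp(-((yc[:, None] - pts[None, :, 1]) ** 2) / (2 * hy * hy)) / (np.sqrt(2 * np.pi) * hy)
    density = (gy @ gx.T) / len(pts)
    mass = density.sum() * cell_km**2
    density = density / mass
    return UtilizationDistribution(density=density, x_edges=x_edges, y_edges=y_edges, cell_km=cell_km)


def kde_density_at(points_km: np.ndarray, bw: Bandwidth, probe_xy) -> float:
    """Direct kernel-sum density at a probe location (no grid)."""
    pts = np.asarray(points_km, dtype=float)
    dx = (probe_xy[0] - pts[:, 0]) / bw.h_x
    dy = (probe_xy[1] - pts[:, 1]) / bw.h_y
    k = np.exp(-0.5 * (dx**2 + dy**2)) / (2 * np.pi * bw.h_x * bw.h_y)
    return float(k.mean())


def _cells_to_polygon(mask: np.ndarray, x_edges: np.ndarray, y_edges: np.ndarray):
    """Union of selected grid cells, merging row-runs into rectangles first."""
    nrows, ncols = mask.shape
    y_desc = y_edges[::-1]  # row 0 is the top
    rects = []
    for r in range(nrows):
        row = mask[r]
        c = 0
        while c < ncols:
            if row[c]:
                c2 = c
                while c2 + 1 < ncols and row[c2 + 1]:
                    c2 += 1
                rects.append(box(x_edges[c], y_desc[r + 1], x_edges[c2 + 1], y_desc[r]))
                c = c2 + 1
            else:
                c += 1
    if not rects:
        return MultiPolygon([])
    geom = unary_union(rects)
    if isinstance(geom, Polygon):
        geom = MultiPolygon([geom])
    return geom


def isopleth(ud: UtilizationDistribution, level: float, water_poly_km=None,
             n_inputs: int = 0, proj=None) -> HomeRange:
    """Home range at an isopleth ``level`` (e.g. 0.50 or 0.95): the smallest
    set of grid cells holding ``level`` of the probability mass, polygonized
    and intersected with water for the in-water area."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    dens = ud.density
    order = np.argsort(dens, axis=None)[::-1]
    mass = dens.flatten()[order] * ud.cell_km**2
    cum = np.cumsum(mass)
    k = int(np.searchsorted(cum, level * cum[-1]) + 1)
    thresh = dens.flatten()[order[min(k - 1, len(order) - 1)]]
    mask = dens >= thresh
    geom = _cells_to_polygon(mask, ud.x_edges, ud.y_edges)
    area_water = geom.area if water_poly_km is None else geom.intersection(water_poly_km).area
    centroid = _largest_center_centroid(geom)
    return HomeRange(
        estimator=f"KDE{int(round(level * 100))}",
        geometry=geom,
        area_water_km2=float(area_water),
        centroid_xy=centroid,
        n_inputs=n_inputs,
        proj=proj,
    )


def _largest_center_centroid(geom) -> tuple:
    """Centroid of the largest disjoint polygon (the dominant activity
    center); computed on the unclipped geometry."""
    if geom.is_empty:
        raise ValueError("empty geometry has no centroid")
    if isinstance(geom, MultiPolygon):
        largest = max(geom.geoms, key=lambda g: g.area)
    else:
        largest = geom
    c = largest.centroid
    return (float(c.x), float(c.y))


def mcp(points_km: np.ndarray, water_poly_km=None, proj=None) -> HomeRange:
    """100% minimum convex polygon of the points; in-water area after
    clipping, centroid of the full hull."""
    pts = np.asarray(points_km, dtype=float)
    if len(pts) < 3:
        raise ValueError("MCP needs at least 3 points")
    try:
        hull = ConvexHull(pts)
    except Exception as e:  # collinear input
        raise ValueError("MCP needs non-collinear points") from e
    poly = Polygon(pts[hull.vertices])
    geom = MultiPolygon([poly])
    area_water = poly.area if water_poly_km is None else poly.intersection(water_poly_km).area
    c = poly.centroid
    return HomeRange(
        estimator="MCP100",
        geometry=geom,
        area_water_km2=float(area_water),
        centroid_xy=(float(c.x), float(c.y)),
        n_inputs=len(pts),
        proj=proj,
    )


def homerange_centroid(hr: HomeRange) -> tuple:
    """Lon/lat centroid under the largest-activity-center rule (KDE50 with
    multiple centers uses the largest polygon only)."""
    return hr.centroid_lonlat()
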