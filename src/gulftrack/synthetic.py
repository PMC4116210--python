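"""Ground-truthed synthetic turtle tracks, habitat, and threat layers.

The generator emulates what the downstream analysis assumes about post-nesting
loggerhead telemetry in the Gulf of Mexico:

* a three-phase itinerary (inter-nesting residency near the tagging beach,
  directed migration, foraging residency) produced by a two-state switching
  first-difference correlated random walk (DCRW) on an 8-hour grid, simulated
  in a local equal-area km frame and reported in lon/lat;
* Argos-like observation: fix times drawn as a Poisson process thinned by the
  tag duty cycle, positions read off the true path by linear interpolation and
  perturbed with heavy-tailed (Student-t, df 5) error scaled per location
  class (LC 3, 2, 1, 0, A, B, Z);
* a shelf habitat with a wiggly northern coastline, a linear depth gradient to
  the -200 m isobath, and synthetic threat layers (trawl zones with fishing
  effort, platform points, an oil-footprint polygon, EEZ and state submerged
  lands, and a 5-region partition).

Everything is reproducible from ``SimParams.seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point, Polygon, box
from shapely.ops import unary_union

from ._geo import AsciiGrid, LocalEqualArea

LC_CLASSES = ("3", "2", "1", "0", "A", "B", "Z")

# 68th percentile of |(t1, t2)| for iid unit-scale Student-t(5) coordinates,
# computed by quadrature; per-class scales put the 68% error radius at the
# Argos accuracy band midpoints (km).
_T5_RADIAL_Q68 = 1.7451
_LC_BAND_MID_KM = {"3": 0.125, "2": 0.375, "1": 1.0, "0": 2.0, "A": 3.0, "B": 5.0, "Z": 15.0}

DEFAULT_LC_SCALE = {k: v / _T5_RADIAL_Q68 for k, v in _LC_BAND_MID_KM.items()}

# Argos class mix typical of epoxy-mounted turtle PTTs: B/A dominate, 3/2 rare.
DEFAULT_LC_PROBS = {"3": 0.05, "2": 0.08, "1": 0.13, "0": 0.15, "A": 0.25, "B": 0.30, "Z": 0.04}

#: phase name -> forced behavioral state (1 resident, 2 migration)
PHASE_STATE = {"internesting": 1, "migration": 2, "foraging": 1}

DT_HOURS = 8.0
STEPS_PER_DAY = 3


@dataclass
class SimParams:
    """Parameters of the synthetic track generator.

    Defaults are the study conditions the analysis is exercised under: an
    inter-nesting month, a ~23-day migration, and a ~134-day foraging
    residency; persistence gamma = (0.2, 0.9) for (resident, migration);
    near-symmetric state transitions; 1.5 km process noise per 8-h step
    (≈45 km/d sustained in migration mode); ~6 Argos fixes per active day.
    """

    n_turtles: int = 5
    #: ordered (name, days) phases; states forced via PHASE_STATE, or pass
    #: (name, days, None) for free Markov switching from ``alpha``.
    phase_plan: tuple = (("internesting", 25), ("migration", 23), ("foraging", 134))
    gamma: tuple[float, float] = (0.2, 0.9)  # (resident, migration)
    theta: tuple[float, float] = (0.0, 0.0)
    alpha: tuple = ((0.95, 0.05), (0.05, 0.95))
    sigma_proc: float = 1.5  # km per 8-h step
    lc_probs: dict = field(default_factory=lambda: dict(DEFAULT_LC_PROBS))
    lc_scale: dict = field(default_factory=lambda: dict(DEFAULT_LC_SCALE))
    duty_cycle: str = "seasonal"  # "continuous" or "seasonal" (every 3rd day off-season)
    fixes_per_day: float = 6.0
    gap_rate: float = 0.1
    start: str = "2012-06-15"
    seed: int = 0

    def __post_init__(self):
        alpha = np.asarray(self.alpha, dtype=float)
        if alpha.shape != (2, 2) or not np.allclose(alpha.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("alpha must be 2x2 with rows summing to 1")
        g = np.asarray(self.gamma, dtype=float)
        if np.any(g < 0) or np.any(g > 1):
            raise ValueError("gamma must lie in [0, 1]")
        if not g[1] > g[0]:
            raise ValueError("identifiability requires gamma[migration] > gamma[resident]")
        p = np.array([self.lc_probs.get(c, 0.0) for c in LC_CLASSES], dtype=float)
        if not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError("lc_probs must sum to 1 over classes 3,2,1,0,A,B,Z")
        if not 0.0 <= self.gap_rate < 1.0:
            raise ValueError("gap_rate must be in [0, 1)")


@dataclass
class HabitatDomain:
    """Synthetic shelf habitat: land, neritic water polygon, bathymetry."""

    coast: Polygon              # land polygon, lon/lat
    water_poly: Polygon         # sea between buffered coast and -200 m isobath, lon/lat
    bathymetry: AsciiGrid       # depth in m (negative below sea level), lon/lat grid
    proj: LocalEqualArea
    coast_line: LineString      # unbuffered coastline, lon/lat

    def depth_at(self, lon, lat):
        return self.bathymetry.sample_bilinear(lon, lat)


@dataclass
class ThreatLayers:
    trawl_zones: list           # (Polygon, {"days_fished": float})
    platforms: list             # Point, lon/lat
    oil_footprint: Polygon
    eez: list                   # (Polygon, {"country": str})
    ssl: list                   # (Polygon, {"state": str})
    regions: list               # (Polygon, {"region_name": str}), 5 names


# ---------------------------------------------------------------------------
# habitat

_COAST_Y0 = 620.0       # km north of domain centre
_COAST_AMP = 40.0
_COAST_WAVELEN = 400.0
_REGION_NAMES = ("WGoM", "NGoM", "WFL", "SNWA", "SGoM")


def _coast_y(x):
    return _COAST_Y0 + _COAST_AMP * np.sin(np.asarray(x, dtype=float) / _COAST_WAVELEN)


def build_habitat(
    extent=(-98.0, 18.0, -80.0, 31.0),
    shelf_slope: float = 1.0,
    seed: int = 0,
    cell_deg: float = 0.05,
    coastal_buffer_km: float = 2.0,
) -> HabitatDomain:
    """Build the synthetic shelf: wiggly northern coastline, linear offshore
    depth gradient (``shelf_slope`` m per km), water polygon clipped between
    the 2-km-buffered coast and the -200 m isobath.
    """
    lon_min, lat_min, lon_max, lat_max = extent
    if lon_max <= lon_min or lat_max <= lat_min:
        raise ValueError("degenerate extent")
    proj = LocalEqualArea((lon_min + lon_max) / 2.0, (lat_min + lat_max) / 2.0)

    # km-frame bounds: project the densified extent ring and pad it, so the
    # construction box covers the curved image of the lon/lat rectangle
    edge = np.linspace(0.0, 1.0, 200)
    ring = np.concatenate([
        np.column_stack([lon_min + (lon_max - lon_min) * edge, np.full_like(edge, lat_min)]),
        np.column_stack([np.full_like(edge, lon_max), lat_min + (lat_max - lat_min) * edge]),
        np.column_stack([lon_min + (lon_max - lon_min) * edge[::-1], np.full_like(edge, lat_max)]),
        np.column_stack([np.full_like(edge, lon_min), lat_min + (lat_max - lat_min) * edge[::-1]]),
    ])
    frame = proj.project_geom(Polygon(ring))
    fx0, fy0, fx1, fy1 = frame.bounds
    x0, x1 = fx0 - 50, fx1 + 50
    y0, y1 = fy0 - 50, fy1 + 50

    xg = np.linspace(x0, x1, 600)
    coast_pts = np.column_stack([xg, _coast_y(xg)])
    isobath_off = 200.0 / shelf_slope
    # land: everything above the coastline
    land_km = Polygon(
        np.vstack([coast_pts, [[x1, y1 + 100], [x0, y1 + 100]]])
    ).buffer(0)
    deep_km = Polygon(
        np.vstack([(coast_pts - [0.0, isobath_off])[::-1], [[x0, y0 - 100], [x1, y0 - 100]]])
    ).buffer(0)
    # clipping to the projected extent ring keeps the water polygon inside
    # the bathymetry raster's coverage
    water_km = frame.difference(land_km.buffer(coastal_buffer_km)).difference(deep_km)

    # bathymetry raster on the lon/lat grid; depth from the analytic gradient
    ncols = int(round((lon_max - lon_min) / cell_deg))
    nrows = int(round((lat_max - lat_min) / cell_deg))
    lon_c = lon_min + (np.arange(ncols) + 0.5) * cell_deg
    lat_c = lat_max - (np.arange(nrows) + 0.5) * cell_deg
    LON, LAT = np.meshgrid(lon_c, lat_c)
    X, Y = proj.forward(LON, LAT)
    depth = np.minimum(0.0, -shelf_slope * (_coast_y(X) - Y))
    grid = AsciiGrid(values=depth, xll=lon_min, yll=lat_min, cell=cell_deg)

    coast_line_km = LineString(coast_pts)
    return HabitatDomain(
        coast=proj.unproject_geom(land_km),
        water_poly=proj.unproject_geom(water_km),
        bathymetry=grid,
        proj=proj,
        coast_line=proj.unproject_geom(coast_line_km),
    )


def build_threat_layers(habitat: HabitatDomain, seed: int = 0) -> ThreatLayers:
    """Synthetic analogues of the trawl-effort, platform, oil, EEZ/SSL and
    5-region layers, placed on the shelf so simulated foraging areas overlap
    at least some of them.
    """
    rng = np.random.default_rng(seed)
    proj = habitat.proj
    wx0, wy0, wx1, wy1 = proj.project_geom(habitat.water_poly).bounds
    frame_km = box(wx0 - 100, wy0 - 100, wx1 + 100, wy1 + 100)

    # 5 longitudinal region strips partitioning the full extent
    cuts = np.linspace(wx0 - 100, wx1 + 100, 6)
    regions = []
    for name, a, b in zip(_REGION_NAMES, cuts[:-1], cuts[1:]):
        regions.append((proj.unproject_geom(box(a, wy0 - 100, b, wy1 + 100)), {"region_name": name}))

    # trawl zones: a row of shelf rectangles with lognormal-ish effort
    zones = []
    n_zone = 6
    zcuts = np.linspace(wx0, wx1, n_zone + 1)
    for i in range(n_zone):
        ymid = _coast_y((zcuts[i] + zcuts[i + 1]) / 2.0)
        poly = box(zcuts[i], ymid - 180.0, zcuts[i + 1], ymid - 5.0)
        effort = float(np.round(np.exp(rng.uniform(np.log(48.8), np.log(10108.0))), 1))
        zones.append((proj.unproject_geom(poly), {"days_fished": effort}))

    # platforms: cluster on the western half of the shelf
    px = rng.uniform(wx0, (wx0 + wx1) / 2.0, size=40)
    py = _coast_y(px) - rng.uniform(5.0, 150.0, size=40)
    plon, plat = proj.inverse(px, py)
    platforms = [Point(lo, la) for lo, la in zip(np.atleast_1d(plon), np.atleast_1d(plat))]

    # oil footprint: blob on the north-central shelf
    cx = (wx0 + wx1) / 2.0
    cy = _coast_y(cx) - 80.0
    oil_km = Point(cx, cy).buffer(120.0)
    oil = proj.unproject_geom(oil_km)

    # EEZ split at the 2/3 longitude line: USA west, Mexico east
    eez_cut = wx0 + (wx1 - wx0) * 2.0 / 3.0
    eez = [
        (proj.unproject_geom(box(wx0 - 100, wy0 - 100, eez_cut, wy1 + 100)), {"country": "USA"}),
        (proj.unproject_geom(box(eez_cut, wy0 - 100, wx1 + 100, wy1 + 100)), {"country": "Mexico"}),
    ]

    # state submerged lands: 15-km coastal ribbon split into 4 states (USA side)
    ribbon = proj.project_geom(habitat.coast).buffer(15.0).intersection(frame_km)
    ribbon = ribbon.difference(proj.project_geom(habitat.coast))
    scuts = np.linspace(wx0 - 100, eez_cut, 5)
    states = ("Texas", "Louisiana", "Alabama", "Florida")
    ssl = []
    for name, a, b in zip(states, scuts[:-1], scuts[1:]):
        piece = ribbon.intersection(box(a, wy0 - 100, b, wy1 + 100))
        if not piece.is_empty:
            ssl.append((proj.unproject_geom(piece), {"state": name}))

    return ThreatLayers(
        trawl_zones=zones,
        platforms=platforms,
        oil_footprint=oil,
        eez=eez,
        ssl=ssl,
        regions=regions,
    )


# ---------------------------------------------------------------------------
# track simulation


def _rot(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s], [s, c]])


def _simulate_states(rng, phase_plan, alpha) -> tuple[np.ndarray, np.ndarray]:
    """Per-step behavioral state; forced by phase, Markov where state is None."""
    states = []
    phase_idx = []
    alpha = np.asarray(alpha, dtype=float)
    prev = 1
    for k, phase in enumerate(phase_plan):
        name, days = phase[0], phase[1]
        forced = phase[2] if len(phase) > 2 else PHASE_STATE.get(name)
        if days <= 0:
            raise ValueError(f"phase {name!r} has non-positive duration")
        n = int(round(days * STEPS_PER_DAY))
        for _ in range(n):
            if forced is None:
                prev = 1 + int(rng.random() < alpha[prev - 1, 1])
            else:
                prev = forced
            states.append(prev)
            phase_idx.append(k)
    return np.array(states, dtype=int), np.array(phase_idx, dtype=int)


def _simulate_path(rng, params: SimParams, states, phase_idx, start_xy, habitat) -> np.ndarray:
    """DCRW in the km frame: d_t = gamma_b R(theta_b) d_{t-1} + N(0, sigma^2 I),
    reflected off the coast (plus 2 km standoff) and the -200 m isobath when a
    habitat is supplied. Migration headings are seeded alongshore."""
    n = len(states)
    xy = np.empty((n + 1, 2))
    xy[0] = start_xy
    d_prev = np.zeros(2)
    sigma = params.sigma_proc
    iso_off = 200.0  # isobath offset for default slope 1 m/km
    heading = None
    for t in range(n):
        b = states[t]
        if t > 0 and b == 2 and states[t - 1] != 2 and habitat is not None:
            # new migration leg: aim alongshore toward a distant point
            sign = -1.0 if rng.random() < 0.5 else 1.0
            heading = np.array([sign, rng.uniform(-0.15, 0.15)])
            heading /= np.hypot(*heading)
            d_prev = heading * sigma / max(1e-6, 1.0 - params.gamma[1])
        g = params.gamma[b - 1]
        th = params.theta[b - 1]
        d = g * (_rot(th) @ d_prev) + rng.normal(0.0, sigma, size=2)
        new = xy[t] + d
        if habitat is not None:
            # reflect vertically off the coastal standoff and the isobath
            ycoast = _coast_y(new[0]) - 2.0
            if new[1] > ycoast:
                new[1] = 2 * ycoast - new[1]
            yiso = _coast_y(new[0]) - iso_off + 2.0
            if new[1] < yiso:
                new[1] = 2 * yiso - new[1]
            d = new - xy[t]
        xy[t + 1] = new
        d_prev = d
    return xy[1:]


def _duty_active(day_offset: np.ndarray, mode: str) -> np.ndarray:
    """Tag transmission schedule: continuously active for the first ~150 d
    (June-November for a mid-June deployment), then every 3rd day."""
    if mode == "continuous":
        return np.ones_like(day_offset, dtype=bool)
    seasonal_end = 150
    day = day_offset.astype(int)
    return (day < seasonal_end) | ((day - seasonal_end) % 3 == 0)


def simulate_tracks(params: SimParams, habitat: HabitatDomain | None = None):
    """Simulate ``params.n_turtles`` turtles.

    Returns a list of ``(true_track, fixes)`` pairs: ``true_track`` has
    columns t, lon, lat, state (8-h grid); ``fixes`` has columns animal_id,
    timestamp, lon, lat, lc at irregular Argos-like times.
    """
    rng = np.random.default_rng(params.seed)
    proj = habitat.proj if habitat is not None else LocalEqualArea(-89.0, 24.5)
    start_time = pd.Timestamp(params.start, tz="UTC")
    lc_names = list(LC_CLASSES)
    lc_p = np.array([params.lc_probs.get(c, 0.0) for c in lc_names])
    lc_p = lc_p / lc_p.sum()

    out = []
    for i in range(params.n_turtles):
        states, phase_idx = _simulate_states(rng, params.phase_plan, params.alpha)
        n = len(states)
        if habitat is not None:
            # nesting beach: on the coast, random longitude in the middle half
            wx0, _, wx1, _ = proj.project_geom(habitat.water_poly).bounds
            sx = rng.uniform(wx0 + 0.3 * (wx1 - wx0), wx0 + 0.7 * (wx1 - wx0))
            start_xy = np.array([sx, _coast_y(sx) - 8.0])
        else:
            start_xy = np.zeros(2)
        xy = _simulate_path(rng, params, states, phase_idx, start_xy, habitat)
        t_grid = start_time + pd.to_timedelta(np.arange(n) * DT_HOURS, unit="h")
        lon, lat = proj.inverse(xy[:, 0], xy[:, 1])
        true_track = pd.DataFrame(
            {"t": t_grid, "lon": lon, "lat": lat, "state": states}
        )

        # observation times: Poisson process thinned by duty cycle and gaps
        total_h = (n - 1) * DT_HOURS  # true path spans n points, n-1 steps
        n_obs = rng.poisson(params.fixes_per_day * total_h / 24.0)
        obs_h = np.sort(rng.uniform(0.0, total_h - 1e-6, size=n_obs))
        active = _duty_active(obs_h / 24.0, params.duty_cycle)
        keep = active & (rng.random(n_obs) >= params.gap_rate)
        obs_h = obs_h[keep]

        # linear interpolation of the true path in the km frame
        gi = obs_h / DT_HOURS
        j = np.clip(np.floor(gi).astype(int), 0, n - 2)
        w = gi - j
        px = xy[j, 0] * (1 - w) + xy[j + 1, 0] * w
        py = xy[j, 1] * (1 - w) + xy[j + 1, 1] * w

        lc_idx = rng.choice(len(lc_names), size=len(obs_h), p=lc_p)
        scale = np.array([params.lc_scale[lc_names[k]] for k in lc_idx])
        err = rng.standard_t(5, size=(len(obs_h), 2)) * scale[:, None]
        olon, olat = proj.inverse(px + err[:, 0], py + err[:, 1])
        fixes = pd.DataFrame(
            {
                "animal_id": f"sim{i:03d}",
                "timestamp": start_time + pd.to_timedelta(obs_h, unit="h"),
                "lon": np.atleast_1d(olon),
                "lat": np.atleast_1d(olat),
                "lc": [lc_names[k] for k in lc_idx],
            }
        )
        out.append((true_track, fixes))
    return out
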