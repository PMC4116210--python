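"""Two-state switching DCRW fitting and behavioral segmentation.

``fit_dcrw_switching`` regularizes an Argos track onto an 8-hour grid while
jointly estimating behavioral state (1 = resident/foraging, 2 = migration) by
MCMC. Downstream, ``classify_modes`` thresholds the posterior mean state,
``segment_track`` smooths the mode sequence into runs, ``select_main_periods``
extracts the main migration and the ordered foraging periods, and
``migration_stats`` summarizes durations and calendar occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._dcrw_mcmc import run_chain
from ._geo import LocalEqualArea
from .synthetic import DEFAULT_LC_SCALE

DT_HOURS = 8.0


@dataclass
class McmcConfig:
    """MCMC schedule. ``n_keep`` counts kept draws after thinning, so a chain
    runs ``n_burn + n_keep * thin`` sweeps."""

    n_chains: int = 2
    n_burn: int = 7000
    n_keep: int = 10000
    thin: int = 5
    seed: int = 0
    rhat_threshold: float = 1.1

    def __post_init__(self):
        if min(self.n_chains, self.n_burn, self.n_keep, self.thin) <= 0:
            raise ValueError("all MCMC counts must be positive")


@dataclass
class SsmFit:
    """Posterior summaries for one track."""

    animal_id: str
    states: pd.DataFrame        # t, lon, lat, lon_lo, lon_hi, lat_lo, lat_hi, b_mean, mode
    param_draws: pd.DataFrame   # per kept draw: gamma1, gamma2, theta1, theta2, a11, a22, sigma, chain
    converged: bool
    rhat: dict
    proj: LocalEqualArea
    accept_rate: float = float("nan")

    @property
    def param_means(self) -> pd.Series:
        return self.param_draws.drop(columns="chain").mean()


def split_rhat(chains: np.ndarray) -> float:
    """Split-R̂ (Gelman et al.) for draws shaped (n_chains, n_draws)."""
    c, n = chains.shape
    half = n // 2
    sub = chains[:, : 2 * half].reshape(c * 2, half)
    m = sub.mean(axis=1)
    w = sub.var(axis=1, ddof=1).mean()
    b = half * m.var(ddof=1)
    if w <= 0:
        return 1.0
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def _prepare_obs(fixes: pd.DataFrame, proj: LocalEqualArea, tau_lc: dict, t0, T: int):
    ox, oy = proj.forward(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    hours = (fixes["timestamp"] - t0).dt.total_seconds().to_numpy() / 3600.0
    gi = hours / DT_HOURS
    j = np.clip(np.floor(gi).astype(int), 0, T - 2)
    w = np.clip(gi - j, 0.0, 1.0)
    tau = fixes["lc"].map(tau_lc).to_numpy(dtype=float)
    obs = np.column_stack([ox, oy, w, tau, j.astype(float)])
    order = np.argsort(j, kind="stable")
    obs = obs[order]
    js = j[order]
    ptr = np.zeros(T, dtype=np.int64)
    np.add.at(ptr, js + 1, 1)
    ptr = np.cumsum(ptr)
    return obs, ptr


def fit_dcrw_switching(
    fixes: pd.DataFrame,
    config: McmcConfig | None = None,
    tau_lc: dict | None = None,
    sigma_prior_scale: float | None = None,
) -> SsmFit:
    """Fit the switching DCRW to one animal's fixes by MCMC.

    Fixes must be chronologically sorted with LC Z removed; at least 50 fixes
    spanning at least 10 days are required. Observation-error scales per LC
    class (``tau_lc``, km) default to the Argos band-midpoint calibration.
    Convergence is judged by split-R̂ <= ``config.rhat_threshold`` on the
    persistence and transition parameters across chains; a non-converged fit
    is returned with ``converged=False`` so callers can drop the animal.
    """
    config = config or McmcConfig()
    tau_lc = dict(DEFAULT_LC_SCALE if tau_lc is None else tau_lc)
    if (fixes["lc"] == "Z").any():
        raise ValueError("LC Z fixes must be removed before SSM fitting")
    fixes = fixes.sort_values("timestamp").reset_index(drop=True)
    animal = str(fixes["animal_id"].iloc[0]) if "animal_id" in fixes.columns else ""
    span_days = (fixes["timestamp"].iloc[-1] - fixes["timestamp"].iloc[0]).total_seconds() / 86400.0
    if len(fixes) < 50 or span_days < 10.0:
        raise ValueError(
            f"track {animal or '<unnamed>'} too short for SSM: "
            f"{len(fixes)} fixes over {span_days:.1f} days (need >=50 fixes, >=10 days)"
        )

    proj = LocalEqualArea(float(fixes["lon"].mean()), float(fixes["lat"].mean()))
    t0 = fixes["timestamp"].iloc[0]
    T = int(math.floor(span_days * 24.0 / DT_HOURS)) + 1
    obs, ptr = _prepare_obs(fixes, proj, tau_lc, t0, T)

    # initialize positions by linear interpolation of observations on the grid
    grid_h = np.arange(T) * DT_HOURS
    obs_h = (fixes["timestamp"] - t0).dt.total_seconds().to_numpy() / 3600.0
    ox, oy = proj.forward(fixes["lon"].to_numpy(), fixes["lat"].to_numpy())
    x_init = np.column_stack([np.interp(grid_h, obs_h, ox), np.interp(grid_h, obs_h, oy)])

    if sigma_prior_scale is None:
        d = np.diff(x_init, axis=0)
        sigma_prior_scale = float(max(np.hypot(d[:, 0], d[:, 1]).std(), 1.0) * 3.0)

    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_chains) % (2**31 - 1)
    all_params, all_pos, b2_total, accs = [], [], np.zeros(T, dtype=np.int64), []
    for c in range(config.n_chains):
        params, pos, b2, acc = run_chain(
            x_init.copy(), obs, ptr, config.n_burn, config.n_keep, config.thin,
            sigma_prior_scale, int(seeds[c]),
        )
        all_params.append(params)
        all_pos.append(pos)
        b2_total += b2
        accs.append(acc)

    names = ["gamma1", "gamma2", "theta1", "theta2", "a11", "a22", "sigma"]
    rhat = {}
    for i, nm in enumerate(["gamma1", "gamma2", "a11", "a22"]):
        k = names.index(nm)
        rhat[nm] = split_rhat(np.stack([p[:, k] for p in all_params]))
    converged = all(v <= config.rhat_threshold for v in rhat.values())

    pdraws = pd.DataFrame(np.vstack(all_params), columns=names)
    pdraws["chain"] = np.repeat(np.arange(config.n_chains), config.n_keep)

    pos = np.concatenate(all_pos, axis=0)  # (draws, T, 2)
    mean_xy = pos.mean(axis=0)
    lo_xy = np.quantile(pos, 0.025, axis=0)
    hi_xy = np.quantile(pos, 0.975, axis=0)
    lon, lat = proj.inverse(mean_xy[:, 0], mean_xy[:, 1])
    lon_lo, lat_lo = proj.inverse(lo_xy[:, 0], lo_xy[:, 1])
    lon_hi, lat_hi = proj.inverse(hi_xy[:, 0], hi_xy[:, 1])
    b_mean = 1.0 + b2_total / (config.n_chains * config.n_keep)

    states = pd.DataFrame(
        {
            "t": t0 + pd.to_timedelta(grid_h, unit="h"),
            "lon": lon, "lat": lat,
            "lon_lo": lon_lo, "lon_hi": lon_hi,
            "lat_lo": lat_lo, "lat_hi": lat_hi,
            "b_mean": b_mean,
        }
    )
    states = classify_modes(states)
    return SsmFit(
        animal_id=animal, states=states, param_draws=pdraws,
        converged=converged, rhat=rhat, proj=proj, accept_rate=float(np.mean(accs)),
    )


def classify_modes(states: pd.DataFrame, lower: float = 1.25, upper: float = 1.75) -> pd.DataFrame:
    """Set mode from b_mean: resident below ``lower``, migration above
    ``upper``, otherwise unassigned (the conventional '1.4' band)."""
    out = states.copy()
    b = out["b_mean"].to_numpy()
    mode = np.where(b > upper, "migration", np.where(b < lower, "resident", "unassigned"))
    out["mode"] = mode
    return out


def _smooth_labels(labels: np.ndarray, min_len: int) -> np.ndarray:
    """Minimum-change relabelling subject to every run having >= min_len
    states (dynamic program over binary labels; 0 resident, 1 migration).

    Short runs are thereby absorbed into whichever neighbour costs least,
    which collapses alternating stretches to the majority mode.
    """
    n = len(labels)
    if n == 0:
        return labels
    if n < min_len:
        # too short to enforce the constraint: collapse to the majority label
        maj = 1 if labels.sum() * 2 > n else 0
        return np.full(n, maj, dtype=labels.dtype)
    INF = np.int64(2**62)
    # cost is lexicographic (relabelled states, mode switches), encoded as
    # changes * (n+1) + switches so absorption is preferred on ties
    BIG = np.int64(n + 1)
    # dp[m][r]: min cost ending at position i with label m and current run
    # length min(r, min_len) (r in 1..min_len; index r-1)
    dp = np.full((2, min_len), INF, dtype=np.int64)
    back = np.full((n, 2, min_len, 2), -1, dtype=np.int16)
    for m in (0, 1):
        dp[m][0] = np.int64(labels[0] != m) * BIG
    for i in range(1, n):
        ndp = np.full((2, min_len), INF, dtype=np.int64)
        for m in (0, 1):
            cost = np.int64(labels[i] != m) * BIG
            # continue the run
            for r in range(min_len):
                if dp[m][r] < INF:
                    nr = min(r + 1, min_len - 1)
                    v = dp[m][r] + cost
                    if v < ndp[m][nr]:
                        ndp[m][nr] = v
                        back[i, m, nr] = (m, r)
            # switch label: allowed only from a completed run
            o = 1 - m
            if dp[o][min_len - 1] < INF:
                v = dp[o][min_len - 1] + cost + 1  # +1 counts the switch
                if v < ndp[m][0]:
                    ndp[m][0] = v
                    back[i, m, 0] = (o, min_len - 1)
        dp = ndp
    # best final state must have a completed run
    best = (0, min_len - 1) if dp[0][min_len - 1] <= dp[1][min_len - 1] else (1, min_len - 1)
    out = np.empty(n, dtype=labels.dtype)
    m, r = best
    for i in range(n - 1, -1, -1):
        out[i] = m
        m, r = back[i, m, r]
    return out


def segment_track(states: pd.DataFrame, min_len: int = 2) -> pd.DataFrame:
    """Run-length segments of the classified modes.

    Unassigned states are kept as gaps (never relabelled and never counted in
    either period); within each contiguous assigned stretch, modes are
    smoothed so no run is shorter than ``min_len`` states, changing as few
    states as possible.
    """
    mode = states["mode"].to_numpy().copy()
    assigned = mode != "unassigned"
    lab = np.where(mode == "migration", 1, 0)
    # smooth each contiguous assigned stretch independently
    i = 0
    n = len(mode)
    while i < n:
        if not assigned[i]:
            i += 1
            continue
        j = i
        while j < n and assigned[j]:
            j += 1
        sm = _smooth_labels(lab[i:j], min_len)
        mode[i:j] = np.where(sm == 1, "migration", "resident")
        i = j
    # run-length encode
    rows = []
    i = 0
    while i < n:
        j = i
        while j < n and mode[j] == mode[i]:
            j += 1
        rows.append(
            {
                "mode": mode[i],
                "start": states["t"].iloc[i],
                "end": states["t"].iloc[j - 1],
                "n_states": j - i,
                "role": "other",
            }
        )
        i = j
    return pd.DataFrame(rows)


def duration_days(start, end) -> int:
    """Inclusive duration: ceiling of elapsed time in days (minimum 1)."""
    return max(1, math.ceil((end - start).total_seconds() / 86400.0 - 1e-9))


def select_main_periods(
    segments: pd.DataFrame,
    daily_locations: pd.DataFrame | None = None,
    f1_index: int | None = None,
):
    """Pick the main migration and the ordered foraging periods.

    The first resident segment after the first migration segment is F1 (the
    per-animal ``f1_index`` override selects a later resident segment when a
    stop-over confuses the default); later resident segments are F2, F3, ...
    The main migration is the migration segment immediately preceding F1.
    Each foraging period is labelled 'kde' (>= 20 mean daily locations),
    'mcp' (>= 6 days), or 'last_point'.

    Returns (main_migration row or None, list of foraging rows). With no
    resident segment after migration, returns (None, []) — the animal joins
    the last-point group.
    """
    seg = segments.reset_index(drop=True)
    mig_idx = seg.index[seg["mode"] == "migration"]
    if len(mig_idx) == 0:
        return None, []
    first_mig = mig_idx[0]
    res_after = [i for i in seg.index if i > first_mig and seg.loc[i, "mode"] == "resident"]
    if not res_after:
        return None, []
    if f1_index is not None:
        res_after = [i for i in res_after if i >= f1_index]
        if not res_after:
            return None, []
    f1 = res_after[0]
    mig_before = [i for i in mig_idx if i < f1]
    main_mig = seg.loc[mig_before[-1]].copy() if mig_before else None
    if main_mig is not None:
        main_mig["role"] = "main_migration"

    foraging = []
    for rank, i in enumerate(res_after, start=1):
        row = seg.loc[i].copy()
        row["role"] = "foraging"
        row["period"] = f"F{rank}"
        days = duration_days(row["start"], row["end"])
        n_daily = 0
        if daily_locations is not None and len(daily_locations):
            d = daily_locations["date"]
            n_daily = int(((d >= row["start"].floor("D")) & (d <= row["end"].floor("D"))).sum())
        if n_daily >= 20:
            row["eligibility"] = "kde"
        elif days >= 6:
            row["eligibility"] = "mcp"
        else:
            row["eligibility"] = "last_point"
        row["days"] = days
        row["n_daily"] = n_daily
        foraging.append(row)
    return main_mig, foraging


def migration_stats(migrations: list, tracking_spans: list | None = None) -> dict:
    """Durations and calendar occupancy of the main migrations.

    ``migrations``: segment rows with start/end. ``tracking_spans``: optional
    (start, end) per animal defining when each was actively tracked; defaults
    to the migration span itself. Occupancy on a calendar day is the fraction
    of actively-tracked animals whose main migration covers that day.
    """
    durations = [duration_days(m["start"], m["end"]) for m in migrations]
    if not migrations:
        return {"durations": [], "total_days": 0, "occupancy": pd.Series(dtype=float)}
    spans = tracking_spans or [(m["start"], m["end"]) for m in migrations]
    day0 = min(s for s, _ in spans).floor("D")
    day1 = max(e for _, e in spans).floor("D")
    days = pd.date_range(day0, day1, freq="D")
    n_tracked = np.zeros(len(days))
    n_migrating = np.zeros(len(days))
    for (s, e), m in zip(spans, migrations):
        n_tracked += (days >= s.floor("D")) & (days <= e.floor("D"))
        n_migrating += (days >= m["start"].floor("D")) & (days <= m["end"].floor("D"))
    with np.errstate(invalid="ignore", divide="ignore"):
        occ = np.where(n_tracked > 0, n_migrating / np.maximum(n_tracked, 1), np.nan)
    return {
        "durations": durations,
        "total_days": int(sum(durations)),
        "occupancy": pd.Series(occ, index=days),
    }
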