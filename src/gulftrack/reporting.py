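"""Summary statistics, hypothesis tests, and recomputation of the published
table arithmetic from the packaged transcriptions.

`reproduce_table_summaries` recomputes every printed summary that is derivable
from the table cells (totals, means, sample SDs, ranges, regional counts,
jurisdiction and oiling tallies) and compares each against the printed value
at the printed precision, with half-away-from-zero rounding and the n−1 SD
convention — the combination that reproduces the printed numbers exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

# ---------------------------------------------------------------------------
# numeric summaries


@dataclass
class SummaryStats:
    n: int
    mean: float
    sd: float
    min: float
    max: float


def summarize_numeric(values) -> SummaryStats:
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("empty input")
    return SummaryStats(
        n=int(v.size),
        mean=float(v.mean()),
        sd=float(v.std(ddof=1)) if v.size > 1 else float("nan"),
        min=float(v.min()),
        max=float(v.max()),
    )


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (presentation convention)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


# ---------------------------------------------------------------------------
# hypothesis tests


def welch_t(a, b) -> dict:
    """Welch two-sample t-test with Welch–Satterthwaite df, two-sided."""
    res = stats.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def anova_oneway(*groups) -> dict:
    res = stats.f_oneway(*[np.asarray(g, float) for g in groups])
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)
    return {"F": float(res.statistic), "df": (df1, df2), "p": float(res.pvalue)}


def chi_square(table) -> dict:
    """Pearson chi-square on a contingency table, no continuity correction."""
    chi2, p, dof, _ = stats.chi2_contingency(np.asarray(table, float), correction=False)
    return {"chi2": float(chi2), "df": int(dof), "p": float(p)}


def group_tests(values, labels, kind: str) -> dict:
    """Dispatch on kind: 'welch_t' (exactly 2 groups), 'anova', 'chi2'
    (values = contingency table, labels ignored)."""
    if kind == "chi2":
        return chi_square(values)
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    if kind == "welch_t":
        if len(groups) != 2:
            raise ValueError("welch_t needs exactly 2 groups")
        return welch_t(groups[0], groups[1])
    if kind == "anova":
        return anova_oneway(*groups)
    raise ValueError(f"unknown test kind {kind!r}")


def simple_regression(x, y) -> dict:
    """OLS with intercept: slope, F on (1, n-2) df, p, R²."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    res = stats.linregress(x, y)
    n = len(x)
    r2 = res.rvalue**2
    f = float(r2 / max(1.0 - r2, 1e-300) * (n - 2))  # F = MSR/MSE on (1, n-2) df
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "F": f,
        "df": (1, n - 2),
        "p": float(res.pvalue),
        "r2": float(r2),
    }


# ---------------------------------------------------------------------------
# published tables


@dataclass
class PaperTables:
    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame
    table4: pd.DataFrame


def load_paper_tables(directory=None) -> PaperTables:
    """Load the packaged table transcriptions (or a drop-in directory) and
    validate the published row counts (40 KDE, 10 MCP, 50 centroids)."""
    def _read(name):
        if directory is not None:
            return pd.read_csv(f"{directory}/{name}", dtype={"tag": str})
        path = resources.files("gulftrack") / "data" / "paper_tables" / name
        with path.open() as fh:
            return pd.read_csv(fh, dtype={"tag": str})

    t = PaperTables(_read("table1.csv"), _read("table2.csv"), _read("table3.csv"), _read("table4.csv"))
    if len(t.table2) != 40:
        raise ValueError(f"table2 must have 40 rows, got {len(t.table2)}")
    if len(t.table3) != 10:
        raise ValueError(f"table3 must have 10 rows, got {len(t.table3)}")
    if len(t.table4) != 50:
        raise ValueError(f"table4 must have 50 rows, got {len(t.table4)}")
    return t


#: printed summary values transcribed from the published text and table
#: mean/SD rows: name -> (printed value, decimals printed)
PRINTED = {
    "table1_total_tracks": (59, 0),
    "table2_total_foraging_days": (5339, 0),
    "table2_days_mean": (133.5, 1),
    "table2_days_sd": (117.1, 1),
    "table2_days_min": (22, 0),
    "table2_days_max": (416, 0),
    "table2_total_filtered_locations": (18938, 0),
    "table2_filtered_mean": (473.5, 1),
    "table2_filtered_sd": (306.8, 1),
    "table2_total_daily_locations": (3181, 0),
    "table2_daily_mean": (79.5, 1),
    "table2_daily_sd": (65.5, 1),
    "table2_kde50_mean": (100.7, 1),
    "table2_kde50_sd": (141.8, 1),
    "table2_kde50_min": (4.5, 1),
    "table2_kde50_max": (851.8, 1),
    "table2_kde95_mean": (504.3, 1),
    "table2_kde95_sd": (621.4, 1),
    "table2_kde95_min": (22.0, 1),
    "table2_kde95_max": (3628.5, 1),
    "table3_days_mean": (26.0, 1),
    "table3_days_sd": (20.4, 1),
    "table3_days_min": (6, 0),
    "table3_days_max": (62, 0),
    "table3_filtered_mean": (106.2, 1),
    "table3_filtered_sd": (88.0, 1),
    "table3_mcp_mean": (648.4, 1),
    "table3_mcp_sd": (562.3, 1),
    "table3_mcp_min": (148.5, 1),
    "table3_mcp_max": (1987.1, 1),
    "table4_kde_depth_mean": (-32.5, 1),
    "table4_kde_depth_sd": (19.8, 1),
    "table4_kde_depth_min": (-72.0, 1),
    "table4_kde_depth_max": (-2.0, 1),
    "table4_kde_dist_mean": (47.6, 1),
    "table4_kde_dist_sd": (38.9, 1),
    "table4_kde_dist_min": (0.6, 1),
    "table4_kde_dist_max": (138.4, 1),
    "table4_mcp_depth_mean": (-24.9, 1),
    "table4_mcp_depth_sd": (22.1, 1),
    "table4_mcp_dist_mean": (43.0, 1),
    "table4_mcp_dist_sd": (50.9, 1),
    "table4_all_depth_mean": (-31.0, 1),
    "table4_all_depth_sd": (20.3, 1),
    "table4_all_dist_mean": (46.7, 1),
    "table4_all_dist_sd": (41.0, 1),
    "table4_trawl_mean": (5058.3, 1),
    "table4_trawl_sd": (4003.7, 1),
    "table4_trawl_min": (48.8, 1),
    "table4_trawl_max": (10108.0, 1),
    "table4_trawl_n": (37, 0),
    "table4_oiled_centroids": (10, 0),
    "table4_ssl_centroids": (9, 0),
    "table4_us_eez_centroids": (37, 0),
    "table4_mexico_eez_centroids": (13, 0),
    "table4_turtles_total": (44, 0),
    "table4_turtles_wfl": (16, 0),
    "table4_turtles_ngom": (14, 0),
    "table4_turtles_sgom": (8, 0),
    "table4_turtles_snwa": (5, 0),
    "table4_turtles_wgom": (1, 0),
}

US_STATES = {"Texas", "Louisiana", "Mississippi", "Alabama", "Florida"}


def compute_table_summaries(tables: PaperTables) -> dict:
    """Every printed summary recomputed from the table cells."""
    t1, t2, t3, t4 = tables.table1, tables.table2, tables.table3, tables.table4
    out: dict[str, float] = {}
    out["table1_total_tracks"] = float(t1[["n_2010", "n_2011", "n_2012", "n_2013"]].to_numpy().sum())

    for name, col in [("days", "days"), ("filtered", "filtered_locations"),
                      ("daily", "daily_locations"), ("kde50", "kde50_km2"), ("kde95", "kde95_km2")]:
        s = summarize_numeric(t2[col])
        out[f"table2_{name}_mean"] = s.mean
        out[f"table2_{name}_sd"] = s.sd
        out[f"table2_{name}_min"] = s.min
        out[f"table2_{name}_max"] = s.max
    out["table2_total_foraging_days"] = float(t2["days"].sum())
    out["table2_total_filtered_locations"] = float(t2["filtered_locations"].sum())
    out["table2_total_daily_locations"] = float(t2["daily_locations"].sum())

    for name, col in [("days", "days"), ("filtered", "filtered_locations"), ("mcp", "mcp_km2")]:
        s = summarize_numeric(t3[col])
        out[f"table3_{name}_mean"] = s.mean
        out[f"table3_{name}_sd"] = s.sd
        out[f"table3_{name}_min"] = s.min
        out[f"table3_{name}_max"] = s.max

    kde = t4[t4["estimator"] == "KDE"]
    mcp_ = t4[t4["estimator"] == "MCP"]
    for sub, nm in [(kde, "kde"), (mcp_, "mcp"), (t4, "all")]:
        sd_ = summarize_numeric(sub["depth_m"])
        sdist = summarize_numeric(sub["dist_to_land_km"])
        out[f"table4_{nm}_depth_mean"] = sd_.mean
        out[f"table4_{nm}_depth_sd"] = sd_.sd
        out[f"table4_{nm}_depth_min"] = sd_.min
        out[f"table4_{nm}_depth_max"] = sd_.max
        out[f"table4_{nm}_dist_mean"] = sdist.mean
        out[f"table4_{nm}_dist_sd"] = sdist.sd
        out[f"table4_{nm}_dist_min"] = sdist.min
        out[f"table4_{nm}_dist_max"] = sdist.max

    trawl = summarize_numeric(t4["trawl_days_fished"])
    out["table4_trawl_mean"] = trawl.mean
    out["table4_trawl_sd"] = trawl.sd
    out["table4_trawl_min"] = trawl.min
    out["table4_trawl_max"] = trawl.max
    out["table4_trawl_n"] = float(trawl.n)
    out["table4_oiled_centroids"] = float(t4["oiled"].sum())
    out["table4_ssl_centroids"] = float(t4["jurisdiction"].isin(US_STATES).sum())
    out["table4_us_eez_centroids"] = float(
        (t4["jurisdiction"].isin(US_STATES) | (t4["jurisdiction"] == "USA")).sum()
    )
    out["table4_mexico_eez_centroids"] = float((t4["jurisdiction"] == "Mexico").sum())

    # per-turtle regional counts: a turtle counts once, in its first-listed region
    per_turtle = t4.groupby("tag", sort=False)["region"].first()
    out["table4_turtles_total"] = float(len(per_turtle))
    counts = per_turtle.value_counts()
    for reg in ("WFL", "NGoM", "SGoM", "SNWA", "WGoM"):
        out[f"table4_turtles_{reg.lower()}"] = float(counts.get(reg, 0))
    return out


def reproduce_table_summaries(tables: PaperTables) -> pd.DataFrame:
    """Recompute each printed summary and compare at the printed precision.

    Returns a frame with columns quantity, computed, printed, precision, ok.
    """
    computed = compute_table_summaries(tables)
    rows = []
    for name, (printed, nd) in PRINTED.items():
        c = computed[name]
        ok = round_half_away(c, nd) == round_half_away(float(printed), nd)
        rows.append({"quantity": name, "computed": c, "printed": printed, "precision": nd, "ok": ok})
    return pd.DataFrame(rows)


def region_disagreements(tables: PaperTables) -> pd.DataFrame:
    """Rows where the KDE table and the centroid table assign the same
    (tag, period) to different regions — a known inconsistency in the
    published tables, flagged rather than resolved."""
    t2 = tables.table2[["tag", "period", "region"]].rename(columns={"region": "region_table2"})
    t4 = tables.table4[tables.table4["estimator"] == "KDE"][["tag", "period", "region"]].rename(
        columns={"region": "region_table4"}
    )
    merged = t2.merge(t4, on=["tag", "period"], how="inner")
    return merged[merged["region_table2"] != merged["region_table4"]].reset_index(drop=True)
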