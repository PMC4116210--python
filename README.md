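# gulftrack

Post-nesting satellite-telemetry analysis for Gulf of Mexico loggerheads
(*Caretta caretta*): behavioral segmentation of Argos tracks with a switching
state-space model, foraging-area estimation, site-fidelity testing, and
spatial overlap of foraging centroids with anthropogenic threat layers.

The package is aimed at movement ecologists who need the full published
pipeline — from raw Argos fix tables to threat-annotated foraging centroids —
as tested, reusable code. Because the original tracking data are not public,
a first-class synthetic-data module generates ground-truthed three-phase
turtle tracks (inter-nesting → migration → foraging residency) observed
through Argos-class error, so every downstream stage can be exercised and
validated against known truth.

## The model

Tracks are regularized to an 8-hour grid by a two-state switching
first-difference correlated random walk (DCRW) fitted by MCMC. With
displacement d_t = x_{t+1} − x_t and behavioral state b_t ∈ {1, 2}
(1 = resident/foraging, 2 = migration):

    d_t = γ_{b_t} T(θ_{b_t}) d_{t−1} + ε_t,      ε_t ~ N(0, σ² I)
    b_t | b_{t−1} ~ Markov(α),                   α rows sum to 1
    y_i ~ t₅( (1−w_i) x_{j_i} + w_i x_{j_i+1},  τ_{LC(i)} )

γ_k is move persistence (γ_migration > γ_resident), T(θ) a rotation, and
observations y_i are heavy-tailed (Student-t, df 5) around the path linearly
interpolated to the irregular fix times, scaled per Argos location class.
The posterior mean of b_t ("b_mean" ∈ [1, 2]) is thresholded at 1.25/1.75
into resident / unassigned / migration.

Downstream: the migration segment immediately before the first post-migration
resident segment is the main migration; foraging periods get fixed-kernel KDE
home ranges (least-squares cross-validated bandwidth, 50/95% isopleths
clipped to water) when ≥ 20 mean daily locations exist, otherwise 100%
minimum convex polygons; site fidelity is tested against 100 habitat-
constrained random walks that retrace the observed step lengths (percentile
100·k/101); and each foraging centroid is annotated with depth, distance to
land, region, trawl effort, platform proximity, oil-footprint membership and
jurisdiction.

## Worked example

The numbered scripts under `analysis/` run the pipeline end-to-end on a
six-turtle synthetic cohort and write their tables under `results/`:

```sh
python analysis/01_simulate.py     # habitat + threat layers + Argos tracks
python analysis/02_filter.py       # LC-Z / on-land / 5 kph / −200 m ladder
python analysis/03_fit_ssm.py      # switching DCRW per track, segmentation
python analysis/04_homerange.py    # KDE / MCP areas + site fidelity
python analysis/05_context.py      # centroid annotation, turtle-day grid
python analysis/06_report.py       # published-table arithmetic check
```

Output from a full run:

```
simulated 6 turtles, 5113 Argos fixes -> results/sim
5113 fixes -> 4226 retained (82.7%); rejections: {'speed': 668, 'lc_z': 197, 'on_land': 22}
955 mean daily locations
sim000: gamma=(0.16,0.88) alpha_diag=(1.00,0.98) converged
...
migration duration: 20-26 d (mean 22.7 +/- 2.1 SD), total 136 d
peak migration occupancy 100% on 2012-07-09
6 foraging periods: 6 KDE, 0 MCP, 0 last-point
KDE50 area: mean 366.9 km^2, KDE95 mean 1462.3 km^2
site fidelity passed: 4/6
6 centroids annotated; regions: {'SNWA': 3, 'NGoM': 2, 'WFL': 1}
turtle-days grid: 1346 turtle-days over 182 cells
oiled foraging days: 33/666 (5.0%)
61/61 printed summaries reproduced at printed precision
```

Reading the numbers: the simulated tags were programmed with a ~23-day
migration, and the model recovers 20–26 day main migrations with the cohort's
occupancy peaking in early July; per-track persistence estimates
(γ ≈ 0.1–0.2 resident, ≈ 0.9 migration) bracket the generator's truth
(0.2 / 0.9). The 50% KDE core areas average ~370 km² — larger than for real
foraging turtles, because the synthetic resident state wanders diffusively
instead of defending a patch (see `docs/methods.md`). The final line verifies
that all 61 summary statistics printed in the published Tables 1–4 (totals,
means, sample SDs, ranges, regional counts) are reproduced exactly at printed
precision from the packaged table transcriptions in
`src/gulftrack/data/paper_tables/`.

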