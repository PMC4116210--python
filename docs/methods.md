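# Methods

## Scope and shape

`gulftrack` implements the post-nesting loggerhead telemetry pipeline as a
library (`src/gulftrack/`) driven by numbered analysis scripts
(`analysis/`). The stages are: synthetic data generation, Argos fix
filtering, switching state-space segmentation, home-range estimation,
site-fidelity testing, spatial annotation, and summary reporting. Because
the original tracking data are not deposited anywhere, the packaged
transcriptions of the published summary tables are the only real data in the
repository; everything else is exercised on synthetic tracks with known
ground truth.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, not
any particular ocean. Its defaults are the study conditions used throughout
the tests:

- **Itinerary**: 25 d inter-nesting residency, 23 d migration, 134 d
  foraging residency — matching the published mean migration (23.0 d) and
  mean foraging duration (133.5 d). Phases force the behavioral state;
  passing a phase with state `None` instead runs the two-state Markov chain
  freely from the transition matrix (used for parameter-recovery tests).
- **Movement**: a two-state DCRW simulated in a local Lambert azimuthal
  equal-area km frame. Defaults γ = (0.2, 0.9) for (resident, migration),
  θ = (0, 0), process s.d. 1.5 km per 8-h step. In migration this sustains
  ≈ 45 km/d, a realistic post-nesting travel rate; migration headings are
  seeded alongshore toward a distant destination and persistence does the
  rest. Tracks reflect off a 2-km coastal standoff and the −200 m isobath.
- **Observation**: fix times are a Poisson process (6/day while the tag is
  active — the tag duty cycle is continuous for the first ~150 days, then
  every 3rd day), thinned by independent Bernoulli gaps (default 10%).
  Positions are linear interpolations of the true path plus isotropic
  Student-t (df 5) error scaled per location class. Class frequencies
  default to a B/A-heavy mix typical of turtle PTTs; per-class scales are
  calibrated so the 68th percentile of the error radius sits at the Argos
  accuracy band midpoints (125 m for LC 3, 375 m for LC 2, 1 km for LC 1,
  then 2/3/5 km for 0/A/B and 15 km for the implausible class Z). The
  68th-percentile radial quantile of the bivariate t₅, 1.7451, was computed
  once by quadrature and frozen.
- **Habitat and threats**: a wiggly northern coastline with a linear depth
  gradient (1 m per km offshore), so the −200 m isobath parallels the coast;
  five longitudinal region strips (WGoM, NGoM, WFL, SNWA, SGoM) partitioning
  the domain; trawl-effort rectangles on the shelf (48.8–10108 days fished,
  log-uniform — the published effort range); a platform cluster in the west;
  an oil-footprint disc; an EEZ split (USA west, Mexico east) and four
  state-submerged-lands ribbons.

What the generator does *not* emulate: site attraction during residency (the
resident state wanders diffusively, so synthetic core areas are several
times larger than real foraging turtles' ~100 km², and very long synthetic
"foraging" tracks can fail site-fidelity tests that real, patch-faithful
turtles pass), tides and currents, diving behavior, or tag battery decay.
Passing tests therefore demonstrate that the estimators recover the known
structure of this model class under Argos-like observation — not that real
turtles behave like the generator.

## Filtering ladder

Flags are applied in the order `manual` → `lc_z` → `on_land` → `speed` →
`deep`. The speed rule pairs each candidate with the last *retained* fix of
the same animal (single forward pass, great-circle distance / elapsed time,
threshold 5 kph) and flags the later fix; coincident duplicate-time fixes
are kept, displaced ones flagged. The depth rule drops fixes over water
deeper than −200 m (neritic cutoff) by bilinear bathymetry sampling. Daily
locations are arithmetic lon/lat means per UTC calendar day; foraging
clusters span well under 2°, where the curvature error is far below the
Argos error floor. Filtering is idempotent and never deletes rows — the
retained set is exactly the unflagged rows.

## Switching DCRW and its sampler

The model is fitted per track by a Metropolis-within-Gibbs sampler written
for this package (numba-compiled):

1. **Discrete states** by forward-filtering backward-sampling on the
   displacement likelihoods.
2. **Positions** on the exact 8-h grid from the first fix, by sequential
   single-site Gaussian Metropolis with per-site scales adapted during
   burn-in to ≈ 30% acceptance. Observations enter through the
   time-proportional interpolation weights.
3. **γ, θ** per state by conjugate draws given σ (truncated normal on [0,1];
   von Mises for θ), with an independence-MH correction for the migration
   persistence prior.
4. **Transition matrix** rows by Beta draws.
5. **σ** by random-walk Metropolis on log σ under a half-normal prior whose
   scale is set from the empirical step distribution.

Priors, and why they are not flat. Label switching is resolved by relabeling
so γ_migration > γ_resident in every retained draw. Beyond the ordering,
two weakly-informative choices are load-bearing:

- γ_migration ~ Beta(20, 3): migration in this model family is
  near-ballistic. Without this, the second state latches onto transient
  mid-persistence excursions that finite resident tracks inevitably contain
  (windowed persistence on a 40-day resident simulation reaches 0.66), and a
  pure-resident track is split 50/50 between states.
- Transition diagonals ~ Beta(30, 1) and an initial state distribution of
  (0.9, 0.1) favoring resident: behavioral phases last weeks relative to the
  8-h step, and tags are deployed on nesting (resident) females. The
  stickiness also keeps the unused state empty on single-state tracks.

Even so, a two-state model on finite resident data yields intermediate
posterior state means over genuinely ambiguous stretches; these fall into
the unassigned band (1.25 < b_mean < 1.75) and are excluded downstream —
which is also why classification accuracy is assessed over mode-assigned
grid points.

Convergence is judged by split-R̂ ≤ 1.1 on (γ₁, γ₂, α₁₁, α₂₂) across two
chains; non-converged animals are dropped by the drivers, mirroring how
short or gappy tracks are discarded in practice. Observation scales τ per
location class are fixed to the generator's calibrated values when fitting
synthetic data.

**Schedules and problem sizes.** `McmcConfig` defaults to the full protocol
(2 chains, 7000 burn-in, 10000 kept, thin 5). The tests, drivers, and the
acceptance script run the scaled-down schedule of 2 chains × 2000 kept draws
(burn-in 1000, thin 2), which on simulated tracks reproduces the full
schedule's posterior summaries to well within their Monte-Carlo error; the
recovery suite uses 20 tracks of ~1500 fixes (250 days) each, and the
acceptance script 6 such tracks.

## Segmentation and period selection

Classified modes are smoothed by a dynamic program that enforces a minimum
run length (default 2 states) while changing as few states as possible,
breaking ties toward fewer mode switches; unassigned runs are immutable gaps
and never count toward either period. The first resident segment after the
first migration segment is the first foraging period F1 (later resident
segments are F2, F3, …); the migration segment immediately before F1 is the
main migration; a per-animal override selects a later segment when a
stop-over confuses the default. Foraging periods are KDE-eligible with ≥ 20
mean daily locations, MCP-eligible at ≥ 6 days, otherwise last-point-only.
Durations are inclusive day counts (ceiling of elapsed time). Calendar
occupancy divides animals in migration mode by animals actively tracked that
UTC day.

## Home ranges

KDE bandwidths minimize the least-squares cross-validation score of a
Gaussian kernel on per-axis standardized coordinates (closed-form pairwise
expression), searched over 50 log-spaced values in [0.05, 2] × the Gaussian
reference bandwidth and refined by bounded scalar minimization; ties break
toward the smaller h, and a monotone CV curve is clamped at the floor with a
warning (LSCV degenerates on duplicate points — hence daily-location inputs,
and resampling checks avoid exact ties). The utilization distribution is
evaluated on a 1-km grid padded 4 bandwidths beyond the points (≤ 1% mass
truncation) and normalized to unit mass; isopleths take the densest cells
holding the target mass, polygonize them by row-run rectangles, and
intersect with the water polygon for in-water area. Centroids follow the
largest-activity-center rule (centroid of the largest disjoint 50% polygon),
computed on the *unclipped* geometry — clipping affects areas only, which is
what keeps near-shore centroids near shore. MCPs are convex hulls of all
filtered fixes with in-water area and full-hull centroids. All geometry is
done in the local equal-area km frame (Lambert azimuthal; over a Gulf-scale
extent the area distortion is negligible relative to every tolerance used).

## Site fidelity

The test statistic is the mean squared distance of fixes from their
centroid. Each of 100 replicates retraces the observed step-length sequence
from the observed start with uniform turning angles, constrained to the
water polygon by redraw-then-reflect (pure rejection can stall in narrow
bays). The reported percentile is 100·k/(m+1) with k the replicates at least
as dispersed as the observation — the (m+1) permutation denominator that
produces the characteristic values 99.0099, 98.0198, 96.0396. A track passes
at the 95 threshold exactly when k ≥ 96, giving a 5/101 ≈ 4.95% type-I rate,
which the calibration test verifies with an exact binomial interval.

## Spatial annotation

Depth is a bilinear bathymetry sample; distance to land is the minimum
great-circle distance to the densified unbuffered coastline (the 2000-m
coastal buffer applies only to random-walk bounding); region, oil, EEZ and
state-lands membership are point-in-polygon with `covers` (boundary points
count); platform proximity is any platform within 10 km great-circle; trawl
effort is the `days_fished` attribute of the containing zone, `None` where
no layer applies. A centroid outside every region polygon raises rather than
snapping to the nearest. Turtle-day grids use half-open 10-km cells in the
km frame; each (animal, UTC day, cell) with ≥ 1 non-Z fix contributes one
turtle-day, so a turtle visiting two cells in a day contributes two.
Oiled-day counting marks an (animal, day) as oiled if any retained fix that
day lies in the oil polygon.

## Reporting

Summary statistics use the sample (n−1) standard deviation — the convention
that reproduces the published MCP-centroid depth summary (−24.9 ± 22.1 m)
exactly — and half-away-from-zero rounding at presentation. Hypothesis tests
delegate to scipy: Welch t with Welch–Satterthwaite df, one-way ANOVA,
Pearson chi-square without continuity correction, OLS regression reported as
F on (1, n−2) df with R². `reproduce_table_summaries` recomputes all 61
printed summaries derivable from the packaged Table 1–4 transcriptions and
compares each at its printed precision. Statistics whose raw inputs were
never published (per-turtle carapace sizes, the migration-duration list, the
published t and regression F values) are not recomputable and are not
attempted. The transcriptions keep two known inconsistencies of the source
tables visible: five KDE rows whose region differs between the KDE table and
the centroid table are flagged (not resolved), and the tag printed once as
"129296" is normalized to 129496, the only reading consistent with the
published per-turtle counts (44 turtles, 8 in SGoM).

## Numerical choices and edge cases

- ESRI ASCII grids are read/written by a small in-package reader (the format
  is a text header plus rows); sampling clamps to the nearest edge outside
  the grid.
- GeoJSON I/O goes through shapely's `mapping`/`shape` (WGS84 lon/lat).
- Zero-elapsed-time fix pairs: the later fix is speed-flagged if displaced,
  retained if coincident.
- `lscv_bandwidth` requires ≥ 20 points and non-degenerate variance;
  `mcp` requires ≥ 3 non-collinear points; `isopleth` requires a level in
  (0, 1); empty geometries have no centroid.
- The grid for a track spanning D days has ⌊3D⌋ + 1 states; b_mean at the
  two leading grid points inherits the first interior state.
- Seeds: every stochastic component takes an explicit seed; chains derive
  per-chain seeds from a `SeedSequence`, and fixed seeds make
  `simulate_tracks` bit-reproducible.

## Known limitations

- The resident state has no home-range attraction, so synthetic long-stay
  "foraging" areas grow with tracking duration faster than real ones.
- The sampler estimates a scalar isotropic process variance rather than a
  full 2×2 covariance; on the simulated conditions this is exact, on real
  data it is an approximation the model family commonly makes.
- Only two behavioral states, on a fixed 8-h grid; no continuous-time
  variant.
- The informative migration-persistence prior trades flexibility for
  identification: systems where migration is weakly persistent (γ ≈ 0.5)
  would need a wider prior and would then re-admit the resident-track
  ambiguity described above.
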