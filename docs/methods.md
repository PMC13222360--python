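# Methods

This note documents the models, operational definitions, default
parameters and numerical choices behind `flyway`, and what the synthetic
generator does and does not emulate.

## Data model

The unit of raw data is a GPS fix: a UTC timestamp and a WGS84 position,
optionally with tag-reported ground speed.  All distances throughout the
package are great-circle distances on a sphere of radius 6371.0 km
(haversine); no map projection is used, so site fidelity (hundreds of
metres), stopover spots (km) and flyway-scale route separations
(thousands of km) are measured with a single consistent metric.

A *season track* is the fix sequence of one migration leg: spring runs
wintering → breeding, autumn the reverse.  The derived master table holds
one row per bird × season × cycle-year with phenology, distances,
stopover statistics, site coordinates, the mean fix interval dt and the
bird's spatial cluster — the input to all statistics.

## Segmentation rules

Everything is rule-based; there are no hidden-state or change-point
models.  The thresholds live in `PipelineConfig` and are all overridable:

| parameter | default | role |
|---|---|---|
| `speed_threshold_kmh` | 24 | flight iff point-to-point speed strictly > threshold |
| `stopover_min_duration_min` | 60 | minimum stationary bout duration at a single spot |
| `stopover_spot_radius_km` | 5 | "single spot" radius around the bout's running centroid |
| `winter_min_stay_days` | 20 | minimum residency duration (strictly >) for a seasonal site |
| `site_radius_km` | 20 | residency radius around the running centroid |
| `site_buffer_km` | 20 | buffer whose crossing defines departure/arrival |
| `nest_grid_deg` | 0.0001 | nest = centre of the densest grid cell (~11 m) |
| `max_gap_h` | 24 | legs with any inter-fix gap strictly > 24 h are discarded |
| `cluster_radius_km` | 250 | spatial pooling radius (150/500 for sensitivity) |

Point-to-point speed is assigned to the *later* fix of each step; the
first fix inherits the label of the second.  The boundary is strict:
exactly 24 km/h is stationary, and a gap of exactly 24 h is accepted.

Residencies are maximal runs of fixes that stay within `site_radius_km`
of their running centroid.  (A running *medoid* would be near-identical
for these compact clouds but is quadratic to maintain; the centroid is the
deliberate choice.)  Residencies longer than 20 days are seasonal sites;
they are classified breeding vs wintering by latitude relative to the
bird's latitudinal midpoint, which encodes the assumption of a
north-breeding population.  When one non-breeding period contains several
>20 d residencies, the southernmost wins.  Wintering-site position is the
mean of member fixes; breeding-site position is the nest-grid mode (ties
broken toward the mean breeding position; the mean itself is the fallback
when no grid mode can be resolved).

Departure is the first fix outside the site buffer after the last
in-buffer fix preceding the next site; arrival is the first fix inside
the destination buffer.  No interpolation is done: with fix intervals
almost always below an hour, the discretisation error is far below the
day-level precision at which phenology is interpreted.

Stopover bouts are runs of stationary fixes at a single spot, extended
backwards by one fix because the step *into* the first stationary fix is
mostly flight while the bird is already at the spot when that fix is
taken; duration is last minus first timestamp of the extended bout.  With
30-min fixes this guarantees detection of every true bout ≥ 90 min, while
true bouts between 60 and 90 min may fall under the threshold depending
on sampling phase — a resolution limit, not a bug.

Phases (wintering / breeding / stopover / migration-flight) tile the
trajectory: every fix carries exactly one label, and intervals are
derived from maximal label runs (single-fix runs are merged into their
predecessor so every interval has positive duration).  A cycle-year is
the calendar year of its spring departure; a wintering phase spanning New
Year belongs to the cycle of the following spring.

## Repeatability

For a Gaussian trait the model is

    y = X beta + Z u + e,   u ~ N(0, sigma2_id I),   e ~ N(0, sigma2_res I)

with X = intercept + spatial-cluster contrasts + log(dt + 1) (dt in
minutes; optionally sex and capture country), and

    R = sigma2_id / (sigma2_id + sigma2_res)

is the *adjusted* repeatability: the fraction of the variance left after
the fixed effects that is attributable to consistent individual
differences.  Fitting cluster as a fixed effect separates individual
consistency from spatially structured variation along a chain-migration
flyway, where departure dates and distances co-vary strongly with where a
bird breeds and winters.

Estimation is REML.  The model has a single variance ratio
λ = sigma2_id/sigma2_res, so the REML criterion is profiled over log λ
with a bounded scalar search (log λ ∈ [−16, 16], tolerance 1e−9) plus an
explicit boundary evaluation; boundary solutions report sigma2_id = 0 and
hence R = 0 rather than failing.  Per-group sufficient statistics make one
fit O(g·p²) after an O(n·p²) setup, which is what makes 1000-fold
bootstrap and permutation loops cheap.  On balanced covariate-free data
with a positive ANOVA estimate the profile-REML solution equals the
one-way ANOVA intraclass correlation to 1e−6, and it matches statsmodels
MixedLM (an independent implementation) on covariate-rich designs; both
checks are in the test suite.

Inference:

* **Bootstrap CI** — parametric: responses are re-simulated from the
  fitted model (fixed effects + Gaussian id effects + Gaussian residuals)
  and refitted; the percentile 2.5/97.5 interval over n_boot = 1000
  resamples is reported.  Refit failures above 5% are recorded as a
  warning on the result.  Measured calibration at 50 ids × 4 obs:
  |bias| < 0.01 and coverage 92–97% for true R ∈ {0.2, 0.5, 0.8}
  (recomputed in `tests/test_acceptance.py`).
* **Permutation p** — individual labels are permuted across observations
  (the fixed-effect design untouched), and
  p = (1 + #{R_perm ≥ R_obs})/(n_perm + 1), never zero by construction.
  Note that the *point* estimate under permutation is a truncated,
  boundary-inflated null with sd ≈ sqrt(2/(k(k−1)N)); at 50 × 4 that is
  ≈ 0.06, so single permuted estimates above 0.05 are expected even
  though the median is ~0.
* **Count traits** (stopover number) — an overdispersion check
  (Pearson χ²/df of a fixed-effects-only Poisson fit) gates the pathway:
  above 1.5 ("substantial", a deliberate operational choice) the trait is
  square-root transformed and analysed by the Gaussian path; otherwise a
  Poisson log-link GLMM is fitted by Laplace approximation (inner Newton
  per group, outer Nelder–Mead over (beta, log sigma2)) and the
  latent-scale R = sigma2_id/(sigma2_id + ln(1 + 1/λ̄)) is reported, with
  λ̄ the fitted mean at the mean covariates.

Sensitivity analyses refit every trait with cluster assignments under
alternative pooling radii (150/250/500 km), reporting per-trait ΔR,
Pearson correlation of R vectors between radii, and R with/without sex
and capture country; a radius yielding fewer than two comparison clusters
or aliased designs is flagged unstable and excluded from correlations.
The distance-class analysis min–max rescales R within each trait
(constant traits are dropped with a note) and regresses the rescaled
values on the class index 1/2/3 by OLS, reporting slope and 95% CI per
season.  Min–max rescaling and the OLS error structure are deliberate
simple choices for what is a coarse three-point trend test.

## Route fidelity

For an ordered pair of season tracks, each focal fix is matched to its
nearest neighbour on the other track (haversine; ball tree above a small
size cutoff, exact brute force below it — the two agree exactly, which is
asserted in the tests).  The overall mean and median of these directed
distances summarise the pair.  Within-individual records pair consecutive
years of one bird per season; between-individual records pair all ordered
track combinations of distinct birds sharing both breeding and wintering
250 km clusters, any year combination (consecutive-year restriction for
between-individual pairs would shrink an already small comparison set and
is not imposed).

The contrast model is a Gaussian mixed model on log distance with fixed
effects season and pair type, and random intercepts for comparison
cluster and focal bird (birds nested in clusters; fitted via statsmodels).
A negative-binomial model on rounded km would target the same
multiplicative effect but presupposes a rounding convention; the
log-Gaussian form is transparent for strictly positive continuous
distances, and the pair-type coefficient converts directly to a percent
reduction (1 − exp(coef)) · 100 with a Wald z-test.

## The synthetic generator

`simulate_population` emulates the data-generating features the analysis
depends on, with every random draw from one seeded generator:

* per-bird wintering and breeding sites drawn around paired regional
  centres (matched south-to-north, producing chain migration), with
  small between-year site jitter (default 0.5 km — high site fidelity)
  and fix-level scatter of 0.15 km;
* departure dates = season mean + per-bird effect (sd 8 d) + per-year
  noise (sd 4 d), so the true timing repeatability is 0.8 by default;
* migration legs as great-circle paths through way-points displaced
  laterally by a persistent per-bird offset (sd 40 km) plus per-year
  noise (sd 15 km) — within-individual routes are closer than
  between-individual routes by construction;
* stopovers: Poisson count per leg (mean 2), Gamma durations
  (shape 2, scale 12 h, floored at 1 h), placed ≥ 20% of the leg away
  from the endpoints so they never interact with the site buffers;
* cruise speed 65 km/h (safely above the 24 km/h threshold), fixes on a
  uniform 30-min grid, optional injected >24 h gaps per leg.

Ground truth records true sites, true buffer-crossing departure/arrival
instants (exact, because the first and last leg segments leave/approach
the site radially), true stopover intervals and all latent effects.

What the generator does *not* emulate — and therefore what passing tests
do not demonstrate about field data: wind drift and weather-dependent
routing, irregular duty-cycled sampling, tag failure and mid-track
dropout, position error beyond small Gaussian jitter, multiple wintering
sites within one season, flocking, and mortality.  Tests built on it
validate the *machinery* (recovery of known truth under clean
conditions), not ecological claims.

`simulate_repeatability_table` is the light-weight counterpart for the
statistics in isolation: Gaussian tables with residual variance 1 and id
variance r/(1−r) (so the latent ICC is exactly r), on top of fixed
cluster effects and a mild log(dt+1) slope; count tables use a log-link
Poisson with latent id variance calibrated against ln(1 + 1/λ₀) at the
baseline mean λ₀ = 5.

## Problem sizes used in the shipped validation

The test suite exercises a 6-bird × 2-year population (≈ 170 k fixes) for
segmentation recovery, 200 replicates × 200 bootstrap resamples per true
R for estimator calibration, 50 replicates for contrast recovery, and
100 permutation replicates for the null validation — sizes chosen so the
whole suite is a routine local run while keeping Monte-Carlo error well
below the tolerances being asserted.

## Known limitations

* Breeding/wintering classification by latitudinal midpoint assumes a
  north-breeding migrant; trans-equatorial cycles would need a different
  rule.
* Bouts of 60–90 min are detected only when sampling phase cooperates at
  30-min fixes (see above).
* The Laplace approximation for the Poisson GLMM is adequate for the
  moderate counts produced here; very sparse counts would deserve
  adaptive quadrature, which is out of scope.
* The similarity contrast treats pair records as exchangeable given bird
  and cluster intercepts; the dependence induced by one track appearing
  in many pairs is not fully modelled (the same is true of the
  nearest-neighbour design it implements).
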