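# Methods

This note records the models, numerical choices and known limitations of
`urbantol`, in the spirit of a statistical software vignette. Nothing here
states an empirical result the test suite or `scripts/acceptance.py` does
not itself compute.

## The abundance model

Per species, checklist counts are modelled as NB2:

    y_i ~ NB(mu_i, theta),  Var(y_i) = mu_i + mu_i^2 / theta,
    log mu_i = b0 + b_ALAN * x_i + sum_j f_j(z_ij)

`x_i` is the median radiance (nW cm^-2 sr^-1) of raster pixels whose
centres fall within a 5-km Euclidean buffer of the checklist. The smooths
f_j absorb detectability variation: observer count, joint (lat, lon),
duration, day of year and distance each get a thin-plate regression-spline
block of basis dimension 4; start time gets a cyclic cubic block of basis
dimension 5 with period 1440 min. The radiance term is linear on the raw
scale by default (`log_alan` switches to log1p). Counts recorded as a
presence marker ("X") enter as 1 — the minimal abundance consistent with a
detection — with a switch to drop them instead. Checklists missing the
start time survive filtering but drop out of fitting, because the
time-of-day smooth needs the covariate.

### Spline bases

The smooths are **unpenalised fixed-rank regression splines**. The cited
degrees of freedom are read as basis dimension: df 4 yields 3 centred
columns per thin-plate term, df 5 yields 4 centred columns for the cyclic
term. No smoothing-parameter selection (REML/GCV) is performed; with rank
3-4 per term there is little to shrink, and fixed rank keeps every fit a
deterministic GLM. This is the one deliberate methodological
simplification relative to penalised-GAM software, and the df are
configurable.

Thin-plate construction: the radial kernel (r^3 in 1-D, r^2 log r in 2-D)
is built on up to 100 deterministic knots (evenly spaced over the sorted
unique covariate rows), its polynomial-orthogonal part eigendecomposed,
and the leading eigenvectors kept; the basis evaluated at the data is
residualised against [1, covariates] so affine content lives only in the
explicit centred linear columns. Intercept + basis therefore reproduces
affine functions exactly (tested to 1e-8), and all columns sum to zero.

Cyclic construction: the df basis functions are the periodic cubic-spline
interpolants (scipy `CubicSpline`, periodic boundary) of knot indicators
on evenly spaced knots over the period; they sum to 1, so after
sum-to-zero centring one redundant column is dropped. Value and first two
derivatives match across the midnight seam by construction.

### Fitting

`fit_nb_glm` alternates (i) IRLS for the coefficients at fixed theta
(working weight mu/(1 + mu/theta), step-halved so the deviance never
increases) and (ii) bounded 1-D maximisation of the profile log-likelihood
in log theta over [-10, 25] at fixed means. Convergence: relative deviance
change < 1e-8 and |d log theta| < 1e-6 within 100 outer iterations;
failures are returned flagged, not raised. Standard errors come from
(X' W X)^-1 with theta held at its estimate — standard NB-GLM practice;
they do not propagate theta uncertainty. The linear predictor is clipped
at +-30 to avoid overflow; an all-zero response is rejected as degenerate.
The estimator agrees with direct Nelder-Mead maximisation of the joint NB
likelihood to 1e-4 and collapses onto the Poisson IRLS fit as theta -> 1e8
(both asserted in the suite, with statsmodels' NegativeBinomial as an
additional independent cross-check).

The profile-likelihood evaluation aggregates `gammaln(y + theta)` over the
distinct count values, and the resampling loop evaluates the smooth bases
once per species on its covariate-complete data, then fits each run on a
row subset of that design with a warm start from the previous converged
run. The smooths are functions of the covariates, so subsetting rows keeps
the same basis functions; only the likelihood's row set changes between
runs — which is exactly what the resampling is meant to vary.

## Subsampling and the tolerance index

Checklists are assigned to a flat-top hexagonal lattice (across-flats
width 5 km, equal to the centre spacing) by fractional-axial cube
rounding, which returns the nearest cell centre deterministically. The
planar lattice replaces the discrete-global-grid construction used with
geographic data at continental scale; at 5-km cells the distinction is
immaterial to the method's logic, and synthetic worlds use planar-km
coordinates where the geometry is exact. Lon/lat inputs are projected with
a local equirectangular mapping about the domain centre — adequate at the
few-km scales involved.

A stratum is (cell, year, week, detection class), with week =
floor((doy - 1)/7) + 1 capped at 52; one checklist is kept per stratum,
uniformly at random, detections and non-detections sampled independently
(`per_class=False` collapses to one per stratum total; `pool_years=True`
pools weeks across years). The retained set is a pure function of the
seed and invariant to input row order.

The tolerance index repeats subsample-and-fit `n_runs` times (default
100; the validation studies use 25) with per-run streams derived from
(master seed, CRC32(species), run). The index is the unweighted mean of
the converged runs' radiance coefficients; the default interval is the
2.5th/97.5th percentile of the run estimates, with a normal-theory
mean +- 1.96 sd option. Species with fewer than 1000 detection checklists
(counted pre-subsampling, boundary inclusive) are excluded; an estimate is
declared unstable if fewer than half the runs converge.

**What the interval does and does not cover.** The percentile interval
quantifies the variability induced by the random subsampling alone. It is
*not* a confidence interval for the true radiance effect: when strata are
mostly singletons the runs fit nearly identical data and the interval
collapses far below the sampling error of the coefficient, and when strata
are crowded the class-balanced sampling can introduce a small bias that
the narrow interval does not absorb. Validation therefore targets the
index itself (mean recovery error and sign classification across replicate
worlds), not interval coverage of the generating slope.

## The trait regression

OLS of the per-species index on body mass, nest substrate breadth and
habitat breadth (each z-scored with the n-1 sd) plus feeding guild and
migratory status (treatment coding; references: generalist, local
dispersal). Intervals use Student t with n - p residual df — at a couple
dozen species the normal multiplier would be anticonservative. Each
predictor gets a drop-one F test, multi-level factors removed as a block:
F = ((RSS_drop - RSS_full)/q) / (RSS_full/(n - p)). Marginal effects hold
the other quantitative predictors at 0 (scaled) and factors at reference,
with partial residuals (residual + own-term contribution) attached.
Breadth traits are treated as quantitative slopes, not factors. An absent
factor level raises immediately, naming the level, rather than silently
producing a rank-deficient design.

## The synthetic world

The generator emulates the observation process behind checklist data on a
planar landscape, with every draw a pure function of the seed:

* **Radiance surface** — point cities placed uniformly, each contributing
  `peak * exp(-d / decay_km)`, plus half-normal (truncated-at-zero) noise
  so radiance stays physically non-negative. Defaults: 100x100 km, 1-km
  pixels, 5 cities, peak 6 nW cm^-2 sr^-1, decay 12 km, noise sd 0.05.
  The modest peak keeps exp(beta * x) in a realistic count range for
  slopes up to |0.5| per radiance unit.
* **Checklist effort** — locations drawn with probability proportional to
  (radiance + 0.05)^bias (default bias 1), mirroring the concentration of
  community-science effort around settlements; durations lognormal around
  45 min, travel distances lognormal around 1.5 km (40% stationary at 0),
  observers 1 + Poisson(0.7), start times normal around 08:00, dates
  uniform over 2010-01-01..2021-06-30. Configurable fractions of rows
  violate each inclusion rule (the recovery studies use 2% each) and a
  fraction of detections is recorded as a presence marker (default 1%).
* **Counts** — gamma-Poisson NB2 draws with log-mean linear in the
  checklist's buffer-median radiance plus optional parametric effort
  effects (log-duration and log-observer slopes, linear distance, seasonal
  and diel sinusoids), zero by default. Both perfect-detection and
  effort-dependent regimes are therefore producible.
* **Trait table** — log-uniform mass 100-4000 g, integer breadths over the
  6-substrate and 30-habitat vocabularies, guild and migratory levels with
  every level guaranteed present; the true index is
  intercept + effect * z(mass) + N(0, sd).

What passing recovery tests shows: the pipeline correctly recovers the
radiance slope of the generating model under spatially biased, filtered,
class-imbalanced observation with NB noise. What it cannot show:
robustness to observer heterogeneity, taxonomic misidentification, range
maps that disagree with occupancy, detection processes not expressible as
smooth effort effects, or spatial autocorrelation beyond what the grid
thinning removes — none of which the generator emulates.

## Problem sizes used in validation

The replicate-world study runs 20 worlds x 3 species (slopes -0.5, 0,
+0.5; intercepts 1.0, 0.0, -0.5 keep detection rates workable for every
slope) x 25 resampling runs at ~20,000 checklists per world, theta = 1.5;
the demonstration analysis uses a 12-species, 8,000-checklist world with
10 runs per species. These sizes were chosen as the smallest at which the
Monte-Carlo error of the summaries is clearly below the decision
thresholds they feed.

## Degenerate inputs and tie-breaking

Boundary effort values are retained (duration 300 min, distance 5.0 km —
removal requires strictly greater); day 365/366 folds into week 52; points
on a range-polygon boundary count as inside (`covers` semantics); hex
boundary points resolve by the cube-rounding rule; an exactly-zero index
is flagged "boundary" rather than forced into a tolerance class; a
constant vector cannot be z-scored and raises; stationary checklists get
distance 0 on read when the field is blank. Filter removals are attributed
to the first failing rule in a fixed documented order, but the rules are
conjunctive so the surviving set is order-independent.
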