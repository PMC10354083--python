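# urbantol

Urban-tolerance indices for birds from community-science checklists and
night-time-lights rasters.

## The problem

How tolerant is each species in a community to urbanization? Community
science platforms such as eBird provide millions of checklists — survey
events with effort metadata (duration, distance travelled, observer count,
protocol) — and satellite night-lights products (VIIRS, nW cm⁻² sr⁻¹)
provide a continuous proxy for urbanization. `urbantol` turns the two into
a per-species **urban tolerance index** and then asks which ecological
traits (body mass, nest substrate breadth, habitat breadth, feeding guild,
migratory status) predict it. The approach was developed for Australian
raptors but the pipeline is generic over any checklist table in the
eBird-Basic-Dataset layout.

## The method

1. **Filter** checklists: complete lists only, allowed protocols, duration
   ≤ 300 min, distance ≤ 5 km, dates within 2010-01-01 … 2021-06-30
   (all configurable), then clip to each species' range polygon.
2. **ALAN covariate**: composite monthly radiance rasters by per-pixel
   median, then attach to each checklist the median radiance of all pixels
   within a 5-km buffer, `x_ALAN`.
3. **Subsample**: assign checklists to a 5-km hexagonal grid and retain at
   most one detection and one non-detection checklist per (cell, year,
   week) stratum, sampled uniformly — removing spatiotemporal clustering
   and class imbalance at once.
4. **Abundance model**: per species, a negative-binomial GAM with log link,

   ```
   y_i ~ NB(μ_i, θ),   log μ_i = β₀ + β_ALAN·x_ALAN,i + Σ_j f_j(z_ij)
   ```

   where the f_j are fixed-rank regression splines of the detectability
   covariates — observer count, joint (lat, lon), duration, day of year,
   distance (thin-plate, df 4) and start time (cyclic cubic, df 5) —
   and Var(y) = μ + μ²/θ.
5. **Tolerance index**: repeat subsample→fit 100 times with independent
   seeds; the index is the mean of the 100 β_ALAN estimates, with a 95%
   interval from their 2.5th/97.5th percentiles. Index > 0 ⇒ tolerant,
   < 0 ⇒ avoidant. Species with fewer than 1000 detection checklists are
   excluded.
6. **Trait regression**: OLS of the index on z-scored quantitative traits
   and treatment-coded factors (references: generalist feeding guild,
   local-dispersal migratory status), with drop-one F tests per predictor.

Because real eBird extracts and VIIRS composites cannot ship with the
code, the package includes a synthetic-world generator with known ground
truth (radiance surface, brightness-biased effort, NB counts, trait
table), so the whole chain is validated by parameter recovery.

## Worked example

The numbered scripts under `analysis/` run a complete demonstration on a
synthetic world (12 species whose true radiance slopes follow a known
body-mass relationship, slope −0.25 per SD of log-uniform mass):

```
$ python analysis/01_simulate_world.py
world: 70x70 km, 4 cities, 8000 checklists (seed 7)
12 species; true radiance slopes follow index = -0.25 * z(body mass) + noise

$ python analysis/02_filter_and_extract.py
removals per rule: {'incomplete': 148, 'protocol': 141, 'duration': 154,
                    'distance': 152, 'date_window': 151}
7252/7998 checklists retained
radiance at checklists: median 3.784, brightest 6.193, darkest 0.282 nW cm-2 sr-1

$ python analysis/03_tolerance_index.py
sp00: index +0.196 [+0.193, +0.199] tolerant (10/10 runs)
...
7 tolerant, 5 avoidant species
correlation between estimated and true indices: 0.997

$ python analysis/04_trait_regression.py
body-mass slope: estimate -0.210 [-0.362, -0.058]; generating value -0.250
inside the 95% CI
```

Each per-species line gives the mean radiance coefficient over the
resampling runs and the percentile interval of the run estimates; the
trait stage then recovers the generating mass effect from the estimated
indices alone. `analysis/05_recovery_study.py` repeats the chain over five
replicate worlds (mean recovery error < 0.015 on slopes of ±0.5) and runs
the 500-replicate trait-model calibration (95% CI coverage 0.952, type-I
error 0.062 at α = 0.05).

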