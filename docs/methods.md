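# Methods

## Units of analysis and the accessibility model

The traffic analysis zone (TAZ) is the unit of analysis throughout: travel
times are measured between zone centroids, and coverage is whole-TAZ — a
zone's entire population is either within the travel-time threshold or not,
with no partial-area interpolation. Within-zone travel time is 0 by
convention, so zones hosting a service are always covered and populations
are never split below the zone level.

Accessibility is a cumulative-opportunity metric: at congestion level *k*
and threshold *t* (minutes), zone *o* is covered iff
`min over services s of T(o, s, k) <= t`. The threshold comparison is
inclusive; the default threshold is 20 minutes by car, with opportunity
curves evaluated at 10-minute intervals. "Peak" and "free-flow" map to the
highest and lowest congestion levels (K and 1).

## Congestion clustering

The 168 hour-of-week slots are partitioned by k-means (10 restarts, fixed
seed) on the standardized 168-vector of city-mean travel times per hour,
with K = 9 by default. Cluster labels are re-ordered by ascending cluster
mean so level 1 is free-flow and level K is peak; ties between equal-mean
clusters break toward the lower original label. Features are city-mean
times, not per-TAZ times, because the level labels are used city-wide;
zones whose own level ordering deviates are surfaced by the ordering audit,
which counts, per origin, adjacent level pairs whose mean outgoing times
are inverted relative to the global order. An exactly constant profile
collapses to a single level with a warning. K outside 1..168 is rejected.

## Sampling and reconstruction of the travel-time tensor

Measuring all `n*(n-1)*168` weekly pairs is avoided by sampling each origin
only against service-hosting destinations (plus optional extras), per
congestion level — `|O|*|D|*K` cells, each the mean (optionally median) of
the hourly times over that level's hours. The full per-level matrix is then
reconstructed by fitting, per level, `minutes ~ alpha + beta * free_flow`
by least squares on the sampled off-diagonal pairs and predicting every
cell. Three repairs keep the tensor physically coherent:

- predictions are clamped to the free-flow floor;
- sampled cells keep their measured values (provenance is tracked per cell);
- per-pair monotonicity across levels is enforced by pooled-adjacent-
  violators, so a higher congestion level is never faster.

A constant free-flow predictor within a level makes the slope
unidentifiable and raises an error naming the level. When no analytic
free-flow matrix is supplied, the level-1 sampled times serve as the
predictor, which requires the plan to cover all destinations.

This linear-regression reconstruction was a genuinely open design choice:
nothing deeper than a per-level affine map of free-flow time is needed for
the generator's data-generating process, it is transparent, and its
parameters are directly comparable to the generator's congestion
multipliers, which makes recovery testable (slope within 2% of the true
multiplier at the default noise level, unbiased by construction — see the
noise model below).

## Synthetic-city generator

The generator emulates the statistical structure of a large Latin-American
city at its defaults: 507 zones on a ~15 km planar grid (0.66 km square
cells, roughly disc-shaped, coordinates in km with no geodesy), 2,258,823
residents, density rising toward the periphery, 11 services concentrated in
the 6 most central zones, and census-shaped sociodemographic marginals
(about 49% of residents in low strata 1–2, 41% middle, 9% high). Age bands
are the non-overlapping partition 0–4 / 5–14 / 15–24 / 25–59 / 60–64 /
65–79 / 80+.

Populations are apportioned by largest-remainder rounding so totals match
exactly. Subgroup tables are built per attribute (marginals only, no
cross-classification): a per-zone seed mixture — tilted by an exponential
income gradient so low-stratum shares rise with distance from the service
cluster, neutral for other attributes — is fitted to the exact city-wide
category totals by iterative proportional fitting and rounded per zone by
largest remainder, so every attribute's category counts sum exactly to each
zone's population.

Travel times follow
`minutes(o, d, h) = ff + (mult(h) - 1) * ff * eps`, where
`ff = distance/speed + access constant` (30 km/h and 2 min by default),
`mult(h) >= 1` is the multiplier of hour *h*'s congestion regime and `eps`
is mean-one lognormal noise (sd 0.05 by default) on the congestion
*increment*. Placing the noise on the increment rather than the whole time
makes the free-flow floor structural — no clamping is needed, times stay
positive, and the level-1 regime is exactly free-flow — and leaves
regression recovery of the multipliers unbiased, whereas clamping noise on
the total at the floor would bias the free-flow level's slope upward by
about `sd/sqrt(2*pi)` (~2% at sd 0.05). The default weekly profile assigns
each hour one of nine regimes (multipliers 1.0 … 2.5) with weekday morning
and evening peaks and a congested working-day plateau, so the
second-highest regime alone covers 40 of the 168 hours; the true regime
labels and multipliers are recorded so clustering and estimation can be
scored for recovery.

What the generator does **not** emulate: road-network routing and
directional asymmetry (times are Euclidean-distance based and symmetric),
day-type structure beyond the hour index, spatial autocorrelation of noise,
and the real city's particular coverage rates — a passing synthetic run
shows the pipeline recovers planted structure, not that any real city has a
particular accessibility level. The arithmetic layer is therefore also
exercised on the shipped reported counts of the Cali 2020 haemodialysis
case study (overall and stratum-group rows of the situational and
prediction tables, and the new-service catchments), which checks every
percentage, variation and demand figure independently of simulation.

## Siting

Adding `p in {1, 2}` services is maximal covering: maximise population with
`min(existing time, time to a new site) <= t`; a new site covers its own
zone. The candidate set defaults to all zones, services are assumed open to
all patients, and capacity (chairs) is informational only. The exhaustive
solver enumerates all candidate sets (128,271 pairs at 507 zones; a cap of
2×10⁵ sets guards larger instances) and is the default at city scale; the
genetic algorithm (chromosome = site set, tournament selection of size 3,
uniform site-swap crossover with duplicate repair, mutation rate 0.1,
elitism 1, population 100, 200 generations, mandatory seed) is retained for
fidelity and for larger `p`. Both solvers break ties toward the
lexicographically smallest zone-id set so results are comparable. Two-site
solutions are optimised jointly by default; the objective is monotone
submodular, so a sequential (greedy) build is within `1 - 1/e` of optimal
and is available by fixing the first site in the candidate handling.

## Numerical and reporting conventions

- Percentages: half-away-from-zero to 1 decimal. Variation columns round
  the difference of the *unrounded* percentages once at the end (the
  convention that reproduces the reported variation columns, e.g. a 6.3
  where differencing rounded percentages would give 6.2).
- Patient demand: `covered * prevalence / 100,000`, rounded half-up to an
  integer; default prevalence 128 per 100,000.
- Fold reduction of the sampling plan: ratio reported rounded to the
  nearest integer (630 for 43,099,056 / 68,445).
- Zero-population categories yield blank (NaN) percentages with a warning.
- All randomness flows through explicit seeds (`numpy` generators,
  k-means `random_state`); identical configuration and seed reproduce
  byte-identical artifacts.

## Problem sizes used by the test suite

Unit and property tests run on 10–60-zone cities where brute-force oracles
(full enumeration of coverage sets, direct hourly aggregation, pairwise
level-mean comparison) are exact and fast. The statistical recovery checks
run at the reference scale the sampling plan is defined for — 507 zones,
68,445 sampled cells (507 × 15 × 9) at noise sd 0.05 — and the GA
validation harness solves 100 seeded 50-zone instances against the
exhaustive optimum. The full suite completes in well under a minute on one
CPU.

## Known limitations

- The congestion-level labels are city-wide; the ordering audit quantifies
  but does not correct per-zone deviations.
- The reconstruction assumes travel times are affine in free-flow time
  within a level; road-network effects that break this (bridges, corridor
  bottlenecks) would be absorbed into residual error, not modelled.
- Whole-TAZ coverage makes results sensitive to zone delineation at the
  threshold boundary (a form of the modifiable areal unit problem).
- The siting objective ignores service capacity and insurance-network
  restrictions; it measures geographic reachability only.
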