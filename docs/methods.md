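# Methods

This note documents the statistical model and procedures implemented in
`skerrydiv`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic data generator does and does not emulate.

## Survey model and inclusion rules

The sampling unit is a 1 km² grid square with four environmental
covariates, all in metres or m²:

| covariate   | definition                                                            |
|-------------|-----------------------------------------------------------------------|
| `dist_sea`  | Euclidean distance from the square midpoint to the open-sea line      |
| `width`     | distance from the midpoint to the nearest mainland + `dist_sea`       |
| `shoreline` | total land/water boundary length within the square                    |
| `land_area` | land surface within the square, 0–1,000,000 m²                        |

A square enters the analysis when it contains both land and water
(0 < land_area < 1 km²) and has ≥ 25 m of shoreline; "minimum shoreline
length of 25 m" is read inclusively (a minimum names the smallest
admissible value).  Presences recorded in excluded squares are
reassigned to the nearest retained square by centroid distance, merging
by set union (the data are 0/1, so no abundance can be transferred);
distance ties break deterministically to the lexicographically smallest
square id.  Reassignment can only add presences, so no species' total
occupied-square count decreases, and it can rise by at most the number
of excluded squares.

## Alpha diversity

Richness per square is counted for six responses: all species,
specialists, generalists, and the red-listed subset of each.
Occupancy tables report per-species counts and 100·count/n percentages
rounded to one decimal, the resolution used in published survey tables.

"Mean-standardised" covariates are z-scores (centre and unit sample
SD).  Centring alone would leave values in the thousands of metres,
whereas gradient plots in this literature show covariates of order
±0.25; a `center` mode is available for sensitivity checks.  Gradient
binning groups squares into half-open intervals [c − 0.25, c + 0.25)
around centres at multiples of 0.5 standardised units, ties going to
the upper bin so the bins partition the squares.

## Sørensen and Raup–Crick beta diversity

For a square pair with richness a and b sharing w species, Sørensen
dissimilarity is β_S = 1 − 2w/(a + b); it is undefined (and flagged
missing) when both squares are empty.  β_S conflates richness
differences with turnover, so the package also computes the
probabilistic Raup–Crick index β_RC conditional on the observed
richness pair:

1. Pool weights are each species' occupied-square count over the full
   regional dataset.  By default the pool is group-specific (only the
   analysed group's species); whether a shared 48-species pool was used
   in the field study is not documented, so both are supported.
2. A null assemblage for a square of richness n draws n distinct
   species sequentially, each draw proportional to weight among the
   species remaining.  The implementation uses the exponential-key
   construction (keep the n smallest Exp(1)/w_s keys), which is
   distributionally identical to draw–remove–renormalise and
   vectorises; the exact enumeration oracle (`raup_crick_exact`) sums
   literal sequential-draw probabilities over all ordered outcomes, so
   the test suite cross-checks the equivalence on pools of ≤ 6 species.
3. β_RC = [#(w_null > w_obs) + ½·#(w_null = w_obs)] / reps.  The
   half-tie rule keeps the null expectation at 0.5 (verified to
   ±0.02 over 2,000 null pairs).  High values mean fewer shared
   species than the richness-conditioned null expects.  An optional
   2x − 1 rescaling maps the index onto [−1, 1]; the default is the
   [0, 1] probability scale, which is the scale on which the tie rule
   has its calibration property.
4. The null distribution depends only on (n1, n2) given fixed weights,
   so it is simulated once per unique richness pair and cached; cost is
   O(#unique richness pairs · reps), which keeps thousands of squares
   feasible.  Default reps = 999 per richness pair: a conventional
   null-model size, with correctness guarded by the exact oracle rather
   than by brute replication.

## Mantel tests

Environmental distance matrices are Manhattan (|vᵢ − vⱼ|) per
covariate.  The simple Mantel statistic is the Pearson correlation of
strictly-upper-triangle vectors; inference permutes rows and columns of
the response matrix jointly, because distance-matrix entries are not
independent.  The partial test residualises both vectors on the control
matrices' vectors by OLS with intercept (method of residuals) and
re-residualises the permuted response at every step — the standard
formulation in the ecological packages this analysis pattern comes
from.  p-values use (exceedances + 1)/(n_perm + 1) and are two-sided on
|r| by default (published tables in this area report both negative and
positive correlations as significant); one-sided alternatives are
available.  Pairs flagged missing in any matrix (e.g. empty–empty
Sørensen pairs) are dropped listwise before vectorisation.  Default
10,000 permutations, significance read at p < 0.05.

Type-I error of the partial test under independence is checked by
simulation (500 independent datasets, n = 15, 199 permutations):
rejection at p < 0.05 stays within [0.03, 0.07].

## Moran's I

I = (n/S0)·Σ wᵢⱼ(xᵢ−x̄)(xⱼ−x̄)/Σ(xᵢ−x̄)², with binary weights wᵢⱼ = 1
iff 0 < dᵢⱼ ≤ 1000 m (the lag between adjacent square midpoints, with
10⁻⁶ relative slack for grid arithmetic).  Expectation −1/(n−1);
variance by the standard normality-assumption formula; two-sided normal
p.  A 2×2 checkerboard gives I = −1 exactly.  In the pipeline, Moran's
I is evaluated on residuals of the preliminary *non-spatial* fit
(nugget fixed at 1), since residual autocorrelation after covariate
adjustment is what motivates the spatial error term.

## Spatial gradient regression

The richness model is y = ln(S + 1) (natural log; +1 because empty
squares occur) regressed on the four standardised covariates and their
two-way interactions, with

Cov(εᵢ, εⱼ) = σ²[(1 − ν)·exp(−dᵢⱼ/ρ) + ν·1(i = j)].

The original field analysis fitted a Gaussian penalised-quasi-likelihood
mixed model with a per-square random effect and exponential spatial
correlation; with one observation per square that model is statistically
a spatial GLS on ln(S+1) with a nugget, which is what this package fits
by exact maximum likelihood — a deliberate substitution of an
equivalent, better-behaved estimator for the same estimand.  The
generalist model drops the land_area × width interaction, mirroring the
convention for that response.

(ρ, ν) are profiled on a coarse grid — 25 log-spaced ρ values spanning
0.1–50 km (bracketing the 1 km square scale through the study-extent
analogue) × 6 nugget values — then refined by golden-section search in
log ρ and in ν; if refinement fails to improve, the grid optimum is
kept, so the selected likelihood never falls below the ν = 1 (OLS)
special case.  β and σ² are GLS/ML estimates at the selected
correlation via Cholesky whitening; standard errors come from
σ̂²(X̃ᵀX̃)⁻¹ and 95 % intervals are Wald (±1.96·SE), matching the
symmetric interval bars conventional for these models.  Fixing
ν = 1 reduces the fit to OLS exactly, which the tests exploit as an
oracle; an n-point intercept-only fit reproduces the closed-form GLS
mean (1ᵀΣ⁻¹y)/(1ᵀΣ⁻¹1).

Simulation checks (200 replicates, n = 400 squares on a 20×20 km grid,
|β| = 0.3, σ = 0.3, ρ = 3000 m, ν = 0.25): all four main-effect signs
recover in every replicate and pooled 95 % CI coverage is ≥ 0.90.
The collinearity screen reports all six covariate-pair Pearson
correlations and flags |r| ≥ 0.7, the conventional threshold above
which gradient models degrade.

## Synthetic archipelago generator

`generate_landscape` builds a raster (50 m cells; any divisor of
1000 m works) with a mainland strip on the western edge whose coastline
is smoothed Gaussian noise, and islands placed seaward whose expected
radius decays exponentially with distance from the coast — the land-
uplift signature of large inner islands and small outer skerries.
`derive_environment` computes the four covariates per 1 km square:
land area from cell counts; shoreline as 4-neighbour land/water cell
edges × cell size (a deterministic, resolution-controlled estimator
that is biased relative to true geometric length, which is acceptable
because only relative gradients matter downstream); the open-sea line
as the outermost-land envelope per raster row, bridged across rows by a
2 km maximum filter, smoothed, and offset 150 m seaward (alternative
hull definitions would shift `dist_sea` by a bounded constant);
`dist_sea` and mainland distance by Euclidean distance transform
sampled at the square midpoint cell (a ≤ half-cell offset).

`simulate_occurrences` draws per-species logistic responses around
group means whose signs encode the canonical field pattern —
specialists: dist_sea −, width +, shoreline +, land_area −, and a
negative shoreline × land_area interaction; generalists: dist_sea +,
width −, shoreline +, land_area ≈ 0 — with the defaults (specialist
means −1.8, −0.8, +0.4, +0.8, −0.5, −0.3; generalist means −1.2, +0.4,
−0.4, +0.8, 0.0, −0.15 on the logit scale; between-species slope SD
0.3, intercept SD 0.7) chosen to give occupancy frequencies spanning a
few percent to well over half of squares, as real surveys of this
community show.  The community matches the surveyed one: 19
specialists, 29 generalists, seven red-listed species per group (3 VU
among specialists, 2 among generalists, the rest NT).  An optional
per-species Gaussian field with exponential correlation (default
amplitude 0.5, range 2 km) adds spatially structured extra-covariate
variation.  The true coefficients travel with the dataset
(`provenance["truth"]`) for recovery tests.

What the generator does **not** emulate: detectability and observer
effects (occupancy is the truth, not a thinned observation), vegetation
and predator covariates, real cartography, and between-year turnover.
Passing tests therefore demonstrate correctness of the statistical
machinery and recoverability of gradient structure under the stated
generative model — not robustness to the observation errors of real
surveys.  Because each species' residual field is independent, summed
richness shows weaker residual autocorrelation than single-species
occupancy; the spatial-GLS recovery checks instead simulate directly
from the regression model, where the spatial error is controlled.

## Problem sizes and determinism

Default analyses run at desk scale: a 20×10-square landscape (200 km²
analogue) for exploration, 24×24 (≈ 350 retained squares) for the
end-to-end checks, and n = 400 for regression recovery; the full-survey
scale (thousands of squares) is supported through richness-pair caching
in β_RC and is configuration, not code.  The pipeline derives one
sub-seed per stage from the master seed and the stage name (CRC32),
so outputs are byte-identical under a fixed config + seed and stage
reordering cannot silently change results.

## Known limitations

* Raster shoreline length systematically underestimates curved
  coastline length; comparisons are valid within a resolution.
* The Wald intervals of the spatial GLS ignore uncertainty in (ρ, ν);
  coverage in the simulation study remains ≥ 90 % at n = 400, but small
  samples with strong correlation may under-cover.
* β_RC at the default 999 reps has Monte-Carlo noise of order 0.016 SD
  per pair; raise `reps` when individual pair values (rather than
  matrix-level correlations) are of interest.
* The Mantel permutation p-values are valid under exchangeability of
  squares; strong spatial autocorrelation in both matrices inflates
  type-I error, as it does for all Mantel-type tests.
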