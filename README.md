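# skerrydiv

Alpha and beta diversity of coastal breeding birds along archipelago
gradients, analysed on a 1 km² survey grid.

## The problem

Coastal archipelagos shaped by post-glacial land uplift show strong
environmental gradients: islands are large and forested near the
mainland and shrink to bare skerries towards the open sea.  Breeding
bird surveys on such coasts record presence/absence of each species in
1 km² grid squares, and the scientific questions are (1) how species
richness per square (α diversity) relates to the gradients — distance
to open sea, archipelago width, shoreline length, land area — for
obligate coastal breeders ("specialists"), facultative ones
("generalists") and red-listed species; and (2) whether community
*composition* (β diversity) turns over along the same gradients once
richness differences are accounted for.

`skerrydiv` implements that full analysis as a reusable, tested
pipeline, plus a synthetic archipelago generator that emulates the
landscape structure and group-specific occupancy responses, so every
method can be exercised and validated without the original survey data.

## Methods at the core

* **Square inclusion and record reassignment** — squares must contain
  both land and water and ≥ 25 m of shoreline; records from excluded
  squares move to the nearest retained square (set-union of presences).
* **α diversity** — richness per square by group; per-species occupancy
  tables (count, % of squares); gradient binning of mean richness.
* **Sørensen dissimilarity** — β_S = 1 − 2w/(a+b) for every square
  pair, where a, b are the two richness values and w the shared count.
* **Raup–Crick dissimilarity** — β_RC, the probability that a null
  assembly shares fewer species than observed, with half weight on
  ties: null assemblages redraw each square's richness from the
  regional pool with probability proportional to each species'
  regional occupancy (sequential weighted sampling without
  replacement).  The null is simulated once per unique richness pair
  and cached; an exact enumeration oracle covers small pools.
* **Partial Mantel tests** — Pearson correlation of β and Manhattan
  covariate distance matrices over square pairs, residualised on the
  other covariates' matrices, with joint row/column permutations
  (default 10,000) and the add-one p-value correction.
* **Moran's I** — residual spatial autocorrelation with binary weights
  at a 1000 m lag (adjacent square midpoints), normality-assumption
  variance.
* **Spatial gradient regression** — ln(richness + 1) on the four
  mean-standardised covariates and their two-way interactions (the
  generalist model drops land_area × width), with Gaussian errors
  under an exponential spatial correlation plus nugget,
  Σᵢⱼ = σ²[(1−ν)e^(−dᵢⱼ/ρ) + ν·1(i=j)]; (ρ, ν) by profile maximum
  likelihood, β and σ² by GLS, Wald 95 % intervals.

The model-shaped pieces are scikit-learn style estimators
(`SorensenDissimilarity`, `RaupCrickDissimilarity`,
`SpatialExponentialGLS`); module-level functions wrap them.

## Worked example

```python
import skerrydiv as sd

ds = sd.generate_survey(sd.LandscapeParams(n_cols=20, n_rows=10, n_islands=150),
                        sd.SimulationParams(), seed=7)
filtered, excluded = sd.filter_squares(ds)
ds = sd.SurveyDataset(filtered.grid, sd.reassign_records(ds, excluded))
print(f"{len(ds.grid)} squares retained ({len(excluded)} excluded)")

rt = sd.richness(ds)
spec = sd.ModelSpec("specialist", interactions=sd.spatial.default_interactions("specialist"))
fit = sd.fit_spatial_gls(rt, ds.grid, spec)
print(fit.summary_frame().loc[["dist_sea", "shoreline", "land_area"]].round(3))

dm = sd.sorensen_matrix(ds, "specialist")
env = sd.manhattan_matrix([s.land_area for s in ds.grid], ds.square_ids)
controls = [sd.manhattan_matrix([getattr(s, v) for s in ds.grid], ds.square_ids)
            for v in ("dist_sea", "width", "shoreline")]
res = sd.partial_mantel(dm, env, controls, n_perm=999, seed=1)
print(f"partial Mantel (specialist beta_S vs land area): r={res.r:.3f}, p={res.p:.3f}")
```

prints

```
130 squares retained (70 excluded)
           estimate     se   lo95   hi95
term
dist_sea     -0.319  0.106 -0.526 -0.112
shoreline     0.504  0.104  0.301  0.707
land_area    -0.701  0.305 -1.298 -0.104
partial Mantel (specialist beta_S vs land area): r=0.227, p=0.001
```

i.e. on this simulated archipelago, specialist richness falls with
distance to open sea and land area and rises with shoreline length
(all 95 % intervals excluding zero), and specialist community
composition turns over along the land-area gradient even after
controlling for the other three covariates.

The same analysis runs from the shell:

```bash
skerrydiv simulate --seed 7 --out data/
skerrydiv alpha --dataset data/ --out tables/
skerrydiv beta --dataset data/ --index raupcrick --group specialist --seed 1 --out brc.csv
skerrydiv run --seed 7 --out results/        # full pipeline, all tables
```

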