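# Methods

## The severity index and its inputs

The unit of observation is the inventory subplot.  A subplot is *infested*
in a cycle if at least one nonnative invasive plant species was recorded on
it; cover is recorded per species in percent of the subplot, in (0, 100].
Only subplots visited in all three cycles enter the panel, so a visited
subplot with no occurrence rows is an uninfested observation, not a gap —
this is what makes N_ij "all subplots" a valid denominator.

Per unit and cycle the index is `P × C` with `P = S/N` and
`C = Σ covers / N`.  Two consequences are deliberate:

* `C` sums across species, so it can exceed 100 in principle; no cap is
  applied.
* `C`'s denominator includes uninfested subplots, so `C = P × (mean cover
  per infested subplot)` and the index scales with the *square* of
  presence for a fixed per-infested-subplot cover.

Duplicate (subplot, cycle, species) rows keep the maximum cover —
conservative toward presence and idempotent under re-ingest.  Cycle coding
from inventory year: 2001–2005 → T1, 2006–2012 → T2, 2013–2019 → T3;
other years are excluded.

Units that contain no subplot get their index (only the index, not P and C
separately — recombining separately interpolated factors would not multiply
back consistently) from inverse-distance weighting over all observed units
of the same system and cycle, power 2, distances between unit centroids.  A
donor coincident with the target centroid contributes its value exactly
(coincident donors are averaged).  Imputed units are flagged and excluded
from Moran and SAR computations by default, because interpolation
manufactures exactly the spatial smoothness those statistics measure; a
config switch can include them.

Subplots exactly on a shared unit boundary are assigned to the
lexicographically smallest unit id — deterministic and order-independent;
real plots essentially never sit on polygon boundaries.

## Spatial weights and Moran's I

Weights are queen contiguity (any shared boundary point) on the polygon
partition, row-standardized; rook is available.  The underlying binary
adjacency is symmetric; islands keep zero rows and are excluded from
statistics with n reduced accordingly.  Restricting weights to a subset of
units (e.g. non-imputed ones) re-standardizes the restricted rows.

Moran's I uses the Cliff–Ord moments: E[I] = −1/(n−1) and the closed-form
variance under either the randomization assumption (default; uses the
sample kurtosis b2) or normality.  The two variances coincide exactly when
b2 equals the finite-sample Gaussian value 3(n−1)/(n+1), not 3; the test
suite asserts that identity.  The permutation distribution of I is mildly
right-skewed at n ≈ 36, so a normal-approximation p-value can differ from
a permutation p-value by a few hundredths in the middle of the
distribution while the first two moments agree to four decimals.  The
calibration experiment therefore compares closed-form and permutation
p-values on a clustered input — the tail regime where the test actually
discriminates — and separately checks the moments.

The default inference is one-sided ("greater"): clustering is the
scientific hypothesis.  Results report the standard deviate z by that
name.

### Choosing the modeling scale

Each candidate unit system is scored per cycle by the Moran's I of its
invasion index; the chosen system per cycle is the argmax, ties to the
system with fewer units, and the overall choice is the majority winner
across cycles with the same tie rule.  The reasoning: the scale with the
strongest spatial organization carries the most structure for a spatial
model, while finer scales dilute the signal with subplot sampling noise
and coarser scales aggregate it away.

## The spatial-lag model

`Y = ρWY + Xβ + ε` is fitted by maximizing the concentrated
log-likelihood of ρ on the feasible interval derived from the real
eigenvalues of W (for row-standardized weights, (1/ω_min, 1)), with
`ln|I − ρW| = Σ ln(1 − ρω_i)` evaluated exactly from the eigenvalues —
exact and fast for the few-hundred-unit problems this package targets; no
sparse or Chebyshev approximations.  Brent search uses tolerance 1e-8, and
ρ = 0 is always evaluated too, so the lag fit never scores below OLS.  β̂
and σ̂² follow in closed form.  Standard errors come from inverting a
central-difference Hessian of the full log-likelihood in (ρ, β, σ²); with
ρ fixed at 0 this reproduces OLS coefficients, maximum-likelihood standard
errors and log-likelihood to numerical precision, which the tests assert
at 1e-6.

AIC is `2k − 2ℓ` with k = (coefficients incl. intercept) + 2: ρ and σ²
count as parameters.  Covariate screening removes, while any pair has
|Pearson r| > 0.6, the member of the worst pair less correlated with the
response (zero-variance columns first).  Stepwise search starts from the
intercept-plus-lag model and greedily adds or drops one covariate per step
while AIC improves, with a deterministic candidate order and a full path
log; covariates are never pruned on p-values.  Model adequacy is judged by
Moran's test on the residuals under the same weights: p ≥ 0.05 is reported
as "lag model adequate".

At n = 100 on a queen lattice the ML estimate of ρ carries a small
downward finite-sample bias (mean ρ̂ ≈ 0.45–0.50 across 50-replicate
batches when ρ* = 0.5); Wald ±3 SE intervals nevertheless cover the truth
in ≈ 98–100% of replicates, which is what the calibration experiment
checks.

## The synthetic landscape

The generator emulates the *structure* of a state-scale inventory study,
not any particular state:

* **Unit systems.** Rectangular nested grids stand in for watershed and
  ecoregion hierarchies (level k+1 subdivides each level-k cell by an
  integer factor), plus one non-nested "county" partition on a grid whose
  interior lines are shifted by a seed-drawn fraction of a cell.  This
  preserves the nested/non-nested distinction that drives the scale
  comparison while staying fully self-contained.
* **Plot network.** A jittered square lattice at 4.9 km spacing (one plot
  per ≈ 24 km²), four subplots per plot in the center-plus-ring layout,
  jitter bounded below spacing/2 so plots cannot swap cells.
* **Covariates.** Unit-level fields built by SAR-filtering white noise on
  the units' queen contiguity and mapping it monotonically: logistic to
  (0, 100) for percents, exponential for densities, softmax across classes
  for compositional groups (six land-use and six forest-type classes by
  default), mirroring the ownership / demography / land-cover drivers used
  in regional invasion models.
* **Severity.** `y = (I − ρW)⁻¹(Xβ + ε)` on the county-like system, the
  exact process the SAR stage assumes.  The draw can dip below zero in the
  weakest units; the pipeline floors it at zero before generating
  occurrences (the occurrence model requires a non-negative target), which
  mimics truly uninvaded units.
* **Occurrences.** Inverting the index definition: for unit target y and
  cover scale s (default 20%), presence is Bernoulli with p = √(y/s)
  capped at 0.95, and total cover given presence is 100·Beta with mean
  y/p², so the expected re-aggregated index is y.  Species identity
  follows a skewed community profile (a dominant vine, a common shrub, a
  minor tail) with per-cycle weight multipliers; a second species joins
  with probability 0.35, splitting the cover 70/30, giving ≈ 1.2–1.7
  species per infested subplot.  One presence uniform per subplot is
  shared across cycles, so non-decreasing cycle multipliers give
  non-decreasing infestation counts in every realization, not merely in
  expectation.

Default run conditions: 98 × 98 km extent; hierarchy levels of 4/16/64/
256/1024 (watershed-like) and 9/36/144 (ecoregion-like) units plus 49
county-like units; severity ρ = 0.6, β = (1.5, 0.03 on population density,
−0.04 on public ownership), σ = 1, cycle multipliers (1.0, 1.2, 1.4).  The
intercept is set so first-cycle infestation sits near 41% and rises to the
low 50s — the regime a heavily invaded state-scale inventory reports.  One
master seed drives everything; stages derive child seeds by fixed offsets
(+11 hierarchy, +12 network, +13 covariates, +14 severity, +15
occurrences) so stages can be re-run in isolation, and identical seeds
yield byte-identical CSV/GeoJSON artifacts.

What the generator does *not* emulate: irregular polygon shapes, plot
nonresponse and swapped public coordinates, species interactions,
observer error in cover, and land-cover rasters beyond per-unit class
percents.  Passing tests therefore certify the estimators and bookkeeping,
not robustness to those field realities.

## The scale-identification experiment

Validating "Moran ranking finds the generating scale" needs a field for
which the generating scale is genuinely optimal.  A purely SAR-smoothed
field is not: its spectrum is red, so *coarser* aggregations denoise it
and can legitimately score a higher Moran's I than the generating
partition.  The experiment therefore drives severity with a
neighbor-averaged covariate (two smoothing passes of white noise over the
county contiguity), whose correlation reaches about two county widths and
then stops, plus a small lag (ρ = 0.15): variance is concentrated at the
county wavelength.  Conditions: 196 × 196 km, 256 county-like units,
competitors of 4, 16 and 784 units, the 4.9-km plot network, and the
majority-across-cycles selection rule.  Under these conditions the county
scale is identified in ≈ 20/20 seeded landscapes: the 784-unit system
inherits the county signal but pays subplot sampling noise (≈ 6 subplots
per unit), the 16-unit system averages across ≈ 16 counties and loses the
short-range variance, and the fully connected 4-unit queen system has
I ≡ −1/3.  Power was established by design-stage simulation before the
condition set was frozen.

## Numerical and degenerate-input conventions

* Boundary ρ (singular I − ρW) raises; an interior optimum sitting within
  10⁻⁵ of the feasible edge is returned with a boundary warning.
* Constant x makes Moran's I undefined (raised, not NaN); n < 3 usable
  units is an error, and the randomization variance additionally requires
  n > 3.
* Rank-deficient designs raise a singular-design error naming the maximum
  absolute inter-covariate correlation; stepwise skips additions that
  would be singular.
* IDW with no observed donors in a system-cycle raises; power must be
  positive.
* Overlapping unit polygons (positive area beyond 1e-9 relative) are
  rejected wherever a partition is assumed.
* All geometry is planar, in meters; GeoJSON artifacts are written with
  sorted keys and fixed separators for byte determinism.
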