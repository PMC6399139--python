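# Methods

## Scope

The package implements a geographic correlation analysis of canine
cancer incidence with a change of spatial support: enumeration units are
dasymetrically refined to their residential land, density and distance
covariates are recomputed on both supports, and four count-model
families are fit and compared across supports. Real registry and GIS
inputs are replaced by a synthetic-region generator with known ground
truth, so every procedure is testable offline and parameter recovery can
be verified exactly.

## Synthetic world

Geography is a raster lattice: a `rows x cols` grid of hectometric
(100 m) cells, partitioned into `n_units` enumeration units by nearest
seeded centre (Euclidean, ties to the lower unit id). This avoids
polygon topology entirely while exercising every spatial operation with
exact geometry; polygon-based cell allocation is still provided (and
oracle-tested) for externally supplied boundaries.

Defaults define the desk-scale study conditions and mirror the Swiss
anchors of the setting being emulated:

| quantity | default | rationale |
| --- | --- | --- |
| units | 200 on a 260x260 grid | ~3.4 km² per unit, so densities land on a realistic 0.5–15 (1,000/km²) range; the full 2,350-unit scale stays a config option |
| cell size | 100 m | hectometric residential / distance grids |
| mountain share | 0.5 | sparse vs dense unit classes |
| residential fraction | mountain U(0.01, 0.10), plateau U(0.10, 0.60) | "mostly <10 %" mountain vs 10–60 % plateau contrast |
| population | log-normal; median 600 (mountain, sigma 0.8) / 2,500 (plateau, sigma 1.0) | municipal-scale populations |
| housing capacity | ≤250 people per residential cell | residential land grows with population; caps density at dense-urban ~25k/km² |
| dogs | Poisson(pop × 6.54/100) per unit | national dog-to-human ratio |
| vets | 80, on residential road cells, weighted by unit population | 938 practices / 2,350 municipalities ≈ 0.4 per unit |
| dog age | Gamma(shape 2, scale 2.5), mean 5 y | no published dog-age distribution; right-skewed by design |
| sex / breed | Bernoulli(0.5) / per-unit mixed probability U(0.2, 0.6) | uninformative defaults |
| income tax | N(4, 1.5) kCHF per capita, floored at 0.5 | plausible per-capita surrogate range |

Roads are the rasterized (L-shaped, 4-connected) minimum spanning tree
over unit centres plus a spur from each unit's residential core, so the
network is connected by construction and road distances are finite.
All randomness flows from explicit seeds through one `numpy` generator
per operation; identical (config, seed) reproduces outputs bit for bit.

Counts are drawn from the zero-inflated NB2 process the models assume:
`pi_i = logistic(gamma0 + gamma_age * age_i)`, otherwise
`y_i ~ NB(mu_i, theta)` with `log mu_i = alpha + beta' x_i + log e_i`,
NB sampled as a gamma–Poisson mixture. The default truth uses the
published coefficient magnitudes for `beta` and the zero-inflation age
effect, `theta = 1.5`, and an intercept `alpha = -7.0` calibrated once
so the expected case-per-dog ratio matches the national 3,611/496,689 ≈
0.73 %; with it a default region yields ~1.5 cases per unit, matching
the registry's per-municipality mean. Truth covariates are taken from
the **refined** support — the generative assumption that people and
dogs live on residential land is exactly what dasymetric refinement is
supposed to recover.

What the generator does *not* emulate: real topography and CRS
geodesy, spatially autocorrelated risk surfaces, unit-to-unit migration,
breed-specific risks, and measurement error in the dog census. Passing
tests therefore demonstrate correctness of the procedures and the
direction of aggregation effects under the stated process, not clinical
conclusions about real registries.

## Dasymetric refinement

Cells are allocated to units by cell-centroid location (boundary ties:
lowest unit id, documented and deterministic). A refined unit is the
dissolved set of its residential cells; it may be spatially
disconnected but remains one logical unit. Areas and centroids are
recomputed from residential cells; units without residential land
yield a flagged empty refinement, excluded from the refined-support
analysis with a warning while the municipal analysis keeps them.
Counts are never rescaled by refinement; `check_pycnophylactic`
asserts exact per-unit preservation on every pipeline run.

## Distance to veterinary care

The travel-distance grid is a multi-source shortest path over the
8-connected road-cell graph from all vet cells, with centre-to-centre
Euclidean step costs (0.1 km orthogonal, 0.1·sqrt(2) km diagonal at the
default cell size). Cells off the road network — and road cells whose
component contains no vet — receive the straight-line snap to the
nearest reachable road cell plus that cell's network distance; ties in
snap distance resolve to the smallest total. This explicit rule stands
in for unstated cost-surface conventions and is verified against an
independent O(V²) Dijkstra implementation on an exhaustive randomized
suite of small grids. Zonal averaging uses all cells of a unit on the
municipal support and residential cells only on the refined support —
that asymmetry *is* the studied change of support. Income tax is a unit
attribute and is never recomputed (it is neither a density nor a
distance); dog demographics and the offset are support-invariant by
construction, which the pipeline asserts bitwise.

## Count models and inference

Likelihoods are implemented directly: Poisson; NB2 with dispersion
`theta` (variance `mu + mu²/theta`); zero-inflated mixtures with
`P(0) = pi + (1-pi) f(0)` and `P(y>0) = (1-pi) f(y)`. Fitting is
maximum likelihood with analytic gradients under L-BFGS-B:

- fixed initialization — intercept `log(sum y / sum e)` for Poisson,
  the Poisson solution for richer families, method-of-moments `theta`,
  `gamma = 0`; zero-inflated fits add a second deterministic start near
  the no-inflation boundary and keep the better optimum, so a ZI family
  can never score below its base family beyond optimizer tolerance;
- internal centering/scaling of design columns for conditioning — an
  exact affine reparameterization, transformed back afterwards, so
  reported coefficients remain on the original, uncentered covariate
  scales (kept uncentered deliberately for interpretability);
- gradient tolerance 1e-8, generous box bounds (|coef| ≤ 50,
  log theta in [-12, 15], |gamma| ≤ 30) as numerical guards;
  non-convergence raises with optimizer diagnostics;
- Wald SEs from the inverse observed information, computed by central
  differences of the analytic gradient in the scaled space and mapped
  to natural parameters by the exact Jacobian (delta method for theta).

AIC counts every estimated quantity (intercept, betas, theta, gammas).
Deviance is `2(ll_sat - ll)` with the saturated model taken at
`mu_i = y_i` (and probability one for zeros under zero inflation,
`theta` held at its fitted value). The per-covariate effect size is the
drop-one deviance reduction relative to the intercept-only null of the
same family, `100 (dev_-k - dev_full) / dev_null` — the published
definition is under-specified, so this convention is fixed and emitted
with the reports. Zero-inflation covariates are selected by backward
elimination on Wald p-values at alpha = 0.05 (ties to the first
candidate in order; count component untouched).

Model comparison reports AIC, the relative likelihood
`exp((AIC_min - AIC_other)/2)` (raw and rounded to two decimals, the
convention under which decisive gaps print as 0.00), and pairwise
likelihood-ratio tests. Pairs that are non-nested (NB vs ZIP) or have
equal parameter counts (the cross-support pair) are labelled
"quasi-LRT, non-nested" and get no chi-square p-value: with df = 0 no
valid reference distribution exists, so the statistic is reported with
the caveat rather than an invented df. Nested pairs whose null pins a
parameter at the boundary of its space (theta, or the inflation
component) keep the conventional df with an explicit boundary note.

## Validation sizes and numerical choices

Estimator validation uses an i.i.d. covariate table
(`simulate_unit_table`) with marginals matching the region generator
but a well-conditioned zero-inflation design
(`gamma = (1.5, -0.6)` on age ~ N(5, 1)): 200 replicates at n = 2,000
for parameter recovery (bias within 3 Monte-Carlo SEs, 95 % Wald
coverage in [90 %, 98 %]) and 100 replicates for AIC model-selection
consistency. The aggregation-direction check runs 100 seeded
default-scale regions. The distance-grid oracle suite uses 40
randomized grids up to 15x15; mass preservation runs 100 seeded small
regions. These sizes are the package's validation design and complete
in a few minutes on one CPU.

## Known limitations

- The lattice world has no geodesy; "km" are planar grid kilometres.
- The quasi-LRT for non-nested pairs is descriptive, not a calibrated
  test (the Vuong test is deliberately out of scope).
- Wald inference near boundaries (very large theta, inflation
  probability near 0) is unreliable; fits at bounds are flagged via the
  optimizer diagnostics and SEs may fall back to a pseudo-inverse with
  a warning.
- Backward elimination inherits the usual multiplicity caveats of
  stepwise selection; it is implemented because it is the procedure
  under study, not because it is recommended practice.
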