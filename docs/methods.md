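# Methods

This note documents the statistical models, the numerical choices, and the
deliberately open design decisions in `urbanfilter`, in the order the
pipeline runs them.

## Landscape metrics

**Urbanisation.** The fraction of impervious surface inside a disc of
radius 500 m around the plot, expressed in percent. 500 m is used because
it approximates the foraging radius of most wild bees; it is configurable
(`radius_m`). The disc is polygonised with 256 segments per quadrant and
the denominator is the exact circle area πr², so the discretisation error
is below 0.01 percentage points. Classes: low ≤ 20 %, medium > 20–≤ 50 %,
high > 50 %.

**3D connectivity.** Hanski's incidence-function connectivity
`S_i = Σ_{j≠i} exp(−α d*_ij) A_j`, with three choices the classic index
leaves open:

- *Effective distance* `d*_ij` is the minimum edge-to-edge distance plus
  the summed heights (m) of every building whose footprint intersects a
  corridor around the segment joining the two patches' nearest boundary
  points. Heights are added directly in metres, with no rescaling, and a
  building counts its full height whenever its footprint touches the
  corridor (no area weighting). Connectivity therefore decreases with
  more or taller buildings between patches.
- *Corridor geometry*: "25 m around the connecting line" is implemented
  as a buffer of radius 25 m (total width 50 m), configurable via
  `halfwidth_m`. A centroid–centroid connector is not offered; nearest
  boundary points keep the corridor consistent with the edge distances.
- *Units*: α defaults to 1/500 m⁻¹ (matching the 500-m action radius) and
  areas enter in km² (`area_scale = 1e-6`), which puts `S` on the order
  of the 0.03 / 0.10 class-bin edges. Both are parameters, not constants,
  because no canonical values exist for them.

Degenerate cases: a single patch has `S = 0` (empty sum); overlapping
patches have edge distance 0 and a corridor that is a 25-m disc around
the contact point.

## Community preparation

`filter_rare` drops species with grand-total abundance ≤ 2 ("found only
once or twice"), then sites with fewer than 3 remaining individuals,
applied once in that order (not iterated to a fixed point — a site drop
can in principle leave a species below threshold; the single pass is the
documented behaviour). The rarity criterion counts individuals, not
occupied sites; an `occupancy` mode implements the alternative reading.

`wisconsin_sqrt` applies the square root first, then the Wisconsin double
standardisation (species ÷ column maximum, then sites ÷ row total), the
conventional combined treatment; every output row sums to 1. Reversing
the order would change results because the row/column scalings do not
commute with the square root; only the documented order is used by the
pipeline.

Bray–Curtis dissimilarities are computed by scipy (`pdist`), verified in
the tests against explicit double loops and against R vegan.

## NMDS and envfit

NMDS minimises Kruskal stress-1,
`sqrt(Σ(d−d̂)²/Σd²)`, by iterative majorisation (SMACOF): each iteration
fits disparities `d̂` by isotonic regression of the configuration
distances against the dissimilarity ranks (primary / "weak" ties: tied
dissimilarities impose no monotonicity constraint among themselves,
implemented by ordering tied blocks by the current distances) and then
applies the Guttman transform. Iteration stops when the stress decrease
falls below `tol` (default 1e-10) or after 300 iterations; the search
restarts from 100 random configurations and keeps the lowest-stress
solution. The solution is declared *stable* when the two best starts
agree to a Procrustes RMSE < 1e-4 after centring, unit-scaling and
optimal rotation. Final scores are centred and rotated to principal axes
with a deterministic sign convention, so runs are reproducible and
envfit directions comparable. Two axes are used by default.

`envfit` regresses each centred variable on the score columns; r² is the
squared multiple correlation and the direction the normalised coefficient
vector. Significance permutes the variable's values across sites
(vectorised; default 99,999 permutations) with the add-one estimator
`p = (1 + #{r²* ≥ r²})/(B + 1)`, so p-values live on the grid
`{1/(B+1), …, 1}`. Constant variables are reported as NaN with a warning
rather than aborting the other fits. The r² computation is
cross-validated against vegan's `envfit` in the test suite.

## Indicator species (IndVal)

For species *s* and class *c*: specificity `A = mean abundance in c ÷ Σ
over classes of mean abundances` (class means correct for unequal class
sizes), fidelity `B = share of class-c sites occupied`, `IV = A·B`. The
input is the filtered, untransformed count matrix — the Wisconsin/sqrt
standardisation is an ordination treatment, not part of IndVal. Species
are selected by `best IV ≥ 0.3` (boundary included); a site-label
permutation test exists but is off by default because selection is by
threshold. Ties for the best class report all tied classes.

## RLQ and fourth-corner

With `P = L/Σ L`, site weights `r` and species weights `c`, environment
and coded trait columns are standardised to weighted mean 0 / sd 1 and
the cross-matrix `M = R̃ᵀ(P − rcᵀ)Q̃` computed; its entries are the
fourth-corner pseudo-correlations (|stat| ≤ 1), and the RLQ eigenvalues
are the squared singular values of M, so the first eigenvalue is the
largest squared association any pair of unit linear combinations can
achieve. The L matrix is expected filtered and with positive totals; a
rank-0 M (abundances exactly proportional to their margins) is an error.

Trait coding: categorical traits are dummy-coded one column per level
(matching per-level reporting such as "eusocial" or "polylectic");
quantitative traits are z-scored under the species weights. Single-level
and zero-variance columns are dropped with warnings.

Permutation model 2 permutes rows of L, breaking the site–environment
link while preserving the species–trait link; site weights are recomputed
for every permutation (species weights are invariant under row
permutations). p-values are two-sided add-one on |stat|, 9,999
permutations by default. No multiple-testing adjustment is applied by
default (raw p-values are reported); the sequential model-2/model-4
max-test is not implemented. A permutation that degenerates a
standardisation is redrawn with a hard cap of 100 redraws.

**Direction checks.** Per site and categorical trait level, the number of
*species present* carrying that level is counted (an abundance-weighted
mode is intentionally not the default: "frequency of a trait in the
community" is read as species counts) and regressed on each environmental
variable with a Poisson log-link GLM (statsmodels IRLS, tol 1e-10, 100
iterations; non-convergence is flagged, not fatal). The GLM sign and the
fourth-corner sign are reported side by side and not reconciled: for
quantitative traits only the fourth-corner statistic carries a sign.

## Synthetic surveys

The generator emulates a pan-trap pollinator survey of urban dry
grassland patches:

- **Landscape**: 49 convex patches (areas 2,000–50,000 m²) placed by
  rejection sampling (limit 1,000 attempts per patch) in a 30 × 30 km
  extent, plus Poisson-count rectangular buildings (default 2 km⁻²,
  heights uniform 5–30 m, footprints 8–30 m a side). The building layer
  doubles as the impervious layer for the geometry stage.
- **Environment**: six variables drawn uniformly over ranges spanning the
  class bins (urbanisation 0–100 %, connectivity 0–0.30, patch size
  500–10⁵ m², herb cover 0–100 %, non-native cover 0–60 %, mean air
  temperature 16–26 °C), independent by default with an optional Gaussian
  copula correlation. The analysis environment table is drawn, not
  derived from the generated geometry — the geometry stage is validated
  separately against analytic fixtures.
- **Traits**: wild bees get sociality/nesting/diet (15 % of species
  cleptoparasitic in all three simultaneously, as in real brood
  parasites), flight period 2–9 months and log-normal body sizes around
  9 mm; hoverflies get body size, flight period, migratory status (0/1)
  and larval food type.
- **Abundances**: `log λ_ij = β₀ + a_i + b_j + Σ c_kt x_ik z_jt` with
  Poisson draws; site effects `a_i ~ N(0, 0.3)`, species baselines
  `b_j ~ N(0, 1)` on the log scale (log-normal dominance, so a few
  species dominate the totals, stressing the rarity filters), `x`
  z-scored environment and `z` the coded traits. The default baseline
  `β₀ = −1` gives mean cell counts of ~0.6 and grand totals of order
  1,500–2,000 individuals for 49 × 50 matrices — between the per-cell
  densities typical of bee (~0.2) and hoverfly (~0.8) pan-trap surveys.
  The acceptance survey scenario uses `β₀ = −2.2` to emulate the sparser
  bee-like regime where the filters visibly bite.

What the generator does **not** model: spatial autocorrelation of
abundances, repeated sampling rounds, trap-colour bias, and any coupling
between the drawn environment table and the generated geometry. Passing
calibration/power checks therefore demonstrate the correctness and
sensitivity of the statistics under the stated log-linear model, not
robustness to spatially structured noise.

All generator stages draw from independent, tagged `numpy` Generator
streams derived from the scenario seed, so every output is bit-for-bit
reproducible and stages can be regenerated in isolation.

## Calibration and power (what the acceptance script measures)

- Type-I error: 400 null surveys (no interactions, 49 sites × 50
  species, filters applied), fourth-corner model 2 with 199 permutations
  per survey; the pooled rejection rate at α = 0.05 is expected in
  [0.03, 0.07], and the p-value of one fixed pair is KS-tested for
  uniformity. 199 permutations suffice here because the add-one p-value
  grid {1/200, …, 1} puts exactly probability 0.05 on p ≤ 0.05 under the
  null.
- Power: 200 surveys with a planted +0.8 urbanisation × polylectic
  log-rate interaction; detection means p < 0.05 with a "+" sign for that
  pair.
- The survey-scale run reports the filter bookkeeping, NMDS stress,
  envfit r²/p for urbanisation, the best urbanisation-class IndVal, the
  fourth-corner statistic/p of the planted pair, and the GLM slope of
  polylectic species counts on urbanisation.

Problem sizes (replicate counts, permutation counts per replicate) are
chosen so the whole battery completes in well under a minute of compute
while keeping Monte-Carlo error on the rejection rates below about one
percentage point.

## Known limitations

- NMDS uses SMACOF majorisation; like any local optimiser it can in
  principle return a local minimum, mitigated by 100 random starts and
  the Procrustes stability check.
- The fourth-corner implementation offers permutation model 2 only;
  model 4 (columns of L) and the combined max-test are out of scope.
- Geometry is strictly planar-metric; geographic coordinates must be
  projected before use.
- The corridor height sum treats buildings as opaque columns; partial
  overlap with the corridor counts the full height.
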