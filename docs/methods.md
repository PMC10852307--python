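# Methods

## Scope and model

`plelscape` implements a grid-based landscape ecological security analysis
for arid-zone oasis cities, from categorical land-use rasters to security
and coordination surfaces and multi-scenario land demand.  The analysis
assumes a single-landscape study area tiled by square evaluation units,
eight PLEL classes in three functional tiers, and areas expressed in hm²
throughout (cell_size² / 10 000 per cell).  All randomness — synthetic
data, permutation tests, classifier fitting, CA allocation — is driven by
explicit seeds, so every table is bit-reproducible from a config snapshot.

## Risk index

Per unit k and class i present: fragmentation C = n/A, separation
S = (A_k/2A)·√(n/A_k), disturbance E = 0.5C + 0.3S + 0.2D, loss R = E·F,
and ERI_k = Σ (A_ki/A_k)·R_ki.  Two reading ambiguities had to be settled:

* **Symbols.**  The same symbol is conventionally used for the patch count
  and the separation index in this family of models; we use n for patch
  count and S for separation, with the 0.5/0.3/0.2 weights applying to
  C/S/D.
* **Dominance scope.**  D_i = (Q_i+M_i)/4 + L_i/2 depends on Q, the share
  of units in which class i occurs, which is only meaningful across units;
  D is therefore computed once per epoch over the whole landscape by
  default.  A per-unit variant (`dominance_scope="unit"`, where Q
  degenerates to presence) is available for sensitivity checks.

Patches are 8-connected components (the Fragstats convention; 4-connected
is available) and are cut at unit borders, since the metrics are
unit-local.  Vulnerability weights are normalized ranks rounded to two
decimals — the canonical table (ULL 0.03 … OEL 0.22) sums to exactly 1.00
and is used as shipped rather than recomputed at full precision, because
the published security-level thresholds were derived from the rounded
values.  Tier risks U1/U2/U3 are partial sums of the same series, so
ERI = U1+U2+U3 holds identically.

## Security surfaces

Unit ERI (and coordination D) values at unit centroids are interpolated by
ordinary kriging with a spherical semivariogram fitted to the binned
empirical semivariogram by count-weighted least squares.  The nugget is
pinned to 0 by default, making the interpolator exact at data points; a
singular system falls back to inverse-distance weighting with a logged
warning.  At least 10 points are required.  The output grid is 500 m, so
every reported level area is a multiple of 25 hm².

Security levels use fixed thresholds 0.0061 / 0.0079 / 0.0096 / 0.012
(half-open, lower-inclusive from level II up), a published calibration of
the 2010 epoch kept constant across epochs so levels are comparable over
time.  A simple 1-D k-means breaks utility is included for users who want
data-driven thresholds; it is off by default.  On the synthetic demo the
mean unit ERI (~0.018–0.023) sits above the 0.012 break, so most of the
demo surface classifies as level IV–V; the thresholds are a property of the
calibration landscape, not of the synthetic texture.

Global Moran's I uses row-standardized queen contiguity between units
(rook available); the weights scheme is a default, not a published choice.
Significance comes from ≥ 999 seeded value permutations (fewer in the fast
demo config); the null expectation is −1/(n−1).

## Coupling coordination

C = [1 − √(((U3−U1)² + (U3−U2)² + (U2−U1)²)/3)] × (Ua/Umax) × (Ub/Umax),
where Umax is the largest tier risk and Ua, Ub the other two.  The
max-denominator convention keeps both ratio factors ≤ 1, makes C symmetric
in its arguments and clamps C to [0,1]; a literal ecological-denominator
variant is switchable.  T = 0.3·(U1+U2+U3) keeps the published weights
even though they sum to 0.9 — fidelity over tidiness.  D = √(C·T) is the
default: at the risk magnitudes this model produces (U ≈ 0.001–0.01) the
plain product C·T cannot exceed ~0.01, which would make the upper
coordination classes (D > 0.034) unreachable; the root form spans all five
published classes.  D = C·T remains available (`form="product"`).  Units
missing an entire tier have C = 0 and classify as severe disorder, which
reproduces the expected "coordinated corridor, disordered flanks" pattern.

## Scenario land demand

* **NLD** — the Markov matrix is the row-normalized area transition of the
  latest observed interval (5-year convention) and is applied twice for a
  10-year horizon.  Zero-area rows become identity rows with a warning.
* **ECD / ELD** — linear programs over the eight class areas: a fixed
  total (732 360.78 hm²), per-class box bounds, and a population-capacity
  constraint (coefficients 0.006/40/1.3/0.0015/0.003 people·hm⁻¹ on
  APL/ULL/RLL/FEL/GEL, cap 320 000).  Solved exactly with HiGHS; because
  the objectives have strictly ordered positive coefficients, the optimum
  is the greedy vertex (classes filled to bounds in coefficient order),
  which the tests verify against an independent greedy oracle.  OEL takes
  an implicit lower bound of 0.
* **EED** — weighted-sum scalarization of the two objectives, each
  normalized by its single-objective optimum, solved as one LP.  A seeded
  real-coded genetic algorithm (box sampling, projection repair onto the
  equality, quadratic population-penalty) is provided for parity with
  GA-based solvers but is not the reference route.
* **GM(1,1)** — standard first-order grey model (AGO accumulation,
  background z(k) = 0.5(x¹(k)+x¹(k−1)), least-squares (a,b), exponential
  time response), exposed as a utility for building demand bounds from
  short positive series; the |a| → 0 limit is handled as a constant
  forecast.  Fitting requires length ≥ 4 and strict positivity.

The shipped default `ScenarioSpec` (objective coefficients and all
constraints) lives in `src/plelscape/data/scenario_defaults.yaml`.  Some
published per-class optima for non-bound-attained classes are mutually
inconsistent with the published bounds (e.g. an FEL area above its own
upper bound); the package treats the bound-attained classes as the
verifiable surface and reports totals, which are conserved exactly.

## Synthetic data

The generator emulates a mountain–oasis–desert corridor landscape:

* **Texture.**  Per-class score = 0.8 × deterministic corridor prior +
  unit-variance Gaussian-smoothed noise; the cell class is the argmax.
  Production/living priors peak at the corridor axis, grassland and forest
  on the flanks, desert at the margins.  Per-class additive offsets are
  calibrated by a damped, clamped log-share fixed point so realized
  proportions land within ~±3 points of the target at ≥ 200×200 cells
  (zero-proportion classes never appear).
* **Defaults** (the study conditions for all shipped tests and the demo):
  300×300 cells at 30 m, proportions echoing a 2020 oasis mix
  (GEL 0.49, OEL 0.21, APL 0.18, WEL 0.067, FEL 0.035, RLL 0.009,
  ULL 0.006, IPL 0.003), smoothness 15 cells (450 m correlation length,
  giving km-scale patches as in a real oasis mosaic), corridor at
  mid-height, near-diagonal epoch transition (stay probabilities
  0.90–1.0) with a reclamation drift from ecological to production/living
  classes.
* **Epoch evolution.**  The number of i→j conversions is drawn
  multinomially from the transition row; converting cells are selected by
  a Gumbel-top-k rule with key 6·log(density+0.02) + 3·prior, executed in
  four batches with the destination-class 3×3 density recomputed in
  between, so change accretes onto growing patches and follows the
  corridor gradient (as real reclamation does).  This makes epoch-to-epoch
  change largely driver- and adjacency-determined — the property that
  makes hindcast validation of the allocator meaningful — while the
  multinomial counts keep the cross-tabulated transition matrix
  recoverable to within ±0.05.
* **Restriction zone.**  A disc of immutable water cells stands in for a
  protected lake; it is stamped as WEL and excluded from all transitions.
* **Drivers.**  Elevation (ridge–valley profile + smooth noise), distance
  to corridor, distance to random road lines, and a smooth climate proxy,
  co-registered with the land-use grid and finite everywhere.

What the generator does **not** emulate: real terrain and hydrology,
anisotropic or curved corridors, class-specific patch-size distributions,
registration error between epochs, and classification noise.  Passing
tests therefore demonstrate internal correctness and behavioral realism of
the pipeline, not agreement with any real landscape's numbers.

## Spatial allocation

Suitability is learned by a pluggable classifier (random forest with 60
trees by default; logistic regression optional) on cells sampled under the
mask with labels from the later epoch, oversampling observed-change cells
3×.  Classes absent from training receive a small spatially uniform floor
so the calibrated probabilities of seen classes are not distorted.

The CA builds one integer conversion plan up front — donors with surplus
feed growers with deficits; optionally the plan starts from the
Markov-expected gross flows counts·P (the CA–Markov convention, used by
the self-validation) and is trimmed/topped up to hit the demand — then
executes it over rounds with a geometric acceptance schedule
(share 1 − decay^t per round, decay 0.9).  Within a round, cells are
chosen by log score + temperature·Gumbel with
score = suitability × (3×3 density + 0.02)³; a binomial share
(patch_seed_prob = 0.02) of each round's conversions instead seeds new
patches at suitability-weighted cells, ignoring the neighborhood term.
Converted cells are frozen for the rest of the run, so no cell is shuffled
through a chain of classes, and the final areas match demand to within
0.5 % whenever the plan is feasible.  Restricted cells never change;
demands below a class's immutable restricted area are rejected before
iteration; a boolean 8×8 matrix can forbid specific conversions.

Accuracy is summarized by the confusion matrix, overall accuracy and
Cohen's kappa (cross-checked against scikit-learn in the tests).  The
built-in self-validation fits suitability on epochs 0→1, allocates the
observed epoch-2 demand from epoch 1, and compares kappa against the
persistence baseline (predicting epoch 1 unchanged); on the default
synthetic conditions the allocator wins (~0.95 vs ~0.92 across seeds).
This allocator is deliberately a reduced-fidelity, behavioral
reimplementation of patch-generating CA simulators — demand convergence,
patch-like growth, restriction handling — not a bit-compatible clone of
any particular software.

## Numerical choices and degenerate inputs

* Rasters are row-major, origin top-left, addressed (row, col) 0-based;
  interchange format is the ESRI ASCII grid (text, exact for integer
  codes).  Masked cells are excluded from every statistic; cells masked in
  either epoch are excluded from cross-tabulation, surfacing mask
  mismatches through the conservation checks rather than silently.
* Evaluation units on the raster edge are kept clipped (valid-area A_k);
  units under 10 % valid coverage are dropped; a zero-area unit is skipped
  with a log entry.
* The evaluation-grid edge must be an integer multiple of the cell size.
  The demo config uses 1.5 km units (instead of the analysis default 3 km)
  because a 9 km synthetic domain holds only 9 three-km units, below the
  kriging minimum of 10 points; 1.5 km preserves the units-per-domain
  ratio of the full-scale analysis.
* Kriging enforces exactness at coincident points explicitly when the
  nugget is 0 (float round-off would otherwise leave ~1e-12 residuals);
  constant fields short-circuit to a constant surface.
* Level classification uses `digitize` (lower-inclusive from level II);
  coordination classification is upper-inclusive at its breaks, matching
  the published interval notation of each table.
* LP demands satisfy the total-area equality to 1e-4 hm²; the greedy
  oracle and the LP agree to the same tolerance.  Tie coefficients (IPL =
  ULL = RLL in the economic objective) are resolved identically by both
  because all three reach their upper bounds at the optimum.

## Problem sizes

Shipped tests and the demo run at 120×120–300×300 cells, 9–100 units,
three epochs, 49–999 permutations, 60-tree forests on ≤ 20 k samples —
sizes chosen so the whole suite completes in well under a minute while
every statistical check retains comfortable margins (transition recovery
tolerance ±0.05 vs observed ~0.01; proportion tolerance ±3 points vs
observed ~2.4 worst-case).

## Known limitations

* The coupling-degree formula family has several renderings in the
  literature; the implemented dispersion-times-ratio form with
  max-denominator is one defensible reading (the alternatives are
  switchable but not exhaustive).
* Kriging fits only a spherical model; no anisotropy, no co-kriging.
* The GA scenario solver is a convenience baseline, not a tuned optimizer.
* Published per-class optima that conflict with their own printed bounds
  cannot be reproduced by any feasible program and are out of scope.
* Real-data headline statistics (multi-decade risk trends, published
  kappa/accuracy of the original simulation) require the original rasters
  and are not reproducible from synthetic data.
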