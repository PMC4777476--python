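# Methods

## Model family and workflow

All models are binary-response logistic regressions fitted by iteratively
reweighted least squares (IRLS). Convergence is declared when the largest
absolute coefficient change falls below 1e-8, with a cap of 50
iterations; non-convergence is flagged on the returned model rather than
raised. Quasi-complete separation is detected as a coefficient exceeding
|β| = 15 while the likelihood is still improving, and likewise flagged,
because univariate screening legitimately encounters near-separating
columns and must not abort. Rank-deficient designs are rejected with the
linearly dependent columns named (pivoted-QR diagnostic), which is also
how duplicate candidates are excluded during selection.

The per-species workflow is: trend-surface construction → FDR screening
within each predictor set → stepwise predictor-set models → combined
space-included / space-excluded models on a 70/30 split → held-out
evaluation → variation partitioning → favourability surfaces under
current and scenario climates.

### Stepwise selection

Entry and removal decisions both use likelihood-ratio (LR) χ² tests.
Many legacy SDM workflows use score tests for entry and Wald tests for
removal; LR is the more accurate member of that trio and using it for
both directions keeps the selection self-consistent (every retained
term's removal p ≤ `p_remove` — asserted on every fit in the suite).
Defaults are `p_enter` = 0.05 and `p_remove` = 0.10; `p_enter` ≤
`p_remove` is enforced to prevent cycling, and an iteration budget of
2 × (number of candidates) guards the loop. Forward ties are broken by
the larger deviance reduction, then by declared candidate order, making
selection deterministic. Linear and quadratic terms are free,
independent candidates: no marginality constraint forces a linear term
in whenever its square is selected, so a quadratic can represent a
one-sided curvature on its own.

### Trend surface (Geog)

Cell-centroid coordinates are centred on their means and scaled by their
standard deviations before the nine monomials X, Y, X², Y², X³, Y³, XY,
X²Y, XY² are constructed; raw cubed map coordinates span many orders of
magnitude and would destabilize the fit. The scaling constants are
stored with the fitted surface, so `Geog` is exactly reproducible on the
original or on new cells. Elimination is backward-only (no re-entry) at
`p_remove` = 0.10. If every term is eliminated the surface degenerates
to the constant intercept logit and a warning is recorded.

By default `Geog` is fitted on all cells before the train/test split and
then treated as a fixed covariate — the trend surface is a
data-preparation step, like deriving a slope layer. This choice leaks
some response information into the held-out cells; a `split-safe` mode
(fit on training cells, evaluate on all via the stored scaling) is
provided for strict out-of-sample evaluation. Future projections hold
`Geog` fixed: coordinates do not change over time, which is precisely
the anchoring behaviour the space-included/space-excluded contrast is
designed to expose.

### Favourability

F = logistic(logit(P) − ln(n₁/n₀)), algebraically identical to the odds
quotient form but stable near P ∈ {0, 1}; the endpoints are returned
exactly. The (n₁, n₀) are those of the model-fitting data — the training
split during evaluation, the full dataset for final maps — because they
parameterize the fitted model's prevalence. Classification cuts for
low/medium/high maps default to 0.2/0.8 (the convention of the
favourability literature) and are configurable. Because F is strictly
increasing in P, rank-based metrics (AUC) are identical on either scale;
the suite asserts this exactly.

### Variation partitioning

"Variation" is Nagelkerke's R², the same statistic reported as deviance
explained, so the partition is commensurate with the headline metric.
For the sets represented in a combined model, every non-empty subset S is
refitted with exactly the model's terms belonging to S — fixed variable
lists, no re-selection — and the fractions are obtained by Möbius
inversion of g(S) = R²(all) − R²(all − S). This makes the fractions sum
to the full model's R² exactly (asserted at 1e-10), and lets shared
fractions go negative, which is reported as-is: a negative joint
fraction is the signature of suppression between predictor sets, not an
error. Partition refits use the training rows, matching where the
combined model was estimated.

### Evaluation

Sensitivity, specificity and CCR are computed at the neutral threshold
F ≥ 0.5 — the boundary cell counts as predicted presence, stated
bit-exactly because CCR at the neutral threshold is a reported metric —
on the 30 % held-out cells; AUC uses the Mann–Whitney formulation with
ties counted half. Deviance explained and AIC are computed on the
training fit (where the model was estimated); the 70/30 split is
unstratified with a validity check (both classes must appear on both
sides; up to 100 seeded redraws), with a stratified option.

### Scenario projection

A scenario supplies replacement values for climatic columns only.
Quadratic climatic terms are recomputed as the square of the shifted
parent — the only physically coherent treatment — and the suite checks
cell-wise that stored squares equal shifted parents squared. A scenario
missing a climatic column required by the model is rejected naming the
column. Non-climatic terms (land use, topography, Geog) keep their
current values.

## Synthetic landscapes

The generator emulates an atlas-style study: a regular lattice of cell
centroids in abstract planar units ("lon"/"lat" are labels; no
great-circle math anywhere), six spatially autocorrelated covariates in
three environmental predictor sets, quadratic terms for the climatic
ones, and a Bernoulli-logistic occurrence process.

* **Covariates** are white noise smoothed with a uniform kernel over all
  cells within a radius (default ~5 cell widths) and standardized to unit
  marginal variance. Kernel smoothing costs O(n·k) instead of a full
  Gaussian-process draw and induces all the autocorrelation the trend
  surface needs to detect (first-order Moran's I ≈ 0.5–0.7 at the default
  radius; the suite checks I is non-decreasing in the radius).
* **Occurrence** mixes environmental effects (per-SD log-odds of order
  0.4–0.8) with a pure spatial term built from coordinate monomials
  inside the nine-term trend-surface span (default −1.2Y + 0.8Y³ + 0.6X,
  scaled by `spatial_strength`, default 2.0 — a distribution dominated by
  where the species is, not only by its measured environment). The
  intercept is calibrated by bisection so the mean generating probability
  equals the target prevalence within ±0.005 (≤100 iterations); the
  default target is 0.055, the rare-species regime in which favourability
  and probability differ most.
* **Scenarios** add constant (optionally spatially graded) shifts to the
  climatic covariates; the default shift (−1.0, +1.5, +0.5 SD on the
  three climate variables) is a deliberately large signal so projection
  anchoring is tested under stress.

What the generator does **not** emulate: irregular coastlines and study
areas, observation error and imperfect detection, covariate
non-stationarity, dispersal dynamics, and real climate fields' cross
correlations. Passing tests therefore demonstrate that the machinery
recovers the structures it assumes, not that those assumptions hold for
any particular atlas dataset.

## Problem sizes and determinism

Simulation-backed checks use a 40×40 grid (1600 cells, ~88 presences at
prevalence 0.055) with 20–50 seeded replicates, and 200 replicates at
n = 2000 for coefficient recovery and FDR control; these sizes give
stable pass/fail behaviour at desk scale. All randomness flows through
explicit integer seeds (numpy `default_rng`); a fixed seed reproduces
grids, fields, occurrences, splits and therefore entire pipeline runs
byte-identically.

## Known limitations

* Stepwise selection inherits the usual instability of variable
  selection; entry order is reported because it is part of the method's
  interpretive vocabulary (broad-scale vs fine-scale drivers), not
  because it is robust.
* The all-data trend-surface mode leaks response information into the
  evaluation split by construction (documented above; `split-safe` mode
  avoids it).
* Inclusion–exclusion partitions with many sets produce 2^k − 1
  fractions whose individual interpretation degrades as k grows; with
  the four sets used here this is not a practical concern.
* IRLS with a flagged separation returns finite but extreme
  coefficients; downstream code treats such fits as screening evidence
  only.
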