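# Methods

## The model

`parasdm` estimates habitat suitability for presence-only data with a
maximum-entropy (Gibbs) distribution over landscape cells.  Given feature
expansions f(x) of the predictor values and a background sample
b₁…bₙ, the model is

    raw(x) = exp(λ·f(x)) / Z,    Z = Σᵢ exp(λ·f(bᵢ)),

and λ maximizes the L1-penalized presence log-likelihood

    (1/m) Σ_presence λ·f(x) − log Z − Σⱼ βⱼ |λⱼ|.

This is the standard convex formulation of MaxEnt-style SDMs: the fitted
distribution is the maximum-entropy distribution subject to (soft) moment
constraints at the presence points.  Assumptions worth keeping in mind:
presences are an unbiased (or at least exchangeable) sample from the
species' occupied cells; the background sample represents the available
environment; and predictors are meaningful at the analysis resolution.

### Feature classes

Predictors are min–max scaled to u ∈ [0, 1] over the training background
(values outside the training range are clamped at projection time).  The
five feature classes are Linear (u), Quadratic (u²), Product (uᵢuⱼ for all
pairs), Hinge (forward `max(0, (u−t)/(1−t))` and reverse `max(0, (t−u)/t)`
at 50 uniform interior knots per variable per direction), and Threshold
(strict step indicators `1[u > t]` at 50 interior knots).  Interior knots
avoid the degenerate hinges at t = 0 and t = 1.

### Regularization

βⱼ = RM · base(class, m) · max(sdⱼ, 1/√m) / √m, where m is the presence
count, sdⱼ the presence standard deviation of feature j, and
base(class, m) the per-class default schedule interpolated
piecewise-linearly against m (linear/quadratic: 1.0 → 0.2 → 0.05 at
m = 10/30/100; product: 2.6 → 1.6 → 0.5 at 0/10/17; hinge: 0.5;
threshold: 2.0 → 1.0 at 0/100).  The per-feature sd factor keeps features
of very different scale (step indicators vs. linear terms) comparably
penalized; the 1/√m floor gives near-constant features a finite penalty.
The regularization multiplier RM scales every βⱼ linearly, so larger RM
means sparser, smoother models.

### Optimization

The non-smooth problem is solved through the exact split λ = λ⁺ − λ⁻
(λ± ≥ 0), which turns the L1 term into a linear one, and bound-constrained
L-BFGS-B (tolerance 1e−7 on the relative objective, 10⁴ iteration cap,
convergence flagged on the model).  The split is equivalent to the
coordinate-wise proximal view of the same concave objective; L-BFGS-B's
active-set handling drives irrelevant coefficients exactly to zero, and a
final |λ| ≤ 1e−7 snap makes the non-zero count k reproducible.  Presence
cells are included in the background by default ("target-group" style);
this is a documented toggle of the fitting helpers.

### Outputs

Raw output sums to one over the training background.  The logistic
suitability index is p = e^H·raw / (1 + e^H·raw) with H the entropy of the
fitted background distribution; it is a monotone rescaling of raw to
(0, 1), and the null model maps every cell to exactly 0.5.

## Model tuning

Candidates cross six feature combinations (L, LQ, LQH, H, LQHP, LQHPT)
with RM 0.5–4.0 in steps of 0.5 (48 models).  Each candidate is fitted on
the full presence set with a shared background; AICc is

    AICc = 2k − 2 ln L + 2k(k+1)/(n−k−1),

where ln L standardizes the raw output to sum to one over *all* valid
study cells and evaluates it at the presences, k counts coefficients with
|λ| > 1e−7, and n is the presence count.  AICc is undefined (and the row
excluded) when k = 0 or k ≥ n−1.  The model with delta.AICc = 0 is
selected; ties break toward smaller k, then larger RM, then grid order.
The full LQHPT feature matrix is expanded once and sliced per candidate.
Selection uses AICc only; the optional per-candidate test AUC in the
tuning table comes from a single 75/25 split refit and is reporting-only.

## Evaluation

* **Splits** — random 75/25 train/test partitions (test size ⌊0.25·n⌋),
  re-drawn per replicate; replicate runs also re-draw the background.
* **AUC** — rank-sum (Mann–Whitney) presence-vs-background AUC with ties
  counted one half; background points act as pseudo-absences.  Reported as
  mean ± sd over replicates (sd, not standard error — labelled as such).
* **Percent contribution** — normalized permutation importance: the mean
  AUC drop over 10 permutations of one variable across the evaluation
  cells, floored at zero and normalized to sum to 100.  This replaces
  path-dependent heuristic attributions with a statistic that is well
  defined for any fitted model; the substitution is deliberate and the
  numbers are not comparable to path-attribution contributions.
* **Jackknife** — regularized training gain
  (1/m)Σλ·f(x) − log Z + log n_bg of the model refitted with each
  variable alone and with each variable withheld; the null model has gain
  exactly 0.

## The host constraint

For an obligate parasite the host is part of the niche.  Two mechanisms
are combined in the Parasitic Constraint Scenario (PCS):

1. the host's mean replicate suitability layer P_HA enters the parasite
   model as an additional continuous predictor, and
2. the **conditional probability transfer** zeroes the parasite
   suitability wherever P_HA < θ (default θ = 0.4, the medium-and-high
   host range) — below the effective-parasitism threshold no amount of
   abiotic suitability makes a cell habitable.

The transfer is applied to the replicate-mean parasite layer (masking
after averaging; the alternative order differs only when replicates
disagree about cells near the threshold).  The Natural Habitat Scenario
(NHS) uses environmental predictors only.  Scenario divergence is
summarized per suitability class by the area difference rate
(area_PCS − area_NHS)/area_NHS × 100 % and by the great-circle shift of
the suitable-area centroid.  By construction every PCS-suitable cell lies
inside the host's θ-range — an invariant the tests assert unconditionally.
When tuning is not fixed by the caller, NHS and PCS are tuned
independently on the AICc grid (reusing NHS settings for PCS is possible
by passing them explicitly).

## Classification, change and centroids

Suitability classes use half-open bins with inclusive lower bounds:
unsuitable P < 0.2, low 0.2 ≤ P < 0.4, medium 0.4 ≤ P < 0.6, high
P ≥ 0.6; the binary "suitable" map is P ≥ 0.4.  Change between periods is
coded 0–0 / 0–1 (expansion) / 1–0 (contraction) / 1–1 (stable), and the
four category areas partition the jointly valid grid.

Cell areas are spherical: a cell spanning Δλ of longitude between
latitudes φ_b and φ_t has area R²·Δλ_rad·(sin φ_t − sin φ_b) with the
authalic radius R = 6371.0072 km.  This is a closed-form, reproducible
choice; GIS engines may report slightly different (ellipsoidal or
projected) areas.  The centroid is the cell-area-weighted mean of
suitable-cell centers in geographic coordinates; it assumes the suitable
region does not straddle the antimeridian (error if it spans ≥ 180° of
longitude).  Centroid shifts use the haversine great-circle distance on
the same sphere (1° of latitude = 111.19 km).

## Raster conventions

The ESRI ASCII grid is the interchange format: corner-registered square
cells, row 0 northernmost, nodata default −9999 (NaN in memory).  Point →
cell assignment is half-open, [west, east) × (south, north], so every
point inside the bounding box maps to exactly one cell.  Layers must be
exactly co-registered (headers equal within 1e−9°); no reprojection or
resampling is provided, by design — harmonization belongs upstream.
Occurrence thinning keeps the first record (file order) in each analysis
grid cell, a deterministic stand-in for the usual "one point per cell"
thinning step; outlier detection beyond region masks is left to the user.

## Synthetic landscapes

The generator emulates the *structure* of a gridded host-parasite study:
co-registered predictors with controllable spatial autocorrelation
(Gaussian-kernel-smoothed white noise; kernel width in cells) and
controllable pairwise correlation (mixing with a shared latent field);
each field is standardized and passed through the normal CDF so its
marginal is stably near-uniform on [0, 1] across seeds.  A virtual host
has a logistic linear+quadratic response; the virtual parasite's truth is
its own environmental response multiplied by 1[host truth ≥ θ_true].
Occurrences are sampled without replacement with probability proportional
to truth, at cell centers.

The canonical study system (`make_study_system`) uses three predictors
(σ = 8 cells, pairwise r = 0.3) on a 100×100 grid of 2.5 arc-minute cells;
the host response 60u₁ − 30u₁² + 16u₂ − 34 puts roughly 35–40 % of cells
above the θ = 0.4 host threshold, and the parasite response
44u₂ − 12u₂² + 20u₃ − 42 (host-masked) leaves roughly 10–15 % of cells
suitable — the suitable fraction a narrow-niche desert specialist occupies
in a continental study window.  Default occurrence sizes are 88 parasite
and 234 host points, the sizes of the filtered datasets in the study this
package models.

What the generator does **not** emulate: sampling bias and imperfect
detection, spatially structured nodata (coastlines), temporally changing
climate surfaces, categorical predictors, and truth–predictor mismatch
(the truth is exactly a logistic function of the supplied predictors).
Passing recovery tests on these landscapes therefore shows the machinery
is correct and self-consistent, not that real-data predictions are
accurate.

## Problem sizes

The test suite and the acceptance script run the canonical 100×100 system
with backgrounds of 500–2000 cells, 2–10 replicates, and the full 6×8
tuning grid where tuning is exercised; these sizes give stable statistics
while keeping a full run in the tens of seconds on one CPU.  Larger grids
and the default 10 000-cell background are supported unchanged through the
same interfaces.

## Known limitations

* No cloglog output, bias files, categorical predictors, or spatial-block
  cross-validation.
* Percent contributions are permutation importances, not path
  attributions (see above).
* Areas are spherical, not ellipsoidal; differences to GIS engines are at
  the few-per-mille level.
* GeoTIFF is not read or written; the ASCII grid is the only raster
  dialect.
* The collinearity filter is the greedy max-|r|-first rule; it is
  deterministic but, like any greedy rule, not guaranteed to keep the
  globally best subset.
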