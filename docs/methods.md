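# Methods

## Model

The package implements presence-background maximum-entropy density
estimation. Let B be a background sample of n cells describing the
available environment and P a set of m deduplicated presence cells.
Covariates are expanded into features f_j ∈ [0, 1]; the model is the
Gibbs density p_w(x) ∝ exp(Σ_j w_j f_j(x)) over B, fitted by minimising

    L(w) = −(1/m) Σ_{i∈P} η(x_i) + log Σ_{b∈B} e^{η(x_b)} − log n + Σ_j λ_j |w_j|

which is the negative penalised presence log-likelihood of the density,
up to constants. The problem is convex; the implementation splits each
weight into positive and negative parts (turning the L1 term into a
smooth bound-constrained objective) and solves it with L-BFGS-B from a
cold start at w = 0, making every fit deterministic. Correctness is not
taken on faith: an algorithmically independent FISTA proximal-gradient
solver (`vector_enm.reference`) serves as an oracle, and the test suite
requires objective agreement within 1e-6 on randomised instances (the
measured gap is ~1e-13).

Two prediction scales are exposed. The *raw* scale is the normalised
density exp(η − log Z), which sums to 1 over the training background.
The *cloglog* scale, 1 − exp(−e^H · raw) with H the entropy of the
fitted density, maps suitability into (0, 1) and equals 1 − 1/e for a
completely uninformative model; it is the scale used for exported maps.

### Features and regularisation

Continuous variables are min–max scaled over the background and clamped
to [0, 1] when projecting. Feature classes: L (linear v), LQ (+v²), H
(forward hinges max(0, (v−k)/(1−k)) and reverse hinges max(0, (k−v)/k)
at knots k), LQH (all three). Hinge knots default to 32 per direction,
evenly spaced strictly inside (0, 1); the knot count is configurable
and the validation runs described below use fewer knots (see *Problem
sizes*). Categorical variables contribute one indicator per code under
every feature class.

Per-feature penalties are λ_j = rm · β(type, m) · s_j / √m where s_j is
the feature's standard deviation over the presences (floored at 0.01 so
no feature is ever unpenalised) and β interpolates the anchor table
(m, β) = (10, 1.0), (30, 0.2), (100, 0.05) for linear/quadratic
features, clamped outside; hinge features use β = 0.5 and indicators
β = 0.25. These constants mirror widely used Maxent defaults and are
all exposed in the run configuration.

## Validation machinery

**Spatial blocks.** Presences are split at their median x coordinate,
then each half at its own median y, giving four contiguous quadrant
blocks with presence counts balanced to within one (for distinct
coordinates); the background inherits the same split lines. The split
lines are stored so the assignment is recomputable. Only k = 4 is
supported.

**Cross-validation.** Each fold's model is trained on the other three
folds' presences and background (feature scaling from the training
background). Test AUC compares held-out presences with the *full*
background — this stabilises evaluation when a quadrant holds few
background cells; a fold-restricted background would be the natural
alternative and the choice is deliberate. Omission uses the minimum
training-presence score as threshold (``mtp``; a 10th-percentile rule
``p10`` is available since the field's "predicted range" threshold is
convention-dependent).

**Model selection.** The grid is rm ∈ {1,…,5} × {L, LQ, H, LQH}
(20 candidates, all sharing one fold assignment). Selection is
lexicographic: minimum mean omission, then maximum mean test AUC. The
further tie-breaks — fewest active features, then largest rm — are
package conventions chosen to prefer the simplest, most-regularised
model; a full selection trace is retained so the choice is auditable.

**AUC bands.** ≤ 0.5 random; (0.5, 0.7) poor to moderate; [0.7, 0.9)
moderate to high; ≥ 0.9 excellent. The interval ends are half-open by
convention here; published usage leaves the exact boundary values
ambiguous.

**Null models.** 100 replicates each draw m cells uniformly without
replacement from the background support, fit a model with the selected
settings, and record its training AUC against the full background. The
observed model's training AUC is significant when it exceeds the 95th
percentile (linear interpolation between order statistics) of the null
distribution; the empirical p-value is (1 + #{null ≥ obs}) / (n_null+1).
Training AUC is used on both sides for a like-for-like comparison.
Under a randomly drawn "observed" species this construction is
exchangeable, so the rejection rate should sit near 5 %; the acceptance
suite measures it over 200 replicates.

**Boyce index.** 101 overlapping windows of width range/10 are placed
over the background score range; per window the ratio of the presence
fraction to the background fraction is computed (windows with no
background mass are skipped) and the index is the Spearman correlation
between that ratio and the window midpoint. Fewer than three usable
windows yields NaN with a warning. The background sample is the
reference distribution; using all map cells instead is a configuration
away but changes little on these landscapes.

**Variable selection.** Permutation importance replaces Maxent's
path-dependent "percent contribution": each source variable's values
are permuted jointly across the pooled presence + background rows
(n_permutations seeded draws), the drop in training AUC is averaged,
negative drops are floored at zero, and drops are normalised to sum to
100 %. This is a deliberate divergence — path contributions depend on a
specific training trajectory and are not reproducible across
optimisers, while permutation importance is defined by the fitted model
alone. Selection keeps the top variables to a cumulative 80 %
contribution, then repeatedly removes the lower-contribution member of
the retained pair with the largest |Pearson r| while that exceeds 0.7
(ties broken by variable name). Correlations are computed over the
background sample — the model's actual data support — not the full
raster. Categorical variables have no Pearson r and are never removed
by the correlation step.

## Pipeline

Per species: occurrences are filtered, pooled across life stages and
deduplicated to unique raster cells (species with fewer than four
unique cells are skipped); the background is sampled uniformly without
replacement (default 10,000 cells) from the "well-surveyed area" —
valid cells within a 250 m radius of cells where at least
``min_species`` (default 2) distinct species were recorded; initial
tuning runs on *all* variables with no correlation pre-screen; the
initial optimum is null-model tested (a non-significant result is
annotated, not fatal) and supplies the permutation contributions;
variable selection reduces the set; a second full tuning grid on the
reduced set yields the final model, which is exported as a cloglog map
with contribution, evaluation and response-curve tables plus metadata.
One seed in the configuration drives background sampling, permutations
and null draws (stage offsets are fixed), so identical runs are
byte-identical.

The ambiguous "two or three species" background rule is the config
integer ``min_species`` = 2 — the looser reading, retaining more
support. The 250 m radius realises "well-sampled areas" because the
spatial unit of an "area" is otherwise undefined on a 10 m grid;
radius 0 degenerates to the exact qualifying cells. The cumulative-80 %
rule serves both as the variable-selection cut and the reporting cut of
the contribution table, sharing one config key.

## Synthetic data

`generate_landscape` builds an island: elevation is a smoothed seeded
Gaussian field on a radial taper (cells outside the taper are nodata
"open sea"); land use follows elevation bands — water lowest, a
mangrove/salt-plain belt split by a second noise field, forest on the
highest ground, scrub elsewhere — with urban as 1–3 compact patches and
temporary waterbodies as low-elevation patches carved from scrub.
Category fractions hit their targets to within a few percentage points
on a 200×200 grid. The stack carries a protected-area mask and a
Euclidean distance-to layer for every category, mirroring the layer
families a vector-survey GIS would provide.

`generate_virtual_species` defines truth as
logistic(intercept + Σ c·t(u)) on min–max scaled layers with fixed
transform shapes (linear u; negative exponential e^{−5u}; Gaussian
around 0.5 with width 0.15) and draws occurrence cells without
replacement with probability proportional to truth. The four presets —
urban, mangrove, forest and ephemeral-water dwellers — each respond to
a single distance-to layer (coefficient +6, intercept −3.5), giving a
strong but spatially localised signal: suitability ≈ 0.92 in the
habitat, ≈ 0.03 far from it.

`generate_survey` allocates sites to land-use strata proportional to
area (≥ 1 site per non-empty stratum), draws them around seeded cluster
centres, and always visits every species' occurrence cells. A species
is recorded at a site when the site is one of its occurrence cells, or
otherwise detected with probability detection_rate × truth — an
imperfect-detection model. The detection component is what makes
multi-species cells (the pipeline's "well-surveyed" support) exist by
construction; with only exact occurrence-cell records, two species
would essentially never share a 10 m cell and the background rule could
not be exercised.

What the generator does *not* emulate: real spatial autocorrelation in
detection effort beyond simple clustering, observation error in
coordinates, correlated covariate suites (soil/geology proxies),
seasonal turnover, or true absence data. Passing the recovery tests
therefore shows the pipeline can identify a known single-variable
response under realistic sample sizes and spatially structured effort —
not that it resolves collinear multi-variable ecologies on real data.

## Problem sizes and numerical choices

Validation runs scale the protocol to desk size as the package's own
test design: parameter recovery uses 200×200 landscapes (≈ 30k land
cells at 10 m), 40 presences per species, 2,000 background cells
(rather than the default 10,000), 6 hinge knots per direction, 50 null
replicates inside each pipeline run, and 20 replicates per preset; the
null-calibration experiment uses an 80×80 landscape, 400 background
cells, linear features, m = 20 and 200×100 model fits. The optimiser
stops when the objective stalls below 1e-12 relative (or the projected
gradient falls under `convergence_tol`, default 1e-7) and errors out at
`max_iter`; weights below 1e-12 are snapped to zero, and features
counted "active" above 1e-8. Aggregation to coarser grids requires an
integer cell-size ratio and divisible grid dimensions; categorical
majority ties resolve to the smallest code. Distances are planar
Euclidean between cell centres, computed by an exact Euclidean distance
transform and checked bit-for-bit against an all-pairs oracle; nodata
cells are never distance targets but do not block straight-line
distance. Degenerate cases are defined, not left to chance: constant
feature expansions fit as the uniform model, zero-variance layers
correlate as r = 0 with a warning, all-tied contribution tables report
zeros, and folds without test presences are skipped with a warning.

## Known limitations

Only 4-quadrant spatial blocks are supported; geodesic distances,
reprojection and polygon GIS are out of scope (synthetic landscapes use
a projected Cartesian frame); no product/threshold features, clamping
diagnostics or MESS maps; abundance is ignored by design (presence
only). Table-level results from field studies that depend on
unpublished occurrence records cannot be reproduced here — validation
is property- and simulation-based instead.
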