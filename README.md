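# vector-enm

Presence-background ecological niche modelling (ENM) for mapping
disease-vector habitat suitability at high spatial resolution, in the
style used for island-scale mosquito surveys: an L1-regularised
maximum-entropy (Maxent-type) model with tuned feature classes, spatial-
block cross-validation, null-model significance testing,
contribution-driven variable selection with a Pearson-correlation
filter, and continuous-Boyce-index validation. Because real survey
records are rarely shareable, the package ships a first-class synthetic
data module: island-like raster landscapes, virtual species with known
habitat responses, and clustered multi-species survey effort, so the
whole pipeline can be exercised and validated end to end.

Intended users: quantitative ecologists and medical-entomology teams who
want a reproducible, scriptable version of the standard
"ENMeval-style" Maxent workflow — and a test bed that checks the
workflow actually recovers known species–environment relationships.

## The model

Given presence cells and a background sample characterising the
available environment, covariates are expanded into features
f_j(x) ∈ [0, 1] (linear, quadratic, and hinge transforms of min–max
scaled continuous variables; indicators for categorical ones). The model
is the Gibbs density over the background,

    raw(x) = exp(η(x) − log Z),   η(x) = Σ_j w_j f_j(x),

with weights minimising the convex penalised objective

    L(w) = −(1/m) Σ_presence η(x_i) + log Σ_background e^{η(x_b)} − log n + Σ_j λ_j |w_j|,

where λ_j = rm · β(type, m) · s_j / √m are per-feature L1 penalties and
rm is the regularization multiplier. Suitability maps use the bounded
cloglog transform 1 − exp(−e^H · raw), with H the entropy of the fitted
density. Models are tuned over the 20-cell grid rm ∈ {1..5} ×
feature classes {L, LQ, H, LQH} by spatial-block cross-validation
(lowest mean omission, then highest mean test AUC), validated against
100 Raes–ter-Steege null models, reduced to the variables carrying a
cumulative 80 % permutation contribution (dropping the weaker member of
any pair with |Pearson r| > 0.7), re-tuned, and exported.

## Worked example

Simulate an island with four virtual species and run the full pipeline
for the mangrove dweller:

```sh
vector-enm simulate --preset mangrove_dweller --size 200 --seed 3 --out sim/
vector-enm pipeline --occurrences sim/survey.csv --stack sim/stack \
    --species mangrove_dweller --out report/ --seed 5 --background-n 2000
```

The pipeline prints a one-line summary (output from the run above):

```
mangrove_dweller: AUC=0.732 (moderate to high), omission=0.010, Boyce=0.960, null p=0.010
```

meaning the selected model's spatially cross-validated test AUC is 0.732
(a random presence outscores a random background cell 73 % of the time,
"moderate to high" performance), 1 % of held-out presences fall below
the minimum training-presence threshold, the continuous Boyce index of
0.96 says the presence-to-background ratio rises almost monotonically
with predicted suitability, and the model beats all 100 null models
(empirical p = 1/101 ≈ 0.01). `report/` then contains five artefacts:
the cloglog suitability raster (`*_suitability.asc`), the permutation
contribution table cut at 80 % cumulative contribution
(`*_contribution.csv` — here `dist_to__mangrove` at 100 %), per-fold
evaluation metrics (`*_evaluation.csv`), response curves
(`*_response_curves.csv`) and a metadata JSON with every seed, setting
and selection trace.

As a library:

```python
from vector_enm import RunConfig, run_species_pipeline
from vector_enm.io import read_occurrences, read_stack

records = read_occurrences("sim/survey.csv")
stack = read_stack("sim/stack")
report = run_species_pipeline(records, "mangrove_dweller", stack,
                              RunConfig(seed=5, background_n=2000))
print(report.contribution_full.head())
```

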