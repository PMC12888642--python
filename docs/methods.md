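# Methods

## Model and procedure

`fedforest` studies horizontal federated learning for binary clinical
risk prediction: K sites share one feature space but hold disjoint
patients. Each site fits a random forest (CART trees, Gini impurity,
bootstrap resampling, no depth limit — the classical R-stack defaults);
the forest's probability for a sample is the arithmetic mean over trees
of the positive-class relative frequency in the terminal node the sample
reaches. Federated prediction is a convex combination of the per-site
probabilities, P = Σ wᵢxᵢ, with weights normalized site values under one
of five schemes (unweighted, samples, positives, minority, mpd). The
mpd value is Shannon evenness times site size, vᵢ = (Hᵢ/ln 2)·nᵢ for two
classes, with the 0·ln 0 := 0 convention so single-class sites get
vᵢ = 0. A site with no minority samples therefore receives weight 0 under
the minority and mpd schemes but still contributes under samples and
unweighted — the formulas are applied literally.

Two aggregation identities are implemented and verified rather than
assumed: unweighted averaging equals predicting with the union of all
trees when each tree of site i carries weight 1/(K·mᵢ) (exact, tested to
1e-12), and federated probabilities always lie inside the envelope of the
per-site probabilities.

## Benchmark protocol

Every site is partitioned into k=5 stratified outer folds; the pooled
"general model" (GM) reuses the same per-site folds, so its fold-i test
set is the union of the sites' fold-i slices. Per outer fold the harness
trains one forest per site plus the GM on training partitions, computes
scheme weights **from training-partition class counts only** (the
published whole-cohort weight table is reproduced separately by the
`weights` CLI), and evaluates all models on the combined test union and
on each site's own test slice. AUROC is rank-based with midrank ties
(equivalent to the Mann–Whitney statistic); fold-wise AUROCs are
summarized as mean ± 1.96·SD/√k, clipped to [0,1] — a normal
approximation chosen because the reported intervals are symmetric around
the mean; a pooled-prediction alternative was considered out of scope.
Operating points maximize Youden's J = sensitivity + specificity − 1 over
the unique observed scores (positive iff score ≥ threshold); ties in J
break toward the lowest qualifying threshold, with ties within 1e-9
treated as exact to absorb float accumulation noise in the ROC cumsums.
Combined-test AUROC is computed per fold and then averaged across folds
(fold-averaged, not pooled over all predictions).

Hyper-parameters (ntree, mtry) are tuned by exhaustive grid search under
repeated stratified inner CV confined to the training partition, scoring
accuracy at the 0.5 probability cutoff (the cutoff is a package choice;
majority vote would be equivalent). Ties break toward the earliest grid
cell. The reference grid ntree ∈ {100,…,1000} × mtry ∈ 1..30 is available
(`HyperParameterGrid.full`), but the default desk grid is
ntree {100,300,500} × mtry ⌊√d⌋±2: the reference grid multiplied by 50
inner fits, 12 models and 5 outer folds is cluster-scale. The benchmark
suite runs with fixed ntree=100, mtry=6 (≈√40) for all models; the tuning
operation itself is validated against a brute-force re-evaluation of the
grid.

## Synthetic cohort generator

The generator emulates an eleven-hospital network: per-site sample counts
552–6,624 (29,479 total) and incidences 0.114–0.634, configurable through
`SiteSpec`s and proportionally shrinkable via `scale`. Features are 30
Bernoulli columns (base rates drawn once per schema from U(0.05, 0.5))
plus 10 unit-variance normal columns — a desk-scale stand-in for the
hundreds of coded-diagnosis/lab features of real EMR cohorts. Labels
follow a logistic latent model: P(y=1|x) = σ(β·x + b_site + shift + ε),
ε ~ N(0, 0.5), with a fixed shared coefficient vector (ten binary
coefficients ±0.9, five continuous 0.5, the rest zero). The per-site
intercept is found by bisection against the site's realized design so the
expected incidence matches the spec; over repeated draws at n = 5000 the
mean empirical incidence lands within ±0.01 of target. All randomness
derives from one master seed through per-site `SeedSequence` substreams,
so identical configs give bit-identical cohorts.

Sites additionally differ in **case mix**: each site perturbs the binary
base rates on the logit scale and offsets the continuous means, both by
N(0, 1) draws (`site_feature_shift_sd`). This mirrors the between-hospital
differences in demographics and diagnosis prevalence that real networks
show, and it is load-bearing for the benchmark's qualitative ordering:
with identical covariate distributions an average of K forests is purely a
variance-reduced ensemble and beats a single pooled forest of any tree
budget, whereas under case-mix shift each site model is biased outside its
own distribution — bias that averaging cannot remove but pooled training
can. Only with this heterogeneity does the synthetic network reproduce the
regime observed in practice: the general model leads, size/imbalance-aware
weighting beats the plain average, small sites produce the weakest models,
and per-site AUROCs spread widely (≈0.56–0.71 at the reduced scale, GM
≈0.79).

What the generator does **not** model: department/case-mix sampling
structure within hospitals, missing data, feature correlation beyond what
the logistic link induces, temporal drift, and label noise from imperfect
chart review. Passing benchmarks therefore demonstrate protocol
correctness and the qualitative aggregation behavior, not real-data
performance; published real-data AUROC values are not reproducible
without the confidential records and are not targeted.

## Numerical choices and degenerate inputs

- Weights are carried at full precision and only rounded (3 dp) in
  printed outputs.
- `normalize_weights` raises when every site value is zero rather than
  emitting NaNs.
- Degenerate sites (incidence exactly 0 or 1) are generated with constant
  labels and a warning; single-class training sets train warn-and-proceed
  forests that predict a constant probability.
- Sites too small to stratify (fewer than k minority samples) fall back
  to plain shuffled folds with a warning.
- mtry larger than the feature count is clipped with a warning.
- Missing cells are rejected on read by default; `impute="mode"/"mean"`
  enables simple per-column imputation.

## Problem sizes in the shipped suites

The test suite runs the full protocol at reduced scale as the package's
own desk-scale configuration: the benchmark-ordering check uses the
eleven-site profile shrunk to ~6,000 rows, 40 features, fixed ntree=100 /
mtry=6, five outer folds and five seeds; generator calibration uses 20
seeds at n=5,000; the pooling equivalence uses 20 randomized small
ensembles; metric oracles use 100 random toy score sets with heavy ties.

## Known limitations

- The federation is simulated in-process; there is no network transport,
  encryption or differential privacy.
- Multi-class problems are supported by the diversity/evenness formulas
  but no multi-class pipeline is built.
- No probability recalibration (Platt/isotonic) and no significance
  testing between models.
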