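# fedforest

Federated ensemble learning for random forests on horizontally partitioned
tabular clinical data — each hospital keeps its patients, trains a forest
locally, and only the trained models travel. `fedforest` implements the
prediction-aggregation approach, the weighting schemes that make it robust
to unequal site sizes and class imbalance, and the multi-site benchmark
protocol used to compare federated models against per-site models and a
pooled "general model". It ships with a seeded synthetic cohort generator
that emulates an eleven-hospital delirium-prediction network (29,479
patients, per-site incidence 11.4%–63.4%), so the whole pipeline runs
end-to-end without any confidential data.

It is aimed at biostatisticians and ML researchers studying multi-site
clinical risk prediction when raw-data pooling is not an option.

## The method

Each site *i* trains a random forest of *mᵢ* trees. A forest's
positive-class probability for a patient is the mean of per-tree
terminal-node relative frequencies,

    xᵢ = (1/mᵢ) Σⱼ pᵢⱼ ,

and the federated prediction is the weighted average over the N sites,

    P = Σᵢ wᵢ · xᵢ ,   wᵢ = vᵢ / Σᵢ vᵢ ,

where the site value vᵢ defines the scheme:

| scheme       | vᵢ                                   |
|--------------|--------------------------------------|
| `unweighted` | 1                                    |
| `samples`    | nᵢ (site sample count)               |
| `positives`  | number of positive cases             |
| `minority`   | size of the smaller class            |
| `mpd`        | Eᵢ · nᵢ (maximum possible diversity) |

`mpd` discounts a site by its class imbalance through the Shannon evenness
Eᵢ = Hᵢ / ln N_classes with Hᵢ = −Σⱼ pⱼ ln pⱼ: a perfectly balanced site
contributes its full sample count, a single-class site contributes
nothing. Unlike positives/minority weighting it generalizes to more than
two classes.

Because each xᵢ is itself a mean over trees, unweighted averaging over
sites is algebraically identical to pooling every tree into one forest in
which each tree of site *i* carries weight 1/(N·mᵢ) —
`pooled_forest_predict` verifies this equivalence to 1e-12.

The benchmark protocol splits every site into five stratified outer folds
(shared with the general model), tunes forests by grid search over ntree
and mtry under repeated stratified inner CV (accuracy criterion), and
reports fold-wise AUROC with normal-approximation 95% CIs plus
sensitivity/specificity at the maximum-Youden-index threshold. Scheme
weights are recomputed per outer fold from training-partition class counts
only, so no test information leaks into the weights.

## Worked example

Recompute the per-site values and weights of the eleven-hospital profile:

```python
import fedforest as ff

counts = [ff.SiteClassCounts(s, n, p) for s, n, p in ff.ELEVEN_SITE_PROFILE]
print(ff.weight_table(counts).round(3).to_string())
```

```
         samples_v  samples_w  positives_v  positives_w  minority_v  minority_w     mpd_v  mpd_w
site_id
H01         5033.0      0.171        953.0        0.107       953.0       0.134  3523.655  0.155
H02         4368.0      0.148       1000.0        0.112      1000.0       0.140  3390.245  0.149
H03         1918.0      0.065        390.0        0.044       390.0       0.055  1397.362  0.061
H04         2904.0      0.099        408.0        0.046       408.0       0.057  1700.396  0.075
H05         2160.0      0.073        385.0        0.043       385.0       0.054  1460.621  0.064
H06         1271.0      0.043        287.0        0.032       287.0       0.040   979.470  0.043
H07          552.0      0.019        160.0        0.018       160.0       0.022   479.431  0.021
H08         1873.0      0.064        628.0        0.071       628.0       0.088  1723.611  0.076
H09         2036.0      0.069        408.0        0.046       408.0       0.057  1471.444  0.065
H10         6624.0      0.225       4197.0        0.472      2427.0       0.340  6278.649  0.276
H11          740.0      0.025         84.0        0.009        84.0       0.012   377.714  0.017
```

Reading the table: under `samples` weighting the largest hospital (H10,
6,624 patients) carries weight 0.225; under `positives` its weight rises
to 0.472 because it holds nearly half of all positive cases; `mpd`
tempers that to 0.276 by crediting H10 for being relatively balanced
(63.4% positives) while cutting the heavily imbalanced H11 (11.4%
positives) to 0.017. The mpd values total 22,782.6 out of 29,479 samples.

Run the scaled-down synthetic benchmark from the shell (writes the report
CSVs to `bench/`):

```
fedforest benchmark --seed 0 --scale 0.2 --ntree 100 --mtry 6 --out-dir bench
```

On this synthetic network the general model leads, the weighted federated
schemes follow, the plain unweighted average trails them, and every
federated model beats every single-site model — the qualitative pattern
expected when site sizes and case mix vary.

Other subcommands: `generate` (write a synthetic cohort as per-site CSVs),
`weights`, `train`, `federate`, `predict` — see `fedforest --help`.

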