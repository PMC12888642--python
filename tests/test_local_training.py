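import numpy as np
import pandas as pd
import pytest
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from fedforest.cohort import GeneratorConfig, SiteCohort, SiteSpec, generate_federated_cohort
from fedforest.local_training import (
    HyperParameterGrid,
    InnerCVSpec,
    train_local_forest,
    tune_hyperparameters,
)


def _leaf_frequency_oracle(model, X):
    """Terminal-node positive frequencies read straight off each tree's
    node-value arrays — independent of the forest's own averaging."""
    X = np.asarray(X, dtype=float)
    pos = np.flatnonzero(model.estimator.classes_ == 1)
    per_tree = []
    for tree in model.trees:
        leaves = tree.apply(X)
        values = tree.tree_.value[leaves, 0, :]  # per-leaf class distribution
        norm = values.sum(axis=1)
        per_tree.append(values[:, pos[0]] / norm if pos.size else np.zeros(len(X)))
    return np.mean(per_tree, axis=0)


def test_probability_is_mean_of_terminal_node_frequencies(small_federated):
    site = small_federated.sites[0]
    model = train_local_forest(site, ntree=5, mtry=3, seed=2)
    X = small_federated.sites[1].features
    np.testing.assert_allclose(
        model.predict_probability(X), _leaf_frequency_oracle(model, X), atol=1e-12
    )


def test_training_is_deterministic(small_federated):
    site = small_federated.sites[1]
    probe = small_federated.sites[0].features.iloc[:20]
    p1 = train_local_forest(site, 10, 3, seed=5).predict_probability(probe)
    p2 = train_local_forest(site, 10, 3, seed=5).predict_probability(probe)
    np.testing.assert_array_equal(p1, p2)


def test_single_class_forest_predicts_constant():
    df = pd.DataFrame({"x": np.linspace(0, 1, 30)})
    cohort = SiteCohort("s", df, np.ones(30, dtype=int))
    with pytest.warns(UserWarning, match="single-class"):
        model = train_local_forest(cohort, 5, 1, seed=0)
    assert model.predict_probability(df) == pytest.approx(np.ones(30))


def test_mtry_clipped_with_warning(small_federated):
    site = small_federated.sites[0]
    with pytest.warns(UserWarning, match="clipping"):
        model = train_local_forest(site, 5, 99, seed=0)
    assert model.mtry == site.features.shape[1]


def test_schema_mismatch_rejected(small_federated):
    model = train_local_forest(small_federated.sites[0], 5, 3, seed=0)
    with pytest.raises(ValueError):
        model.predict_probability(np.zeros((4, 3)))


def test_one_cell_grid_short_circuits(small_federated):
    grid = HyperParameterGrid((50,), (3,))
    assert tune_hyperparameters(small_federated.sites[0], grid, InnerCVSpec()) == (50, 3)


def test_tuning_matches_bruteforce_grid_oracle():
    cfg = GeneratorConfig(
        specs=(SiteSpec("T", 150, 0.4),), d_binary=6, d_continuous=4, seed=21
    )
    site = generate_federated_cohort(cfg).sites[0]
    grid = HyperParameterGrid((10, 40), (2, 5))
    spec = InnerCVSpec(repeats=2, folds=3, seed=9)

    chosen = tune_hyperparameters(site, grid, spec)
    assert tune_hyperparameters(site, grid, spec) == chosen  # deterministic

    # independent exhaustive re-evaluation of all four cells
    X = site.features.to_numpy(float)
    y = site.labels
    splits = list(
        RepeatedStratifiedKFold(n_splits=3, n_repeats=2, random_state=9).split(X, y)
    )
    scores = {}
    for nt in grid.ntree_values:
        for m in grid.mtry_values:
            accs = []
            for tr, va in splits:
                est = RandomForestClassifier(
                    n_estimators=nt, max_features=m, random_state=9, n_jobs=1
                ).fit(X[tr], y[tr])
                p = est.predict_proba(X[va])[:, list(est.classes_).index(1)]
                accs.append(np.mean((p >= 0.5) == y[va]))
            scores[(nt, m)] = np.mean(accs)
    best = max(scores, key=lambda c: (scores[c], -c[0], -c[1]))
    assert scores[chosen] == pytest.approx(scores[best], abs=1e-12)


def test_tuning_rejects_single_class():
    df = pd.DataFrame({"x": np.arange(30.0)})
    cohort = SiteCohort("s", df, np.zeros(30, dtype=int))
    with pytest.raises(ValueError, match="single-class"):
        tune_hyperparameters(cohort, HyperParameterGrid((5, 10), (1,)), InnerCVSpec(2, 3, 0))


def test_more_training_data_does_not_hurt():
    """Mean held-out AUROC is non-decreasing in training size — larger
    sites build better models."""
    from fedforest.evaluation import auroc

    sizes = (100, 500, 2000)
    means = {n: [] for n in sizes}
    for seed in range(5):
        cfg = GeneratorConfig(specs=(SiteSpec("S", 3000, 0.25),), seed=100 + seed)
        site = generate_federated_cohort(cfg).sites[0]
        test_X, test_y = site.features.iloc[:1000], site.labels[:1000]
        for n in sizes:
            tr = SiteCohort("S", site.features.iloc[1000 : 1000 + n], site.labels[1000 : 1000 + n])
            model = train_local_forest(tr, 100, 6, seed)
            means[n].append(auroc(model.predict_probability(test_X), test_y))
    avg = {n: np.mean(v) for n, v in means.items()}
    assert avg[500] >= avg[100] - 0.02
    assert avg[2000] >= avg[500] - 0.02
    assert avg[2000] > 0.5
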