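import numpy as np
import pandas as pd
import pytest

from fedforest.cohort import GeneratorConfig, SiteCohort, SiteSpec, FederatedCohort, FeatureSchema, generate_federated_cohort
from fedforest.evaluation import (
    BenchmarkConfig,
    auroc,
    build_fold_plan,
    run_benchmark,
    summarize_folds,
    youden_operating_point,
)


def _toy_cohort():
    return generate_federated_cohort(
        GeneratorConfig(
            specs=(
                SiteSpec("A", 120, 0.3),
                SiteSpec("B", 120, 0.5),
                SiteSpec("C", 120, 0.2),
            ),
            d_binary=6,
            d_continuous=4,
            seed=13,
        )
    )


def test_fold_plan_exact_stratification():
    df = pd.DataFrame({"x": np.arange(10.0)})
    site = SiteCohort("S", df, np.array([1, 0] * 5))
    fed = FederatedCohort(FeatureSchema(("x",), ("continuous",)), (site,))
    plan = build_fold_plan(fed, k=5, seed=3)
    a = plan.assignments["S"]
    for fold in range(5):
        idx = np.flatnonzero(a == fold)
        assert len(idx) == 2
        assert site.labels[idx].sum() == 1


def test_fold_plan_partition_and_determinism():
    fed = _toy_cohort()
    p1 = build_fold_plan(fed, 5, seed=8)
    p2 = build_fold_plan(fed, 5, seed=8)
    for sid in fed.site_ids:
        np.testing.assert_array_equal(p1.assignments[sid], p2.assignments[sid])
        # union of fold test sets recovers each row exactly once
        covered = np.concatenate(
            [p1.site_fold_indices(sid, f)[1] for f in range(5)]
        )
        assert sorted(covered) == list(range(len(p1.assignments[sid])))


def test_fold_plan_falls_back_for_tiny_class():
    df = pd.DataFrame({"x": np.arange(12.0)})
    site = SiteCohort("tiny", df, np.array([1] * 2 + [0] * 10))
    fed = FederatedCohort(FeatureSchema(("x",), ("continuous",)), (site,))
    with pytest.warns(UserWarning, match="non-stratified"):
        plan = build_fold_plan(fed, 5, seed=0)
    assert len(plan.assignments["tiny"]) == 12


def test_auroc_extremes_and_null():
    assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0
    rng = np.random.default_rng(0)
    scores = rng.random(4000)
    labels = rng.integers(0, 2, 4000)
    assert auroc(scores, labels) == pytest.approx(0.5, abs=0.03)
    with pytest.raises(ValueError):
        auroc([0.1, 0.2], [1, 1])


def test_auroc_invariant_under_monotone_transforms():
    rng = np.random.default_rng(4)
    scores = rng.random(300)
    labels = rng.integers(0, 2, 300)
    base = auroc(scores, labels)
    for f in (np.exp, lambda s: 3 * s - 7, lambda s: s**3 + s):
        assert auroc(f(scores), labels) == pytest.approx(base, abs=1e-12)


def test_youden_perfect_separation():
    op = youden_operating_point([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1])
    assert op.sensitivity == 1.0 and op.specificity == 1.0


def test_youden_tie_breaks_to_lowest_threshold():
    # J = 0.5 at thresholds 0.9 and 0.2; the lower one must win
    op = youden_operating_point([0.1, 0.2, 0.8, 0.9], [0, 1, 0, 1])
    assert op.threshold == pytest.approx(0.2)
    assert op.sensitivity == 1.0 and op.specificity == pytest.approx(0.5)


def test_summarize_folds_closed_form():
    mean, lo, hi = summarize_folds([0.7, 0.8, 0.9])
    half = 1.96 * np.std([0.7, 0.8, 0.9], ddof=1) / np.sqrt(3)
    assert (mean, lo, hi) == pytest.approx((0.8, 0.8 - half, 0.8 + half))
    same = summarize_folds([0.75, 0.75, 0.75, 0.75])
    assert same == pytest.approx((0.75, 0.75, 0.75))
    _, _, hi = summarize_folds([0.99, 1.0, 1.0, 0.98, 1.0])
    assert hi <= 1.0
    with pytest.raises(ValueError):
        summarize_folds([0.8])


def test_benchmark_report_structure_and_leak_free_weights():
    fed = _toy_cohort()
    config = BenchmarkConfig(k_outer=5, ntree=10, mtry=3, seed=2)
    report = run_benchmark(fed, config)

    labels = list(report.combined_table["model"])
    assert labels == ["A", "B", "C", "GM"] + list(config.schemes)
    assert report.cross_table.shape == (3, 9)
    assert set(report.per_fold["fold"]) == set(range(5))
    assert ((report.combined_table["ci_lo"] <= report.combined_table["mean_auroc"])
            & (report.combined_table["mean_auroc"] <= report.combined_table["ci_hi"])).all()

    # scheme weights must derive from training-partition counts only
    plan = build_fold_plan(fed, 5, seed=2)
    w = report.weights_used
    for fold in range(5):
        train_n = {
            s.site_id: len(plan.site_fold_indices(s.site_id, fold)[0])
            for s in fed.sites
        }
        total = sum(train_n.values())
        sel = w[(w.fold == fold) & (w.scheme == "samples")]
        for _, row in sel.iterrows():
            assert row.weight == pytest.approx(train_n[row.site_id] / total)
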