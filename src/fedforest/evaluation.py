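"""Benchmark protocol: shared stratified outer folds, AUROC with fold-wise
confidence intervals, Youden-index operating points, and the full
multi-model report.

Every site is split into five stratified outer folds; the general model
(GM, trained on all sites' pooled data) reuses the same per-site folds, so
its fold-i test set is the union over sites of each site's fold i.  For
each outer fold the protocol trains one forest per site plus the GM on the
training partitions, derives the scheme weights from *training-partition*
class counts only (no test-fold leakage), and evaluates every model and
every federated scheme on the combined test union as well as on each
site's own test slice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import KFold, StratifiedKFold

from .cohort import FederatedCohort, SiteCohort
from .federation import FederatedEnsemble, federated_predict, unweighted_predict
from .local_training import (
    HyperParameterGrid,
    InnerCVSpec,
    LocalForest,
    train_local_forest,
    tune_hyperparameters,
)
from .weighting import SCHEMES, SiteClassCounts, scheme_weights


@dataclass
class FoldPlan:
    """Per-site assignment of every row to exactly one of k folds,
    stratified by label."""

    k: int
    seed: int
    assignments: dict[str, np.ndarray]

    def site_fold_indices(self, site_id: str, fold: int) -> tuple[np.ndarray, np.ndarray]:
        """(train_rows, test_rows) for one site and fold."""
        a = self.assignments[site_id]
        test = np.flatnonzero(a == fold)
        train = np.flatnonzero(a != fold)
        return train, test


def build_fold_plan(cohort: FederatedCohort, k: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified k-fold partition per site, deterministic in ``seed``.

    Sites too small to stratify (fewer than k samples of a class) fall
    back to a plain shuffled split with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    assignments: dict[str, np.ndarray] = {}
    for j, site in enumerate(cohort.sites):
        rs = seed + 1000 * j  # distinct deterministic stream per site
        y = site.labels
        counts = np.bincount(y, minlength=2)
        folds = np.empty(site.n, dtype=int)
        if counts.min() >= k:
            splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
            split_iter = splitter.split(np.zeros(site.n), y)
        else:
            warnings.warn(
                f"site {site.site_id}: class count {counts.min()} < k={k}; "
                "falling back to non-stratified folds",
                stacklevel=2,
            )
            splitter = KFold(n_splits=min(k, site.n), shuffle=True, random_state=rs)
            split_iter = splitter.split(np.zeros(site.n))
        for fold, (_, test_idx) in enumerate(split_iter):
            folds[test_idx] = fold
        assignments[site.site_id] = folds
    return FoldPlan(k=k, seed=seed, assignments=assignments)


def auroc(scores, labels) -> float:
    """Rank-based (Mann-Whitney) AUROC with midrank tie handling."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("AUROC needs both classes")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass(frozen=True)
class OperatingPoint:
    threshold: float
    sensitivity: float
    specificity: float


def youden_operating_point(scores, labels) -> OperatingPoint:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Candidate thresholds are the unique observed scores (a sample is called
    positive when its score >= threshold); ties in J break toward the
    lowest qualifying threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("Youden point needs both classes")
    fpr, tpr, thresholds = roc_curve(labels, scores, drop_intermediate=False)
    # skip roc_curve's synthetic leading threshold (inf); remaining
    # thresholds are the unique scores in decreasing order
    fpr, tpr, thresholds = fpr[1:], tpr[1:], thresholds[1:]
    j = tpr - fpr
    # ties within float accumulation noise count as exact ties
    best = np.flatnonzero(j >= j.max() - 1e-9)[-1]  # last index = lowest threshold
    return OperatingPoint(
        threshold=float(thresholds[best]),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
    )


def summarize_folds(per_fold_aurocs: Sequence[float]) -> tuple[float, float, float]:
    """Mean with a normal-approximation 95% CI over folds, clipped to [0,1]."""
    a = np.asarray(per_fold_aurocs, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 folds")
    mean = float(a.mean())
    half = 1.96 * a.std(ddof=1) / np.sqrt(a.size)
    return mean, max(0.0, mean - half), min(1.0, mean + half)


@dataclass
class ModelEvaluation:
    """One report row: fold-wise AUROCs and Youden operating points."""

    label: str
    fold_aurocs: tuple[float, ...]
    operating_points: tuple[OperatingPoint, ...]

    @property
    def mean_auroc(self) -> float:
        return summarize_folds(self.fold_aurocs)[0]

    @property
    def ci(self) -> tuple[float, float]:
        _, lo, hi = summarize_folds(self.fold_aurocs)
        return lo, hi

    def row(self) -> dict:
        mean, lo, hi = summarize_folds(self.fold_aurocs)
        sens = np.array([p.sensitivity for p in self.operating_points])
        spec = np.array([p.specificity for p in self.operating_points])
        return {
            "model": self.label,
            "mean_auroc": mean,
            "ci_lo": lo,
            "ci_hi": hi,
            "sens_mean": float(sens.mean()),
            "sens_sd": float(sens.std(ddof=1)) if sens.size > 1 else 0.0,
            "spec_mean": float(spec.mean()),
            "spec_sd": float(spec.std(ddof=1)) if spec.size > 1 else 0.0,
        }


@dataclass(frozen=True)
class BenchmarkConfig:
    """Protocol knobs for one benchmark run.

    With ``grid=None`` the forests use the fixed (ntree, mtry) pair; a grid
    plus inner spec enables nested tuning per model and outer fold.
    """

    k_outer: int = 5
    ntree: int = 100
    mtry: int = 6
    grid: HyperParameterGrid | None = None
    inner: InnerCVSpec | None = None
    schemes: tuple[str, ...] = ("unweighted", "samples", "positives", "minority", "mpd")
    seed: int = 0


@dataclass
class BenchmarkReport:
    evaluations: dict[str, ModelEvaluation]
    combined_table: pd.DataFrame      # one row per model: AUROC CI + operating point
    cross_table: pd.DataFrame         # test-site x model mean AUROC matrix
    per_fold: pd.DataFrame            # raw fold-wise AUROCs, long format
    weights_used: pd.DataFrame        # scheme weights per outer fold


def _fit_model(train: SiteCohort, config: BenchmarkConfig, seed: int) -> LocalForest:
    ntree, mtry = config.ntree, config.mtry
    if config.grid is not None:
        inner = config.inner or InnerCVSpec(seed=seed)
        ntree, mtry = tune_hyperparameters(train, config.grid, inner)
    return train_local_forest(train, ntree, mtry, seed)


def run_benchmark(cohort: FederatedCohort, config: BenchmarkConfig) -> BenchmarkReport:
    """Run the full multi-site protocol and assemble the report tables."""
    plan = build_fold_plan(cohort, k=config.k_outer, seed=config.seed)
    model_labels = list(cohort.site_ids) + ["GM"] + list(config.schemes)

    fold_aurocs: dict[str, list[float]] = {m: [] for m in model_labels}
    fold_points: dict[str, list[OperatingPoint]] = {m: [] for m in model_labels}
    cross_rows: list[dict] = []
    weight_rows: list[dict] = []

    for fold in range(config.k_outer):
        site_models: list[LocalForest] = []
        train_counts: list[SiteClassCounts] = []
        test_parts: list[tuple[str, pd.DataFrame, np.ndarray]] = []

        for j, site in enumerate(cohort.sites):
            tr, te = plan.site_fold_indices(site.site_id, fold)
            train = SiteCohort(site.site_id, site.features.iloc[tr], site.labels[tr])
            model_seed = config.seed + 97 * fold + j
            site_models.append(_fit_model(train, config, model_seed))
            train_counts.append(SiteClassCounts.from_labels(site.site_id, train.labels))
            test_parts.append((site.site_id, site.features.iloc[te], site.labels[te]))

        pooled_train = SiteCohort(
            "GM",
            pd.concat([s.features.iloc[plan.site_fold_indices(s.site_id, fold)[0]]
                       for s in cohort.sites], ignore_index=True),
            np.concatenate([s.labels[plan.site_fold_indices(s.site_id, fold)[0]]
                            for s in cohort.sites]),
        )
        gm = _fit_model(pooled_train, config, config.seed + 97 * fold + 71)

        X_test = pd.concat([x for _, x, _ in test_parts], ignore_index=True)
        y_test = np.concatenate([y for _, _, y in test_parts])

        preds: dict[str, np.ndarray] = {}
        for m in site_models:
            preds[m.site_id] = m.predict_probability(X_test)
        preds["GM"] = gm.predict_probability(X_test)
        for scheme in config.schemes:
            wv = scheme_weights(train_counts, scheme)
            ens = FederatedEnsemble(tuple(site_models), wv)
            preds[scheme] = federated_predict(ens, X_test)
            for sid, w in zip(wv.site_ids, wv.weights):
                weight_rows.append(
                    {"fold": fold, "scheme": scheme, "site_id": sid, "weight": w}
                )

        for label, p in preds.items():
            fold_aurocs[label].append(auroc(p, y_test))
            fold_points[label].append(youden_operating_point(p, y_test))

        # per-test-site cross matrix (each model applied to each site's test slice)
        offset = 0
        for sid, x_part, y_part in test_parts:
            sl = slice(offset, offset + len(y_part))
            offset += len(y_part)
            if np.unique(y_part).size < 2:
                continue
            for label, p in preds.items():
                cross_rows.append(
                    {"fold": fold, "test_site": sid, "model": label,
                     "auroc": auroc(p[sl], y_part)}
                )

    evaluations = {
        m: ModelEvaluation(m, tuple(fold_aurocs[m]), tuple(fold_points[m]))
        for m in model_labels
    }
    combined = pd.DataFrame([evaluations[m].row() for m in model_labels])
    per_fold = pd.DataFrame(
        [{"model": m, "fold": f, "auroc": a}
         for m in model_labels for f, a in enumerate(fold_aurocs[m])]
    )
    cross_long = pd.DataFrame(cross_rows)
    cross = (
        cross_long.groupby(["test_site", "model"])["auroc"].mean().unstack()
        .reindex(index=list(cohort.site_ids), columns=model_labels)
        if len(cross_rows)
        else pd.DataFrame()
    )
    return BenchmarkReport(
        evaluations=evaluations,
        combined_table=combined,
        cross_table=cross,
        per_fold=per_fold,
        weights_used=pd.DataFrame(weight_rows),
    )
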