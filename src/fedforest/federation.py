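"""Aggregation of per-site forest predictions into federated probabilities.

The federated probability for a patient is the weighted average of the
per-site forest probabilities, P = sum_i w_i * x_i, with the weight vector
coming from one of the schemes in :mod:`fedforest.weighting`.  Because each
x_i is itself a mean of per-tree terminal-node frequencies, unweighted
averaging over sites is algebraically identical to pooling every tree into
one big forest in which each tree of site i carries weight 1/(N * m_i) —
the prediction-equivalence that makes sharing forests equivalent to
sharing one merged model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .local_training import LocalForest
from .weighting import WeightVector


@dataclass
class FederatedEnsemble:
    """Ordered site forests plus an aligned normalized weight vector."""

    models: tuple[LocalForest, ...]
    weights: WeightVector

    def __post_init__(self) -> None:
        if tuple(m.site_id for m in self.models) != self.weights.site_ids:
            raise ValueError("weight vector is not aligned with the models")
        schemas = {m.feature_names for m in self.models}
        if len(schemas) > 1:
            raise ValueError("models do not share one feature schema")


def federated_predict(ensemble: FederatedEnsemble, features) -> np.ndarray:
    """P = sum_i w_i * x_i per sample; lies in [min_i x_i, max_i x_i]."""
    probs = np.stack([m.predict_probability(features) for m in ensemble.models])
    w = np.asarray(ensemble.weights.weights)
    return w @ probs


def unweighted_predict(models: Sequence[LocalForest], features) -> np.ndarray:
    """Plain mean over the site models' probabilities (w_i = 1/N)."""
    if not models:
        raise ValueError("empty model list")
    probs = np.stack([m.predict_probability(features) for m in models])
    return probs.mean(axis=0)


def pooled_forest_predict(models: Sequence[LocalForest], features) -> np.ndarray:
    """Predict from the union of all trees as one forest.

    Each tree of model i carries weight 1/(N * m_i), so sites with
    different tree counts still contribute equally; with equal m_i this is
    the plain mean over all trees.  Matches unweighted_predict exactly.
    """
    if not models:
        raise ValueError("empty model union")
    N = len(models)
    acc = None
    for m in models:
        per_tree = m.per_tree_probabilities(features)  # (m_i, n)
        contrib = per_tree.sum(axis=0) / (N * m.ntree)
        acc = contrib if acc is None else acc + contrib
    return acc
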