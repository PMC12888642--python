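"""Per-site aggregation weights for federated prediction averaging.

Five schemes turn a site's class counts into a nonnegative value v_i which
is then normalized to a weight w_i = v_i / sum(v):

* ``unweighted`` — v_i = 1 (plain mean over site models),
* ``samples``    — v_i = n_i,
* ``positives``  — v_i = number of positive cases,
* ``minority``   — v_i = size of the smaller class,
* ``mpd``        — maximum possible diversity, v_i = E_i * n_i, where E_i
  is the Shannon evenness of the site's class proportions.  mpd discounts a
  site by how imbalanced it is: a perfectly balanced site contributes its
  full sample count, a single-class site contributes nothing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

SCHEMES: tuple[str, ...] = ("unweighted", "samples", "positives", "minority", "mpd")


@dataclass(frozen=True)
class SiteClassCounts:
    """Per-site totals — the sufficient statistics for every scheme."""

    site_id: str
    n: int
    positives: int

    def __post_init__(self) -> None:
        if self.n < 0 or self.positives < 0 or self.positives > self.n:
            raise ValueError("need 0 <= positives <= n")

    @property
    def negatives(self) -> int:
        return self.n - self.positives

    @classmethod
    def from_labels(cls, site_id: str, labels) -> "SiteClassCounts":
        labels = np.asarray(labels)
        return cls(site_id, int(labels.size), int((labels == 1).sum()))


@dataclass(frozen=True)
class SiteValue:
    site_id: str
    value: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.value) and self.value >= 0):
            raise ValueError("site value must be finite and >= 0")


@dataclass(frozen=True)
class WeightVector:
    """Normalized per-site weights under a named scheme; order preserved."""

    scheme: str
    site_ids: tuple[str, ...]
    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights)
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("weights must sum to 1")

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.site_ids, self.weights))


def shannon_diversity(proportions: Sequence[float]) -> float:
    """Shannon diversity H = -sum p ln p, with the 0 ln 0 := 0 convention.

    ``proportions`` must be nonnegative and sum to 1 (within 1e-9).
    """
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise ValueError("proportions must sum to 1")
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


def shannon_evenness(H: float, n_classes: int) -> float:
    """Evenness E = H / ln(n_classes), in [0, 1]."""
    if n_classes < 2:
        raise ValueError("n_classes must be >= 2")
    if not -1e-9 <= H <= math.log(n_classes) + 1e-9:
        raise ValueError("H outside [0, ln(n_classes)]")
    return float(min(1.0, max(0.0, H / math.log(n_classes))))


def mpd_value(counts: SiteClassCounts) -> SiteValue:
    """Maximum possible diversity v = E * n for the two-class split.

    v ranges from 0 (single-class site) to n (perfect balance).
    """
    if counts.n == 0:
        raise ValueError("empty site")
    props = [counts.positives / counts.n, counts.negatives / counts.n]
    E = shannon_evenness(shannon_diversity(props), 2)
    return SiteValue(counts.site_id, E * counts.n)


def site_value(scheme: str, counts: SiteClassCounts) -> SiteValue:
    if scheme == "unweighted":
        return SiteValue(counts.site_id, 1.0)
    if scheme == "samples":
        return SiteValue(counts.site_id, float(counts.n))
    if scheme == "positives":
        return SiteValue(counts.site_id, float(counts.positives))
    if scheme == "minority":
        return SiteValue(counts.site_id, float(min(counts.positives, counts.negatives)))
    if scheme == "mpd":
        return mpd_value(counts)
    raise ValueError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")


def normalize_weights(values: Sequence[SiteValue], scheme: str) -> WeightVector:
    """w_i = v_i / sum(v), preserving site order.

    Raises if every value is zero — with no usable site the scheme is
    undefined and silently returning NaN would poison downstream averages.
    """
    total = sum(v.value for v in values)
    if total <= 0:
        raise ValueError(f"all site values are zero under scheme {scheme!r}")
    return WeightVector(
        scheme,
        tuple(v.site_id for v in values),
        tuple(v.value / total for v in values),
    )


def scheme_weights(counts: Sequence[SiteClassCounts], scheme: str) -> WeightVector:
    """Values + normalization in one step."""
    return normalize_weights([site_value(scheme, c) for c in counts], scheme)


def weight_table(counts: Sequence[SiteClassCounts]) -> pd.DataFrame:
    """Values and weights for every scheme except unweighted, one row per
    site — the layout of the published weight table."""
    rows = {c.site_id: {} for c in counts}
    for scheme in ("samples", "positives", "minority", "mpd"):
        wv = scheme_weights(counts, scheme)
        for c, w in zip(counts, wv.weights):
            rows[c.site_id][f"{scheme}_v"] = site_value(scheme, c).value
            rows[c.site_id][f"{scheme}_w"] = w
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "site_id"
    return df
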