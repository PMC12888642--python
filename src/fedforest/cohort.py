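"""Multi-site tabular cohorts: domain types, delimited-file I/O and a
seeded synthetic generator.

The synthetic generator emulates a horizontally partitioned clinical
dataset: every site holds its own patients but shares one feature space.
Labels come from a logistic latent model with a shared coefficient vector
(the signal every site can learn) plus a per-site intercept calibrated by
bisection so each site hits its target incidence.  Sites additionally
differ in case mix: each site perturbs the shared binary-feature rates
(on the logit scale) and continuous-feature means, mirroring the
between-hospital differences in demographics and diagnosis prevalence
that multi-hospital cohorts show.  The default eleven-site profile
mirrors a real multi-hospital delirium cohort: sample sizes from 552 to
6,624 (29,479 rows in total) with positive-class incidence ranging from
11.4% to 63.4%.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

FeatureKind = Literal["binary", "continuous"]

#: (site_id, n, positives) for the default eleven-hospital profile.
ELEVEN_SITE_PROFILE: tuple[tuple[str, int, int], ...] = (
    ("H01", 5033, 953),
    ("H02", 4368, 1000),
    ("H03", 1918, 390),
    ("H04", 2904, 408),
    ("H05", 2160, 385),
    ("H06", 1271, 287),
    ("H07", 552, 160),
    ("H08", 1873, 628),
    ("H09", 2036, 408),
    ("H10", 6624, 4197),
    ("H11", 740, 84),
)


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered feature names with a binary/continuous tag per feature.

    All sites of one federated cohort share a single schema (horizontal
    partitioning: same columns, disjoint rows).
    """

    names: tuple[str, ...]
    kinds: tuple[FeatureKind, ...]

    def __post_init__(self) -> None:
        if len(self.names) != len(self.kinds):
            raise ValueError("names and kinds must have equal length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")
        bad = set(self.kinds) - {"binary", "continuous"}
        if bad:
            raise ValueError(f"unknown feature kinds: {sorted(bad)}")

    @property
    def d(self) -> int:
        return len(self.names)

    @classmethod
    def infer(cls, features: pd.DataFrame) -> "FeatureSchema":
        """Infer a schema from a feature table: a column whose values are a
        subset of {0, 1} is binary, anything else continuous."""
        kinds = []
        for col in features.columns:
            vals = pd.unique(features[col].dropna())
            kinds.append("binary" if set(vals) <= {0, 1} else "continuous")
        return cls(tuple(str(c) for c in features.columns), tuple(kinds))

    def validate(self, features: pd.DataFrame) -> None:
        if tuple(str(c) for c in features.columns) != self.names:
            raise ValueError("feature columns do not match schema")


@dataclass
class SiteCohort:
    """One site's feature table plus binary labels (1 = positive)."""

    site_id: str
    features: pd.DataFrame
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.features) != len(self.labels):
            raise ValueError("feature rows and labels differ in length")
        if len(self.labels) < 1:
            raise ValueError("a site cohort needs at least one row")
        if not np.isin(self.labels, (0, 1)).all():
            raise ValueError("labels must be 0 or 1")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def n_positive(self) -> int:
        return int(self.labels.sum())

    @property
    def schema(self) -> FeatureSchema:
        return FeatureSchema.infer(self.features)


@dataclass
class FederatedCohort:
    """An ordered collection of sites sharing one feature schema."""

    schema: FeatureSchema
    sites: tuple[SiteCohort, ...]

    def __post_init__(self) -> None:
        ids = [s.site_id for s in self.sites]
        if len(set(ids)) != len(ids):
            raise ValueError("site_ids must be distinct")
        for s in self.sites:
            self.schema.validate(s.features)

    @property
    def site_ids(self) -> tuple[str, ...]:
        return tuple(s.site_id for s in self.sites)

    @property
    def n_total(self) -> int:
        return sum(s.n for s in self.sites)

    def pooled(self) -> SiteCohort:
        """All rows concatenated — the training set of the general model."""
        X = pd.concat([s.features for s in self.sites], ignore_index=True)
        y = np.concatenate([s.labels for s in self.sites])
        return SiteCohort("pooled", X, y)


@dataclass(frozen=True)
class SiteSpec:
    """Target size, incidence and log-odds shift for one synthetic site."""

    site_id: str
    n: int
    incidence: float
    site_shift: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.incidence <= 1.0:
            raise ValueError("incidence must lie in [0, 1]")
        if not np.isfinite(self.site_shift):
            raise ValueError("site_shift must be finite")


@dataclass(frozen=True)
class GeneratorConfig:
    specs: tuple[SiteSpec, ...]
    d_binary: int = 30
    d_continuous: int = 10
    effect_sizes: tuple[float, ...] | None = None
    noise_sd: float = 0.5
    site_feature_shift_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_binary + self.d_continuous < 1:
            raise ValueError("need at least one feature")
        if not (np.isfinite(self.site_feature_shift_sd) and self.site_feature_shift_sd >= 0):
            raise ValueError("site_feature_shift_sd must be finite and >= 0")
        if self.effect_sizes is not None:
            beta = np.asarray(self.effect_sizes, float)
            if beta.size != self.d_binary + self.d_continuous:
                raise ValueError("effect_sizes length must equal d_binary + d_continuous")
            if not np.isfinite(beta).all():
                raise ValueError("effect_sizes must be finite")
        if not (np.isfinite(self.noise_sd) and self.noise_sd >= 0):
            raise ValueError("noise_sd must be finite and >= 0")


def default_effect_sizes(d_binary: int = 30, d_continuous: int = 10) -> tuple[float, ...]:
    """Fixed shared coefficient vector: ten informative binary features with
    alternating-sign log-odds ratios of 0.9, five informative continuous
    features at 0.5, the rest pure noise."""
    beta = np.zeros(d_binary + d_continuous)
    k_bin = min(10, d_binary)
    beta[:k_bin] = 0.9 * (-1.0) ** np.arange(k_bin)
    k_cont = min(5, d_continuous)
    beta[d_binary : d_binary + k_cont] = 0.5
    return tuple(beta)


def default_generator_config(
    seed: int = 0,
    scale: float = 1.0,
    d_binary: int = 30,
    d_continuous: int = 10,
    min_site_n: int = 40,
) -> GeneratorConfig:
    """The eleven-site profile, optionally scaled down proportionally.

    At ``scale=1`` the sites total 29,479 rows with the real per-site
    incidences; smaller scales keep the size *ratios* and incidences while
    shrinking every site (useful for desk-scale benchmarks).
    """
    specs = tuple(
        SiteSpec(sid, max(min_site_n, round(n * scale)), pos / n)
        for sid, n, pos in ELEVEN_SITE_PROFILE
    )
    return GeneratorConfig(
        specs=specs,
        d_binary=d_binary,
        d_continuous=d_continuous,
        effect_sizes=default_effect_sizes(d_binary, d_continuous),
        noise_sd=0.5,
        seed=seed,
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _calibrate_intercept(eta: np.ndarray, target: float, tol: float = 1e-10) -> float:
    """Bisection on the intercept b so that mean(sigmoid(eta + b)) == target."""
    lo, hi = -40.0, 40.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if _sigmoid(eta + mid).mean() < target:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


def generate_federated_cohort(config: GeneratorConfig) -> FederatedCohort:
    """Draw one SiteCohort per SiteSpec from the logistic latent model.

    Binary features are Bernoulli with per-feature base rates drawn once
    for the schema; continuous features are normal with unit variance.
    Each site perturbs the binary rates on the logit scale and offsets the
    continuous means by N(0, site_feature_shift_sd) draws — the
    between-site case-mix heterogeneity of real hospital networks.  The
    label probability is sigmoid(beta.x + site_shift + b + eps) with the
    intercept b bisected against the site's realized design so the
    expected incidence equals the spec.  Fully deterministic given
    ``config.seed``.
    """
    ss = np.random.SeedSequence(config.seed)
    schema_stream, *site_streams = ss.spawn(1 + len(config.specs))
    schema_rng = np.random.default_rng(schema_stream)

    d = config.d_binary + config.d_continuous
    rates = schema_rng.uniform(0.05, 0.5, size=config.d_binary)
    beta = np.asarray(
        config.effect_sizes
        if config.effect_sizes is not None
        else default_effect_sizes(config.d_binary, config.d_continuous),
        dtype=float,
    )

    names = tuple(f"b{i:02d}" for i in range(config.d_binary)) + tuple(
        f"x{i:02d}" for i in range(config.d_continuous)
    )
    kinds = ("binary",) * config.d_binary + ("continuous",) * config.d_continuous
    schema = FeatureSchema(names, kinds)

    sites = []
    for spec, stream in zip(config.specs, site_streams):
        rng = np.random.default_rng(stream)
        shift = config.site_feature_shift_sd
        rate_logits = np.log(rates / (1.0 - rates)) + rng.normal(
            0.0, shift, size=config.d_binary
        )
        site_rates = 1.0 / (1.0 + np.exp(-rate_logits))
        cont_means = rng.normal(0.0, shift, size=config.d_continuous)
        Xb = (rng.random((spec.n, config.d_binary)) < site_rates).astype(float)
        Xc = rng.standard_normal((spec.n, config.d_continuous)) + cont_means
        X = np.hstack([Xb, Xc]) if d else np.empty((spec.n, 0))
        eps = rng.normal(0.0, config.noise_sd, size=spec.n) if config.noise_sd > 0 else 0.0
        eta = X @ beta + spec.site_shift + eps

        if spec.incidence in (0.0, 1.0):
            warnings.warn(
                f"site {spec.site_id}: degenerate incidence {spec.incidence}",
                stacklevel=2,
            )
            y = np.full(spec.n, int(spec.incidence))
        else:
            b = _calibrate_intercept(eta, spec.incidence)
            y = (rng.random(spec.n) < _sigmoid(eta + b)).astype(int)

        sites.append(
            SiteCohort(spec.site_id, pd.DataFrame(X, columns=list(names)), y)
        )
    return FederatedCohort(schema, tuple(sites))


# ---------------------------------------------------------------------------
# delimited-file I/O

def read_site_table(
    path: str | Path,
    label_column: str = "label",
    site_id: str | None = None,
    impute: Literal["mode", "mean"] | None = None,
) -> SiteCohort:
    """Read one site's cohort from a comma- or tab-separated file.

    Schema is inferred per column (values within {0,1} -> binary).  Missing
    cells are rejected unless ``impute`` selects per-column mode or mean
    imputation.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = pd.read_csv(path, sep=sep)
    if label_column not in df.columns:
        raise ValueError(f"label column {label_column!r} not found in {path}")
    labels = df[label_column]
    if labels.isna().any() or not set(pd.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1 without missing values")
    features = df.drop(columns=[label_column])
    if features.isna().any().any():
        if impute is None:
            raise ValueError(
                f"{path} contains missing cells; pass impute='mode' or 'mean'"
            )
        for col in features.columns:
            if features[col].isna().any():
                fill = (
                    features[col].mode(dropna=True).iloc[0]
                    if impute == "mode"
                    else features[col].mean()
                )
                features[col] = features[col].fillna(fill)
    return SiteCohort(site_id or path.stem, features, labels.to_numpy(dtype=int))


def write_site_table(cohort: SiteCohort, path: str | Path, label_column: str = "label") -> None:
    """Write a cohort as a delimited file re-readable by read_site_table."""
    path = Path(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    df = cohort.features.copy()
    df[label_column] = cohort.labels
    df.to_csv(path, sep=sep, index=False)


def write_manifest(cohort: FederatedCohort, path: str | Path, seed: int | None = None) -> None:
    """JSON manifest with the schema and per-site class counts."""
    payload = {
        "seed": seed,
        "schema": {"names": list(cohort.schema.names), "kinds": list(cohort.schema.kinds)},
        "sites": [
            {"site_id": s.site_id, "n": s.n, "positives": s.n_positive,
             "negatives": s.n - s.n_positive}
            for s in cohort.sites
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))
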