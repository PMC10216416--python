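"""Feature-set assembly and classifier fitting.

Three feature sets are compared:

* ``handcrafted`` — first-order + shape + GLCM texture;
* ``deep``        — pooled frozen-CNN features at depth ``k``;
* ``hybrid``      — first-order + shape + deep (the higher-order hand-crafted
  texture block is deliberately excluded, since the deep features replace it).

Models are an L1+L2-penalized ("elastic") logistic regression and a random
forest, both fitted without class weighting.  Feature standardization and the
optional PCA decorrelation (retaining the smallest component count explaining
the configured variance fraction, default 95%) are always estimated on
training rows only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .errors import (
    AlignmentError,
    ConfigurationError,
    DegenerateInputError,
    DegenerateLabelError,
)

FEATURE_SET_KINDS = ("handcrafted", "deep", "hybrid")


@dataclass(frozen=True)
class FeatureSetSpec:
    """Which feature columns a model sees."""

    kind: str

    def __post_init__(self) -> None:
        if self.kind not in FEATURE_SET_KINDS:
            raise ConfigurationError(f"unknown feature set kind: {self.kind}")

    @property
    def prefixes(self) -> tuple[str, ...]:
        if self.kind == "handcrafted":
            return ("firstorder", "shape", "glcm")
        if self.kind == "deep":
            return ("deep",)
        return ("firstorder", "shape", "deep")  # hybrid: no glcm


def assemble_feature_set(
    handcrafted_table: pd.DataFrame,
    deep_table: pd.DataFrame,
    spec: FeatureSetSpec,
) -> pd.DataFrame:
    """Column-select and concatenate the two tables per the feature-set spec.

    Both tables must be indexed by node_id with identical row order.
    """
    if not handcrafted_table.index.equals(deep_table.index):
        raise AlignmentError("handcrafted and deep tables do not align on node_id")
    merged = pd.concat([handcrafted_table, deep_table], axis=1)
    cols = [c for c in merged.columns if c.split(".")[0] in spec.prefixes]
    out = merged[cols].copy()
    out.attrs["feature_set"] = spec.kind
    return out


@dataclass
class PcaTransform:
    """Train-estimated PCA keeping the smallest L with cum. variance >= threshold."""

    center: np.ndarray
    components: np.ndarray  # (L, n_features), orthonormal rows
    n_components: int
    variance_threshold: float
    explained_variance_ratio: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.center) @ self.components.T


def fit_pca(train_features: np.ndarray, variance_threshold: float = 0.95) -> PcaTransform:
    """Fit PCA on (already standardized) training rows.

    L is the smallest component count whose cumulative explained variance
    reaches ``variance_threshold``; ``variance_threshold=1.0`` keeps every
    component with nonzero variance (the matrix rank).
    """
    X = np.asarray(train_features, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DegenerateInputError("PCA needs at least 2 rows")
    if not 0.0 < variance_threshold <= 1.0:
        raise ConfigurationError("variance_threshold must be in (0, 1]")
    if np.allclose(X.var(axis=0), 0.0):
        raise DegenerateInputError("all features have zero variance")
    pca = PCA(n_components=None, svd_solver="full")
    pca.fit(X)
    ratio = pca.explained_variance_ratio_
    cum = np.cumsum(ratio)
    nonzero = int((pca.explained_variance_ > 1e-12 * pca.explained_variance_[0]).sum())
    hit = np.flatnonzero(cum >= variance_threshold - 1e-12)
    L = int(hit[0]) + 1 if hit.size else nonzero
    L = min(L, nonzero) if variance_threshold >= 1.0 else L
    return PcaTransform(
        center=pca.mean_.copy(),
        components=pca.components_[:L].copy(),
        n_components=L,
        variance_threshold=variance_threshold,
        explained_variance_ratio=ratio[:L].copy(),
    )


@dataclass(frozen=True)
class HyperparameterConfig:
    """One point of the random search space."""

    model: str = "elastic_logit"  # or "random_forest"
    # elastic logit
    penalty_strength: float = 1.0  # overall penalty (sklearn C = 1/strength)
    l1_ratio: float = 0.5
    # random forest
    n_trees: int = 500
    max_depth: int | None = None
    min_leaf: int = 1
    criterion: str = "gini"
    max_features: str | float = "sqrt"
    # shared
    depth_k: int = 3       # CNN stage depth for deep features
    use_pca: bool = True
    variance_threshold: float = 0.95
    config_id: str = "cfg000"

    def __post_init__(self) -> None:
        if self.model not in ("elastic_logit", "random_forest"):
            raise ConfigurationError(f"unknown model: {self.model}")
        if self.penalty_strength < 0:
            raise ConfigurationError("penalty_strength must be >= 0")
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise ConfigurationError("l1_ratio must be in [0, 1]")
        if self.n_trees < 1:
            raise ConfigurationError("n_trees must be >= 1")


#: Default random-search space; brackets the reported optimum
#: (890 trees, min leaf 5, gini, unlimited depth, CNN depth 3).
DEFAULT_SEARCH_SPACE: dict[str, dict] = {
    "elastic_logit": {
        "penalty_strength": ("log-uniform", 1e-2, 1e2),
        "l1_ratio": ("uniform", 0.0, 1.0),
    },
    "random_forest": {
        "n_trees": ("int-uniform", 100, 1000),
        "max_depth": ("choice", (None, 3, 5, 10)),
        "min_leaf": ("choice", (1, 2, 5, 10)),
        "criterion": ("choice", ("gini", "entropy")),
        "max_features": ("choice", ("sqrt", "log2", 0.5)),
    },
    "shared": {
        "depth_k": ("choice", (1, 2, 3, 4)),
        "use_pca": ("choice", (True, False)),
    },
}


def sample_hyperparameters(
    space_spec: Mapping[str, Mapping] | None,
    n_configs: int,
    seed: int,
    models: tuple[str, ...] = ("elastic_logit", "random_forest"),
    depth_k_choices: tuple[int, ...] | None = None,
) -> list[HyperparameterConfig]:
    """Draw i.i.d. configurations from the declared per-field distributions."""
    if n_configs < 1:
        raise ConfigurationError("n_configs must be >= 1")
    if not models:
        raise ConfigurationError("empty model list")
    space = dict(DEFAULT_SEARCH_SPACE if space_spec is None else space_spec)
    rng = np.random.default_rng(seed)

    def draw(dist):
        kind = dist[0]
        if kind == "uniform":
            return float(rng.uniform(dist[1], dist[2]))
        if kind == "log-uniform":
            return float(np.exp(rng.uniform(np.log(dist[1]), np.log(dist[2]))))
        if kind == "int-uniform":
            return int(rng.integers(dist[1], dist[2] + 1))
        if kind == "choice":
            return dist[1][rng.integers(len(dist[1]))]
        raise ConfigurationError(f"unknown distribution kind: {kind}")

    configs = []
    for i in range(n_configs):
        model = models[rng.integers(len(models))]
        fields: dict = {"model": model, "config_id": f"cfg{i:03d}"}
        for name, dist in space.get(model, {}).items():
            fields[name] = draw(dist)
        for name, dist in space.get("shared", {}).items():
            fields[name] = draw(dist)
        if depth_k_choices is not None:
            fields["depth_k"] = depth_k_choices[rng.integers(len(depth_k_choices))]
        configs.append(HyperparameterConfig(**fields))
    return configs


class FittedModel:
    """A fitted classifier exposing calibrated-scale probabilities."""

    def __init__(self, estimator, feature_names: list[str] | None = None):
        self._est = estimator
        self.feature_names = feature_names

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        return self._est.predict_proba(np.asarray(X, dtype=float))[:, 1]


def fit_model(
    X_train: np.ndarray,
    y_train: np.ndarray,
    hp: HyperparameterConfig,
    seed: int = 0,
) -> FittedModel:
    """Fit one classifier on prepared (standardized / decorrelated) features.

    No class weighting is applied, so predicted probabilities retain their
    natural calibration against the training prevalence.
    """
    y = np.asarray(y_train, dtype=int)
    if len(np.unique(y)) < 2:
        raise DegenerateLabelError("training labels contain a single class")
    if hp.model == "elastic_logit":
        strength = max(hp.penalty_strength, 1e-12)
        est = LogisticRegression(
            solver="saga",
            C=1.0 / strength,
            l1_ratio=hp.l1_ratio,
            max_iter=1000,
            tol=1e-5,
            random_state=int(seed) % (2**31),
        )
    else:
        est = RandomForestClassifier(
            n_estimators=hp.n_trees,
            max_depth=hp.max_depth,
            min_samples_leaf=hp.min_leaf,
            criterion=hp.criterion,
            max_features=hp.max_features,
            random_state=int(seed) % (2**31),
            n_jobs=1,
        )
    X = np.asarray(X_train, dtype=float)
    est.fit(X, y)
    if hp.model == "elastic_logit":
        _refine_intercept(est, X, y)
    return FittedModel(est)


def _refine_intercept(est, X: np.ndarray, y: np.ndarray, steps: int = 25) -> None:
    """Newton-polish the (unpenalized) intercept of a fitted logistic model.

    At a fully converged optimum the intercept gradient is zero and this is a
    no-op; under strong penalties saga can stop before the intercept reaches
    the train log-odds, which would leave strongly-shrunk models miscalibrated.
    """
    eta = X @ est.coef_.ravel()
    b = float(est.intercept_[0])
    for _ in range(steps):
        p = 1.0 / (1.0 + np.exp(-(eta + b)))
        grad = float(np.mean(p - y))
        hess = float(np.mean(p * (1.0 - p)))
        if hess < 1e-12 or abs(grad) < 1e-12:
            break
        b -= grad / hess
    est.intercept_[0] = b


@dataclass
class TrainedPipeline:
    """Scaler [+ PCA] + classifier, all statistics estimated on training rows."""

    scaler: StandardScaler
    pca: PcaTransform | None
    model: FittedModel
    hp: HyperparameterConfig

    def predict_probability(self, X: np.ndarray) -> np.ndarray:
        Z = self.scaler.transform(np.asarray(X, dtype=float))
        if self.pca is not None:
            Z = self.pca.transform(Z)
        return self.model.predict_probability(Z)


def fit_pipeline(
    X_train: np.ndarray,
    y_train: np.ndarray,
    hp: HyperparameterConfig,
    seed: int = 0,
    prepared: tuple[StandardScaler, PcaTransform | None, np.ndarray] | None = None,
) -> TrainedPipeline:
    """Standardize, optionally decorrelate, then fit.

    ``prepared`` lets cross-validation reuse the (fold-local) scaler/PCA and
    transformed design matrix across hyperparameter configurations that share
    the same preprocessing.
    """
    if prepared is not None:
        scaler, pca, Z = prepared
    else:
        scaler = StandardScaler().fit(np.asarray(X_train, dtype=float))
        Z = scaler.transform(np.asarray(X_train, dtype=float))
        pca = None
        if hp.use_pca:
            pca = fit_pca(Z, hp.variance_threshold)
            Z = pca.transform(Z)
    model = fit_model(Z, y_train, hp, seed)
    return TrainedPipeline(scaler=scaler, pca=pca, model=model, hp=hp)


def prepare_design(
    X_train: np.ndarray, use_pca: bool, variance_threshold: float = 0.95
) -> tuple[StandardScaler, PcaTransform | None, np.ndarray]:
    """Fit the fold-local scaler (and PCA if requested) once for reuse."""
    X = np.asarray(X_train, dtype=float)
    scaler = StandardScaler().fit(X)
    Z = scaler.transform(X)
    pca = None
    if use_pca:
        pca = fit_pca(Z, variance_threshold)
        Z = pca.transform(Z)
    return scaler, pca, Z
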