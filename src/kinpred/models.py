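"""Kinetics regressors and the two-layer environmental-factor stack.

The default predictor is an Extra Trees ensemble over the concatenated
enzyme–substrate pair vector; alternative scikit-learn regressors are exposed
through a backend registry (default library hyperparameters throughout). The
environmental-factor extension stacks two base models — one blind to the
condition (trained on a large condition-free dataset) and one trained with
the raw pH or temperature value appended to the pair vector — under a linear
meta-learner fit by least squares on a held-out meta-training split.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.ensemble import (
    AdaBoostRegressor,
    BaggingRegressor,
    ExtraTreesRegressor,
    GradientBoostingRegressor,
    RandomForestRegressor,
)
from sklearn.linear_model import (
    BayesianRidge,
    ElasticNet,
    Lasso,
    LinearRegression,
    Ridge,
)
from sklearn.neighbors import KNeighborsRegressor
from sklearn.svm import SVR
from sklearn.tree import DecisionTreeRegressor

from .datasets import split_holdout, split_nested_ef
from .reweighting import WeightVector

_MODEL_FORMAT_VERSION = 1

#: backend name → (estimator class, accepts random_state)
_BACKENDS = {
    "extra_trees": (ExtraTreesRegressor, True),
    "random_forest": (RandomForestRegressor, True),
    "gradient_boosting": (GradientBoostingRegressor, True),
    "decision_tree": (DecisionTreeRegressor, True),
    "bagging": (BaggingRegressor, True),
    "adaboost": (AdaBoostRegressor, True),
    "linear": (LinearRegression, False),
    "ridge": (Ridge, False),
    "lasso": (Lasso, False),
    "elastic_net": (ElasticNet, False),
    "bayesian_ridge": (BayesianRidge, False),
    "knn": (KNeighborsRegressor, False),
    "svr": (SVR, False),
}


def available_backends() -> tuple:
    return tuple(sorted(_BACKENDS))


@dataclass(frozen=True)
class RegressorConfig:
    """Backend choice plus overrides; the seed fixes all stochastic parts."""

    backend: str = "extra_trees"
    backend_params: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.backend not in _BACKENDS:
            raise ValueError(
                f"unknown backend {self.backend!r}; choose from {available_backends()}"
            )

    def make_estimator(self):
        cls, seeded = _BACKENDS[self.backend]
        params = dict(self.backend_params)
        if seeded:
            params.setdefault("random_state", self.seed)
        return cls(**params)


@dataclass
class TrainedModel:
    """A fitted regressor with its feature-dimension contract and metadata."""

    config: RegressorConfig
    feature_dim: int
    parameter_kind: str
    estimator: object
    n_train: int
    embedder_id: str | None = None

    def predict(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=float)
        if features.ndim != 2:
            raise ValueError("features must be a 2-d matrix")
        if features.shape[0] == 0:
            return np.empty(0)
        if features.shape[1] != self.feature_dim:
            raise ValueError(
                f"feature dim {features.shape[1]} ≠ model dim {self.feature_dim}"
            )
        if not np.all(np.isfinite(features)):
            raise ValueError("features contain non-finite values")
        return np.asarray(self.estimator.predict(features), dtype=float)


def train_regressor(
    features: np.ndarray,
    labels: np.ndarray,
    config: RegressorConfig = RegressorConfig(),
    weights: WeightVector | np.ndarray | None = None,
    parameter_kind: str = "kcat",
    embedder_id: str | None = None,
) -> TrainedModel:
    """Fit a regressor on (features, log-scale labels), optionally weighted."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if features.ndim != 2:
        raise ValueError("features must be a 2-d matrix")
    n, d = features.shape
    if n < 2:
        raise ValueError("need at least 2 training samples")
    if labels.shape != (n,):
        raise ValueError("labels must align with feature rows")
    if not (np.all(np.isfinite(features)) and np.all(np.isfinite(labels))):
        raise ValueError("training inputs contain non-finite values")

    sample_weight = None
    if weights is not None:
        w = weights.weights if isinstance(weights, WeightVector) else np.asarray(weights, float)
        if w.shape != (n,):
            raise ValueError("weights must align with samples")
        if np.any(w < 0) or not np.any(w > 0):
            raise ValueError("weights must be nonnegative with at least one positive")
        sample_weight = w

    estimator = config.make_estimator()
    if sample_weight is not None:
        estimator.fit(features, labels, sample_weight=sample_weight)
    else:
        estimator.fit(features, labels)
    return TrainedModel(config, d, parameter_kind, estimator, n, embedder_id)


def predict(model: TrainedModel, features: np.ndarray) -> np.ndarray:
    return model.predict(features)


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_model(model: TrainedModel, path: str | Path) -> None:
    joblib.dump(
        {
            "format_version": _MODEL_FORMAT_VERSION,
            "config": model.config,
            "feature_dim": model.feature_dim,
            "parameter_kind": model.parameter_kind,
            "estimator": model.estimator,
            "n_train": model.n_train,
            "embedder_id": model.embedder_id,
        },
        path,
    )


def load_model(path: str | Path) -> TrainedModel:
    payload = joblib.load(path)
    version = payload.get("format_version")
    if version != _MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model file version {version!r}")
    return TrainedModel(
        payload["config"],
        payload["feature_dim"],
        payload["parameter_kind"],
        payload["estimator"],
        payload["n_train"],
        payload["embedder_id"],
    )


# ---------------------------------------------------------------------------
# Environmental-factor stacking
# ---------------------------------------------------------------------------

@dataclass
class StackedModel:
    """Condition-blind and condition-aware base models under a linear meta layer.

    The meta prediction is ``b0 + b1·plain(x) + b2·revised(x ⊕ condition)``.
    The coefficients are the minimum-norm least-squares solution, so exactly
    collinear base predictions remain well-defined.
    """

    base_plain: TrainedModel
    base_revised: TrainedModel
    intercept: float
    coef_plain: float
    coef_revised: float

    def predict(self, pair_features: np.ndarray, conditions: np.ndarray) -> np.ndarray:
        pair_features = np.asarray(pair_features, dtype=float)
        conditions = np.asarray(conditions, dtype=float).reshape(-1)
        if pair_features.shape[0] != conditions.size:
            raise ValueError("conditions must align with feature rows")
        p_plain = self.base_plain.predict(pair_features)
        revised_features = np.column_stack([pair_features, conditions])
        p_revised = self.base_revised.predict(revised_features)
        return self.intercept + self.coef_plain * p_plain + self.coef_revised * p_revised


def _fit_meta(p_plain: np.ndarray, p_revised: np.ndarray, y: np.ndarray):
    design = np.column_stack([np.ones_like(y), p_plain, p_revised])
    coef = np.linalg.pinv(design) @ y
    return float(coef[0]), float(coef[1]), float(coef[2])


def train_ef(
    env_free: tuple[np.ndarray, np.ndarray],
    env: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: RegressorConfig = RegressorConfig(),
    seed: int = 0,
    base_indices: np.ndarray | None = None,
    meta_indices: np.ndarray | None = None,
    parameter_kind: str = "kcat",
) -> StackedModel:
    """Train the two-layer stack.

    ``env_free`` is ``(pair_features, labels)`` for the large condition-free
    dataset; ``env`` is ``(pair_features, conditions, labels)`` for the
    condition-annotated dataset. Unless explicit base/meta index sets are
    given, the env rows are split 80/20 (seeded) into the base-model and
    meta-model training sets.
    """
    X0, y0 = env_free
    X0 = np.asarray(X0, float)
    y0 = np.asarray(y0, float).reshape(-1)
    if X0.shape[0] == 0:
        raise ValueError("condition-free dataset must be nonempty")
    Xe, ce, ye = env
    Xe = np.asarray(Xe, float)
    ce = np.asarray(ce, float).reshape(-1)
    ye = np.asarray(ye, float).reshape(-1)
    if not (Xe.shape[0] == ce.size == ye.size):
        raise ValueError("env features, conditions, and labels must align")
    if Xe.shape[1] != X0.shape[1]:
        raise ValueError("env and env-free pair features must share one dimension")

    if base_indices is None or meta_indices is None:
        base_indices, meta_indices = split_holdout(Xe.shape[0], 0.2, seed)
    base_indices = np.asarray(base_indices)
    meta_indices = np.asarray(meta_indices)
    if meta_indices.size < 3:
        raise ValueError("meta training set needs at least 3 samples")

    base_plain = train_regressor(X0, y0, config, parameter_kind=parameter_kind)
    revised_features = np.column_stack([Xe, ce])
    base_revised = train_regressor(
        revised_features[base_indices], ye[base_indices], config,
        parameter_kind=parameter_kind,
    )

    p_plain = base_plain.predict(Xe[meta_indices])
    p_revised = base_revised.predict(revised_features[meta_indices])
    b0, b1, b2 = _fit_meta(p_plain, p_revised, ye[meta_indices])
    return StackedModel(base_plain, base_revised, b0, b1, b2)


def predict_ef(
    stacked: StackedModel, pair_features: np.ndarray, conditions: np.ndarray | float
) -> np.ndarray:
    pair_features = np.asarray(pair_features, dtype=float)
    if pair_features.ndim == 1:
        pair_features = pair_features.reshape(1, -1)
    conditions = np.asarray(conditions, dtype=float).reshape(-1)
    if conditions.size == 1:
        conditions = np.full(pair_features.shape[0], conditions[0])
    return stacked.predict(pair_features, conditions)


def evaluate_ef(
    env_free: tuple[np.ndarray, np.ndarray],
    env: tuple[np.ndarray, np.ndarray, np.ndarray],
    config: RegressorConfig = RegressorConfig(),
    seed: int = 0,
    repeats: int = 3,
) -> dict:
    """Repeat the nested split, train, and average test R² for the three models.

    Each repeat draws a fresh nested 64/16/20 split of the env dataset, trains
    the stack on base+meta, and scores the stacked model, the condition-blind
    base, and the condition-aware base on the held-out test portion. Returns
    mean R² per model over the repeats, mirroring the average-of-three
    evaluation protocol.
    """
    from .evaluation import r2_score

    Xe, ce, ye = (np.asarray(a, float) for a in env)
    ce, ye = ce.reshape(-1), ye.reshape(-1)
    scores = {"ef": [], "plain": [], "revised": []}
    for r in range(repeats):
        base_idx, meta_idx, test_idx = split_nested_ef(Xe.shape[0], seed + r)
        stacked = train_ef(
            env_free, (Xe, ce, ye), config, seed=seed + r,
            base_indices=base_idx, meta_indices=meta_idx,
        )
        y_test = ye[test_idx]
        revised_features = np.column_stack([Xe, ce])
        scores["ef"].append(r2_score(y_test, stacked.predict(Xe[test_idx], ce[test_idx])))
        scores["plain"].append(r2_score(y_test, stacked.base_plain.predict(Xe[test_idx])))
        scores["revised"].append(
            r2_score(y_test, stacked.base_revised.predict(revised_features[test_idx]))
        )
    return {name: float(np.mean(vals)) for name, vals in scores.items()}
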