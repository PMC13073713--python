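"""Per-bag stacked generalization: out-of-fold probability meta-features
from heterogeneous base learners, fused by a logistic meta-learner.

The learner registry is pluggable (tests inject dummy/oracle learners).
Registry names follow the common boosted-tree tool names; when the
corresponding third-party library is not installed, an equivalently
configured scikit-learn histogram gradient-boosting model is used instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from sklearn.dummy import DummyClassifier
from sklearn.ensemble import (
    GradientBoostingClassifier,
    HistGradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from riskstack.features import FeatureTable

CLASSES = (0, 1, 2)
N_CLASSES = len(CLASSES)


@dataclass(frozen=True)
class LearnerSpec:
    """A registry name plus hyperparameter overrides and a seed."""

    name: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int | None = None

    def resolve_seed(self, fallback: int) -> int:
        return self.seed if self.seed is not None else fallback


def _rf(params: dict, seed: int):
    defaults = dict(
        n_estimators=150, max_depth=6, min_samples_split=2,
        min_samples_leaf=1, class_weight="balanced", n_jobs=1,
    )
    return RandomForestClassifier(random_state=seed, **{**defaults, **params})


def _gb(params: dict, seed: int):
    defaults = dict(n_estimators=150, max_depth=5, learning_rate=0.1)
    return GradientBoostingClassifier(random_state=seed, **{**defaults, **params})


def _hist_gb(defaults: dict):
    def factory(params: dict, seed: int):
        return HistGradientBoostingClassifier(
            random_state=seed, **{**defaults, **params}
        )

    return factory


def _xgboost(params: dict, seed: int):
    try:
        from xgboost import XGBClassifier
    except ImportError:
        return _hist_gb(
            dict(max_iter=150, max_depth=6, learning_rate=0.05)
        )(params, seed)
    defaults = dict(
        n_estimators=150, max_depth=6, learning_rate=0.05,
        min_child_weight=1, subsample=0.8, colsample_bytree=0.8,
        verbosity=0, eval_metric="mlogloss", objective="multi:softprob",
    )
    return XGBClassifier(random_state=seed, **{**defaults, **params})


def _lightgbm(params: dict, seed: int):
    try:
        from lightgbm import LGBMClassifier
    except ImportError:
        return _hist_gb(
            dict(max_iter=150, max_depth=6, learning_rate=0.1, max_leaf_nodes=31)
        )(params, seed)
    defaults = dict(
        n_estimators=150, max_depth=6, learning_rate=0.1, num_leaves=31,
        min_child_samples=20, subsample=0.8, colsample_bytree=0.8, verbose=-1,
    )
    return LGBMClassifier(random_state=seed, **{**defaults, **params})


def _catboost(params: dict, seed: int):
    try:
        from catboost import CatBoostClassifier
    except ImportError:
        return _hist_gb(
            dict(max_iter=150, max_depth=6, learning_rate=0.1, l2_regularization=3.0)
        )(params, seed)
    defaults = dict(iterations=150, depth=6, learning_rate=0.1,
                    l2_leaf_reg=3, verbose=False)
    return CatBoostClassifier(random_state=seed, **{**defaults, **params})


def _svm(params: dict, seed: int):
    defaults = dict(kernel="rbf", C=1.0, gamma="scale", probability=True,
                    class_weight="balanced")
    return SVC(random_state=seed, **{**defaults, **params})


def _knn(params: dict, seed: int):
    defaults = dict(n_neighbors=5, weights="uniform", algorithm="auto")
    return KNeighborsClassifier(**{**defaults, **params})


def _mlp(params: dict, seed: int):
    defaults = dict(
        hidden_layer_sizes=(100, 50), activation="relu", solver="adam",
        alpha=1e-4, batch_size="auto", learning_rate="constant",
        learning_rate_init=1e-3, max_iter=500,
    )
    return MLPClassifier(random_state=seed, **{**defaults, **params})


def _lr(params: dict, seed: int):
    defaults = dict(C=1.0, max_iter=2000)
    return LogisticRegression(random_state=seed, **{**defaults, **params})


def _prior(params: dict, seed: int):
    return DummyClassifier(strategy="prior")


LEARNER_REGISTRY: dict[str, Callable] = {
    "RF": _rf,
    "GB": _gb,
    "XGBoost": _xgboost,
    "LightGBM": _lightgbm,
    "CatBoost": _catboost,
    "SVM": _svm,
    "KNN": _knn,
    "MLP": _mlp,
    "LR": _lr,
    "prior": _prior,
}


def register_learner(name: str, factory: Callable) -> None:
    """Register ``factory(params, seed) -> estimator`` under ``name``."""
    LEARNER_REGISTRY[name] = factory


def make_learner(spec: LearnerSpec, fallback_seed: int = 0):
    if spec.name not in LEARNER_REGISTRY:
        raise KeyError(
            f"unknown learner {spec.name!r}; registered: "
            f"{sorted(LEARNER_REGISTRY)}"
        )
    return LEARNER_REGISTRY[spec.name](
        dict(spec.hyperparameters), spec.resolve_seed(fallback_seed)
    )


def default_base_specs() -> list[LearnerSpec]:
    """The five tree-based base learners, in fixed order."""
    return [
        LearnerSpec("RF"),
        LearnerSpec("GB"),
        LearnerSpec("XGBoost"),
        LearnerSpec("CatBoost"),
        LearnerSpec("LightGBM"),
    ]


def default_meta_spec() -> LearnerSpec:
    return LearnerSpec("LR")


def assign_stratified_folds(y: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Disjoint, exhaustive fold ids with per-class sizes balanced within 1."""
    y = np.asarray(y)
    if k < 2:
        raise ValueError("k must be >= 2")
    folds = np.full(y.shape[0], -1, dtype=int)
    rng = np.random.default_rng(seed)
    offset = 0
    for c in np.unique(y):
        members = np.flatnonzero(y == c)
        if members.size < k:
            raise ValueError(
                f"class {c} has {members.size} rows, fewer than k={k} folds"
            )
        members = rng.permutation(members)
        folds[members] = (np.arange(members.size) + offset) % k
        offset += members.size
    return folds


def _aligned_proba(model, X: np.ndarray) -> np.ndarray:
    """predict_proba with columns fixed to the (0, 1, 2) class order."""
    raw = model.predict_proba(X)
    out = np.zeros((X.shape[0], N_CLASSES))
    out[:, np.asarray(model.classes_, dtype=int)] = raw
    return out


def oof_probabilities(
    spec: LearnerSpec,
    ft: FeatureTable,
    folds: np.ndarray,
    fallback_seed: int = 0,
) -> tuple[np.ndarray, list]:
    """Out-of-fold class probabilities for one learner.

    Row i comes from the model trained with fold(i) excluded; every row is
    filled exactly once.  Returns (N x 3 block, per-fold fitted models).
    """
    block = np.full((ft.n_rows, N_CLASSES), np.nan)
    fold_models = []
    for fold_id in np.unique(folds):
        held = folds == fold_id
        model = make_learner(spec, fallback_seed)
        try:
            model.fit(ft.X[~held], ft.y[~held])
            block[held] = _aligned_proba(model, ft.X[held])
        except Exception as exc:  # surface the learner and fold
            raise RuntimeError(
                f"base learner {spec.name!r} failed on fold {fold_id}: {exc}"
            ) from exc
        fold_models.append(model)
    assert not np.isnan(block).any()
    return block, fold_models


def assemble_meta_features(blocks: list[np.ndarray]) -> np.ndarray:
    """Horizontally concatenate per-learner probability blocks (width 3M)."""
    if not blocks:
        raise ValueError("no blocks")
    n_rows = blocks[0].shape[0]
    for b in blocks:
        if b.shape[0] != n_rows:
            raise ValueError("meta-feature blocks differ in row count")
    return np.hstack(blocks)


@dataclass
class StackingModel:
    """One fitted stacking ensemble: fold models (audit), full-data refit
    base models (inference) and the fitted meta-learner."""

    base_specs: list[LearnerSpec]
    fold_models: list[list]
    refit_models: list
    meta_model: object
    folds: np.ndarray
    n_features: int

    @property
    def meta_width(self) -> int:
        return N_CLASSES * len(self.base_specs)


def fit_stacking_model(
    ft: FeatureTable,
    base_specs: list[LearnerSpec] | None = None,
    meta_spec: LearnerSpec | None = None,
    k: int = 3,
    seed: int = 0,
) -> StackingModel:
    """Fit OOF meta-features, train the meta-learner on them, then refit
    every base learner on the full table for inference."""
    base_specs = list(base_specs) if base_specs is not None else default_base_specs()
    meta_spec = meta_spec if meta_spec is not None else default_meta_spec()
    folds = assign_stratified_folds(ft.y, k, seed)

    blocks = []
    all_fold_models = []
    for m, spec in enumerate(base_specs):
        block, fold_models = oof_probabilities(spec, ft, folds, seed + m)
        blocks.append(block)
        all_fold_models.append(fold_models)
    Z = assemble_meta_features(blocks)

    meta = make_learner(meta_spec, seed)
    meta.fit(Z, ft.y)

    refit = []
    for m, spec in enumerate(base_specs):
        model = make_learner(spec, seed + m)
        model.fit(ft.X, ft.y)
        refit.append(model)

    return StackingModel(
        base_specs=base_specs,
        fold_models=all_fold_models,
        refit_models=refit,
        meta_model=meta,
        folds=folds,
        n_features=ft.X.shape[1],
    )


def stacking_predict_proba(model: StackingModel, X: np.ndarray) -> np.ndarray:
    """Fused class probabilities (rows sum to 1) for new samples."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.n_features:
        raise ValueError(
            f"expected {model.n_features} features, got {X.shape[1]}"
        )
    Z = assemble_meta_features(
        [_aligned_proba(m, X) for m in model.refit_models]
    )
    return _aligned_proba(model.meta_model, Z)
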