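"""Bagged stacking: B independently balanced subsets, B stacking models,
soft-vote probability fusion and the high-risk threshold decision rule."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np

from riskstack.features import FeatureTable
from riskstack.resampling import SmoteConfig, smote_tomek_balance, stratified_bootstrap
from riskstack.stacking import (
    LearnerSpec,
    StackingModel,
    default_base_specs,
    default_meta_spec,
    fit_stacking_model,
    stacking_predict_proba,
)

RISK_HIGH = 2


@dataclass
class EnsembleConfig:
    """All framework constants.

    Per-bag seeds are derived as ``seed + b`` for bag b = 1..B, so any
    single bag is independently reproducible.  ``decision_rule`` is
    "threshold" (high-risk via tau only) or "argmax" (plain argmax,
    ablation).
    """

    n_bags: int = 5
    k_folds: int = 3
    tau: float = 0.5
    bootstrap: bool = True
    smote: SmoteConfig = field(default_factory=SmoteConfig)
    base_specs: list[LearnerSpec] = field(default_factory=default_base_specs)
    meta_spec: LearnerSpec = field(default_factory=default_meta_spec)
    decision_rule: str = "threshold"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bags < 1:
            raise ValueError("n_bags must be >= 1")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must be in [0, 1]")
        if self.decision_rule not in ("threshold", "argmax"):
            raise ValueError(f"unknown decision rule {self.decision_rule!r}")

    def bag_seed(self, b: int) -> int:
        return self.seed + b


@dataclass
class BaggingStackingModel:
    members: list[StackingModel]
    config: EnsembleConfig
    subset_hashes: list[str] = field(default_factory=list)  # per-bag training-subset digests

    @property
    def n_features(self) -> int:
        return self.members[0].n_features


@dataclass
class Prediction:
    labels: np.ndarray
    probabilities: np.ndarray  # final soft-voted matrix, columns (Low, Medium, High)
    tau: float


def fit_bagging_stacking(ft: FeatureTable, cfg: EnsembleConfig) -> BaggingStackingModel:
    """Fit the full framework: for each bag, (optional) stratified
    bootstrap, SMOTE-Tomek balancing, then a stacking model."""
    members = []
    hashes = []
    for b in range(1, cfg.n_bags + 1):
        seed_b = cfg.bag_seed(b)
        try:
            subset = stratified_bootstrap(ft, seed_b) if cfg.bootstrap else ft
            balanced = smote_tomek_balance(
                subset, SmoteConfig(
                    k_neighbors=cfg.smote.k_neighbors,
                    target=cfg.smote.target,
                    seed=seed_b,
                )
            )
            hashes.append(
                hashlib.sha256(
                    np.ascontiguousarray(balanced.X).tobytes()
                    + np.ascontiguousarray(balanced.y).tobytes()
                ).hexdigest()
            )
            members.append(
                fit_stacking_model(
                    balanced, cfg.base_specs, cfg.meta_spec,
                    k=cfg.k_folds, seed=seed_b,
                )
            )
        except Exception as exc:
            raise RuntimeError(f"bag {b} failed: {exc}") from exc
    return BaggingStackingModel(members=members, config=cfg, subset_hashes=hashes)


def soft_vote(member_probs: list[np.ndarray]) -> np.ndarray:
    """Element-wise arithmetic mean of member probability matrices."""
    if not member_probs:
        raise ValueError("no member probabilities")
    shape = member_probs[0].shape
    for p in member_probs:
        if p.shape != shape:
            raise ValueError("member probability shapes differ")
    return np.mean(member_probs, axis=0)


def decide_labels(P_final: np.ndarray, tau: float, rule: str = "threshold") -> np.ndarray:
    """High-risk iff P_High strictly exceeds tau; otherwise argmax over
    {Low, Medium} only, with an exact tie going to Medium.

    ``rule="argmax"`` is the plain three-way argmax ablation.
    """
    P_final = np.asarray(P_final, dtype=float)
    if rule == "argmax":
        return P_final.argmax(axis=1)
    high = P_final[:, RISK_HIGH] > tau
    # tie at P_Low == P_Medium resolves to Medium (risk-conservative)
    low_vs_med = (P_final[:, 0] > P_final[:, 1]).astype(int) ^ 1
    return np.where(high, RISK_HIGH, low_vs_med)


def member_probabilities(model: BaggingStackingModel, X: np.ndarray) -> list[np.ndarray]:
    return [stacking_predict_proba(m, X) for m in model.members]


def predict_proba(model: BaggingStackingModel, X: np.ndarray) -> np.ndarray:
    return soft_vote(member_probabilities(model, X))


def predict(model: BaggingStackingModel, X: np.ndarray,
            tau: float | None = None) -> Prediction:
    """Soft-voted probabilities plus thresholded labels."""
    cfg = model.config
    tau = cfg.tau if tau is None else tau
    P_final = predict_proba(model, X)
    labels = decide_labels(P_final, tau, cfg.decision_rule)
    return Prediction(labels=labels, probabilities=P_final, tau=tau)


def save_model(model: BaggingStackingModel, out_dir) -> None:
    """Persist the model as a directory bundle (config JSON + joblib blob)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = model.config
    meta = {
        "n_bags": cfg.n_bags,
        "k_folds": cfg.k_folds,
        "tau": cfg.tau,
        "bootstrap": cfg.bootstrap,
        "decision_rule": cfg.decision_rule,
        "seed": cfg.seed,
        "base_learners": [s.name for s in cfg.base_specs],
        "meta_learner": cfg.meta_spec.name,
    }
    (out / "config.json").write_text(json.dumps(meta, indent=2))
    joblib.dump(model, out / "model.joblib")


def load_model(model_dir) -> BaggingStackingModel:
    return joblib.load(Path(model_dir) / "model.joblib")
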