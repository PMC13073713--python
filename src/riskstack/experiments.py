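"""Experiment harnesses: baseline-vs-framework benchmark and robustness
across test fractions, on synthetic inspection records."""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from riskstack.ensemble import EnsembleConfig, fit_bagging_stacking, predict
from riskstack.features import build_feature_matrix
from riskstack.metrics import MetricsReport, attach_auc, classification_report
from riskstack.stacking import LearnerSpec, _aligned_proba, make_learner
from riskstack.synthetic import GeneratorConfig, generate_inspection_records, stratified_split

logger = logging.getLogger(__name__)

DEFAULT_BASELINES = ("RF", "XGBoost", "GB", "CatBoost", "LightGBM")


@dataclass
class ExperimentConfig:
    generator: GeneratorConfig = field(
        default_factory=lambda: GeneratorConfig(n_records=792, seed=7)
    )
    ensemble: EnsembleConfig = field(default_factory=EnsembleConfig)
    baselines: tuple[str, ...] = DEFAULT_BASELINES
    test_fraction: float = 0.2
    test_fractions: tuple[float, ...] = (0.1, 0.2, 0.4)
    split_seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.test_fraction, *self.test_fractions):
            if not 0.0 < f < 1.0:
                raise ValueError("test fractions must be in (0, 1)")


def report_row(model_name: str, rep: MetricsReport) -> dict:
    row = {"model": model_name, "accuracy": rep.accuracy,
           "macro_f1": rep.macro_f1, "weighted_f1": rep.weighted_f1,
           "macro_auc": rep.macro_auc}
    for c, name in enumerate(("low", "medium", "high")):
        row[f"precision_{name}"] = rep.precision[c]
        row[f"recall_{name}"] = rep.recall[c]
        row[f"f1_{name}"] = rep.f1[c]
        row[f"auc_{name}"] = rep.auc[c] if rep.auc is not None else np.nan
    return row


def _prepared_split(cfg: ExperimentConfig, test_fraction: float):
    records = generate_inspection_records(cfg.generator)
    train, test = stratified_split(records, test_fraction, cfg.split_seed)
    ft_train, schema = build_feature_matrix(train, fit=True)
    ft_test = build_feature_matrix(test, schema=schema, fit=False)
    return ft_train, ft_test


def evaluate_baseline(name: str, ft_train, ft_test, seed: int) -> MetricsReport:
    """A single learner, no resampling, conventional argmax decision."""
    model = make_learner(LearnerSpec(name), seed)
    model.fit(ft_train.X, ft_train.y)
    proba = _aligned_proba(model, ft_test.X)
    rep = classification_report(ft_test.y, proba.argmax(axis=1))
    return attach_auc(rep, ft_test.y, proba)


def evaluate_framework(cfg: EnsembleConfig, ft_train, ft_test) -> MetricsReport:
    model = fit_bagging_stacking(ft_train, cfg)
    pred = predict(model, ft_test.X)
    rep = classification_report(ft_test.y, pred.labels)
    return attach_auc(rep, ft_test.y, pred.probabilities)


def run_benchmark(cfg: ExperimentConfig) -> pd.DataFrame:
    """Baselines (unresampled, argmax) and the full framework on one
    shared stratified split; one report row per model."""
    ft_train, ft_test = _prepared_split(cfg, cfg.test_fraction)
    rows = []
    for name in cfg.baselines:
        t0 = time.perf_counter()
        try:
            rep = evaluate_baseline(name, ft_train, ft_test, cfg.ensemble.seed)
            rows.append(report_row(name, rep))
        except Exception:
            logger.exception("baseline %s failed; continuing", name)
        logger.info("baseline %s: %.1fs", name, time.perf_counter() - t0)
    t0 = time.perf_counter()
    try:
        rep = evaluate_framework(cfg.ensemble, ft_train, ft_test)
        rows.append(report_row("BaggingStacking", rep))
    except Exception:
        logger.exception("framework failed")
    logger.info("framework: %.1fs", time.perf_counter() - t0)
    return pd.DataFrame(rows)


def run_robustness(cfg: ExperimentConfig) -> pd.DataFrame:
    """Framework metrics per test fraction: long-form
    (test_fraction, class, metric, value) grid for heatmap rendering."""
    rows = []
    for frac in cfg.test_fractions:
        t0 = time.perf_counter()
        ft_train, ft_test = _prepared_split(cfg, frac)
        rep = evaluate_framework(cfg.ensemble, ft_train, ft_test)
        for c, name in enumerate(("low", "medium", "high")):
            for metric, value in (
                ("precision", rep.precision[c]),
                ("recall", rep.recall[c]),
                ("f1", rep.f1[c]),
                ("auc", rep.auc[c]),
            ):
                rows.append(
                    {"test_fraction": frac, "class": name,
                     "metric": metric, "value": value}
                )
        logger.info("fraction %.2f: %.1fs", frac, time.perf_counter() - t0)
    return pd.DataFrame(rows)
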