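"""YAML configuration loading for the CLI."""

from __future__ import annotations

from pathlib import Path

import yaml

from riskstack.ensemble import EnsembleConfig
from riskstack.experiments import DEFAULT_BASELINES, ExperimentConfig
from riskstack.resampling import SmoteConfig
from riskstack.stacking import LearnerSpec, default_base_specs, default_meta_spec
from riskstack.synthetic import GeneratorConfig


def _specs(entries) -> list[LearnerSpec]:
    specs = []
    for e in entries:
        if isinstance(e, str):
            specs.append(LearnerSpec(e))
        else:
            specs.append(
                LearnerSpec(e["name"], dict(e.get("hyperparameters", {})),
                            e.get("seed"))
            )
    return specs


def ensemble_config_from_dict(d: dict) -> EnsembleConfig:
    smote = d.get("smote", {})
    stacking = d.get("stacking", {})
    bagging = d.get("bagging", {})
    decision = d.get("decision", {})
    base = stacking.get("base")
    meta = stacking.get("meta")
    return EnsembleConfig(
        n_bags=bagging.get("B", d.get("n_bags", 5)),
        k_folds=stacking.get("k", d.get("k_folds", 3)),
        tau=decision.get("tau", d.get("tau", 0.5)),
        bootstrap=bagging.get("bootstrap", d.get("bootstrap", True)),
        smote=SmoteConfig(
            k_neighbors=smote.get("k_neighbors", 5),
            seed=smote.get("seed", d.get("seed", 0)),
        ),
        base_specs=_specs(base) if base else default_base_specs(),
        meta_spec=_specs([meta])[0] if meta else default_meta_spec(),
        decision_rule=decision.get("rule", "threshold"),
        seed=d.get("seed", 0),
    )


def generator_config_from_dict(d: dict) -> GeneratorConfig:
    return GeneratorConfig(
        n_records=d.get("n", d.get("n_records", 792)),
        class_proportions=tuple(
            d.get("class_proportions", (0.3523, 0.5783, 0.0694))
        ),
        signal_strength=d.get("signal_strength", 1.0),
        seed=d.get("seed", 7),
    )


def experiment_config_from_dict(d: dict) -> ExperimentConfig:
    return ExperimentConfig(
        generator=generator_config_from_dict(d.get("generator", {})),
        ensemble=ensemble_config_from_dict(d.get("ensemble", {})),
        baselines=tuple(d.get("baselines", DEFAULT_BASELINES)),
        test_fraction=d.get("test_fraction", 0.2),
        test_fractions=tuple(d.get("test_fractions", (0.1, 0.2, 0.4))),
        split_seed=d.get("split_seed", 0),
    )


def load_yaml(path) -> dict:
    with open(Path(path), encoding="utf-8") as fh:
        return yaml.safe_load(fh) or {}
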