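"""Synthetic inspection-record generator and stratified splitting.

Emulates three-class risk-labelled sampling records (heavily imbalanced,
categorical-dominated schema) so the full pipeline can be exercised without
any external data.  Class-conditional skews are controlled by a single
``signal_strength`` knob: at 0 every feature is drawn from the same
distribution for all classes; above 0, high-risk rows tilt toward summer
production months, ambient storage, unpackaged products and shorter shelf
life (low-risk rows tilt the opposite way, medium-risk rows stay neutral).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import ceil, pi

import numpy as np
import pandas as pd

from riskstack._alloc import largest_remainder

RISK_LOW, RISK_MEDIUM, RISK_HIGH = 0, 1, 2

COLUMNS = [
    "food_category",
    "cross_province",
    "sampling_site",
    "sampling_province",
    "package",
    "production_month",
    "shelf_life_months",
    "storage_condition",
    "risk_class",
]

FOOD_CATEGORIES = [
    "special_dietary_foods", "fruit_products", "condiments", "pastries",
    "health_foods", "roasted_nuts", "convenience_foods", "beverages",
    "dairy_products", "meat_products", "aquatic_products", "edible_oils",
    "grain_products", "egg_products", "honey_products", "frozen_foods",
    "candied_foods", "tea_products", "alcoholic_drinks", "soy_products",
    "starch_products", "canned_foods", "sugar_products", "vegetable_products",
    "infant_foods", "biscuits", "instant_noodles", "pickled_vegetables",
    "mineral_water", "snack_foods",
]

CROSS_PROVINCE_LEVELS = ["local", "cross_city", "cross_province", "unknown"]
SAMPLING_SITES = [
    "general_store", "grocery_store", "supermarket",
    "restaurant", "online_store", "farmers_market",
]
PROVINCES = [f"province_{i:02d}" for i in range(1, 33)]
PACKAGE_LEVELS = ["unpackaged", "prepackaged"]
STORAGE_LEVELS = ["ambient", "refrigerated", "frozen"]

# Baseline (signal-free) categorical distributions.
_FOOD_BASE = 1.0 / (np.arange(len(FOOD_CATEGORIES)) + 3.0)
_FOOD_BASE /= _FOOD_BASE.sum()
_CROSS_BASE = np.array([0.40, 0.25, 0.25, 0.10])
_SITE_BASE = np.full(len(SAMPLING_SITES), 1.0 / len(SAMPLING_SITES))
_PROVINCE_BASE = np.full(len(PROVINCES), 1.0 / len(PROVINCES))
_PACKAGE_BASE = np.array([0.35, 0.65])
_STORAGE_BASE = np.array([0.50, 0.30, 0.20])


@dataclass
class GeneratorConfig:
    """Parameters for :func:`generate_inspection_records`."""

    n_records: int
    class_proportions: tuple[float, float, float] = (0.3523, 0.5783, 0.0694)
    signal_strength: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_records < 3:
            raise ValueError("n_records must be >= 3")
        props = np.asarray(self.class_proportions, dtype=float)
        if props.shape != (3,) or np.any(props < 0):
            raise ValueError("class_proportions must be 3 non-negative values")
        if abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(
                f"class_proportions must sum to 1, got {props.sum()!r}"
            )
        if self.signal_strength < 0:
            raise ValueError("signal_strength must be >= 0")


def _class_tilt(risk_class: int) -> float:
    # low -> -1, medium -> 0, high -> +1
    return float(risk_class - 1)


def _tilted(base: np.ndarray, direction: np.ndarray, amount: float) -> np.ndarray:
    w = base * np.exp(amount * direction)
    return w / w.sum()


def _month_probs(tilt: float) -> np.ndarray:
    # peak at July when tilt > 0
    months = np.arange(1, 13)
    w = np.exp(tilt * np.cos(2.0 * pi * (months - 7) / 12.0))
    return w / w.sum()


def _draw_class_rows(rng: np.random.Generator, n: int, risk_class: int,
                     s: float) -> pd.DataFrame:
    t = _class_tilt(risk_class) * s
    storage_dir = np.array([1.0, 0.0, -1.0])   # ambient up with risk
    package_dir = np.array([1.0, -1.0])        # unpackaged up with risk
    rows = {
        "food_category": rng.choice(FOOD_CATEGORIES, size=n, p=_FOOD_BASE),
        "cross_province": rng.choice(CROSS_PROVINCE_LEVELS, size=n, p=_CROSS_BASE),
        "sampling_site": rng.choice(SAMPLING_SITES, size=n, p=_SITE_BASE),
        "sampling_province": rng.choice(PROVINCES, size=n, p=_PROVINCE_BASE),
        "package": rng.choice(
            PACKAGE_LEVELS, size=n, p=_tilted(_PACKAGE_BASE, package_dir, t)),
        "production_month": rng.choice(
            np.arange(1, 13), size=n, p=_month_probs(t)),
        # shorter shelf life for riskier classes
        "shelf_life_months": np.exp(
            rng.normal(np.log(12.0) - 0.4 * t, 0.6, size=n)),
        "storage_condition": rng.choice(
            STORAGE_LEVELS, size=n, p=_tilted(_STORAGE_BASE, storage_dir, t)),
    }
    df = pd.DataFrame(rows)
    df["risk_class"] = risk_class
    return df


def class_counts_for(cfg: GeneratorConfig) -> np.ndarray:
    """Realized per-class counts: largest-remainder rounding of
    ``n_records x class_proportions`` (class order low, medium, high)."""
    cfg.validate()
    shares = cfg.n_records * np.asarray(cfg.class_proportions, dtype=float)
    return largest_remainder(shares, cfg.n_records)


def generate_inspection_records(cfg: GeneratorConfig) -> pd.DataFrame:
    """Generate a seeded, reproducible inspection-record table.

    Returns a DataFrame with :data:`COLUMNS` in order; class counts equal
    the largest-remainder rounding of the requested proportions exactly.
    """
    cfg.validate()
    counts = class_counts_for(cfg)
    rng = np.random.default_rng(cfg.seed)
    parts = [
        _draw_class_rows(rng, int(counts[c]), c, cfg.signal_strength)
        for c in (RISK_LOW, RISK_MEDIUM, RISK_HIGH)
        if counts[c] > 0
    ]
    table = pd.concat(parts, ignore_index=True)
    table = table.iloc[rng.permutation(len(table))].reset_index(drop=True)
    return table[COLUMNS]


def validate_records(table: pd.DataFrame) -> None:
    """Raise if the table violates the record-schema invariants."""
    missing = [c for c in COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    if table[COLUMNS].isna().any().any():
        raise ValueError("records contain missing values")
    if not table["risk_class"].isin([0, 1, 2]).all():
        raise ValueError("risk_class must be in {0, 1, 2}")
    months = table["production_month"]
    if not ((months >= 1) & (months <= 12)).all():
        raise ValueError("production_month must be in [1, 12]")
    if not (table["shelf_life_months"] > 0).all():
        raise ValueError("shelf_life_months must be positive")


def allocate_test_counts(class_counts: np.ndarray, test_fraction: float) -> np.ndarray:
    """Per-class test-set sizes for a stratified split.

    Total test size is ``ceil(test_fraction * N)``; per-class counts are the
    largest-remainder allocation against exact shares
    ``test_fraction * class_count``.
    """
    class_counts = np.asarray(class_counts, dtype=int)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    n_test = ceil(test_fraction * int(class_counts.sum()))
    alloc = largest_remainder(test_fraction * class_counts, n_test)
    if np.any(alloc > class_counts):
        # can only happen with empty classes absorbing leftovers
        raise ValueError("allocation exceeds a class size")
    return alloc


def stratified_split(
    table: pd.DataFrame, test_fraction: float, seed: int
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified train/test partition of an inspection-record table.

    The partition is disjoint and exhaustive; per-class test counts follow
    :func:`allocate_test_counts`.  A class allocated zero test rows raises an
    error when it holds at least ``1/test_fraction`` rows (it should have
    earned one) and warns otherwise.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    labels = table["risk_class"].to_numpy()
    classes, counts = np.unique(labels, return_counts=True)
    alloc = allocate_test_counts(counts, test_fraction)
    for cls, n_c, a_c in zip(classes, counts, alloc):
        if a_c == 0:
            if n_c >= 1.0 / test_fraction:
                raise ValueError(
                    f"class {cls} ({n_c} rows) received no test rows"
                )
            warnings.warn(
                f"class {cls} has too few rows ({n_c}) for a test share",
                stacklevel=2,
            )
    rng = np.random.default_rng(seed)
    test_idx: list[np.ndarray] = []
    for cls, a_c in zip(classes, alloc):
        members = np.flatnonzero(labels == cls)
        test_idx.append(rng.permutation(members)[: int(a_c)])
    test_mask = np.zeros(len(table), dtype=bool)
    test_mask[np.concatenate(test_idx)] = True
    train = table.loc[~test_mask].reset_index(drop=True)
    test = table.loc[test_mask].reset_index(drop=True)
    return train, test


def write_records_csv(table: pd.DataFrame, path) -> None:
    table[COLUMNS].to_csv(path, index=False)


def read_records_csv(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    validate_records(table)
    return table[COLUMNS]
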