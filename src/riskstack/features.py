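"""Feature engineering: cyclical month terms, shelf-life binning, one-hot
encoding and zero-variance filtering, with a fit/transform schema so the
exact training-time design matrix is replayed at prediction time."""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from math import pi

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SHELF_LIFE_BINS = ("short", "medium", "long")

# (field, encoding) in design-matrix order
_CATEGORICAL_FIELDS = [
    "food_category",
    "cross_province",
    "sampling_site",
    "sampling_province",
    "package",
]


@dataclass
class FeatureTable:
    """A numeric design matrix with aligned labels and column names."""

    X: np.ndarray
    y: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValueError("X and y row counts differ")
        if self.X.shape[1] != len(self.column_names):
            raise ValueError("X width and column_names length differ")
        if len(set(self.column_names)) != len(self.column_names):
            raise ValueError("column_names must be unique")
        if np.isnan(self.X).any():
            raise ValueError("X contains missing values")

    @property
    def n_rows(self) -> int:
        return self.X.shape[0]


@dataclass
class FeatureSchema:
    """Fitted encoding state: category vocabularies, conventions, and the
    zero-variance-filtered column list."""

    categories: dict[str, list[str]] = field(default_factory=dict)
    month_convention: str = "january_phase_zero"
    shelf_life_edges: tuple[float, float] = (6.0, 18.0)
    kept_columns: list[str] | None = None
    unknown_policy: str = "ignore"  # "ignore" -> all-zero row, "strict" -> error

    @property
    def fitted(self) -> bool:
        return self.kept_columns is not None

    def to_json(self) -> str:
        return json.dumps(
            {
                "categories": self.categories,
                "month_convention": self.month_convention,
                "shelf_life_edges": list(self.shelf_life_edges),
                "kept_columns": self.kept_columns,
                "unknown_policy": self.unknown_policy,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "FeatureSchema":
        d = json.loads(text)
        return cls(
            categories={k: list(v) for k, v in d["categories"].items()},
            month_convention=d["month_convention"],
            shelf_life_edges=tuple(d["shelf_life_edges"]),
            kept_columns=d["kept_columns"],
            unknown_policy=d.get("unknown_policy", "ignore"),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "FeatureSchema":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(fh.read())


def encode_month_cyclical(month: int) -> tuple[float, float]:
    """Map month 1..12 onto the unit circle with January at phase zero:
    angle = 2*pi*(month - 1)/12, returning (sin, cos)."""
    if not 1 <= int(month) <= 12 or int(month) != month:
        raise ValueError(f"month must be an integer in 1..12, got {month!r}")
    angle = 2.0 * pi * (int(month) - 1) / 12.0
    return float(np.sin(angle)), float(np.cos(angle))


def bin_shelf_life(months: float, edges: tuple[float, float] = (6.0, 18.0)) -> str:
    """Bin a positive shelf life into short (< lower edge), medium
    (closed interval) or long (> upper edge)."""
    if months <= 0:
        raise ValueError(f"shelf life must be positive, got {months!r}")
    lo, hi = edges
    if months < lo:
        return "short"
    if months <= hi:
        return "medium"
    return "long"


def one_hot_encode(values, categories, policy: str = "strict") -> np.ndarray:
    """One column per category, in list order.  Unseen values error under
    "strict" and produce an all-zero row under "ignore"."""
    categories = list(categories)
    if len(set(categories)) != len(categories):
        raise ValueError("categories must be duplicate-free")
    index = {c: j for j, c in enumerate(categories)}
    values = list(values)
    out = np.zeros((len(values), len(categories)))
    for i, v in enumerate(values):
        j = index.get(v)
        if j is None:
            if policy == "strict":
                raise ValueError(f"unseen category value {v!r}")
            logger.warning("unseen category value %r encoded as all-zero", v)
            continue
        out[i, j] = 1.0
    return out


def drop_zero_variance(
    X: np.ndarray, column_names: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Keep exactly the columns with more than one distinct value,
    preserving order; returns the kept names for test-time replay."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("empty design matrix")
    varying = [
        j for j in range(X.shape[1]) if np.unique(X[:, j]).size > 1
    ]
    if not varying:
        raise ValueError("all columns are constant: degenerate design")
    kept = [column_names[j] for j in varying]
    return X[:, varying], kept


def _encode_full(records: pd.DataFrame, schema: FeatureSchema):
    """All encoded blocks, pre-filter, in the documented column order."""
    blocks: list[np.ndarray] = []
    names: list[str] = []
    policy = schema.unknown_policy
    for fld in _CATEGORICAL_FIELDS:
        cats = schema.categories[fld]
        blocks.append(one_hot_encode(records[fld].astype(str), cats, policy))
        names.extend(f"{fld}={c}" for c in cats)

    sin_cos = np.array(
        [encode_month_cyclical(int(m)) for m in records["production_month"]]
    )
    blocks.append(sin_cos)
    names.extend(["month_sin", "month_cos"])

    bins = [
        bin_shelf_life(float(v), schema.shelf_life_edges)
        for v in records["shelf_life_months"]
    ]
    blocks.append(one_hot_encode(bins, SHELF_LIFE_BINS, "strict"))
    names.extend(f"shelf_life={b}" for b in SHELF_LIFE_BINS)

    cats = schema.categories["storage_condition"]
    blocks.append(one_hot_encode(records["storage_condition"].astype(str), cats, policy))
    names.extend(f"storage_condition={c}" for c in cats)
    return np.hstack(blocks), names


def build_feature_matrix(
    records: pd.DataFrame,
    schema: FeatureSchema | None = None,
    fit: bool = True,
):
    """Encode an inspection-record table into a :class:`FeatureTable`.

    With ``fit=True``, category vocabularies are taken from the data (sorted)
    where the schema does not already provide them, the zero-variance filter
    is fitted, and ``(table, fitted_schema)`` is returned.  With
    ``fit=False`` a previously fitted schema is replayed and only the table
    is returned.
    """
    if fit:
        schema = schema or FeatureSchema()
        for fld in _CATEGORICAL_FIELDS + ["storage_condition"]:
            if fld not in schema.categories:
                schema.categories[fld] = sorted(
                    records[fld].astype(str).unique()
                )
        X_full, names = _encode_full(records, schema)
        X, kept = drop_zero_variance(X_full, names)
        schema.kept_columns = kept
        y = records["risk_class"].to_numpy(dtype=int)
        return FeatureTable(X, y, kept), schema

    if schema is None or not schema.fitted:
        raise ValueError("transform requires a fitted schema")
    X_full, names = _encode_full(records, schema)
    keep_idx = [names.index(c) for c in schema.kept_columns]
    y = (
        records["risk_class"].to_numpy(dtype=int)
        if "risk_class" in records.columns
        else np.zeros(len(records), dtype=int)
    )
    return FeatureTable(X_full[:, keep_idx], y, list(schema.kept_columns))
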