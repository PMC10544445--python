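"""Tabular data model and CSV I/O for the PIMA-layout diabetes table.

The single tabular currency of the pipeline is :class:`FeatureTable`: a
pandas DataFrame of named numeric feature columns plus a binary outcome
vector (1 = diabetic, 0 = non-diabetic).  Eight canonical clinical
features are recognised and always reordered into their canonical
F1..F8 order at load time; any additional numeric columns (for example
derived ``__MVR``/``__LFM`` columns written by an earlier run) are kept
after them in file order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, SchemaError

logger = logging.getLogger("diabmod")

#: Canonical PIMA feature layout: name, short code, valid range,
#: whether a zero is physiologically impossible (hence encodes a
#: missing measurement).
PIMA_SCHEMA: tuple[tuple[str, str, tuple[float, float], bool], ...] = (
    ("Pregnancies", "F1", (0, 17), False),
    ("Glucose", "F2", (0, 199), True),
    ("BloodPressure", "F3", (0, 122), True),
    ("SkinThickness", "F4", (0, 99), True),
    ("Insulin", "F5", (0, 846), True),
    ("BMI", "F6", (0, 67.1), True),
    ("DiabetesPedigreeFunction", "F7", (0.08, 2.42), False),
    ("Age", "F8", (21, 81), False),
)

PIMA_FEATURES: tuple[str, ...] = tuple(name for name, *_ in PIMA_SCHEMA)
FEATURE_CODES: dict[str, str] = {name: code for name, code, *_ in PIMA_SCHEMA}
VALID_RANGES: dict[str, tuple[float, float]] = {
    name: rng for name, _, rng, _ in PIMA_SCHEMA
}
#: Columns whose zeros encode an unrecorded measurement.
DEFAULT_ZERO_MISSING: tuple[str, ...] = tuple(
    name for name, _, _, zm in PIMA_SCHEMA if zm
)

OUTCOME_COLUMN = "Outcome"
_OUTCOME_TEXT = {"yes": 1, "no": 0, "1": 1, "0": 0}


@dataclass
class FeatureTable:
    """Rows x named numeric features plus a binary outcome.

    Parameters
    ----------
    features : pandas.DataFrame
        Numeric feature columns; unique names, equal length.
    outcome : pandas.Series
        0/1 labels aligned with ``features`` (1 = diabetic).
    provenance : str
        Free-text stage tag (``raw``, ``imputed``, ``relative`` ...).
    """

    features: pd.DataFrame
    outcome: pd.Series
    provenance: str = "raw"

    def __post_init__(self) -> None:
        feats = self.features.reset_index(drop=True)
        out = pd.Series(np.asarray(self.outcome), name=OUTCOME_COLUMN)
        if len(feats.columns) != len(set(feats.columns)):
            raise SchemaError("feature column names must be unique")
        if len(out) != len(feats):
            raise SchemaError(
                f"outcome length {len(out)} != number of rows {len(feats)}"
            )
        for col in feats.columns:
            if not pd.api.types.is_numeric_dtype(feats[col]):
                raise SchemaError(f"feature column {col!r} is not numeric")
        bad = set(pd.unique(out.dropna())) - {0, 1}
        if bad:
            raise SchemaError(f"outcome values outside {{0,1}}: {sorted(bad)}")
        object.__setattr__(self, "features", feats.astype(float))
        object.__setattr__(self, "outcome", out.astype(int))

    # -- basic protocol -------------------------------------------------
    @property
    def n_rows(self) -> int:
        return len(self.features)

    @property
    def feature_names(self) -> list[str]:
        return list(self.features.columns)

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def __len__(self) -> int:  # pragma: no cover - trivial
        return self.n_rows

    def copy(self, provenance: str | None = None) -> "FeatureTable":
        return FeatureTable(
            self.features.copy(),
            self.outcome.copy(),
            provenance or self.provenance,
        )

    def with_features(
        self, features: pd.DataFrame, provenance: str | None = None
    ) -> "FeatureTable":
        """Return a new table with replaced feature block, same outcome."""
        return FeatureTable(
            features, self.outcome.copy(), provenance or self.provenance
        )

    def take(self, index: Sequence[int], provenance: str | None = None) -> "FeatureTable":
        """Row subset by positional index (order preserved)."""
        idx = np.asarray(index)
        return FeatureTable(
            self.features.iloc[idx].reset_index(drop=True),
            self.outcome.iloc[idx].reset_index(drop=True),
            provenance or self.provenance,
        )

    def to_frame(self) -> pd.DataFrame:
        """Features plus the outcome column, in order."""
        frame = self.features.copy()
        frame[OUTCOME_COLUMN] = self.outcome.to_numpy()
        return frame


@dataclass
class RunConfig:
    """Run configuration shared by the pipeline stages.

    Defaults mirror the study protocol: 5 folds, 20% held-out test
    fraction, top-4 correlation selection, class-conditional mean
    imputation, all statistics fitted on the training partition only.
    Setting ``fit_scope="paper_literal"`` fits imputation means,
    feature statistics and binarization thresholds on the full table
    instead (the closest-to-publication replication mode, at the cost
    of train/test leakage).
    """

    selected_feature_rule: str = "top_k"  # top_k | threshold
    k: int = 4
    r_min: float | None = None
    seed: int = 0
    cv_folds: int = 5
    test_fraction: float = 0.20
    imputation_mode: str = "class_conditional"  # class_conditional | global
    logical_feature_set: str = "selected"  # selected | paper_literal
    fit_scope: str = "train_only"  # train_only | paper_literal
    standardize_before_fit: bool = True
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        if self.selected_feature_rule not in ("top_k", "threshold"):
            raise ValueError(f"unknown selection rule {self.selected_feature_rule!r}")
        if self.imputation_mode not in ("class_conditional", "global"):
            raise ValueError(f"unknown imputation mode {self.imputation_mode!r}")

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def replace(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def _map_outcome(values: pd.Series, path: str) -> pd.Series:
    """Map 0/1 integers or Yes/No text to the 0/1 integer convention."""
    if pd.api.types.is_numeric_dtype(values):
        return values.astype(int)
    mapped = values.astype(str).str.strip().str.lower().map(_OUTCOME_TEXT)
    if mapped.isna().any():
        row = int(mapped.index[mapped.isna()][0])
        raise ParseError(
            f"{path}: unrecognised outcome value {values.iloc[row]!r} at row {row}"
        )
    return mapped.astype(int)


def read_table(
    path: str | Path,
    outcome_col: str = OUTCOME_COLUMN,
) -> FeatureTable:
    """Read a PIMA-layout CSV into a :class:`FeatureTable`.

    The eight canonical features present in the file are reordered into
    the canonical F1..F8 order; any extra columns follow in file order.
    The outcome is accepted as {0,1} integers or {"Yes","No"} text.
    """
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"no such file: {path}")
    try:
        # round_trip parsing so write_table -> read_table is bit-exact
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, expected a header row") from exc
    if frame.empty and frame.columns.empty:
        raise SchemaError(f"{path}: empty file, expected a header row")
    if outcome_col not in frame.columns:
        raise SchemaError(
            f"{path}: outcome column {outcome_col!r} not found "
            f"(columns: {list(frame.columns)})"
        )
    outcome = _map_outcome(frame[outcome_col], str(path))
    feats = frame.drop(columns=[outcome_col])
    for col in feats.columns:
        coerced = pd.to_numeric(feats[col], errors="coerce")
        bad = coerced.isna() & feats[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {feats[col].iloc[row]!r} "
                f"in column {col!r}, row {row}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ParseError(f"{path}: empty cell in column {col!r}, row {row}")
        feats[col] = coerced
    canonical = [c for c in PIMA_FEATURES if c in feats.columns]
    extras = [c for c in feats.columns if c not in PIMA_FEATURES]
    table = FeatureTable(feats[canonical + extras], outcome, provenance=f"loaded:{path.name}")
    logger.info("[io] loaded %s: %d rows, %d feature columns", path.name, table.n_rows, table.n_features)
    return table


def write_table(table: FeatureTable, path: str | Path) -> None:
    """Write the table as CSV (header + one row per record).

    Values are serialised with pandas' shortest round-trip float
    format, so ``read_table(write_table(t))`` reproduces every numeric
    value exactly.
    """
    frame = table.to_frame()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False)
    logger.info("[io] wrote %s: %d rows, %d columns", path, len(frame), frame.shape[1])


@dataclass
class ValidationReport:
    """Report-only schema check: never mutates the table."""

    out_of_range: dict[str, int] = field(default_factory=dict)
    zero_designated: dict[str, int] = field(default_factory=dict)
    missing: dict[str, int] = field(default_factory=dict)

    @property
    def is_clean(self) -> bool:
        return not (
            any(self.out_of_range.values())
            or any(self.zero_designated.values())
            or any(self.missing.values())
        )

    def to_dict(self) -> dict:
        return {
            "out_of_range": dict(self.out_of_range),
            "zero_designated": dict(self.zero_designated),
            "missing": dict(self.missing),
        }

    def __str__(self) -> str:
        if self.is_clean:
            return "schema OK: no out-of-range, designated-missing or NaN cells"
        lines = []
        for col, n in self.out_of_range.items():
            if n:
                lo, hi = VALID_RANGES[col]
                lines.append(f"{col}: {n} values outside [{lo}, {hi}]")
        for col, n in self.zero_designated.items():
            if n:
                lines.append(f"{col}: {n} zeros designated as missing measurements")
        for col, n in self.missing.items():
            if n:
                lines.append(f"{col}: {n} NaN cells")
        return "\n".join(lines)


def validate_schema(
    table: FeatureTable,
    zero_is_missing: Iterable[str] = DEFAULT_ZERO_MISSING,
    valid_ranges: Mapping[str, tuple[float, float]] | None = None,
) -> ValidationReport:
    """Count per-column out-of-range and missing-designated cells.

    Zeros in ``zero_is_missing`` columns are exempt from the range
    check (they are sentinels, not measurements).
    """
    ranges = VALID_RANGES if valid_ranges is None else valid_ranges
    zset = set(zero_is_missing)
    report = ValidationReport()
    for col in table.feature_names:
        values = table.features[col]
        report.missing[col] = int(values.isna().sum())
        observed = values.dropna()
        if col in zset:
            report.zero_designated[col] = int((observed == 0).sum())
            observed = observed[observed != 0]
        if col in ranges:
            lo, hi = ranges[col]
            report.out_of_range[col] = int(((observed < lo) | (observed > hi)).sum())
    return report
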