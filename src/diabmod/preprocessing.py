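"""Missing-value designation, mean imputation and standardization.

Zeros in clinically impossible columns (glucose, blood pressure, skin
thickness, insulin, BMI) encode unrecorded measurements.  They are
first designated as missing (NaN) and then replaced by the mean of the
observed values of that column — by default within the row's outcome
class (class-conditional mean imputation), optionally with a single
global column mean.

Replacement means can be fitted on one partition (the training fold)
and applied to another, so cross-validation never lets validation rows
influence the imputed values.  Note that applying a class-conditional
plan requires the outcome of the rows being imputed; this mirrors the
construction of the original protocol, where imputation precedes any
split, and is documented as a limitation for deployment-style use.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .errors import NoDonorError
from .io import DEFAULT_ZERO_MISSING, FeatureTable

if TYPE_CHECKING:  # pragma: no cover
    from .modeling import FeatureStats

logger = logging.getLogger("diabmod")


@dataclass
class ImputationPlan:
    """Which zeros are missing and what replaces them.

    ``replacements[col]`` maps an outcome class (0/1, or ``None`` in
    global mode) to the fitted replacement mean.  Replacement values
    are computed only from observed (non-missing) entries.
    """

    zero_is_missing: tuple[str, ...] = DEFAULT_ZERO_MISSING
    mode: str = "class_conditional"  # class_conditional | global
    replacements: dict[str, dict[int | None, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("class_conditional", "global"):
            raise ValueError(f"unknown imputation mode {self.mode!r}")

    @property
    def is_fitted(self) -> bool:
        return bool(self.replacements)

    @classmethod
    def default_for(
        cls, table: FeatureTable, mode: str = "class_conditional"
    ) -> "ImputationPlan":
        """Default plan restricted to the flaggable columns actually
        present in ``table``."""
        cols = tuple(c for c in DEFAULT_ZERO_MISSING if c in table.feature_names)
        return cls(cols, mode)


def designate_missing(table: FeatureTable, plan: ImputationPlan) -> FeatureTable:
    """Mark zeros in the plan's flagged columns as missing (NaN).

    Unflagged columns are untouched.  Flagging ``Pregnancies`` is
    allowed but warned against: zero pregnancies is physiologic.
    """
    unknown = set(plan.zero_is_missing) - set(table.feature_names)
    if unknown:
        raise KeyError(f"plan flags columns not in the table: {sorted(unknown)}")
    if "Pregnancies" in plan.zero_is_missing:
        warnings.warn(
            "flagging zeros in 'Pregnancies' as missing: zero is a valid count",
            UserWarning,
            stacklevel=2,
        )
    feats = table.features.copy()
    n_marked = {}
    for col in plan.zero_is_missing:
        mask = feats[col] == 0
        n_marked[col] = int(mask.sum())
        feats.loc[mask, col] = np.nan
    logger.info("[preprocess] designated missing: %s", n_marked)
    return table.with_features(feats, provenance="designated")


def fit_imputation(table: FeatureTable, plan: ImputationPlan) -> ImputationPlan:
    """Fit replacement means from the observed cells of ``table``.

    Returns a new plan carrying the fitted values.  Raises
    :class:`NoDonorError` when a flagged column has no observed value
    in some outcome class (class-conditional mode) or at all.
    """
    replacements: dict[str, dict[int | None, float]] = {}
    for col in plan.zero_is_missing:
        values = table.features[col]
        observed = values.notna()
        per_col: dict[int | None, float] = {}
        if plan.mode == "class_conditional":
            for cls in sorted(table.outcome.unique()):
                donors = values[observed & (table.outcome == cls)]
                if donors.empty:
                    raise NoDonorError(
                        f"no observed donor values for column {col!r}, class {cls}"
                    )
                per_col[int(cls)] = float(donors.mean())
        else:
            donors = values[observed]
            if donors.empty:
                raise NoDonorError(f"no observed donor values for column {col!r}")
            per_col[None] = float(donors.mean())
        replacements[col] = per_col
    return ImputationPlan(plan.zero_is_missing, plan.mode, replacements)


def impute(table: FeatureTable, plan: ImputationPlan) -> FeatureTable:
    """Replace missing cells by the fitted (or self-fitted) means.

    If the plan carries no fitted replacements they are computed from
    ``table`` itself.  Non-missing cells are never changed, and the
    operation is idempotent.
    """
    fitted = plan if plan.is_fitted else fit_imputation(table, plan)
    feats = table.features.copy()
    n_filled = {}
    for col, per_class in fitted.replacements.items():
        missing = feats[col].isna()
        n_filled[col] = int(missing.sum())
        if not missing.any():
            continue
        if fitted.mode == "class_conditional":
            unseen = set(table.outcome[missing].unique()) - set(per_class)
            if unseen:
                raise NoDonorError(
                    f"no fitted replacement for column {col!r}, class(es) {sorted(unseen)}"
                )
            for cls, value in per_class.items():
                sel = missing & (table.outcome == cls).to_numpy()
                feats.loc[sel, col] = value
        else:
            feats.loc[missing, col] = per_class[None]
    logger.info("[preprocess] imputed cells: %s", n_filled)
    return table.with_features(feats, provenance="imputed")


def preprocess(
    table: FeatureTable, plan: ImputationPlan | None = None
) -> tuple[FeatureTable, ImputationPlan]:
    """designate -> fit -> impute in one step; returns the fitted plan."""
    plan = plan or ImputationPlan.default_for(table)
    designated = designate_missing(table, plan)
    fitted = plan if plan.is_fitted else fit_imputation(designated, plan)
    return impute(designated, fitted), fitted


def standardize(table: FeatureTable, stats: "FeatureStats") -> FeatureTable:
    """Scale each covered column to zero mean / unit variance.

    Uses the supplied statistics (fitted by the caller, typically on a
    training partition, to avoid leakage).  Columns the stats do not
    cover are left untouched; a zero-SD column is centred only, with a
    warning.
    """
    feats = table.features.copy()
    for col in stats.columns:
        if col not in feats.columns:
            raise KeyError(f"statistics cover column {col!r} absent from the table")
        mean = stats.mean(col)
        sd = stats.sd(col)
        if sd == 0:
            warnings.warn(
                f"column {col!r} has zero SD; centering only", UserWarning, stacklevel=2
            )
            feats[col] = feats[col] - mean
        else:
            feats[col] = (feats[col] - mean) / sd
    return table.with_features(feats, provenance="standardized")
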