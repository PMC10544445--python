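"""The correlation-based data-modeling framework.

Three stages expand a clinical feature table:

1. *Statistical*: per-feature mean (F̄), median (FM) and population
   standard deviation (σ, divisor N) are computed on the preprocessed
   values.
2. *Relative*: for each feature selected by its point-biserial
   correlation with the outcome, three absolute-deviation columns are
   added — ``MVR = |x − F̄|``, ``MDR = |x − FM|``, ``SDR = |x − σ|``.
   With the default four selected features an 8-column table becomes a
   20-column table.
3. *Logical*: each deviation column is binarized — ``LFM = [MVR > 0]``,
   ``LFMD = [MDR > 0]``, ``LFSD = [SDR > mean(SDR)]`` with strict
   inequalities (ties map to 0) — growing the table to 32 columns.

Note that SDR is the absolute deviation of the value from the standard
deviation *itself* (not a z-score), and that LFM/LFMD, being indicators
of a nonnegative quantity exceeding zero, are near-constant columns on
continuous data; both behaviours are implemented verbatim and a warning
is emitted when a logical column comes out constant.

Derived columns follow the naming contract
``<feature>__<MVR|MDR|SDR|LFM|LFMD|LFSD>``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import FeatureTable, RunConfig
from .preprocessing import ImputationPlan, designate_missing, fit_imputation, impute

logger = logging.getLogger("diabmod")

RELATIVE_SUFFIXES = ("MVR", "MDR", "SDR")
LOGICAL_SUFFIXES = ("LFM", "LFMD", "LFSD")
#: The restricted feature set named by the logical-stage equations.
PAPER_LITERAL_LOGICAL = ("Glucose", "BMI", "Age")


def derived_name(feature: str, suffix: str) -> str:
    return f"{feature}__{suffix}"


@dataclass
class FeatureStats:
    """Per-feature mean / median / SD triple.

    SD uses the population convention (divisor N) unless ``ddof`` was
    set at fit time; the fold-summary statistics elsewhere in the
    package use the sample convention (divisor n−1) instead.
    """

    frame: pd.DataFrame  # index: feature, columns: mean, median, sd, n
    ddof: int = 0

    @property
    def columns(self) -> list[str]:
        return list(self.frame.index)

    def mean(self, col: str) -> float:
        return float(self.frame.at[col, "mean"])

    def median(self, col: str) -> float:
        return float(self.frame.at[col, "median"])

    def sd(self, col: str) -> float:
        return float(self.frame.at[col, "sd"])

    @classmethod
    def from_values(
        cls, values: Mapping[str, tuple[float, float, float]], n: int = 0
    ) -> "FeatureStats":
        """Build from explicit (mean, median, sd) triples, e.g. printed
        reference statistics."""
        frame = pd.DataFrame(
            {c: {"mean": m, "median": md, "sd": sd} for c, (m, md, sd) in values.items()}
        ).T
        frame["n"] = n
        return cls(frame)


def compute_stats(
    table: FeatureTable, columns: Sequence[str] | None = None, ddof: int = 0
) -> FeatureStats:
    """Mean, median and SD (divisor N by default) per feature column."""
    cols = list(columns) if columns is not None else table.feature_names
    rows = {}
    for col in cols:
        values = table.features[col].to_numpy()
        if values.size == 0:
            raise ValueError(f"column {col!r} is empty")
        if np.isnan(values).any():
            raise ValueError(f"column {col!r} contains missing values; impute first")
        rows[col] = {
            "mean": float(values.mean()),
            "median": float(np.median(values)),
            "sd": float(values.std(ddof=ddof)),
            "n": values.size,
        }
    return FeatureStats(pd.DataFrame(rows).T, ddof=ddof)


@dataclass
class CorrelationReport:
    """Point-biserial correlation of each feature with the outcome."""

    r: pd.Series  # indexed by feature, table order
    selected: tuple[str, ...] = ()
    rule: str = ""

    def ranked(self) -> list[str]:
        """Features by descending |r|; ties broken by table order."""
        order = np.argsort(-np.abs(self.r.to_numpy()), kind="stable")
        return [self.r.index[i] for i in order]


def correlate_with_outcome(
    table: FeatureTable, columns: Sequence[str] | None = None
) -> CorrelationReport:
    """Pearson correlation of each (continuous) feature with the 0/1
    outcome — the point-biserial correlation."""
    y = table.outcome.to_numpy().astype(float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    cols = list(columns) if columns is not None else table.feature_names
    r = {}
    for col in cols:
        x = table.features[col].to_numpy()
        if np.isnan(x).any():
            raise ValueError(f"column {col!r} contains missing values; impute first")
        if x.std() == 0:
            warnings.warn(
                f"column {col!r} has zero variance; correlation reported as 0",
                UserWarning,
                stacklevel=2,
            )
            r[col] = 0.0
        else:
            r[col] = float(np.corrcoef(x, y)[0, 1])
    return CorrelationReport(pd.Series(r))


def select_features(
    report: CorrelationReport,
    rule: str = "top_k",
    k: int = 4,
    r_min: float | None = None,
) -> tuple[str, ...]:
    """Deterministic feature subset by correlation strength.

    ``top_k`` keeps the k features with largest |r|; ``threshold``
    keeps every feature with |r| >= r_min.  Ties are broken by the
    table's canonical column order.
    """
    ranked = report.ranked()
    if rule == "top_k":
        if k > len(ranked):
            raise ValueError(f"k={k} exceeds the {len(ranked)} available features")
        chosen = tuple(ranked[:k])
    elif rule == "threshold":
        if r_min is None:
            raise ValueError("threshold rule requires r_min")
        chosen = tuple(c for c in ranked if abs(report.r[c]) >= r_min)
        if not chosen:
            warnings.warn(
                f"no feature reaches |r| >= {r_min}; downstream stages are a no-op",
                UserWarning,
                stacklevel=2,
            )
    else:
        raise ValueError(f"unknown selection rule {rule!r}")
    report.selected = chosen
    report.rule = rule
    return chosen


@dataclass
class TransformedTable(FeatureTable):
    """A FeatureTable augmented with relative/logical columns.

    Carries the stage tag, the selected-feature subset and the SDR
    column means used as the LFSD binarization thresholds.
    """

    stage: str = "relative"
    selected: tuple[str, ...] = ()
    sdr_thresholds: dict[str, float] = field(default_factory=dict)


def relative_transform(
    table: FeatureTable, stats: FeatureStats, selected: Sequence[str]
) -> TransformedTable:
    """Append the absolute-deviation columns for each selected feature.

    Each selected feature contributes ``__MVR = |x − mean|``,
    ``__MDR = |x − median|`` and ``__SDR = |x − sd|``; the original
    columns are retained, so k selected features turn an 8-column
    table into an 8+3k-column one.
    """
    missing = [c for c in selected if c not in stats.columns]
    if missing:
        raise KeyError(f"selected features missing from statistics: {missing}")
    feats = table.features.copy()
    for col in selected:
        x = feats[col]
        feats[derived_name(col, "MVR")] = (x - stats.mean(col)).abs()
        feats[derived_name(col, "MDR")] = (x - stats.median(col)).abs()
        feats[derived_name(col, "SDR")] = (x - stats.sd(col)).abs()
    return TransformedTable(
        feats,
        table.outcome.copy(),
        provenance="relative",
        stage="relative",
        selected=tuple(selected),
    )


def sdr_thresholds(table: TransformedTable, features: Sequence[str] | None = None) -> dict[str, float]:
    """Mean of each ``__SDR`` column — the LFSD binarization threshold."""
    feats = features if features is not None else table.selected
    out = {}
    for col in feats:
        name = derived_name(col, "SDR")
        if name not in table.features.columns:
            raise KeyError(f"missing column {name!r}: apply the relative stage first")
        out[col] = float(table.features[name].mean())
    return out


def logical_transform(
    table: TransformedTable,
    thresholds: Mapping[str, float] | None = None,
    features: Sequence[str] | None = None,
) -> TransformedTable:
    """Binarize the deviation columns into 0/1 logical features.

    ``LFM``/``LFMD`` indicate a strictly positive mean/median
    deviation; ``LFSD`` indicates an SDR strictly above the supplied
    threshold (the mean of that SDR column on the fitting partition).
    Ties map to 0.
    """
    feats_list = list(features) if features is not None else list(table.selected)
    thr = dict(thresholds) if thresholds is not None else sdr_thresholds(table, feats_list)
    feats = table.features.copy()
    for col in feats_list:
        for src_suffix, dst_suffix, cutoff in (
            ("MVR", "LFM", 0.0),
            ("MDR", "LFMD", 0.0),
            ("SDR", "LFSD", thr[col]),
        ):
            src = derived_name(col, src_suffix)
            if src not in feats.columns:
                raise KeyError(f"missing column {src!r}: apply the relative stage first")
            binary = (feats[src] > cutoff).astype(float)
            name = derived_name(col, dst_suffix)
            feats[name] = binary
            if binary.nunique() == 1:
                warnings.warn(
                    f"logical column {name!r} is constant ({binary.iloc[0]:.0f})",
                    UserWarning,
                    stacklevel=2,
                )
    return TransformedTable(
        feats,
        table.outcome.copy(),
        provenance="logical",
        stage="logical",
        selected=table.selected,
        sdr_thresholds=thr,
    )


@dataclass
class FittedFramework:
    """All statistics the framework fits on one partition.

    ``transform`` re-applies them to any table with the same base
    layout, so cross-validation can fit on a training fold and map a
    validation fold without re-estimating anything.
    """

    plan: ImputationPlan
    stats: FeatureStats
    report: CorrelationReport
    selected: tuple[str, ...]
    thresholds: dict[str, float]
    logical_features: tuple[str, ...]
    config: RunConfig

    def transform(self, table: FeatureTable, stage: str = "logical") -> TransformedTable:
        if stage not in ("relative", "logical"):
            raise ValueError(f"unknown stage {stage!r}")
        clean = impute(designate_missing(table, self.plan), self.plan)
        if not self.selected:
            return TransformedTable(
                clean.features, clean.outcome, provenance=stage, stage=stage, selected=()
            )
        rel = relative_transform(clean, self.stats, self.selected)
        if stage == "relative":
            return rel
        return logical_transform(rel, self.thresholds, self.logical_features)

    def provenance(self) -> dict:
        """JSON-serializable record of everything that was fitted."""
        return {
            "imputation": {
                "mode": self.plan.mode,
                "zero_is_missing": list(self.plan.zero_is_missing),
                "replacements": {
                    col: {str(k): v for k, v in per.items()}
                    for col, per in self.plan.replacements.items()
                },
            },
            "stats": self.stats.frame.to_dict(orient="index"),
            "correlations": self.report.r.to_dict(),
            "selected": list(self.selected),
            "selection_rule": self.report.rule,
            "lfsd_thresholds": dict(self.thresholds),
            "logical_features": list(self.logical_features),
        }


def fit_framework(table: FeatureTable, config: RunConfig | None = None) -> FittedFramework:
    """Fit every stage of the framework on ``table``.

    Fitting order: impute -> per-feature statistics -> correlation with
    the outcome -> feature selection -> SDR thresholds on the imputed
    fitting data.
    """
    config = config or RunConfig()
    plan = ImputationPlan.default_for(table, config.imputation_mode)
    designated = designate_missing(table, plan)
    plan = fit_imputation(designated, plan)
    clean = impute(designated, plan)
    base_cols = [c for c in clean.feature_names if "__" not in c]
    stats = compute_stats(clean, columns=base_cols)
    report = correlate_with_outcome(clean, columns=base_cols)
    selected = select_features(
        report, rule=config.selected_feature_rule, k=config.k, r_min=config.r_min
    )
    if config.logical_feature_set == "paper_literal":
        logical_features = tuple(c for c in selected if c in PAPER_LITERAL_LOGICAL)
    else:
        logical_features = selected
    thresholds: dict[str, float] = {}
    if selected:
        rel = relative_transform(clean, stats, selected)
        thresholds = sdr_thresholds(rel, selected)
    logger.info(
        "[modeling] fitted framework: selected=%s thresholds=%s", selected, thresholds
    )
    return FittedFramework(plan, stats, report, selected, thresholds, logical_features, config)


def apply_framework(
    table: FeatureTable, config: RunConfig | None = None, stage: str = "logical"
) -> TransformedTable:
    """Fit the framework on ``table`` and transform it in place.

    This is the single-table (non-cross-validated) entry point: the
    statistics, correlations, selection and thresholds all come from
    ``table`` itself.
    """
    fitted = fit_framework(table, config)
    out = fitted.transform(table, stage=stage)
    out.sdr_thresholds = dict(fitted.thresholds)
    return out
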