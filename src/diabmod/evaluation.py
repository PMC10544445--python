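"""Experiment harness: splitting, cross-validation and metrics.

The evaluation protocol holds out a stratified 20% test partition and
runs stratified 5-fold cross-validation inside the remaining 80%
training partition.  Within every fold the whole pipeline — missing
value imputation, the data-modeling transforms and standardization —
is fitted on the fold's training part only and applied to its
validation part, so fold metrics are leakage-free.  The positive class
is outcome = 1 (diabetic) for all asymmetric metrics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .io import FeatureTable, RunConfig
from .modeling import (
    LOGICAL_SUFFIXES,
    FittedFramework,
    compute_stats,
    fit_framework,
)
from .preprocessing import (
    ImputationPlan,
    designate_missing,
    fit_imputation,
    impute,
    standardize,
)

logger = logging.getLogger("diabmod")


# ---------------------------------------------------------------------------
# classifier plug-ins
# ---------------------------------------------------------------------------

@dataclass
class ClassifierSpec:
    """A named, seedable classifier plug-in.

    ``factory(seed)`` must return an object with sklearn's
    ``fit``/``predict`` contract; ``predict_proba`` or
    ``decision_function`` is used for ROC scores when available,
    otherwise predicted labels stand in (degenerate ROC, warned).
    """

    name: str
    factory: Callable[[int], object]


def _make_registry() -> dict[str, ClassifierSpec]:
    return {
        "logreg": ClassifierSpec(
            "logreg", lambda seed: LogisticRegression(max_iter=2000, random_state=seed)
        ),
        "rf": ClassifierSpec(
            "rf",
            lambda seed: RandomForestClassifier(n_estimators=200, random_state=seed),
        ),
        "svm_linear": ClassifierSpec(
            "svm_linear", lambda seed: SVC(kernel="linear", random_state=seed)
        ),
        "svm_rbf": ClassifierSpec(
            "svm_rbf", lambda seed: SVC(kernel="rbf", random_state=seed)
        ),
        "mlp": ClassifierSpec(
            "mlp",
            lambda seed: MLPClassifier(
                hidden_layer_sizes=(16,), max_iter=800, random_state=seed
            ),
        ),
    }


CLASSIFIERS: dict[str, ClassifierSpec] = _make_registry()


def get_classifier(name_or_spec: str | ClassifierSpec) -> ClassifierSpec:
    if isinstance(name_or_spec, ClassifierSpec):
        return name_or_spec
    try:
        return CLASSIFIERS[name_or_spec]
    except KeyError:
        raise KeyError(
            f"unknown classifier {name_or_spec!r}; available: {sorted(CLASSIFIERS)}"
        ) from None


# ---------------------------------------------------------------------------
# splitting
# ---------------------------------------------------------------------------

def stratified_split(
    table: FeatureTable, test_fraction: float, seed: int
) -> tuple[FeatureTable, FeatureTable]:
    """Exact stratified partition into training and test tables."""
    y = table.outcome.to_numpy()
    counts = np.bincount(y, minlength=2)
    if counts.min() < 2:
        raise ValueError(f"each class needs >= 2 rows (counts: {counts.tolist()})")
    idx = np.arange(table.n_rows)
    train_idx, test_idx = train_test_split(
        idx, test_size=test_fraction, stratify=y, random_state=seed
    )
    return table.take(np.sort(train_idx)), table.take(np.sort(test_idx))


def kfold_indices(table: FeatureTable, folds: int, seed: int) -> np.ndarray:
    """Stratified fold assignment (0..folds-1) per row.

    Fold sizes differ by at most one and each fold's class ratio stays
    within one row of the global ratio.
    """
    if folds > table.n_rows:
        raise ValueError(f"{folds} folds exceed {table.n_rows} rows")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    assignment = np.empty(table.n_rows, dtype=int)
    X_dummy = np.zeros((table.n_rows, 1))
    for fold, (_, val_idx) in enumerate(skf.split(X_dummy, table.outcome.to_numpy())):
        assignment[val_idx] = fold
    return assignment


# ---------------------------------------------------------------------------
# confusion matrix and metrics
# ---------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __str__(self) -> str:
        w = max(len(str(v)) for v in (self.tp, self.tn, self.fp, self.fn))
        return (
            "              predicted\n"
            "             pos    neg\n"
            f"actual pos  {self.tp:>{w + 3}}  {self.fn:>{w + 3}}\n"
            f"actual neg  {self.fp:>{w + 3}}  {self.tn:>{w + 3}}"
        )


def confusion(true_labels: Sequence[int], predicted_labels: Sequence[int]) -> ConfusionMatrix:
    """Count TP/TN/FP/FN with positive class = 1 (diabetic)."""
    y = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if not (np.isin(y, (0, 1)).all() and np.isin(p, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    return ConfusionMatrix(
        tp=int(((y == 1) & (p == 1)).sum()),
        tn=int(((y == 0) & (p == 0)).sum()),
        fp=int(((y == 0) & (p == 1)).sum()),
        fn=int(((y == 1) & (p == 0)).sum()),
    )


METRIC_NAMES = (
    "accuracy",
    "sensitivity",
    "specificity",
    "precision",
    "f_measure",
    "fpr",
    "fnr",
    "mcc",
    "roc_area",
)


@dataclass
class MetricSet:
    """Confusion-matrix metric suite (proportions in [0, 1])."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f_measure: float
    fpr: float
    fnr: float
    mcc: float
    roc_area: float | None = None

    def as_dict(self) -> dict[str, float | None]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, reported as 0", UserWarning, stacklevel=3)
        return 0.0
    return num / den


def metrics(
    cm: ConfusionMatrix,
    true_labels: Sequence[int] | None = None,
    scores: Sequence[float] | None = None,
) -> MetricSet:
    """Derive the metric suite from a confusion matrix.

    accuracy = (TP+TN)/total, sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP), precision = TP/(TP+FP),
    F = 2·precision·recall/(precision+recall), plus FPR, FNR and the
    Matthews correlation coefficient.  ROC area is the rank-based
    (Mann-Whitney) area when real-valued scores are supplied.  Any
    zero-denominator metric is reported as 0 with a warning, never NaN.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    tp, tn, fp, fn = cm.tp, cm.tn, cm.fp, cm.fn
    acc = (tp + tn) / cm.total
    sens = _safe_div(tp, tp + fn, "sensitivity")
    spec = _safe_div(tn, tn + fp, "specificity")
    prec = _safe_div(tp, tp + fp, "precision")
    f_meas = _safe_div(2 * prec * sens, prec + sens, "f_measure")
    fpr = _safe_div(fp, fp + tn, "fpr")
    fnr = _safe_div(fn, fn + tp, "fnr")
    mcc_den = np.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "mcc")
    roc = None
    if scores is not None:
        if true_labels is None:
            raise ValueError("ROC area needs true labels alongside scores")
        y = np.asarray(true_labels)
        if len(np.unique(y)) < 2:
            warnings.warn(
                "ROC area undefined with a single class present; omitted",
                UserWarning,
                stacklevel=2,
            )
        else:
            roc = float(roc_auc_score(y, np.asarray(scores, dtype=float)))
    return MetricSet(acc, sens, spec, prec, f_meas, fpr, fnr, float(mcc), roc)


@dataclass
class CVResult:
    """Per-fold metrics plus mean and sample SD (divisor n−1)."""

    folds: pd.DataFrame  # rows: fold index, columns: metrics
    mean: pd.Series
    sd: pd.Series

    @classmethod
    def from_metric_sets(cls, fold_metrics: Sequence[MetricSet]) -> "CVResult":
        frame = pd.DataFrame([m.as_dict() for m in fold_metrics], dtype=float)
        frame.index.name = "fold"
        return cls(frame, frame.mean(), frame.std(ddof=1))

    def summary_frame(self) -> pd.DataFrame:
        out = self.folds.T.copy()
        out.columns = [f"fold_{i + 1}" for i in range(out.shape[1])]
        out["mean"] = self.mean
        out["sd"] = self.sd
        return out


def aggregate_cv(fold_metrics: Sequence[MetricSet]) -> CVResult:
    """Aggregate fold metrics: arithmetic mean and sample SD (n−1)."""
    if len(fold_metrics) < 2:
        raise ValueError("need at least 2 folds to aggregate")
    return CVResult.from_metric_sets(fold_metrics)


# ---------------------------------------------------------------------------
# experiment orchestration
# ---------------------------------------------------------------------------

def _feature_matrix(
    train: FeatureTable,
    others: Sequence[FeatureTable],
    standardize_features: bool,
) -> list[np.ndarray]:
    """Column-aligned design matrices; continuous columns standardized
    with training-partition statistics, binary logical columns left as
    0/1."""
    columns = train.feature_names
    continuous = [
        c for c in columns if not any(c.endswith(f"__{s}") for s in LOGICAL_SUFFIXES)
    ]
    tables = [train, *others]
    if standardize_features and continuous:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # constant-column centering
            scale_stats = compute_stats(train, columns=continuous)
            tables = [standardize(t, scale_stats) for t in tables]
    return [t.features[columns].to_numpy() for t in tables]


@dataclass
class _FittedPipeline:
    """Per-partition fit: imputation (+ optional modeling framework)."""

    plan: ImputationPlan
    framework: FittedFramework | None

    def transform(self, table: FeatureTable) -> FeatureTable:
        if self.framework is not None:
            return self.framework.transform(table, stage="logical")
        return impute(designate_missing(table, self.plan), self.plan)


def _fit_pipeline(
    fit_table: FeatureTable, config: RunConfig, with_modeling: bool
) -> _FittedPipeline:
    if with_modeling:
        fw = fit_framework(fit_table, config)
        return _FittedPipeline(fw.plan, fw)
    plan = ImputationPlan.default_for(fit_table, config.imputation_mode)
    plan = fit_imputation(designate_missing(fit_table, plan), plan)
    return _FittedPipeline(plan, None)


def _evaluate_fold(
    pipeline: _FittedPipeline,
    fit_table: FeatureTable,
    eval_table: FeatureTable,
    spec: ClassifierSpec,
    config: RunConfig,
) -> MetricSet:
    train_t = pipeline.transform(fit_table)
    eval_t = pipeline.transform(eval_table)
    X_train, X_eval = _feature_matrix(
        train_t, [eval_t], config.standardize_before_fit
    )
    clf = spec.factory(config.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        clf.fit(X_train, train_t.outcome.to_numpy())
    y_true = eval_t.outcome.to_numpy()
    y_pred = np.asarray(clf.predict(X_eval)).astype(int)
    if hasattr(clf, "predict_proba"):
        scores = clf.predict_proba(X_eval)[:, 1]
    elif hasattr(clf, "decision_function"):
        scores = clf.decision_function(X_eval)
    else:  # pragma: no cover - all shipped plug-ins expose one of the above
        warnings.warn(
            f"classifier {spec.name!r} has no scores; labels used (degenerate ROC)",
            UserWarning,
            stacklevel=2,
        )
        scores = y_pred.astype(float)
    return metrics(confusion(y_true, y_pred), y_true, scores)


@dataclass
class ExperimentResult:
    """Cross-validated and held-out-test performance of one pipeline."""

    cv: CVResult
    test: MetricSet
    fold_accuracies: np.ndarray  # percent, one per fold
    n_features_seen: int
    manifest: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "cv": {
                "folds": self.cv.folds.to_dict(orient="records"),
                "mean": self.cv.mean.to_dict(),
                "sd": self.cv.sd.to_dict(),
            },
            "test": self.test.as_dict(),
            "fold_accuracies_percent": [float(a) for a in self.fold_accuracies],
            "n_features_seen": self.n_features_seen,
            "manifest": self.manifest,
        }


def run_experiment(
    table: FeatureTable,
    classifier: str | ClassifierSpec,
    config: RunConfig | None = None,
    with_modeling: bool = True,
) -> ExperimentResult:
    """Run the full evaluation protocol for one pipeline variant.

    A stratified ``test_fraction`` partition is held out; stratified
    k-fold cross-validation runs inside the training partition with
    the pipeline (imputation, optional data-modeling framework,
    standardization) refitted on each fold's training part.  With
    ``config.fit_scope == "paper_literal"`` the framework and
    imputation means are instead fitted once on the full table before
    splitting (replication mode, leaky by construction).
    """
    config = config or RunConfig()
    spec = get_classifier(classifier)

    global_pipeline: _FittedPipeline | None = None
    if config.fit_scope == "paper_literal":
        global_pipeline = _fit_pipeline(table, config, with_modeling)

    train, test = stratified_split(table, config.test_fraction, config.seed)
    assignment = kfold_indices(train, config.cv_folds, config.seed)

    fold_metrics: list[MetricSet] = []
    for fold in range(config.cv_folds):
        fit_part = train.take(np.flatnonzero(assignment != fold))
        val_part = train.take(np.flatnonzero(assignment == fold))
        try:
            pipeline = global_pipeline or _fit_pipeline(fit_part, config, with_modeling)
            fold_metrics.append(
                _evaluate_fold(pipeline, fit_part, val_part, spec, config)
            )
        except Exception as exc:
            raise RuntimeError(f"fold {fold}: {exc}") from exc
    cv = aggregate_cv(fold_metrics)

    pipeline = global_pipeline or _fit_pipeline(train, config, with_modeling)
    test_metrics = _evaluate_fold(pipeline, train, test, spec, config)

    n_features = pipeline.transform(train).n_features
    manifest = {
        "classifier": spec.name,
        "with_modeling": with_modeling,
        "config": config.to_dict(),
        "rows": {"total": table.n_rows, "train": train.n_rows, "test": test.n_rows},
        "n_features_seen": n_features,
    }
    logger.info(
        "[evaluate] %s with_modeling=%s: cv acc %.3f±%.3f, test acc %.3f (%d features)",
        spec.name,
        with_modeling,
        cv.mean["accuracy"],
        cv.sd["accuracy"],
        test_metrics.accuracy,
        n_features,
    )
    return ExperimentResult(
        cv=cv,
        test=test_metrics,
        fold_accuracies=cv.folds["accuracy"].to_numpy() * 100.0,
        n_features_seen=n_features,
        manifest=manifest,
    )
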