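"""Model-style front end over the experiment harness.

Two small model classes mirror the fit/results idiom of statistical
modelling packages: construct from data, call ``fit()``, get a results
object with a ``summary()`` table.

``ModelingExperiment`` evaluates one pipeline variant (a classifier
with or without the data-modeling framework); ``PipelineComparison``
runs both variants on identical folds and paired-t tests the per-fold
accuracies.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .evaluation import ExperimentResult, run_experiment
from .io import FeatureTable, OUTCOME_COLUMN, RunConfig
from .stats import PipelineComparisonResult, compare_pipelines


def _table_from_frame(frame: pd.DataFrame, outcome_col: str = OUTCOME_COLUMN) -> FeatureTable:
    if outcome_col not in frame.columns:
        raise KeyError(f"outcome column {outcome_col!r} not in frame")
    return FeatureTable(
        frame.drop(columns=[outcome_col]), frame[outcome_col], provenance="frame"
    )


@dataclass
class ModelingExperimentResults:
    """Results wrapper: per-fold metrics, aggregates, held-out test."""

    result: ExperimentResult

    @property
    def cv(self):
        return self.result.cv

    @property
    def test(self):
        return self.result.test

    @property
    def fold_accuracies(self):
        return self.result.fold_accuracies

    def summary(self) -> str:
        man = self.result.manifest
        frame = self.result.cv.summary_frame()
        lines = [
            "Cross-validated pipeline evaluation",
            "=" * 60,
            f"classifier:        {man['classifier']}",
            f"data modeling:     {'on' if man['with_modeling'] else 'off'}",
            f"features seen:     {self.result.n_features_seen}",
            f"rows (train/test): {man['rows']['train']}/{man['rows']['test']}",
            "-" * 60,
            frame.to_string(float_format=lambda v: f"{v:.4f}"),
            "-" * 60,
            "held-out test: "
            + ", ".join(
                f"{k}={v:.4f}" for k, v in self.test.as_dict().items() if v is not None
            ),
        ]
        return "\n".join(lines)


class ModelingExperiment:
    """One pipeline variant as a fittable model.

    Parameters
    ----------
    table : FeatureTable
        The clinical table (features + binary outcome).
    classifier : str
        Registered plug-in name (``logreg``, ``rf``, ``svm_linear``,
        ``svm_rbf``, ``mlp``).
    config : RunConfig, optional
    with_modeling : bool
        Apply the correlation-based data-modeling framework inside
        each fold (default) or feed the classifier the raw features.
    """

    def __init__(
        self,
        table: FeatureTable,
        classifier: str = "rf",
        config: RunConfig | None = None,
        with_modeling: bool = True,
    ) -> None:
        self.table = table
        self.classifier = classifier
        self.config = config or RunConfig()
        self.with_modeling = with_modeling

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, outcome_col: str = OUTCOME_COLUMN, **kwargs
    ) -> "ModelingExperiment":
        return cls(_table_from_frame(frame, outcome_col), **kwargs)

    def fit(self) -> ModelingExperimentResults:
        return ModelingExperimentResults(
            run_experiment(self.table, self.classifier, self.config, self.with_modeling)
        )


@dataclass
class PipelineComparisonResults:
    """Paired-test results with a publication-style summary table."""

    result: PipelineComparisonResult
    classifier: str

    @property
    def paired(self):
        return self.result.test

    def summary(self) -> str:
        t = self.result.test
        name = f"{self.classifier} vs {self.classifier}-DM"
        lines = [
            "Paired t-test: data modeling on vs off",
            "=" * 72,
            t.summary(name),
            "-" * 72,
            f"fold accuracies with modeling (%):    "
            + ", ".join(f"{a:.2f}" for a in self.result.with_modeling.fold_accuracies),
            f"fold accuracies without modeling (%): "
            + ", ".join(f"{a:.2f}" for a in self.result.without_modeling.fold_accuracies),
            f"(t uses m*sqrt(n)/sigma; the as-printed ratio m/sigma is also shown)",
        ]
        return "\n".join(lines)


class PipelineComparison:
    """With- vs without-modeling comparison as a fittable model."""

    def __init__(
        self,
        table: FeatureTable,
        classifier: str = "rf",
        config: RunConfig | None = None,
    ) -> None:
        self.table = table
        self.classifier = classifier
        self.config = config or RunConfig()

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, outcome_col: str = OUTCOME_COLUMN, **kwargs
    ) -> "PipelineComparison":
        return cls(_table_from_frame(frame, outcome_col), **kwargs)

    def fit(self) -> PipelineComparisonResults:
        return PipelineComparisonResults(
            compare_pipelines(self.table, self.classifier, self.config),
            classifier=self.classifier,
        )
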