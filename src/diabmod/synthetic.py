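"""Synthetic PIMA-like tables with controlled class structure.

The generator emulates the layout and the gross statistical features
of the public PIMA Indians diabetes table that the pipeline assumes:
768 rows by default, class prevalence 268/768, class-conditional
Gaussian features truncated to each feature's valid clinical range,
and structural zero-inflation in the five columns whose zeros encode
unrecorded measurements (so the imputation rules are exercised).

Default class-conditional locations reflect the well-documented
direction of the class differences in this dataset — diabetic rows
have higher glucose, BMI, age and pregnancy counts — and the default
zero rates match the observed zero fractions (about 49% of insulin
and 30% of skin-thickness measurements unrecorded, a handful of
glucose/blood-pressure/BMI cells).  Higher moments, inter-feature
correlations and the exact marginals of the real table are *not*
reproduced; see the methods note for what that implies about test
coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .io import OUTCOME_COLUMN, PIMA_FEATURES, FeatureTable


@dataclass
class FeatureSpec:
    """Class-conditional truncated-Gaussian spec for one feature.

    ``mean``/``sd`` are (class-0, class-1) pairs; ``zero_rate`` is the
    probability a cell is overwritten with the structural-zero missing
    sentinel; ``decimals`` rounds values (0 = integer-valued feature,
    None = leave unrounded).
    """

    mean: tuple[float, float]
    sd: tuple[float, float]
    valid_range: tuple[float, float]
    zero_rate: float = 0.0
    decimals: int | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.zero_rate < 1:
            raise ValueError("zero_rate must lie in [0, 1)")
        if min(self.sd) <= 0:
            raise ValueError("SDs must be positive")
        lo, hi = self.valid_range
        for m, s in zip(self.mean, self.sd):
            if lo > m + 6 * s or hi < m - 6 * s:
                raise ValueError(
                    f"range [{lo}, {hi}] excludes mean ± 6 SD ({m} ± {6 * s})"
                )


def default_feature_specs() -> dict[str, FeatureSpec]:
    """PIMA-emulating defaults (clinical units; ranges as published)."""
    return {
        "Pregnancies": FeatureSpec((3.3, 4.9), (3.0, 3.7), (0, 17), 0.0, 0),
        "Glucose": FeatureSpec((110.0, 142.0), (25.0, 30.0), (0, 199), 0.007, 0),
        "BloodPressure": FeatureSpec((68.0, 71.0), (12.0, 12.5), (0, 122), 0.046, 0),
        "SkinThickness": FeatureSpec((20.0, 22.5), (9.0, 10.0), (0, 99), 0.30, 0),
        "Insulin": FeatureSpec((70.0, 100.0), (60.0, 80.0), (0, 846), 0.49, 0),
        "BMI": FeatureSpec((30.3, 35.1), (6.5, 6.5), (0, 67.1), 0.014, 1),
        "DiabetesPedigreeFunction": FeatureSpec(
            (0.43, 0.55), (0.27, 0.30), (0.08, 2.42), 0.0, 3
        ),
        "Age": FeatureSpec((31.2, 37.1), (11.0, 11.0), (21, 81), 0.0, 0),
    }


@dataclass
class SyntheticSpec:
    """Full generator specification; deterministic given ``seed``."""

    n: int = 768
    prevalence: float = 268 / 768
    features: dict[str, FeatureSpec] = field(default_factory=default_feature_specs)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.n < 2:
            raise ValueError("need at least 2 rows")

    def replace(self, **kwargs) -> "SyntheticSpec":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "prevalence": self.prevalence,
            "seed": self.seed,
            "features": {
                name: {
                    "mean": list(fs.mean),
                    "sd": list(fs.sd),
                    "valid_range": list(fs.valid_range),
                    "zero_rate": fs.zero_rate,
                    "decimals": fs.decimals,
                }
                for name, fs in self.features.items()
            },
        }


def truncated_class_mean(fs: FeatureSpec, cls: int) -> float:
    """Theoretical mean of the truncated sampling distribution — the
    oracle for moment-recovery checks (truncation shifts the mean away
    from the nominal location, e.g. for Age with its lower bound)."""
    m, s = fs.mean[cls], fs.sd[cls]
    lo, hi = fs.valid_range
    a, b = (lo - m) / s, (hi - m) / s
    return float(truncnorm.mean(a, b, loc=m, scale=s))


def _sample_feature(
    fs: FeatureSpec, labels: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    values = np.empty(labels.size)
    for cls in (0, 1):
        mask = labels == cls
        m, s = fs.mean[cls], fs.sd[cls]
        lo, hi = fs.valid_range
        a, b = (lo - m) / s, (hi - m) / s
        values[mask] = truncnorm.rvs(
            a, b, loc=m, scale=s, size=int(mask.sum()), random_state=rng
        )
    if fs.decimals is not None:
        values = np.round(values, fs.decimals)
        # rounding must not fabricate the structural-zero sentinel
        unit = 10.0 ** -fs.decimals
        if fs.valid_range[0] <= 0:
            values[values == 0] = unit
        values = np.clip(values, *fs.valid_range)
    if fs.zero_rate > 0:
        values[rng.random(labels.size) < fs.zero_rate] = 0.0
    return values


def generate(spec: SyntheticSpec | None = None, **overrides) -> FeatureTable:
    """Draw a PIMA-layout table from the spec.

    Labels are Bernoulli(prevalence); each feature is a
    class-conditional Gaussian truncated to its valid range, with
    structural zeros injected at the feature's ``zero_rate``.
    """
    spec = (spec or SyntheticSpec()).replace(**overrides) if overrides else (spec or SyntheticSpec())
    rng = np.random.default_rng(spec.seed)
    labels = rng.binomial(1, spec.prevalence, spec.n)
    if len(np.unique(labels)) < 2:  # pathological tiny-n draw
        labels[0], labels[-1] = 0, 1
    columns = {
        name: _sample_feature(fs, labels, rng) for name, fs in spec.features.items()
    }
    frame = pd.DataFrame(columns)
    ordered = [c for c in PIMA_FEATURES if c in frame.columns] + [
        c for c in frame.columns if c not in PIMA_FEATURES
    ]
    return FeatureTable(
        frame[ordered], pd.Series(labels, name=OUTCOME_COLUMN), provenance="synthetic"
    )


def worked_example_fixtures() -> dict:
    """Published worked-example anchor values for the reference dataset.

    Machine-readable copies of the printed reference numbers used as
    exact test anchors: the post-imputation BMI and glucose statistics,
    the BMI rows of the relative-stage worked example (value, MVR, MDR,
    SDR), the glucose rows (value, SDR and logical LFSD bit — the
    printed glucose MDR entries are mutually inconsistent and are not
    anchored), the five reference fold accuracies, and the published
    paired-test rows (m, σ_diff, printed t, critical value).
    """
    return {
        # post-imputation statistics: mean, median, population SD
        "bmi_stats": {"mean": 32.1942, "median": 32.0, "sd": 6.6210},
        "glucose_stats": {"mean": 119.1211, "median": 143.0, "sd": 29.8172},
        "bmi_examples": [
            {"value": 33.6, "mvr": 1.4058, "mdr": 1.6, "sdr": 26.979, "lfsd": 1},
            {"value": 26.6, "mvr": 5.5942, "mdr": 5.4, "sdr": 19.979, "lfsd": 0},
            {"value": 23.3, "mvr": 8.8942, "mdr": 8.7, "sdr": 16.679, "lfsd": 0},
            {"value": 28.1, "mvr": 4.0942, "mdr": 3.9, "sdr": 21.479, "lfsd": 0},
            {"value": 43.1, "mvr": 10.9058, "mdr": 11.1, "sdr": 36.479, "lfsd": 1},
            {"value": 25.6, "mvr": 6.5942, "mdr": 6.4, "sdr": 18.979, "lfsd": 0},
        ],
        "glucose_examples": [
            {"value": 148.0, "sdr": 118.1828, "lfsd": 1},
            {"value": 85.0, "sdr": 55.1828, "lfsd": 0},
            {"value": 183.0, "sdr": 153.1828, "lfsd": 1},
            {"value": 89.0, "sdr": 59.1828, "lfsd": 0},
            {"value": 137.0, "sdr": 107.1828, "lfsd": 1},
            {"value": 116.0, "sdr": 86.1828, "lfsd": 0},
        ],
        # reference 5-fold accuracies (percent) and their printed summary
        "fold_accuracies": [97.51, 97.28, 97.68, 95.94, 97.49],
        "fold_summary": {"mean": 97.181, "sd": 0.707},
        # published paired-test rows: m, sigma_diff, printed t, critical
        "paired_tests": {
            "MLP-NN": {"m": 4.020, "sigma_diff": 0.967, "t_printed": 4.1565},
            "SVM": {"m": 3.284, "sigma_diff": 0.379, "t_printed": 8.6645},
            "RF": {"m": 5.820, "sigma_diff": 0.491, "t_printed": 11.8450},
            "DeepCNN": {"m": 6.861, "sigma_diff": 0.393, "t_printed": 17.4469},
        },
        "t_critical": {"df": 4, "alpha": 0.05, "value": 2.776},
    }
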