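import numpy as np
import pandas as pd
import pytest

from diabmod import FeatureTable, SyntheticSpec, generate, worked_example_fixtures


@pytest.fixture(scope="session")
def anchors():
    """Published worked-example anchor values."""
    return worked_example_fixtures()


@pytest.fixture(scope="session")
def pima_like():
    """Default-spec synthetic table (768 rows, PIMA layout)."""
    return generate(SyntheticSpec(seed=42))


@pytest.fixture()
def tiny_table():
    """Hand-built 6-row table with known zeros for imputation checks."""
    feats = pd.DataFrame(
        {
            "Pregnancies": [0, 2, 4, 1, 0, 3],
            "Glucose": [148, 0, 183, 90, 110, 0],
            "BloodPressure": [72, 66, 64, 70, 0, 74],
            "SkinThickness": [35, 29, 0, 23, 30, 32],
            "Insulin": [0, 0, 0, 94, 168, 88],
            "BMI": [33.6, 26.6, 23.3, 28.1, 43.1, 25.6],
            "DiabetesPedigreeFunction": [0.627, 0.351, 0.672, 0.167, 2.288, 0.201],
            "Age": [50, 31, 32, 21, 33, 30],
        }
    )
    return FeatureTable(feats, pd.Series([1, 0, 1, 0, 1, 0]))


def random_table(rng: np.random.Generator, n: int = 40, p: int = 5) -> FeatureTable:
    """Small random numeric table for oracle-equivalence checks."""
    feats = pd.DataFrame(
        rng.normal(size=(n, p)) * rng.uniform(0.5, 20, p) + rng.uniform(-5, 50, p),
        columns=[f"X{i}" for i in range(p)],
    )
    outcome = rng.integers(0, 2, n)
    if outcome.min() == outcome.max():
        outcome[0] = 1 - outcome[0]
    return FeatureTable(feats, pd.Series(outcome))
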