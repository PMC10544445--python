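import numpy as np
import pandas as pd
import pytest

from diabmod import (
    FeatureStats,
    FeatureTable,
    RunConfig,
    SyntheticSpec,
    apply_framework,
    compute_stats,
    correlate_with_outcome,
    fit_framework,
    generate,
    logical_transform,
    relative_transform,
    sdr_thresholds,
    select_features,
)
from diabmod.modeling import derived_name

from conftest import random_table


# ---------------------------------------------------------------------------
# independent scalar oracle for the relative/logical transforms
# ---------------------------------------------------------------------------

def oracle_relative(value, mean, median, sd):
    return abs(value - mean), abs(value - median), abs(value - sd)


def oracle_logical(mvr, mdr, sdr, sdr_mean):
    return (
        1.0 if mvr > 0 else 0.0,
        1.0 if mdr > 0 else 0.0,
        1.0 if sdr > sdr_mean else 0.0,
    )


class TestComputeStats:
    def test_hand_arithmetic_population_sd(self):
        table = FeatureTable(
            pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0]}), pd.Series([0, 1, 0, 1])
        )
        stats = compute_stats(table)
        assert stats.mean("x") == 2.5
        assert stats.median("x") == 2.5
        assert stats.sd("x") == pytest.approx(np.sqrt(5 / 4), abs=1e-12)

    def test_constant_column(self):
        table = FeatureTable(pd.DataFrame({"x": [5.0, 5.0, 5.0]}), pd.Series([0, 1, 0]))
        stats = compute_stats(table)
        assert (stats.mean("x"), stats.median("x"), stats.sd("x")) == (5, 5, 0)

    def test_permutation_invariance(self, pima_like):
        rng = np.random.default_rng(0)
        perm = pima_like.take(rng.permutation(pima_like.n_rows))
        pd.testing.assert_frame_equal(
            compute_stats(pima_like).frame, compute_stats(perm).frame
        )

    def test_median_within_column_range(self, pima_like):
        stats = compute_stats(pima_like)
        for col in stats.columns:
            values = pima_like.features[col]
            assert values.min() <= stats.median(col) <= values.max()


class TestCorrelation:
    def test_feature_identical_to_outcome(self):
        y = pd.Series([0, 1, 0, 1, 1, 0])
        table = FeatureTable(pd.DataFrame({"x": y.astype(float)}), y)
        assert correlate_with_outcome(table).r["x"] == pytest.approx(1.0)

    def test_independent_feature_near_zero(self):
        rng = np.random.default_rng(7)
        n = 5000
        table = FeatureTable(
            pd.DataFrame({"x": rng.normal(size=n)}),
            pd.Series(rng.integers(0, 2, n)),
        )
        assert abs(correlate_with_outcome(table).r["x"]) < 3 / np.sqrt(n)

    def test_zero_variance_reports_zero_with_warning(self):
        table = FeatureTable(pd.DataFrame({"x": [1.0, 1.0]}), pd.Series([0, 1]))
        with pytest.warns(UserWarning, match="zero variance"):
            assert correlate_with_outcome(table).r["x"] == 0.0

    def test_single_class_outcome_rejected(self):
        table = FeatureTable(pd.DataFrame({"x": [1.0, 2.0]}), pd.Series([1, 1]))
        with pytest.raises(ValueError, match="both classes"):
            correlate_with_outcome(table)


class TestSelection:
    def test_top_k_orders_by_abs_r(self):
        report = correlate_with_outcome(
            FeatureTable(
                pd.DataFrame(
                    {
                        "a": [0.0, 1.0, 0.0, 1.0],
                        "b": [0.1, 0.9, 0.2, 0.7],
                        "c": [3.0, 1.0, 4.0, 1.0],
                    }
                ),
                pd.Series([0, 1, 0, 1]),
            )
        )
        assert select_features(report, k=2) == ("a", "b")

    def test_tied_correlations_break_by_column_order(self):
        x = [0.0, 1.0, 0.0, 1.0]
        table = FeatureTable(
            pd.DataFrame({"m": x, "n": x, "p": [0.5] * 4}), pd.Series([0, 1, 0, 1])
        )
        with pytest.warns(UserWarning, match="zero variance"):
            report = correlate_with_outcome(table)
        assert select_features(report, k=2) == ("m", "n")

    def test_k_too_large_errors(self):
        table = FeatureTable(pd.DataFrame({"x": [0.0, 1.0]}), pd.Series([0, 1]))
        with pytest.raises(ValueError, match="exceeds"):
            select_features(correlate_with_outcome(table), k=2)

    def test_unreachable_threshold_gives_empty_selection(self, pima_like):
        report = correlate_with_outcome(pima_like)
        with pytest.warns(UserWarning, match="no feature"):
            assert select_features(report, rule="threshold", r_min=1.0) == ()

    def test_recovers_features_with_injected_effect(self):
        spec = SyntheticSpec(n=5000, seed=11)
        # neutralise every class difference except Glucose and BMI
        for name, fs in spec.features.items():
            if name not in ("Glucose", "BMI"):
                fs.mean = (fs.mean[0], fs.mean[0])
                fs.sd = (fs.sd[0], fs.sd[0])
            fs.zero_rate = 0.0
        table = generate(spec)
        report = correlate_with_outcome(table)
        assert set(select_features(report, k=2)) == {"Glucose", "BMI"}


class TestRelativeTransform:
    def test_worked_example_bmi_rows(self, anchors):
        stats = FeatureStats.from_values(
            {
                "BMI": tuple(anchors["bmi_stats"][k] for k in ("mean", "median", "sd")),
            }
        )
        values = [row["value"] for row in anchors["bmi_examples"]]
        table = FeatureTable(
            pd.DataFrame({"BMI": values}), pd.Series([0, 1] * 3)
        )
        out = relative_transform(table, stats, ["BMI"])
        for i, row in enumerate(anchors["bmi_examples"]):
            assert out.features["BMI__MVR"][i] == pytest.approx(row["mvr"], abs=5e-5)
            assert out.features["BMI__MDR"][i] == pytest.approx(row["mdr"], abs=5e-5)
            assert out.features["BMI__SDR"][i] == pytest.approx(row["sdr"], abs=5e-4)

    def test_worked_example_glucose_sdr(self, anchors):
        stats = FeatureStats.from_values(
            {
                "Glucose": tuple(
                    anchors["glucose_stats"][k] for k in ("mean", "median", "sd")
                )
            }
        )
        values = [row["value"] for row in anchors["glucose_examples"]]
        table = FeatureTable(pd.DataFrame({"Glucose": values}), pd.Series([0, 1] * 3))
        out = relative_transform(table, stats, ["Glucose"])
        for i, row in enumerate(anchors["glucose_examples"]):
            assert out.features["Glucose__SDR"][i] == pytest.approx(
                row["sdr"], abs=5e-5
            )

    def test_value_at_mean_gives_zero_mvr(self):
        stats = FeatureStats.from_values({"x": (10.0, 9.0, 2.0)})
        table = FeatureTable(pd.DataFrame({"x": [10.0]}), pd.Series([1]))
        assert relative_transform(table, stats, ["x"]).features["x__MVR"][0] == 0.0

    def test_selected_feature_missing_from_stats_errors(self, pima_like):
        stats = compute_stats(pima_like, columns=["BMI"])
        with pytest.raises(KeyError, match="Glucose"):
            relative_transform(pima_like, stats, ["Glucose"])


class TestLogicalTransform:
    def test_worked_example_glucose_lfsd_bits(self, anchors):
        stats = FeatureStats.from_values(
            {
                "Glucose": tuple(
                    anchors["glucose_stats"][k] for k in ("mean", "median", "sd")
                )
            }
        )
        values = [row["value"] for row in anchors["glucose_examples"]]
        table = FeatureTable(pd.DataFrame({"Glucose": values}), pd.Series([0, 1] * 3))
        rel = relative_transform(table, stats, ["Glucose"])
        # threshold at the SDR column mean of the example rows
        with pytest.warns(UserWarning, match="constant"):
            out = logical_transform(rel)
        expected = [row["lfsd"] for row in anchors["glucose_examples"]]
        assert list(out.features["Glucose__LFSD"]) == expected
        # the full-dataset threshold mean(SDR) ~ mean - sd gives the same bits
        full_thr = anchors["glucose_stats"]["mean"] - anchors["glucose_stats"]["sd"]
        with pytest.warns(UserWarning, match="constant"):
            out2 = logical_transform(rel, thresholds={"Glucose": full_thr})
        assert list(out2.features["Glucose__LFSD"]) == expected

    def test_ties_map_to_zero(self):
        stats = FeatureStats.from_values({"x": (5.0, 5.0, 5.0)})
        table = FeatureTable(pd.DataFrame({"x": [5.0, 7.0]}), pd.Series([0, 1]))
        rel = relative_transform(table, stats, ["x"])
        # x=5: MVR=MDR=0 -> LFM=LFMD=0 (strict inequality)
        out = logical_transform(rel, thresholds={"x": 1.0})
        assert out.features["x__LFM"][0] == 0.0
        assert out.features["x__LFMD"][0] == 0.0
        # x=7: SDR=2 > 1 -> 1; x=5: SDR=0 -> 0
        assert list(out.features["x__LFSD"]) == [0.0, 1.0]
        # SDR exactly equal to the threshold -> 0
        out_tie = logical_transform(rel, thresholds={"x": 2.0})
        assert list(out_tie.features["x__LFSD"]) == [0.0, 0.0]

    def test_missing_sdr_column_errors(self, pima_like):
        rel = apply_framework(pima_like, RunConfig(seed=0), stage="relative")
        with pytest.raises(KeyError, match="__SDR"):
            sdr_thresholds(rel, ["DiabetesPedigreeFunction"])


class TestFrameworkComposition:
    def test_column_count_law(self, pima_like):
        for k in (0, 1, 2, 3, 4):
            config = RunConfig(seed=0, k=k) if k else RunConfig(seed=0, k=1)
            fitted = fit_framework(pima_like, config)
            if k == 0:
                fitted.selected = ()
            rel = fitted.transform(pima_like, stage="relative")
            assert rel.n_features == 8 + 3 * k
            if k:
                log = fitted.transform(pima_like, stage="logical")
                assert log.n_features == 8 + 6 * k

    def test_default_run_yields_20_then_32_columns(self, pima_like):
        assert apply_framework(pima_like, stage="relative").n_features == 20
        assert apply_framework(pima_like, stage="logical").n_features == 32

    def test_paper_literal_logical_set_restricts_to_named_features(self, pima_like):
        config = RunConfig(seed=0, logical_feature_set="paper_literal")
        fitted = fit_framework(pima_like, config)
        out = fitted.transform(pima_like, stage="logical")
        logical_cols = [c for c in out.feature_names if "__LF" in c]
        bases = {c.split("__")[0] for c in logical_cols}
        assert bases <= {"Glucose", "BMI", "Age"}

    def test_relative_outputs_nonnegative(self, pima_like):
        out = apply_framework(pima_like, stage="relative")
        derived = [c for c in out.feature_names if "__" in c]
        assert (out.features[derived].to_numpy() >= 0).all()

    def test_logical_outputs_binary(self, pima_like):
        out = apply_framework(pima_like)
        logical = [c for c in out.feature_names if "__LF" in c]
        assert set(np.unique(out.features[logical].to_numpy())) <= {0.0, 1.0}

    def test_row_permutation_equivariance(self, pima_like):
        fitted = fit_framework(pima_like, RunConfig(seed=0))
        rng = np.random.default_rng(3)
        perm = rng.permutation(pima_like.n_rows)
        direct = fitted.transform(pima_like).features.to_numpy()[perm]
        permuted = fitted.transform(pima_like.take(perm)).features.to_numpy()
        np.testing.assert_array_equal(direct, permuted)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_oracle_equivalence_on_random_tables(self, seed):
        """Batch transform matches a per-cell scalar re-implementation."""
        rng = np.random.default_rng(seed)
        table = random_table(rng, n=rng.integers(10, 100), p=5)
        stats = compute_stats(table)
        selected = list(table.feature_names[:3])
        rel = relative_transform(table, stats, selected)
        thr = sdr_thresholds(rel, selected)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            log = logical_transform(rel, thr)
        for col in selected:
            m, md, sd = stats.mean(col), stats.median(col), stats.sd(col)
            sdr_mean = thr[col]
            for i, value in enumerate(table.features[col]):
                mvr, mdr, sdr = oracle_relative(value, m, md, sd)
                assert rel.features[derived_name(col, "MVR")][i] == mvr
                assert rel.features[derived_name(col, "MDR")][i] == mdr
                assert rel.features[derived_name(col, "SDR")][i] == sdr
                lfm, lfmd, lfsd = oracle_logical(mvr, mdr, sdr, sdr_mean)
                assert log.features[derived_name(col, "LFM")][i] == lfm
                assert log.features[derived_name(col, "LFMD")][i] == lfmd
                assert log.features[derived_name(col, "LFSD")][i] == lfsd

    def test_empty_selection_is_identity_on_features(self, pima_like):
        report = correlate_with_outcome(pima_like)
        with pytest.warns(UserWarning, match="no feature"):
            select_features(report, rule="threshold", r_min=1.0)
        fitted = fit_framework(pima_like, RunConfig(seed=0))
        fitted.selected = ()
        out = fitted.transform(pima_like)
        assert out.n_features == 8
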