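import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfgap.evaluation import (
    brier,
    calibration_curve,
    calibration_report,
    calibration_slope_intercept,
    confusion_and_rates,
    ece_mce,
    hosmer_lemeshow,
    learning_curve,
    permutation_importance,
    roc_auc,
)


def _auc_bruteforce(scores, labels):
    """O(n²) pairwise concordance: P(case > control) + half the ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else 0.5 if a == b else 0.0
    return total / (len(pos) * len(neg))


class TestAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_null_large_sample(self):
        rng = np.random.default_rng(0)
        s = rng.random(10_000)
        y = rng.integers(0, 2, 10_000)
        assert abs(roc_auc(s, y) - 0.5) < 0.02

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    @given(st.data())
    @settings(max_examples=100)
    def test_equals_pairwise_concordance_oracle(self, data):
        n = data.draw(st.integers(4, 30))
        scores = data.draw(st.lists(
            st.floats(0, 1, allow_nan=False).map(lambda x: round(x, 2)),
            min_size=n, max_size=n))
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n)
                           .filter(lambda ls: 0 < sum(ls) < len(ls)))
        assert roc_auc(scores, labels) == pytest.approx(
            _auc_bruteforce(scores, labels), abs=1e-12)


class TestConfusion:
    def test_perfect_classification(self):
        rep = confusion_and_rates([0.9, 0.1], [1, 0])
        assert rep.accuracy == 1.0 and rep.recall == 1.0

    def test_accuracy_trap_at_low_prevalence(self):
        """All-negative predictions at 2% prevalence look accurate while
        detecting nothing."""
        y = np.zeros(1000, dtype=int)
        y[:20] = 1
        s = np.full(1000, 0.01)
        rep = confusion_and_rates(s, y)
        assert rep.accuracy == pytest.approx(0.98)
        assert rep.recall == 0.0
        assert np.isnan(rep.precision)  # zero denominator -> NA, not 0

    def test_zero_threshold_gives_full_recall(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 100)
        rep = confusion_and_rates(rng.random(100), y, threshold=0.0)
        assert rep.recall == 1.0

    def test_counts_sum_to_n(self):
        rng = np.random.default_rng(2)
        rep = confusion_and_rates(rng.random(57), rng.integers(0, 2, 57))
        assert rep.tp + rep.fp + rep.tn + rep.fn == 57


class TestBrier:
    def test_perfect_and_uninformative(self):
        assert brier([1.0, 0.0], [1, 0]) == 0.0
        assert brier([0.5] * 4, [1, 0, 1, 0]) == 0.25

    @given(p=st.floats(0.01, 0.99), pi=st.floats(0.01, 0.99),
           n=st.integers(50, 400))
    @settings(max_examples=50)
    def test_constant_predictor_closed_form(self, p, pi, n):
        k = int(round(pi * n))
        y = np.array([1] * k + [0] * (n - k))
        expected = p**2 * (1 - k / n) + (1 - p) ** 2 * (k / n)
        assert brier(np.full(n, p), y) == pytest.approx(expected, abs=1e-12)


def _ece_oracle(scores, labels, n_bins):
    """Independent re-binning implementation."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    ece, mce = 0.0, 0.0
    for b in range(n_bins):
        lo, hi = b / n_bins, (b + 1) / n_bins
        mask = (scores >= lo) & (scores < hi) if b < n_bins - 1 else (
            (scores >= lo) & (scores <= hi))
        if mask.sum() == 0:
            continue
        gap = abs(scores[mask].mean() - labels[mask].mean())
        ece += mask.sum() / len(scores) * gap
        mce = max(mce, gap)
    return ece, mce


class TestEceMce:
    def test_scores_equal_to_labels(self):
        assert ece_mce([1, 0, 1, 0], [1, 0, 1, 0]) == (0.0, 0.0)

    def test_constant_prediction_at_prevalence(self):
        y = [1, 1, 1, 0, 0, 0, 0, 0, 0, 0]
        ece, mce = ece_mce([0.3] * 10, y)
        assert ece == pytest.approx(0.0, abs=1e-12)
        assert mce == pytest.approx(0.0, abs=1e-12)

    @given(st.data())
    @settings(max_examples=50)
    def test_matches_independent_binning_oracle(self, data):
        n = data.draw(st.integers(10, 60))
        # keep scores off the bin edges so both binning implementations
        # agree regardless of floating-point edge representation
        scores = np.round(data.draw(st.lists(
            st.floats(0, 1, allow_nan=False), min_size=n, max_size=n)), 3)
        scores = np.clip(scores + 0.0005, 0.0, 1.0) - 0.0005
        scores = np.where(np.isclose(scores * 10, np.round(scores * 10)),
                          scores + 0.013, scores)
        scores = np.clip(scores, 0, 0.9995)
        labels = data.draw(st.lists(st.integers(0, 1), min_size=n, max_size=n))
        ece, mce = ece_mce(scores, labels, n_bins=10)
        o_ece, o_mce = _ece_oracle(scores, labels, 10)
        assert ece == pytest.approx(o_ece, abs=1e-12)
        assert mce == pytest.approx(o_mce, abs=1e-12)
        assert ece <= mce + 1e-12

    def test_quantile_scheme_available(self):
        rng = np.random.default_rng(0)
        s = rng.random(500)
        y = (rng.random(500) < s).astype(int)
        ece_q, mce_q = ece_mce(s, y, scheme="quantile")
        assert 0 <= ece_q <= mce_q


class TestCalibrationSlope:
    def test_recovers_identity_under_perfect_calibration(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0.05, 0.95, 50_000)
        y = (rng.random(50_000) < s).astype(int)
        fit = calibration_slope_intercept(s, y)
        assert 0.95 <= fit.slope <= 1.05
        assert -0.05 <= fit.intercept <= 0.05

    def test_detects_overconfident_scores(self):
        rng = np.random.default_rng(4)
        s = rng.uniform(0.05, 0.95, 20_000)
        y = (rng.random(20_000) < s).astype(int)
        fit = calibration_slope_intercept(s**2, y)  # artificially extreme
        assert fit.slope < 1.0

    def test_degenerate_constant_scores_raise(self):
        with pytest.raises(ValueError):
            calibration_slope_intercept([0.5] * 100, [0, 1] * 50)


class TestHosmerLemeshow:
    def test_calibrated_model_is_not_rejected_wildly(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(0.05, 0.95, 10_000)
        y = (rng.random(10_000) < s).astype(int)
        stat, df, p = hosmer_lemeshow(s, y)
        assert df == 8
        assert stat > 0

    def test_external_df_convention(self):
        rng = np.random.default_rng(5)
        s = rng.uniform(0.05, 0.95, 1000)
        y = (rng.random(1000) < s).astype(int)
        _, df, _ = hosmer_lemeshow(s, y, n_fitted_params=0)
        assert df == 10

    def test_gross_miscalibration_is_rejected(self):
        rng = np.random.default_rng(6)
        s = rng.uniform(0.6, 0.99, 5000)
        y = (rng.random(5000) < 0.2).astype(int)
        _, _, p = hosmer_lemeshow(s, y)
        assert p < 0.001

    def test_curve_partitions_sample(self):
        rng = np.random.default_rng(7)
        s = rng.random(1000)
        y = (rng.random(1000) < s).astype(int)
        curve = calibration_curve(s, y)
        assert sum(n for _, _, n in curve) == 1000


def test_calibration_report_bundles_consistent_values():
    rng = np.random.default_rng(8)
    s = rng.uniform(0.05, 0.95, 5000)
    y = (rng.random(5000) < s).astype(int)
    rep = calibration_report(s, y)
    assert rep.ece <= rep.mce
    assert rep.brier < 0.3
    assert rep.hl_df == rep.hl_df  # recorded
    assert rep.binning_scheme == "equal_width"


@pytest.fixture(scope="module")
def signal_data():
    rng = np.random.default_rng(9)
    n = 800
    y = rng.integers(0, 2, n)
    df = pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(n)],
        "age": rng.normal(60, 10, n),
        "sex": rng.choice(["male", "female"], n),
        "race": rng.choice(["parda", "branca"], n),
        "bmi": rng.normal(27, 4, n),
        "icd_I25": rng.poisson(1 + 3 * y),
        "proc_ECHO": rng.poisson(1, n),  # pure noise
    })
    return df, y


class TestModelDiagnostics:
    def test_learning_curve_optimism_and_shape(self, signal_data):
        from hfgap.model import ModelSpec

        df, y = signal_data
        spec = ModelSpec(hyperparameters={"depth": 3, "learning_rate": 0.3,
                                          "iterations": 50, "l2_leaf_reg": 3.0,
                                          "border_count": 32})
        curve = learning_curve(df, y, spec, train_fractions=(0.3, 1.0), seed=0)
        assert list(curve["fraction"]) == [0.3, 1.0]
        assert (curve["train_auc"] >= curve["validation_auc"] - 0.02).all()

    def test_permutation_importance_finds_planted_feature(self, signal_data):
        from hfgap.model import ModelSpec, crossval_train

        df, y = signal_data
        spec = ModelSpec(hyperparameters={"depth": 3, "learning_rate": 0.3,
                                          "iterations": 50, "l2_leaf_reg": 3.0,
                                          "border_count": 32})
        _, fitted = crossval_train(df, y, spec, k=2, seed=0)
        imp = permutation_importance(fitted, df, y, n_repeats=3, seed=0)
        imp = imp.set_index("feature")["importance"]
        assert imp["icd_I25"] > 0.05
        assert imp["icd_I25"] == imp.max()
        assert abs(imp["proc_ECHO"]) < 0.05

    def test_permutation_importance_deterministic(self, signal_data):
        from hfgap.model import ModelSpec, crossval_train

        df, y = signal_data
        spec = ModelSpec(hyperparameters={"depth": 3, "learning_rate": 0.3,
                                          "iterations": 50, "l2_leaf_reg": 3.0,
                                          "border_count": 32})
        _, fitted = crossval_train(df, y, spec, k=2, seed=0)
        a = permutation_importance(fitted, df, y, n_repeats=2, seed=1)
        b = permutation_importance(fitted, df, y, n_repeats=2, seed=1)
        pd.testing.assert_frame_equal(a, b)
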