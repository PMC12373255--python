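"""Normalized reconstruction metrics against a brute-force oracle,
classification reporting conventions, k-fold splits, and
distribution-consistency metrics."""

import numpy as np
import pytest

from cardioaug.evaluate import (SignalPair, nrmse, nmae, nprd, macro_stats,
                                classification_report, kfold_split,
                                distribution_report)


def brute_force_metrics(y, yh):
    """Independent single-expression implementations of the three metrics."""
    y, yh = np.asarray(y, float), np.asarray(yh, float)
    rng_ = y.max() - y.min()
    return (
        np.sqrt(np.sum((y - yh) ** 2) / len(y)) / rng_,
        np.sum(np.abs(y - yh)) / len(y) / rng_,
        100.0 * np.sqrt(np.sum((y - yh) ** 2) / np.sum(y ** 2)) / rng_,
    )


class TestReconstructionMetrics:
    def test_identical_signals_give_zero(self):
        pair = SignalPair(np.arange(5.0), np.arange(5.0))
        assert nrmse(pair) == 0 and nmae(pair) == 0 and nprd(pair) == 0

    def test_hand_arithmetic_example(self):
        pair = SignalPair([0, 1, 2, 1, 0], [0, 1, 1, 1, 0])
        assert nrmse(pair) == pytest.approx(np.sqrt(0.2) / 2, abs=1e-5)
        assert nmae(pair) == pytest.approx(0.1, abs=1e-12)
        assert nprd(pair) == pytest.approx(100 * np.sqrt(1 / 6) / 2, abs=1e-3)
        assert nprd(pair) == pytest.approx(20.412, abs=1e-3)

    def test_oracle_equivalence_on_random_pairs(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = rng.integers(5, 200)
            y = rng.normal(size=n)
            yh = y + rng.normal(scale=0.3, size=n)
            pair = SignalPair(y, yh)
            e_rmse, e_mae, e_prd = brute_force_metrics(y, yh)
            assert abs(nrmse(pair) - e_rmse) < 1e-12
            assert abs(nmae(pair) - e_mae) < 1e-12
            assert abs(nprd(pair) - e_prd) < 1e-12

    @pytest.mark.parametrize("c", [0.5, 3.0])
    def test_scale_invariance(self, c):
        rng = np.random.default_rng(1)
        y = rng.normal(size=64)
        yh = y + rng.normal(scale=0.2, size=64)
        p1, p2 = SignalPair(y, yh), SignalPair(c * y, c * yh)
        assert nrmse(p2) == pytest.approx(nrmse(p1), rel=1e-12)
        assert nmae(p2) == pytest.approx(nmae(p1), rel=1e-12)
        # the classical PRD ratio is scale-free, so dividing it by the
        # amplitude range makes NPRD scale exactly as 1/c
        assert nprd(p2) * c == pytest.approx(nprd(p1), rel=1e-9)

    def test_constant_signal_undefined(self):
        with pytest.raises(ValueError):
            nrmse(SignalPair(np.ones(5), np.zeros(5)))

    def test_zero_energy_nprd_undefined(self):
        with pytest.raises(ValueError):
            nprd(SignalPair([0, 0, 1e-330], [1, 2, 3]))

    def test_raw_flag_drops_percent_factor(self):
        pair = SignalPair([0, 1, 2, 1, 0], [0, 1, 1, 1, 0])
        assert nprd(pair, raw=True) * 100 == pytest.approx(nprd(pair))


class TestClassificationReport:
    def test_printed_per_class_cells_reproduce_macro_and_std(self):
        # RF post-augmentation F1 column: macro 99.27, sample std 0.38
        f1 = [98.76, 99.30, 99.65, 99.60, 99.04]
        mean, std = macro_stats(f1)
        assert round(mean, 2) == 99.27
        assert round(std, 2) == 0.38

    def test_perfect_predictions(self):
        y = np.array(list("NAVLR") * 4)
        rep = classification_report(y, y)
        assert rep.macro_f1 == 100.0
        assert rep.std_f1 == 0.0
        assert rep.accuracy == 100.0

    def test_hand_confusion_example(self):
        rep = classification_report(["A", "A", "N", "N"], ["A", "N", "N", "N"],
                                    class_order=("N", "A"))
        assert rep.precision["A"] == pytest.approx(100.0)
        assert rep.recall["A"] == pytest.approx(50.0)
        assert rep.f1["A"] == pytest.approx(66.67, abs=0.01)
        assert rep.precision["N"] == pytest.approx(66.67, abs=0.01)
        assert rep.recall["N"] == pytest.approx(100.0)
        assert rep.f1["N"] == pytest.approx(80.0)

    def test_matches_sklearn_oracle(self):
        from sklearn.metrics import precision_recall_fscore_support
        rng = np.random.default_rng(0)
        y_true = rng.choice(list("NAVLR"), size=300)
        y_pred = np.where(rng.random(300) < 0.3,
                          rng.choice(list("NAVLR"), size=300), y_true)
        rep = classification_report(y_true, y_pred)
        p, r, f, _ = precision_recall_fscore_support(
            y_true, y_pred, labels=list("NAVLR"), zero_division=0)
        assert np.allclose([rep.precision[c] for c in "NAVLR"], 100 * p)
        assert np.allclose([rep.recall[c] for c in "NAVLR"], 100 * r)
        assert np.allclose([rep.f1[c] for c in "NAVLR"], 100 * f, atol=1e-9)
        assert rep.macro_f1 == pytest.approx(100 * f.mean())

    def test_zero_predicted_positives_flagged(self):
        rep = classification_report(["N", "A", "N"], ["N", "N", "N"],
                                    class_order=("N", "A"))
        assert rep.precision["A"] == 0.0
        assert any("A" in f for f in rep.zero_division_flags)

    def test_sample_order_permutation_invariance(self):
        rng = np.random.default_rng(2)
        y_true = rng.choice(list("NAVLR"), size=100)
        y_pred = rng.choice(list("NAVLR"), size=100)
        perm = rng.permutation(100)
        r1 = classification_report(y_true, y_pred)
        r2 = classification_report(y_true[perm], y_pred[perm])
        assert r1.macro_f1 == r2.macro_f1
        assert np.array_equal(r1.confusion, r2.confusion)

    def test_confusion_rows_sum_to_support(self):
        rng = np.random.default_rng(3)
        y_true = rng.choice(list("NAVLR"), size=200)
        y_pred = rng.choice(list("NAVLR"), size=200)
        rep = classification_report(y_true, y_pred)
        for i, c in enumerate("NAVLR"):
            assert rep.confusion[i].sum() == np.sum(y_true == c)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            classification_report(["N", "Z"], ["N", "N"])


class TestKfold:
    def test_five_folds_of_two(self):
        y = np.array(list("NA") * 5)
        splits = kfold_split(y, folds=5, seed=0)
        tests = [set(te) for _, te in splits]
        assert all(len(t) == 2 for t in tests)
        assert set().union(*tests) == set(range(10))
        assert sum(len(t) for t in tests) == 10

    def test_stratification_preserves_ratio(self):
        y = np.array(["N"] * 77 + ["A"] * 23)
        for _, te in kfold_split(y, folds=5, seed=1):
            n_a = np.sum(y[te] == "A")
            assert abs(n_a - 23 / 5) <= 1

    def test_deterministic_given_seed(self):
        y = np.random.default_rng(0).choice(list("NA"), size=50)
        s1 = kfold_split(y, folds=5, seed=7)
        s2 = kfold_split(y, folds=5, seed=7)
        for (a, b), (c, d) in zip(s1, s2):
            assert np.array_equal(a, c) and np.array_equal(b, d)

    def test_tiny_class_degrades_with_warning(self):
        y = np.array(["N"] * 20 + ["A"] * 2)
        with pytest.warns(UserWarning, match="fewer members"):
            splits = kfold_split(y, folds=5, seed=0)
        assert len(splits) == 5


class TestDistributionReport:
    def test_same_sample_is_indistinguishable(self):
        X = np.random.default_rng(0).normal(size=(200, 3))
        rep = distribution_report(X, X)
        assert rep["wasserstein_1"] == 0.0
        assert rep["js_divergence"] == pytest.approx(0.0, abs=1e-12)
        assert rep["ks_p_value"] == pytest.approx(1.0)

    def test_shifted_gaussians_wasserstein_one(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0.0, 1.0, size=(10000, 1))
        b = rng.normal(1.0, 1.0, size=(10000, 1))
        rep = distribution_report(a, b)
        assert rep["wasserstein_1"] == pytest.approx(1.0, abs=0.05)

    def test_disjoint_supports_reach_ln2(self):
        a = np.zeros((500, 1))
        b = np.full((500, 1), 10.0)
        rep = distribution_report(a, b)
        assert rep["js_divergence"] == pytest.approx(np.log(2), abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            distribution_report(np.zeros((5, 2)), np.zeros((5, 3)))
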