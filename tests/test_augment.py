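"""Augmentation planning arithmetic, the strict-improvement gate automaton,
and the build loop's count/provenance guarantees."""

import numpy as np
import pytest

from cardioaug.augment import (plan_augmentation, truncate, AcceptanceGate,
                               acceptance_gate, GateConfig, synthesize,
                               build_augmented_dataset, AugmentedDataset)
from cardioaug.models import ModelConfig, build_networks, CganBundle


class TestPlanning:
    @pytest.mark.parametrize("before,target,ratio", [
        (1950, 15000, 769.230),
        (6974, 15000, 215.084),
        (6578, 15000, 228.032),
        (4967, 15000, 301.993),
    ])
    def test_ratios_match_three_decimal_truncation(self, before, target, ratio):
        plan = plan_augmentation({"A": before, "N": 99999}, target,
                                 augment_classes=["A"])
        assert plan.ratio_pct("A") == ratio

    def test_already_at_target_needs_nothing(self):
        plan = plan_augmentation({"A": 100, "N": 200}, 100,
                                 augment_classes=["A"])
        assert plan.ratio_pct("A") == 100.000
        assert plan.n_synthetic("A") == 0

    def test_synthetic_count_is_target_minus_before(self):
        plan = plan_augmentation({"L": 6578, "N": 99999}, 15000,
                                 augment_classes=["L"])
        assert plan.n_synthetic("L") == 8422

    def test_majority_class_excluded_by_default(self):
        plan = plan_augmentation({"N": 1000, "A": 20, "V": 70}, 1000)
        assert set(plan.target) == {"A", "V"}

    def test_zero_before_count_rejected(self):
        with pytest.raises(ValueError, match="ratio undefined"):
            plan_augmentation({"A": 0, "N": 10}, 100, augment_classes=["A"])

    def test_truncation_does_not_round_up(self):
        assert truncate(769.2307, 3) == 769.230
        assert truncate(2.11494, 3) == 2.114


class TestGateAutomaton:
    def test_improvement_accepts_and_updates_baseline(self):
        gate = AcceptanceGate(lambda X, y: 0.96, baseline_metric=0.95)
        assert gate.consider(np.zeros((1, 2)), np.array(["A"]))
        assert gate.baseline == 0.96

    def test_tie_rejects(self):
        gate = AcceptanceGate(lambda X, y: 0.95, baseline_metric=0.95)
        assert not gate.consider(np.zeros((1, 2)), np.array(["A"]))
        assert gate.baseline == 0.95

    def test_three_batch_enumeration(self):
        # batch metrics 0.97, 0.96, 0.96 against initial baseline 0.95:
        # only the first is kept; baseline sticks at 0.97
        metrics = iter([0.97, 0.96, 0.96])
        pool = (np.zeros((4, 2)), np.array(["N"] * 4))
        baseline = 0.95
        accepted = []
        for i in range(3):
            m = next(metrics)
            ok, baseline, pool = acceptance_gate(
                (np.full((2, 2), float(i)), np.array(["A", "A"])),
                pool, lambda X, y, m=m: m, baseline)
            accepted.append(ok)
        assert accepted == [True, False, False]
        assert baseline == 0.97
        assert len(pool[0]) == 6  # original 4 + batch 1 only

    def test_history_strictly_increasing(self):
        vals = iter([0.5, 0.7, 0.6, 0.8, 0.8])
        gate = AcceptanceGate(lambda X, y: next(vals), baseline_metric=0.4)
        for _ in range(5):
            gate.consider(np.zeros((1, 1)), np.array(["A"]))
        assert gate.history == sorted(set(gate.history))
        assert all(b > a for a, b in zip(gate.history, gate.history[1:]))


class TestSynthesize:
    def test_untrained_bundle_rejected(self):
        cfg = ModelConfig(k=3, backbone="mlp", width=8, cond_embed_dim=4)
        bundle = CganBundle(cfg, *build_networks(cfg, 0))
        with pytest.raises(RuntimeError, match="stage-2"):
            synthesize(bundle, "A", 5, seed=0)

    def test_zero_request_empty(self, tiny_trained_bundle):
        bundle, *_ = tiny_trained_bundle
        assert synthesize(bundle, "A", 0, seed=0).shape == (0, bundle.config.k)

    def test_seed_reproducibility(self, tiny_trained_bundle):
        bundle, *_ = tiny_trained_bundle
        a = synthesize(bundle, "A", 7, seed=3)
        b = synthesize(bundle, "A", 7, seed=3)
        assert np.array_equal(a, b)
        assert a.shape == (7, bundle.config.k)


class TestBuildLoop:
    def test_no_op_plan_returns_input(self, tiny_trained_bundle):
        bundle, X, y, mu = tiny_trained_bundle
        labels = np.array(["N", "A"], dtype=object)[y]
        counts = {"N": 150, "A": 150}
        plan = plan_augmentation(counts, 150, augment_classes=["A"])
        out = build_augmented_dataset(X, labels, bundle, plan,
                                      gate_cfg=GateConfig(disabled=True))
        assert np.array_equal(out.X, X)
        assert out.n_real() == len(X)

    def test_gate_disabled_counts_match_plan_exactly(self, tiny_trained_bundle):
        bundle, X, y, mu = tiny_trained_bundle
        keep = np.concatenate([np.flatnonzero(y == 0),
                               np.flatnonzero(y == 1)[:30]])
        Xs, ys = X[keep], np.array(["N", "A"], dtype=object)[y[keep]]
        plan = plan_augmentation({"N": 150, "A": 30}, 150,
                                 augment_classes=["A"])
        out = build_augmented_dataset(Xs, ys, bundle, plan,
                                      gate_cfg=GateConfig(disabled=True),
                                      seed=1)
        assert out.class_counts() == {"N": 150, "A": 150}
        assert out.n_real() == len(keep)  # provenance conserved

    def test_gated_run_keeps_baseline_monotone(self, tiny_trained_bundle):
        bundle, X, y, mu = tiny_trained_bundle
        rng = np.random.default_rng(0)
        keep = np.concatenate([np.flatnonzero(y == 0),
                               np.flatnonzero(y == 1)[:20]])
        Xs, ys = X[keep], np.array(["N", "A"], dtype=object)[y[keep]]
        from cardioaug.classifiers import RfConfig
        gcfg = GateConfig(batch_per_round=40, max_rounds=6,
                          surrogate=RfConfig(n_trees=25, seed=0))
        out = build_augmented_dataset(Xs, ys, bundle,
                                      plan_augmentation({"N": 150, "A": 20},
                                                        150,
                                                        augment_classes=["A"]),
                                      gate_cfg=gcfg, seed=2)
        for hist in out.gate_history.values():
            assert all(b > a for a, b in zip(hist, hist[1:]))
        assert out.n_real() <= len(keep)

    def test_dimension_mismatch_rejected(self, tiny_trained_bundle):
        bundle, X, y, mu = tiny_trained_bundle
        plan = plan_augmentation({"N": 10, "A": 5}, 10, augment_classes=["A"])
        with pytest.raises(ValueError):
            build_augmented_dataset(X[:, :2], np.array(["N"] * len(X)),
                                    bundle, plan,
                                    gate_cfg=GateConfig(disabled=True))


def test_augmented_dataset_csv_roundtrip(tmp_path):
    ds = AugmentedDataset(np.array([[1.5, -2.0], [0.25, 3.5]]),
                          np.array(["N", "A"], dtype=object),
                          np.array(["real", "synthetic"], dtype=object))
    ds.save(tmp_path / "a.csv")
    back = AugmentedDataset.load(tmp_path / "a.csv")
    assert np.allclose(back.X, ds.X)
    assert list(back.source) == ["real", "synthetic"]
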