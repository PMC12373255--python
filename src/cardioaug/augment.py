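"""Class-conditional synthesis, the acceptance gate, and augmentation plans.

The augmentation loop raises each minority class toward a target count by
drawing batches of synthetic PCA component vectors from the trained
generator.  Each batch must pass an acceptance gate: a surrogate
classifier is retrained on the current pool plus the candidates and
scored on a dedicated validation split; the batch is kept only if the
gate metric (macro F1 by default) *strictly* improves on the running
baseline — ties and regressions are discarded.  The majority class is
never augmented by default.

Plan ratios are reported as 100 * target / before, truncated (not
rounded) to three decimals, matching the printed convention of the study
this package reproduces.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import CganBundle, CLASS_SYMBOLS
from .classifiers import RfConfig, fit_classifier
from .evaluate import classification_report

__all__ = ["AugmentationPlan", "AugmentedDataset", "GateConfig",
           "plan_augmentation", "synthesize", "acceptance_gate",
           "AcceptanceGate", "build_augmented_dataset", "truncate"]


def truncate(x: float, decimals: int = 3) -> float:
    """Truncate toward zero at ``decimals`` places (printed-table convention)."""
    f = 10.0 ** decimals
    return math.trunc(x * f) / f


@dataclass
class AugmentationPlan:
    before: dict[str, int]
    target: dict[str, int]

    def __post_init__(self):
        for c, t in self.target.items():
            if t < 0:
                raise ValueError("targets must be >= 0")
            if self.before.get(c, 0) == 0 and t > 0:
                raise ValueError(
                    f"class {c!r} has zero existing samples: ratio undefined")

    def ratio_pct(self, cls: str) -> float:
        return truncate(100.0 * self.target[cls] / self.before[cls], 3)

    def n_synthetic(self, cls: str) -> int:
        return max(self.target[cls] - self.before[cls], 0)

    def rows(self) -> list[dict]:
        return [{"label": c, "before": self.before[c], "after": self.target[c],
                 "augmentation_ratio_pct": self.ratio_pct(c)}
                for c in self.target]

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.rows(), indent=1))


def plan_augmentation(class_counts: dict[str, int],
                      target_per_class: int | dict[str, int],
                      augment_classes=None) -> AugmentationPlan:
    """Plan raising each augmented class to a target count.

    ``augment_classes`` defaults to every class except the most frequent
    one (the majority class is left untouched).  Classes already at or
    above target need 0 synthetic samples.
    """
    if augment_classes is None:
        majority = max(class_counts, key=class_counts.get)
        augment_classes = [c for c in class_counts if c != majority]
    if isinstance(target_per_class, int):
        target = {c: target_per_class for c in augment_classes}
    else:
        target = dict(target_per_class)
    before = {c: int(class_counts.get(c, 0)) for c in target}
    target = {c: max(int(t), before[c]) for c, t in target.items()}
    return AugmentationPlan(before, target)


def synthesize(bundle: CganBundle, label: str, n: int,
               seed: int) -> np.ndarray:
    """Draw ``n`` synthetic component vectors of one class, reproducibly."""
    if bundle.trained_stages < 2:
        raise RuntimeError("bundle has no trained generator "
                           "(run stage-2 training first)")
    if n == 0:
        return np.zeros((0, bundle.config.k))
    rng = np.random.default_rng(seed)
    return bundle.generate([label] * n, rng)


@dataclass
class GateConfig:
    disabled: bool = False
    metric: str = "macro_f1"         # "macro_f1" | "recall:<class>"
    batch_per_round: int = 500
    max_rounds: int = 50
    surrogate: RfConfig = field(default_factory=lambda: RfConfig(n_trees=100))


class AcceptanceGate:
    """Strict-improvement gate over a validation metric.

    ``eval_fn(candidate_X, candidate_y)`` must return the gate metric for
    the pool extended with the candidates.  A batch is accepted iff its
    metric strictly exceeds the running baseline, which then updates.
    """

    def __init__(self, eval_fn, baseline_metric: float):
        self.eval_fn = eval_fn
        self.baseline = float(baseline_metric)
        self.history: list[float] = [self.baseline]

    def consider(self, candidate_X, candidate_y) -> bool:
        metric = float(self.eval_fn(candidate_X, candidate_y))
        if metric > self.baseline:
            self.baseline = metric
            self.history.append(metric)
            return True
        return False


def acceptance_gate(candidate_batch, base_pool, eval_fn,
                    baseline_metric: float):
    """One gate decision; returns (accepted, new_baseline, new_pool).

    Functional form of :class:`AcceptanceGate` for single decisions:
    accept iff ``eval_fn`` on pool + candidates strictly beats the
    baseline; on accept the candidates join the pool.
    """
    X, y = candidate_batch
    metric = float(eval_fn(X, y))
    if metric > baseline_metric:
        pool_X, pool_y = base_pool
        return True, metric, (np.vstack([pool_X, X]),
                              np.concatenate([pool_y, y]))
    return False, baseline_metric, base_pool


@dataclass
class AugmentedDataset:
    """PCA-space dataset = real rows plus accepted synthetic rows."""

    X: np.ndarray
    y: np.ndarray
    source: np.ndarray          # "real" | "synthetic" per row
    gate_history: dict = field(default_factory=dict)

    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.y.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def n_real(self) -> int:
        return int(np.sum(self.source == "real"))

    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with path.open("w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["label", "source",
                        *(f"c{i}" for i in range(self.X.shape[1]))])
            for i in range(len(self.y)):
                w.writerow([self.y[i], self.source[i],
                            *(repr(float(v)) for v in self.X[i])])

    @classmethod
    def load(cls, path) -> "AugmentedDataset":
        with Path(path).open() as fh:
            r = csv.reader(fh)
            header = next(r)
            k = len(header) - 2
            rows, ys, srcs = [], [], []
            for row in r:
                ys.append(row[0])
                srcs.append(row[1])
                rows.append([float(v) for v in row[2:]])
        X = np.array(rows) if rows else np.zeros((0, k))
        return cls(X, np.array(ys, dtype=object), np.array(srcs, dtype=object))


def _gate_metric_fn(train_X, train_y, val_X, val_y, cfg: GateConfig):
    """Builds eval_fn: retrain the surrogate on pool+candidates, score val."""
    if cfg.metric.startswith("recall:"):
        target_cls = cfg.metric.split(":", 1)[1]
    else:
        target_cls = None

    def eval_fn(cand_X, cand_y):
        X = np.vstack([train_X, cand_X]) if len(cand_X) else train_X
        y = np.concatenate([train_y, cand_y]) if len(cand_y) else train_y
        model = fit_classifier(cfg.surrogate, X, y)
        rep = classification_report(val_y, model.predict(val_X))
        if target_cls is not None:
            return rep.recall[target_cls]
        return rep.macro_f1

    return eval_fn


def build_augmented_dataset(X_pca: np.ndarray, y, bundle: CganBundle,
                            plan: AugmentationPlan,
                            gate_cfg: GateConfig | None = None,
                            val: tuple | None = None,
                            seed: int = 0) -> AugmentedDataset:
    """Run the synthesize -> gate loop per class until targets are met.

    ``val`` is a held-out (X, y) validation split for the gate; when absent
    a 25% stratified tail of the training pool is carved off.  With the
    gate disabled every requested sample is kept, so the final class
    histogram equals the plan exactly.
    """
    gate_cfg = gate_cfg or GateConfig()
    X_pca = np.asarray(X_pca, dtype=np.float64)
    y = np.asarray(y, dtype=object)
    if bundle.config.k != X_pca.shape[1]:
        raise ValueError("component dimension of bundle and data differ")

    pool_X, pool_y = X_pca, y
    src = np.array(["real"] * len(y), dtype=object)
    gate_history: dict[str, list[float]] = {}

    if not gate_cfg.disabled:
        if val is None:
            from .evaluate import kfold_split
            tr, va = kfold_split(y.astype(str), folds=4, seed=seed)[0]
            val = (X_pca[va], y[va])
            pool_X, pool_y = X_pca[tr], y[tr]
            src = src[: len(pool_y)]
        val_X, val_y = val

    for ci, cls in enumerate(c for c in plan.target if c in CLASS_SYMBOLS):
        need = plan.n_synthetic(cls)
        if need == 0:
            continue
        if not gate_cfg.disabled:
            eval_fn = _gate_metric_fn(pool_X, pool_y, val_X, val_y, gate_cfg)
            baseline = eval_fn(np.zeros((0, X_pca.shape[1])), np.array([]))
            gate = AcceptanceGate(
                lambda cx, cy: _gate_metric_fn(pool_X, pool_y, val_X, val_y,
                                               gate_cfg)(cx, cy), baseline)
            gate_history[cls] = [baseline]
        produced, rounds = 0, 0
        while produced < need and rounds < gate_cfg.max_rounds:
            m = min(gate_cfg.batch_per_round, need - produced)
            cand = synthesize(bundle, cls, m, seed=seed + 7919 * rounds + 104729 * ci)
            cand_y = np.array([cls] * m, dtype=object)
            rounds += 1
            if gate_cfg.disabled or gate.consider(cand, cand_y):
                pool_X = np.vstack([pool_X, cand])
                pool_y = np.concatenate([pool_y, cand_y])
                src = np.concatenate([src, ["synthetic"] * m])
                produced += m
                if not gate_cfg.disabled:
                    gate_history[cls].append(gate.baseline)
        if produced < need:
            warnings.warn(f"class {cls}: reached only {produced}/{need} "
                          f"accepted synthetic samples in "
                          f"{gate_cfg.max_rounds} rounds")
    return AugmentedDataset(pool_X, pool_y, src, gate_history)
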