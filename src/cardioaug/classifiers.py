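"""Downstream classifier harnesses: a random forest and a 1-D ResNet.

Both consume either raw beat windows or PCA component vectors and share
the fit/predict surface used by the baseline, the augmentation gate and
the final evaluation.  The ResNet realises the standard residual layouts
(depths 10/18/34) with 1-D convolutions — kernel 7 stem, kernel 3 in the
blocks — treating a length-k component vector as a 1-channel sequence.
``base_channels`` scales the width; the default 64 matches the common
ResNet-18 stem, tests use a reduced width.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .nn.autograd import Tensor, no_grad
from .nn.layers import Module, Linear, Conv1d, BatchNorm1d, Dropout
from .nn.optim import AdamW
from .nn import autograd
from .models import CLASS_SYMBOLS, labels_to_indices

__all__ = ["RfConfig", "ResNetConfig", "fit_classifier", "predict",
           "pca_sweep", "RandomForestHarness", "ResNetHarness"]


@dataclass
class RfConfig:
    n_trees: int = 500
    min_leaf: int = 5
    criterion: str = "gini"
    max_features: str = "sqrt"
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class ResNetConfig:
    depth: int = 18
    batch: int = 64
    lr: float = 1e-3
    epochs: int = 100
    weight_decay: float = 1e-4
    dropout: float = 0.3
    base_channels: int = 64
    input_mode: str = "pca_k"        # "pca_k" | "raw_beat"
    seed: int = 0

    def __post_init__(self):
        if self.depth not in (10, 18, 34):
            raise ValueError("depth must be one of 10, 18, 34")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


_BLOCKS_PER_STAGE = {10: (1, 1, 1, 1), 18: (2, 2, 2, 2), 34: (3, 4, 6, 3)}


class _BasicBlock(Module):
    def __init__(self, c_in, c_out, rng, stride=1):
        super().__init__()
        self.conv1 = Conv1d(c_in, c_out, 3, rng, stride=stride)
        self.bn1 = BatchNorm1d(c_out)
        self.conv2 = Conv1d(c_out, c_out, 3, rng)
        self.bn2 = BatchNorm1d(c_out)
        self.short = Conv1d(c_in, c_out, 1, rng, stride=stride, padding=0) \
            if (stride != 1 or c_in != c_out) else None

    def __call__(self, x):
        h = self.bn1(self.conv1(x)).relu()
        h = self.bn2(self.conv2(h))
        sc = self.short(x) if self.short is not None else x
        return (h + sc).relu()


class _ResNet1d(Module):
    def __init__(self, cfg: ResNetConfig, n_classes: int, rng):
        super().__init__()
        c = cfg.base_channels
        self.stem = Conv1d(1, c, 7, rng, stride=2)
        self.bn = BatchNorm1d(c)
        self.stages = []
        blocks = _BLOCKS_PER_STAGE[cfg.depth]
        c_in = c
        for si, nb in enumerate(blocks):
            c_out = c * (2 ** si)
            for bi in range(nb):
                stride = 2 if (si > 0 and bi == 0) else 1
                self.stages.append(_BasicBlock(c_in, c_out, rng, stride))
                c_in = c_out
        self.drop = Dropout(cfg.dropout, rng)
        self.fc = Linear(c_in, n_classes, rng)

    def __call__(self, x: Tensor) -> Tensor:
        # x: (batch, length, 1)
        h = self.bn(self.stem(x)).relu()
        for blk in self.stages:
            h = blk(h)
        h = h.mean(axis=1)          # global average pool over time
        return self.fc(self.drop(h))


class ResNetHarness:
    def __init__(self, cfg: ResNetConfig):
        self.cfg = cfg
        self.net: _ResNet1d | None = None
        self.classes_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y) -> "ResNetHarness":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y).astype(str)
        self.classes_ = np.array(sorted(set(y),
                                        key=lambda s: CLASS_SYMBOLS.index(s)
                                        if s in CLASS_SYMBOLS else 99))
        if len(self.classes_) < 2:
            warnings.warn("training data contains a single class; "
                          "the fitted model is degenerate")
        cls_idx = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([cls_idx[c] for c in y])
        rng = np.random.default_rng(self.cfg.seed)
        self.net = _ResNet1d(self.cfg, len(self.classes_), rng)
        params = self.net.parameters()
        opt = AdamW(params, lr=self.cfg.lr, betas=(0.9, 0.999),
                    weight_decay=self.cfg.weight_decay)
        n = len(X)
        self.net.train()
        for _ in range(self.cfg.epochs):
            order = rng.permutation(n)
            for s in range(0, n, self.cfg.batch):
                b = order[s:s + self.cfg.batch]
                if len(b) < 2:
                    continue
                xb = Tensor(X[b][:, :, None])
                logits = self.net(xb)
                loss = _cross_entropy(logits, yi[b])
                opt.zero_grad()
                autograd.backward(loss, params)
                opt.step()
        return self

    def predict(self, X: np.ndarray, return_scores: bool = False):
        X = np.asarray(X, dtype=np.float64)
        was_training = self.net.training
        self.net.eval()
        with no_grad():
            logits = self.net(Tensor(X[:, :, None])).numpy()
        if was_training:
            self.net.train()
        pred = self.classes_[np.argmax(logits, axis=1)]
        if return_scores:
            e = np.exp(logits - logits.max(axis=1, keepdims=True))
            return pred, e / e.sum(axis=1, keepdims=True)
        return pred

    def training_error(self, X, y) -> float:
        return float(np.mean(self.predict(X) != np.asarray(y).astype(str)))


def _cross_entropy(logits: Tensor, target_idx: np.ndarray) -> Tensor:
    shifted = logits - logits.max_detached(axis=1, keepdims=True)
    logz = shifted.exp().sum(axis=1, keepdims=True).log()
    logp = shifted - logz
    picked = logp[np.arange(len(target_idx)), target_idx]
    return -picked.mean()


class RandomForestHarness:
    def __init__(self, cfg: RfConfig):
        self.cfg = cfg
        self.model = RandomForestClassifier(
            n_estimators=cfg.n_trees, min_samples_leaf=cfg.min_leaf,
            criterion=cfg.criterion, max_features=cfg.max_features,
            random_state=cfg.seed, n_jobs=1)

    def fit(self, X, y):
        y = np.asarray(y).astype(str)
        if len(set(y)) < 2:
            warnings.warn("training data contains a single class; "
                          "the fitted model is degenerate")
        self.model.fit(np.asarray(X, dtype=np.float64), y)
        return self

    def predict(self, X, return_scores: bool = False):
        X = np.asarray(X, dtype=np.float64)
        pred = self.model.predict(X)
        if return_scores:
            return pred, self.model.predict_proba(X)
        return pred


def fit_classifier(cfg, X, y):
    """Dispatch on config type; returns a fitted harness."""
    X = np.asarray(X, dtype=np.float64)
    if not np.all(np.isfinite(X)):
        raise ValueError("features contain non-finite values")
    labels_to_indices(np.asarray(y))  # validates symbols
    if isinstance(cfg, RfConfig):
        return RandomForestHarness(cfg).fit(X, y)
    if isinstance(cfg, ResNetConfig):
        return ResNetHarness(cfg).fit(X, y)
    raise TypeError(f"unknown classifier config {type(cfg).__name__}")


def predict(model, X, return_scores: bool = False):
    return model.predict(X, return_scores=return_scores)


def pca_sweep(beatset, k_values, clf_cfg, folds: int = 3, seed: int = 0,
              normalize: bool = True):
    """Cross-validated classification quality as a function of k.

    All k values share the same folds and classifier seed, so differences
    reflect the representation only.  Returns {k: MetricReport}.
    """
    from .pca import fit_pca, minmax_normalize
    from .evaluate import kfold_split, classification_report

    X = minmax_normalize(beatset.X) if normalize else beatset.X
    y = beatset.y.astype(str)
    splits = kfold_split(y, folds=folds, seed=seed)
    out = {}
    for k in k_values:
        if not 1 <= k <= X.shape[1]:
            raise ValueError(f"k={k} outside [1, {X.shape[1]}]")
        y_true_all, y_pred_all = [], []
        for tr, te in splits:
            space = fit_pca(X[tr], k=k)
            model = fit_classifier(clf_cfg, space.transform(X[tr]), y[tr])
            y_pred_all.append(model.predict(space.transform(X[te])))
            y_true_all.append(y[te])
        out[k] = classification_report(np.concatenate(y_true_all),
                                       np.concatenate(y_pred_all))
    return out
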