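"""Quantitative reporting: normalized reconstruction metrics, classification
reports with macro/sample-std conventions, k-fold splits, and
distribution-consistency metrics for generated samples.

Reconstruction metrics divide the classical RMSE / MAE / PRD by the
amplitude range of the original signal, making them invariant to a common
rescaling of both signals:

    NRMSE = sqrt(mean((y - yhat)^2)) / (ymax - ymin)
    NMAE  = mean(|y - yhat|) / (ymax - ymin)
    NPRD  = 100 * sqrt(sum((y - yhat)^2) / sum(y^2)) / (ymax - ymin)

NPRD follows the classical percent convention (values on the order of
tens); ``raw=True`` drops the factor of 100.

Classification aggregates follow the reporting convention used throughout
this package: the "avg" row is the unweighted (macro) mean of the
per-class values and the "std" row is their sample standard deviation
(n - 1 denominator) over the five classes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold, KFold

from .models import CLASS_SYMBOLS

__all__ = ["SignalPair", "MetricReport", "nrmse", "nmae", "nprd",
           "classification_report", "kfold_split", "distribution_report",
           "macro_stats"]


@dataclass
class SignalPair:
    y: np.ndarray      # original
    yhat: np.ndarray   # generated / reconstructed

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=np.float64).ravel()
        self.yhat = np.asarray(self.yhat, dtype=np.float64).ravel()
        if self.y.shape != self.yhat.shape:
            raise ValueError("signals must have equal length")
        if len(self.y) == 0:
            raise ValueError("signals must be nonempty")

    @property
    def amplitude_range(self) -> float:
        r = float(np.ptp(self.y))
        if r == 0:
            raise ValueError("metric undefined: original signal is constant")
        return r


def nrmse(pair: SignalPair) -> float:
    return float(np.sqrt(np.mean((pair.y - pair.yhat) ** 2))) / pair.amplitude_range


def nmae(pair: SignalPair) -> float:
    return float(np.mean(np.abs(pair.y - pair.yhat))) / pair.amplitude_range


def nprd(pair: SignalPair, raw: bool = False) -> float:
    energy = float(np.sum(pair.y ** 2))
    if energy == 0:
        raise ValueError("NPRD undefined: original signal has zero energy")
    prd = np.sqrt(float(np.sum((pair.y - pair.yhat) ** 2)) / energy)
    scale = 1.0 if raw else 100.0
    return scale * prd / pair.amplitude_range


# ---------------------------------------------------------------------------
# classification reporting
# ---------------------------------------------------------------------------

@dataclass
class MetricReport:
    class_order: tuple
    precision: dict            # per-class, percent
    recall: dict
    f1: dict
    macro_precision: float
    macro_recall: float
    macro_f1: float
    std_precision: float       # sample std (n-1) of the per-class values
    std_recall: float
    std_f1: float
    accuracy: float
    confusion: np.ndarray      # rows = true class, cols = predicted
    zero_division_flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "class_order": list(self.class_order),
            "precision": self.precision, "recall": self.recall, "f1": self.f1,
            "macro": {"precision": self.macro_precision,
                      "recall": self.macro_recall, "f1": self.macro_f1},
            "std": {"precision": self.std_precision,
                    "recall": self.std_recall, "f1": self.std_f1},
            "accuracy": self.accuracy,
            "confusion": self.confusion.tolist(),
            "zero_division_flags": self.zero_division_flags,
        }


def macro_stats(values) -> tuple[float, float]:
    """(unweighted mean, sample std with n-1 denominator) of per-class values."""
    v = np.asarray(values, dtype=np.float64)
    return float(v.mean()), float(v.std(ddof=1)) if len(v) > 1 else 0.0


def classification_report(y_true, y_pred,
                          class_order=CLASS_SYMBOLS) -> MetricReport:
    """Per-class one-vs-rest precision/recall/F1 in percent, plus aggregates."""
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    idx = {c: i for i, c in enumerate(class_order)}
    if not set(y_true).issubset(idx) or not set(y_pred).issubset(idx):
        raise ValueError(f"labels outside class_order: "
                         f"{sorted(set(list(y_true) + list(y_pred)) - set(class_order))}")
    m = len(class_order)
    conf = np.zeros((m, m), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        conf[idx[t], idx[p]] += 1
    prec, rec, f1 = {}, {}, {}
    flags = []
    for i, c in enumerate(class_order):
        tp = conf[i, i]
        pred_pos = conf[:, i].sum()
        true_pos = conf[i, :].sum()
        if pred_pos == 0:
            prec[c] = 0.0
            flags.append(f"precision[{c}] set to 0 (no predicted positives)")
        else:
            prec[c] = 100.0 * tp / pred_pos
        rec[c] = 100.0 * tp / true_pos if true_pos else 0.0
        denom = prec[c] + rec[c]
        f1[c] = 2.0 * prec[c] * rec[c] / denom if denom else 0.0
    mp, sp = macro_stats(list(prec.values()))
    mr, sr = macro_stats(list(rec.values()))
    mf, sf = macro_stats(list(f1.values()))
    acc = 100.0 * np.trace(conf) / conf.sum() if conf.sum() else 0.0
    return MetricReport(tuple(class_order), prec, rec, f1, mp, mr, mf,
                        sp, sr, sf, float(acc), conf, flags)


def kfold_split(y, folds: int = 5, seed: int = 0, stratified: bool = True):
    """Deterministic (stratified) k-fold index partitions.

    Accepts a BeatSet or a label array.  Classes with fewer members than
    ``folds`` trigger a warning and an unstratified split.
    """
    y = np.asarray(getattr(y, "y", y)).astype(str)
    n = len(y)
    if n < folds:
        raise ValueError(f"need at least {folds} samples for {folds} folds")
    if stratified:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < folds:
            warnings.warn("a class has fewer members than folds; "
                          "falling back to an unstratified split")
            stratified = False
    if stratified:
        kf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        return list(kf.split(np.zeros(n), y))
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(kf.split(np.zeros(n)))


# ---------------------------------------------------------------------------
# distribution consistency of generated component vectors
# ---------------------------------------------------------------------------

def distribution_report(real_comps: np.ndarray, fake_comps: np.ndarray,
                        bins: int = 50) -> dict[str, float]:
    """Per-dimension 1-D Wasserstein-1 / Jensen-Shannon / two-sample KS,
    each averaged over the k component dimensions.

    JS divergence uses shared ``bins``-bin histograms over the pooled range
    and the natural-log convention (upper bound ln 2).
    """
    real = np.atleast_2d(np.asarray(real_comps, dtype=np.float64))
    fake = np.atleast_2d(np.asarray(fake_comps, dtype=np.float64))
    if real.size == 0 or fake.size == 0:
        raise ValueError("both samples must be nonempty")
    if real.shape[1] != fake.shape[1]:
        raise ValueError("component dimension mismatch")
    w, js, ks = [], [], []
    for d in range(real.shape[1]):
        a, b = real[:, d], fake[:, d]
        w.append(stats.wasserstein_distance(a, b))
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        if hi == lo:
            hi = lo + 1.0
        pa, _ = np.histogram(a, bins=bins, range=(lo, hi), density=False)
        pb, _ = np.histogram(b, bins=bins, range=(lo, hi), density=False)
        js.append(_js_divergence(pa / pa.sum(), pb / pb.sum()))
        ks.append(stats.ks_2samp(a, b).pvalue)
    return {"wasserstein_1": float(np.mean(w)),
            "js_divergence": float(np.mean(js)),
            "ks_p_value": float(np.mean(ks))}


def _js_divergence(p: np.ndarray, q: np.ndarray) -> float:
    m = 0.5 * (p + q)

    def kl(a, b):
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))

    return 0.5 * kl(p, m) + 0.5 * kl(q, m)
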