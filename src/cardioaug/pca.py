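"""The PCA feature space: fit, project, invert, and diagnose.

Beats live in a W-dimensional sample space; the generation target of this
package is their coordinate vector in the top-k eigenvector basis of the
beat covariance (default k = 16).  The projection is affine
(x -> components @ (x - mean)) and its pseudo-inverse maps generated
component vectors back to waveforms.  A fixed sign convention (the
largest-|loading| entry of every component is positive) makes fitted
spaces, and therefore component heat maps, comparable across runs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.decomposition import PCA

__all__ = ["PcaSpace", "fit_pca", "component_heatmap", "minmax_normalize"]


@dataclass
class PcaSpace:
    mean: np.ndarray                 # (W,)
    components: np.ndarray           # (k, W), orthonormal rows
    explained_var_ratio: np.ndarray  # (k,), fractions of *total* variance
    k: int

    def transform(self, beats: np.ndarray) -> np.ndarray:
        beats = np.atleast_2d(np.asarray(beats, dtype=np.float64))
        if beats.shape[1] != self.mean.shape[0]:
            raise ValueError(f"beats have width {beats.shape[1]}, "
                             f"space expects {self.mean.shape[0]}")
        return (beats - self.mean) @ self.components.T

    def inverse_transform(self, comps: np.ndarray) -> np.ndarray:
        comps = np.atleast_2d(np.asarray(comps, dtype=np.float64))
        if comps.shape[1] != self.k:
            raise ValueError(f"component vectors have dim {comps.shape[1]}, "
                             f"space expects k={self.k}")
        return comps @ self.components + self.mean

    def cumulative_ratio(self, j: int) -> float:
        """Cumulative explained-variance ratio of the first ``j`` components."""
        return float(np.sum(self.explained_var_ratio[:j]))

    # -- persistence ---------------------------------------------------------
    def save(self, path) -> None:
        Path(path).write_text(json.dumps({
            "mean": self.mean.tolist(),
            "components": self.components.tolist(),
            "explained_var_ratio": self.explained_var_ratio.tolist(),
            "k": self.k}))

    @classmethod
    def load(cls, path) -> "PcaSpace":
        d = json.loads(Path(path).read_text())
        return cls(np.array(d["mean"]), np.array(d["components"]),
                   np.array(d["explained_var_ratio"]), int(d["k"]))


def minmax_normalize(X: np.ndarray) -> np.ndarray:
    """Per-beat min-max amplitude normalisation to [0, 1]."""
    X = np.atleast_2d(np.asarray(X, dtype=np.float64))
    lo = X.min(axis=1, keepdims=True)
    rng = np.ptp(X, axis=1, keepdims=True)
    rng[rng == 0] = 1.0
    return (X - lo) / rng


def fit_pca(X, k: int = 16) -> PcaSpace:
    """Top-k principal components of a beat matrix (rows = beats).

    Accepts a BeatSet or an (n, W) array.  Components carry the fixed sign
    convention; explained-variance ratios are fractions of the total
    variance over all W directions, so they sum to 1 at k = W.
    """
    X = np.asarray(getattr(X, "X", X), dtype=np.float64)
    n, W = X.shape
    if not 1 <= k <= min(n, W):
        raise ValueError(f"k must be in [1, min(n, W)] = [1, {min(n, W)}]")
    if not np.all(np.isfinite(X)):
        raise ValueError("beat matrix contains non-finite values")
    p = PCA(n_components=k, svd_solver="full")
    p.fit(X)
    comps = p.components_.copy()
    # sign convention: largest-|loading| entry of each component positive
    for i in range(k):
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return PcaSpace(mean=p.mean_.copy(), components=comps,
                    explained_var_ratio=p.explained_variance_ratio_.copy(), k=k)


def component_heatmap(comp_vector) -> np.ndarray:
    """Row-major 4x4 view of a 16-component vector (heat-map layout)."""
    v = np.asarray(comp_vector, dtype=np.float64).ravel()
    if v.shape[0] != 16:
        raise ValueError(f"expected 16 components, got {v.shape[0]}")
    return v.reshape(4, 4)
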