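"""The four conditional networks: encoder, decoder, generator, discriminator.

All four share one conditional backbone.  With the transformer backbone,
each scalar of the input vector becomes one token (scalar -> width
projection plus a learned positional embedding) and a class-conditioning
token — the class embedding projected to model width — is prepended; the
network reads out from that conditioning token.  The MLP backbone simply
concatenates the input vector with the class embedding.

The generator maps noise to codes in the encoder's latent space; the
decoder turns codes (real or generated) into PCA component vectors; the
discriminator scores PCA-space vectors by default (decoded fakes), with a
flag for latent-space scoring.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .nn.autograd import Tensor, concat, no_grad
from .nn.layers import Module, Linear, Embedding, TransformerBlock

__all__ = [
    "CLASS_SYMBOLS", "ModelConfig", "ConditionalNet", "CganBundle",
    "labels_to_indices", "one_hot",
]

CLASS_SYMBOLS = ("N", "A", "V", "L", "R")
_SYMBOL_INDEX = {s: i for i, s in enumerate(CLASS_SYMBOLS)}


def labels_to_indices(labels) -> np.ndarray:
    """Map class symbols (N/A/V/L/R) to integer indices; validates symbols."""
    try:
        return np.array([_SYMBOL_INDEX[str(s)] for s in np.atleast_1d(labels)],
                        dtype=np.intp)
    except KeyError as e:
        raise ValueError(f"unknown beat class {e.args[0]!r}; "
                         f"expected one of {CLASS_SYMBOLS}") from None


def one_hot(labels) -> np.ndarray:
    idx = labels_to_indices(labels)
    out = np.zeros((len(idx), len(CLASS_SYMBOLS)))
    out[np.arange(len(idx)), idx] = 1.0
    return out


@dataclass
class ModelConfig:
    """Capacity and conditioning settings shared by the four networks.

    Defaults mirror the experimental configuration: a 2-layer transformer
    with 8 attention heads, hidden width 512 and a 256-dimensional class
    embedding.  ``latent_dim`` defaults to ``k`` so that latent codes and
    PCA component vectors are interchangeable in shape.
    """

    k: int = 16
    backbone: str = "transformer"   # "transformer" | "mlp"
    layers: int = 2
    heads: int = 8
    width: int = 512
    cond_embed_dim: int = 256
    latent_dim: int | None = None
    n_classes: int = len(CLASS_SYMBOLS)
    discriminate_latent: bool = False
    conditional: bool = True        # ablation flag: drop class conditioning

    def __post_init__(self):
        if self.backbone not in ("transformer", "mlp"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.backbone == "transformer" and self.width % self.heads:
            raise ValueError("width must be divisible by heads")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.latent_dim is None:
            self.latent_dim = self.k
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")


class ConditionalNet(Module):
    """Conditional vector-to-vector function approximator."""

    def __init__(self, cfg: ModelConfig, d_in: int, d_out: int,
                 rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        self.d_in, self.d_out = d_in, d_out
        w = cfg.width
        self.class_embed = Embedding(cfg.n_classes, cfg.cond_embed_dim, rng)
        if cfg.backbone == "transformer":
            self.tok_proj = Linear(1, w, rng)
            self.pos = Tensor(rng.normal(0.0, 0.02, size=(d_in, w)),
                              requires_grad=True)
            self.cond_proj = Linear(cfg.cond_embed_dim, w, rng)
            self.blocks = [TransformerBlock(w, cfg.heads, rng)
                           for _ in range(cfg.layers)]
            self.head = Linear(w, d_out, rng)
        else:
            d0 = d_in + (cfg.cond_embed_dim if cfg.conditional else 0)
            self.fc = [Linear(d0, w, rng)]
            self.fc += [Linear(w, w, rng) for _ in range(cfg.layers - 1)]
            self.head = Linear(w, d_out, rng)

    def __call__(self, x: Tensor | np.ndarray, class_idx) -> Tensor:
        x = x if isinstance(x, Tensor) else Tensor(x)
        if x.ndim != 2 or x.shape[1] != self.d_in:
            raise ValueError(f"expected input of shape (n, {self.d_in}), "
                             f"got {x.shape}")
        class_idx = np.asarray(class_idx, dtype=np.intp)
        if class_idx.ndim == 0:
            class_idx = np.repeat(class_idx, x.shape[0])
        if np.any(class_idx < 0) or np.any(class_idx >= self.cfg.n_classes):
            raise ValueError("class index out of range")
        emb = self.class_embed(class_idx)
        if not self.cfg.conditional:
            emb = emb * 0.0
        if self.cfg.backbone == "transformer":
            n, k = x.shape
            tok = self.tok_proj(x.reshape(n, k, 1)) + self.pos
            cond = self.cond_proj(emb).reshape(n, 1, self.cfg.width)
            h = concat([cond, tok], axis=1)
            for blk in self.blocks:
                h = blk(h)
            return self.head(h[:, 0, :])
        h = concat([x, emb], axis=1)
        for lin in self.fc:
            h = lin(h).leaky_relu(0.2)
        return self.head(h)

    def forward_numpy(self, x: np.ndarray, class_idx) -> np.ndarray:
        """Graph-free eval-mode forward pass."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                return self(Tensor(x), class_idx).numpy()
        finally:
            self.training = was_training


def build_networks(cfg: ModelConfig, seed: int):
    """Construct (encoder, decoder, generator, discriminator) from one seed."""
    rng = np.random.default_rng(seed)
    enc = ConditionalNet(cfg, cfg.k, cfg.latent_dim, rng)
    dec = ConditionalNet(cfg, cfg.latent_dim, cfg.k, rng)
    gen = ConditionalNet(cfg, cfg.latent_dim, cfg.latent_dim, rng)
    d_in = cfg.latent_dim if cfg.discriminate_latent else cfg.k
    disc = ConditionalNet(cfg, d_in, 1, rng)
    return enc, dec, gen, disc


@dataclass
class CganBundle:
    """The four trained networks plus their config and loss histories."""

    config: ModelConfig
    encoder: ConditionalNet
    decoder: ConditionalNet
    generator: ConditionalNet
    discriminator: ConditionalNet
    stage1_history: dict = field(default_factory=dict)
    stage2_history: dict = field(default_factory=dict)
    trained_stages: int = 0

    # -- inference ------------------------------------------------------------
    def encode(self, x_pca: np.ndarray, labels) -> np.ndarray:
        return self.encoder.forward_numpy(np.atleast_2d(x_pca),
                                          labels_to_indices(labels))

    def decode(self, s: np.ndarray, labels) -> np.ndarray:
        return self.decoder.forward_numpy(np.atleast_2d(s),
                                          labels_to_indices(labels))

    def generate(self, labels, rng: np.random.Generator) -> np.ndarray:
        """Noise -> latent codes -> decoded PCA component vectors."""
        idx = labels_to_indices(labels)
        if len(idx) == 0:
            return np.zeros((0, self.config.k))
        z = rng.standard_normal((len(idx), self.config.latent_dim))
        h = self.generator.forward_numpy(z, idx)
        return self.decoder.forward_numpy(h, idx)

    def discriminate(self, x: np.ndarray, labels) -> np.ndarray:
        return self.discriminator.forward_numpy(
            np.atleast_2d(x), labels_to_indices(labels)).ravel()

    # -- persistence ----------------------------------------------------------
    def save(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        arrays = {}
        for name, net in self._nets():
            for i, a in enumerate(net.state_arrays()):
                arrays[f"{name}_{i}"] = a
        np.savez(path.with_suffix(".npz"), **arrays)
        meta = {"config": asdict(self.config),
                "trained_stages": self.trained_stages,
                "stage1_history": _hist_to_json(self.stage1_history),
                "stage2_history": _hist_to_json(self.stage2_history)}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path, seed: int = 0) -> "CganBundle":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        cfg = ModelConfig(**meta["config"])
        enc, dec, gen, disc = build_networks(cfg, seed)
        bundle = cls(cfg, enc, dec, gen, disc,
                     stage1_history=meta.get("stage1_history", {}),
                     stage2_history=meta.get("stage2_history", {}),
                     trained_stages=meta.get("trained_stages", 0))
        with np.load(path.with_suffix(".npz")) as z:
            for name, net in bundle._nets():
                arrays = []
                i = 0
                while f"{name}_{i}" in z:
                    arrays.append(z[f"{name}_{i}"])
                    i += 1
                net.load_arrays(arrays)
        return bundle

    def _nets(self):
        return [("encoder", self.encoder), ("decoder", self.decoder),
                ("generator", self.generator),
                ("discriminator", self.discriminator)]


def _hist_to_json(hist: dict) -> dict:
    return {k: [float(x) for x in v] for k, v in hist.items()}
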