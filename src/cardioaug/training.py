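"""Two-stage training: reconstruction pretraining then adversarial training.

Stage 1 fits the conditional encoder-decoder by mean-squared reconstruction
error on PCA component vectors.  Stage 2 freezes nothing: the generator
learns to emit latent codes whose decodings fool a conditional critic.
Default objective is WGAN-GP (critic maximises score(real) - score(fake)
minus an interpolate gradient penalty, lambda = 10) with two critic updates
per generator update; auxiliary L1/L2 terms pull decoded fakes toward the
class-matched real batch mean.  A vanilla log-loss mode is kept for
comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .nn.autograd import Tensor, grad, backward
from .nn.optim import Adam
from .models import ModelConfig, ConditionalNet, CganBundle, build_networks

__all__ = ["TrainConfig", "TrainState", "train_stage1", "train_stage2",
           "train_cgan", "gradient_penalty"]


@dataclass
class TrainConfig:
    """Optimisation settings (defaults mirror the experimental setup)."""

    batch: int = 32
    epochs: int = 500
    lr: float = 1e-4
    adam_beta1: float = 0.5
    adam_beta2: float = 0.999
    gp_lambda: float = 10.0
    aux_l1_weight: float = 1.0
    aux_l2_weight: float = 1.0
    d_steps_per_g: int = 2
    loss_mode: str = "wgan_gp"      # "wgan_gp" | "vanilla"
    balanced_sampling: bool = True  # inverse-frequency minibatch sampling
    seed: int = 0
    collapse_var_eps: float = 1e-6
    collapse_patience: int = 20

    def __post_init__(self):
        if self.batch < 1 or self.epochs < 1 or self.lr <= 0:
            raise ValueError("batch, epochs and lr must be positive")
        if self.d_steps_per_g < 1:
            raise ValueError("d_steps_per_g must be >= 1")
        if self.loss_mode not in ("wgan_gp", "vanilla"):
            raise ValueError(f"unknown loss_mode {self.loss_mode!r}")


@dataclass
class TrainState:
    epoch: int = 0
    loss_history: dict = field(default_factory=dict)
    mode_collapse: bool = False
    n_critic_updates: int = 0
    n_generator_updates: int = 0

    def record(self, **losses):
        for k, v in losses.items():
            self.loss_history.setdefault(k, []).append(float(v))


class NaNLossError(RuntimeError):
    pass


def _check_finite(value: float, what: str, epoch: int, lr: float):
    if not np.isfinite(value):
        raise NaNLossError(
            f"{what} became non-finite at epoch {epoch} (lr={lr}); "
            "reduce the learning rate or inspect the input scaling")


def _batches(labels_idx: np.ndarray, batch: int, rng: np.random.Generator,
             balanced: bool):
    """Minibatch index stream for one epoch.

    With ``balanced=True`` indices are drawn with replacement with
    inverse-class-frequency weights, so rare classes receive the same
    expected gradient share as common ones — the conditional networks
    must carve out feature space for every class, not just the majority.
    """
    n = len(labels_idx)
    if balanced:
        _, inverse, counts = np.unique(labels_idx, return_inverse=True,
                                       return_counts=True)
        w = 1.0 / counts[inverse]
        idx = rng.choice(n, size=n, replace=True, p=w / w.sum())
    else:
        idx = rng.permutation(n)
    for start in range(0, n, batch):
        b = idx[start:start + batch]
        if len(b) == 1:
            continue
        yield b


def train_stage1(x_pca: np.ndarray, labels_idx: np.ndarray,
                 encoder: ConditionalNet, decoder: ConditionalNet,
                 cfg: TrainConfig) -> TrainState:
    """Reconstruction pretraining of the conditional encoder-decoder."""
    x_pca = np.asarray(x_pca, dtype=np.float64)
    n = len(x_pca)
    if n < 2:
        raise ValueError("need at least 2 training vectors")
    rng = np.random.default_rng(cfg.seed)
    params = encoder.parameters() + decoder.parameters()
    opt = Adam(params, lr=cfg.lr, betas=(cfg.adam_beta1, cfg.adam_beta2))
    state = TrainState()
    encoder.train(); decoder.train()
    for epoch in range(cfg.epochs):
        ep_loss, nb = 0.0, 0
        for b in _batches(labels_idx, cfg.batch, rng, cfg.balanced_sampling):
            xb, yb = Tensor(x_pca[b]), labels_idx[b]
            s = encoder(xb, yb)
            xhat = decoder(s, yb)
            diff = xhat - xb
            loss = (diff * diff).mean()
            opt.zero_grad()
            backward(loss, params)
            opt.step()
            ep_loss += loss.item(); nb += 1
        ep_loss /= max(nb, 1)
        _check_finite(ep_loss, "reconstruction loss", epoch, cfg.lr)
        state.record(l_rec=ep_loss)
        state.epoch = epoch + 1
    return state


def gradient_penalty(discriminator: ConditionalNet, real: Tensor | np.ndarray,
                     fake: Tensor | np.ndarray, labels_idx,
                     lam: float, rng: np.random.Generator) -> Tensor:
    """Interpolate gradient penalty lam * mean((||grad D(xhat)|| - 1)^2).

    xhat = eps*real + (1-eps)*fake with eps ~ U(0,1) per sample; the result
    is a graph node so its parameter gradient flows through the critic.
    """
    if lam == 0.0:
        return Tensor(0.0)
    real_d = real.data if isinstance(real, Tensor) else np.asarray(real)
    fake_d = fake.data if isinstance(fake, Tensor) else np.asarray(fake)
    if real_d.shape != fake_d.shape:
        raise ValueError("real and fake batches must share a shape")
    eps = rng.uniform(size=(len(real_d), 1))
    xhat = Tensor(eps * real_d + (1.0 - eps) * fake_d, requires_grad=True)
    score = discriminator(xhat, labels_idx).sum()
    g = grad(score, xhat, create_graph=True)
    norm = ((g * g).sum(axis=1) + 1e-12).sqrt()
    dev = norm - 1.0
    return (dev * dev).mean() * lam


def train_stage2(x_pca: np.ndarray, labels_idx: np.ndarray,
                 encoder: ConditionalNet, decoder: ConditionalNet,
                 generator: ConditionalNet, discriminator: ConditionalNet,
                 model_cfg: ModelConfig, cfg: TrainConfig) -> TrainState:
    """Adversarial training of the conditional generator and critic."""
    x_pca = np.asarray(x_pca, dtype=np.float64)
    n = len(x_pca)
    rng = np.random.default_rng(cfg.seed + 1)
    latent = model_cfg.latent_dim

    g_params = generator.parameters()
    d_params = discriminator.parameters()
    opt_g = Adam(g_params, lr=cfg.lr, betas=(cfg.adam_beta1, cfg.adam_beta2))
    opt_d = Adam(d_params, lr=cfg.lr, betas=(cfg.adam_beta1, cfg.adam_beta2))
    state = TrainState()
    generator.train(); discriminator.train()
    decoder.eval()
    collapse_run = 0

    def fake_batch(yb):
        z = Tensor(rng.standard_normal((len(yb), latent)))
        h = generator(z, yb)
        if model_cfg.discriminate_latent:
            return h, h
        return decoder(h, yb), h

    for epoch in range(cfg.epochs):
        ep_d, ep_g, nb_d, nb_g = 0.0, 0.0, 0, 0
        fake_var = []
        for b in _batches(labels_idx, cfg.batch, rng, cfg.balanced_sampling):
            yb = labels_idx[b]
            realb = Tensor(x_pca[b]) if not model_cfg.discriminate_latent \
                else encoder(Tensor(x_pca[b]), yb).detach()
            # -- critic updates ------------------------------------------------
            for _ in range(cfg.d_steps_per_g):
                fb, _ = fake_batch(yb)
                fb = fb.detach()
                d_real = discriminator(realb, yb)
                d_fake = discriminator(fb, yb)
                if cfg.loss_mode == "wgan_gp":
                    gp = gradient_penalty(discriminator, realb, fb, yb,
                                          cfg.gp_lambda, rng)
                    loss_d = d_fake.mean() - d_real.mean() + gp
                else:
                    pr, pf = d_real.sigmoid(), d_fake.sigmoid()
                    loss_d = -((pr + 1e-12).log().mean()
                               + (1.0 - pf + 1e-12).log().mean())
                opt_d.zero_grad()
                backward(loss_d, d_params)
                opt_d.step()
                ep_d += loss_d.item(); nb_d += 1
                state.n_critic_updates += 1
            # -- generator update ---------------------------------------------
            fb, h = fake_batch(yb)
            d_fake = discriminator(fb, yb)
            if cfg.loss_mode == "wgan_gp":
                loss_g = -d_fake.mean()
            else:
                pf = d_fake.sigmoid()
                loss_g = (1.0 - pf + 1e-12).log().mean()
            if cfg.aux_l1_weight or cfg.aux_l2_weight:
                loss_g = loss_g + _aux_consistency(fb, realb, yb,
                                                   cfg.aux_l1_weight,
                                                   cfg.aux_l2_weight)
            opt_g.zero_grad()
            backward(loss_g, g_params)
            opt_g.step()
            ep_g += loss_g.item(); nb_g += 1
            state.n_generator_updates += 1
            fake_var.append(fb.data.var(axis=0).mean())
        ep_d /= max(nb_d, 1); ep_g /= max(nb_g, 1)
        _check_finite(ep_d, "critic loss", epoch, cfg.lr)
        _check_finite(ep_g, "generator loss", epoch, cfg.lr)
        state.record(l_d=ep_d, l_g=ep_g)
        state.epoch = epoch + 1
        if fake_var and np.mean(fake_var) < cfg.collapse_var_eps:
            collapse_run += 1
            if collapse_run >= cfg.collapse_patience and not state.mode_collapse:
                state.mode_collapse = True
                warnings.warn("possible mode collapse: fake-batch variance "
                              f"below {cfg.collapse_var_eps} for "
                              f"{cfg.collapse_patience} epochs")
        else:
            collapse_run = 0
    return state


def _aux_consistency(fake: Tensor, real: Tensor, yb: np.ndarray,
                     w1: float, w2: float) -> Tensor:
    """L1/L2 pull of per-class fake means toward per-class real means."""
    total = Tensor(0.0)
    classes = np.unique(yb)
    for c in classes:
        m = yb == c
        sel = np.flatnonzero(m)
        diff = fake.take(sel, axis=0).mean(axis=0) - \
            Tensor(real.data[sel].mean(axis=0))
        if w1:
            total = total + diff.abs().mean() * w1
        if w2:
            total = total + (diff * diff).mean() * w2
    return total * (1.0 / len(classes))


def train_cgan(x_pca: np.ndarray, labels_idx: np.ndarray,
               model_cfg: ModelConfig, stage1_cfg: TrainConfig,
               stage2_cfg: TrainConfig | None = None,
               seed: int | None = None) -> CganBundle:
    """Convenience wrapper: build networks, run stage 1 then stage 2."""
    seed = stage1_cfg.seed if seed is None else seed
    enc, dec, gen, disc = build_networks(model_cfg, seed)
    s1 = train_stage1(x_pca, labels_idx, enc, dec, stage1_cfg)
    bundle = CganBundle(model_cfg, enc, dec, gen, disc,
                        stage1_history=s1.loss_history, trained_stages=1)
    if stage2_cfg is not None:
        s2 = train_stage2(x_pca, labels_idx, enc, dec, gen, disc,
                          model_cfg, stage2_cfg)
        bundle.stage2_history = s2.loss_history
        bundle.stage2_history["mode_collapse"] = [float(s2.mode_collapse)]
        bundle.trained_stages = 2
    return bundle
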