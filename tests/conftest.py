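import numpy as np
import pytest

from cardioaug.synth import SynthConfig, make_dataset


def quiet_config(seed: int = 0, **overrides) -> SynthConfig:
    """Simulator config with all stochastic effects switched off."""
    params = dict(seed=seed, amplitude_jitter_sd=0.0, wave_center_jitter_sd=0.0,
                  wave_amp_jitter_sd=0.0, patient_scale_sd=0.0,
                  patient_offset_sd=0.0, noise_sd=0.0, baseline_wander_amp=0.0,
                  powerline_amp=0.0)
    params.update(overrides)
    return SynthConfig(**params)


@pytest.fixture(scope="session")
def balanced_clean_beats():
    """500 noiseless beats, 100 per class."""
    return make_dataset(quiet_config(seed=11), n_beats=500,
                        proportions={c: 0.2 for c in "NAVLR"})


@pytest.fixture(scope="session")
def default_beats():
    """600 beats under the default (noisy, imbalanced) study conditions."""
    return make_dataset(SynthConfig(seed=7), n_beats=600, noisy=True)


@pytest.fixture(scope="session")
def tiny_trained_bundle():
    """A small conditional GAN trained on well-separated 2-class data.

    Session-scoped: several tests assert post-training properties on it.
    """
    from cardioaug.models import ModelConfig
    from cardioaug.training import TrainConfig, train_cgan

    rng = np.random.default_rng(42)
    n = 150
    mu = {0: np.array([3.0, 0.0, -2.0, 1.0]), 1: np.array([-3.0, 2.0, 2.0, -1.0])}
    X = np.vstack([rng.normal(mu[c], 0.3, size=(n, 4)) for c in (0, 1)])
    y = np.repeat([0, 1], n)
    cfg = ModelConfig(k=4, backbone="mlp", width=32, cond_embed_dim=8,
                      layers=2, heads=4)
    bundle = train_cgan(
        X, y, cfg,
        TrainConfig(epochs=40, lr=1e-3, seed=0),
        TrainConfig(epochs=60, lr=1e-3, seed=0))
    return bundle, X, y, mu
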