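"""Pipeline configuration: one structured file (YAML or JSON) validated
into the nested dataclass configs of the individual stages."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synth import SynthConfig
from .preprocess import WaveletConfig
from .models import ModelConfig
from .training import TrainConfig
from .augment import GateConfig
from .classifiers import RfConfig, ResNetConfig

__all__ = ["PipelineConfig", "load_pipeline_config", "small_synthetic_config"]


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "runs/run0"
    # data source: the synthetic simulator by default, else a record directory
    synthetic: bool = True
    n_beats: int = 2000
    data_dir: str | None = None
    test_fraction: float = 0.25
    pca_k: int = 16
    normalize: str = "minmax"       # "minmax" | "none"
    synth: SynthConfig = field(default_factory=SynthConfig)
    wavelet: WaveletConfig = field(default_factory=WaveletConfig)
    model: ModelConfig = field(default_factory=lambda: ModelConfig(k=16))
    stage1: TrainConfig = field(default_factory=TrainConfig)
    stage2: TrainConfig = field(default_factory=TrainConfig)
    gate: GateConfig = field(default_factory=GateConfig)
    classifier: str = "rf"          # "rf" | "resnet"
    rf: RfConfig = field(default_factory=RfConfig)
    resnet: ResNetConfig = field(default_factory=ResNetConfig)
    target_per_class: int | None = None   # None -> majority count

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.classifier not in ("rf", "resnet"):
            raise ValueError(f"unknown classifier {self.classifier!r}")
        if self.model.k != self.pca_k:
            self.model.k = self.pca_k
            self.model.__post_init__()

    def config_hash(self) -> str:
        blob = json.dumps(_as_jsonable(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def save(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(_as_jsonable(self),
                                             sort_keys=False))


def _as_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _as_jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_as_jsonable(x) for x in obj]
    return obj


_NESTED = {"synth": SynthConfig, "wavelet": WaveletConfig,
           "model": ModelConfig, "stage1": TrainConfig, "stage2": TrainConfig,
           "gate": GateConfig, "rf": RfConfig, "resnet": ResNetConfig}


def load_pipeline_config(path) -> PipelineConfig:
    """Load and validate a YAML/JSON pipeline config file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key, val in raw.items():
        if key in _NESTED:
            sub = dict(val)
            if key == "gate" and "surrogate" in sub:
                sub["surrogate"] = RfConfig(**sub["surrogate"])
            kwargs[key] = _NESTED[key](**sub)
        else:
            kwargs[key] = val
    allowed = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(kwargs) - allowed
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**kwargs)


def small_synthetic_config(seed: int = 0, out_dir: str = "runs/small") -> PipelineConfig:
    """Desk-scale defaults: k=16 components, width-32 networks, 60 + 120
    training epochs on ~2,000 synthetic beats with the A class near 2%."""
    return PipelineConfig(
        seed=seed, out_dir=out_dir, synthetic=True, n_beats=2000, pca_k=16,
        synth=SynthConfig(seed=seed),
        model=ModelConfig(k=16, backbone="mlp", width=32, cond_embed_dim=16,
                          layers=2, heads=4),
        stage1=TrainConfig(epochs=60, lr=1e-3, seed=seed),
        stage2=TrainConfig(epochs=120, lr=5e-4, seed=seed),
        gate=GateConfig(disabled=False, batch_per_round=500, max_rounds=12,
                        surrogate=RfConfig(n_trees=60, seed=seed)),
        rf=RfConfig(n_trees=200, seed=seed),
    )
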