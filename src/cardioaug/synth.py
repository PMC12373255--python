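"""Synthetic five-class ECG beat simulator.

Generates single-cycle beats (default 300 samples at 360 Hz) as sums of
Gaussian bumps standing in for the P, Q, R, S and T waves, with the R wave
centred at the window midpoint.  The five default templates are
morphologically disjoint caricatures of the five beat classes:

* N — normal: P + narrow QRS + upright T
* A — atrial premature: early, tall P wave, otherwise normal QRS/T
* V — ventricular premature: no P, wide QRS, inverted T
* L — left bundle branch block: widened, notched QRS (late notch)
* R — right bundle branch block: widened, notched QRS (early notch)

Patient variation is a per-patient lognormal amplitude scale plus a
constant baseline offset; per-beat variation is a lognormal amplitude
jitter.  Noise injection (white Gaussian + sub-1-Hz baseline wander +
powerline sinusoid) is a separate step so denoising can be scored against
the clean beat.

Class-imbalance defaults follow the five-class beat frequencies of the
standard arrhythmia corpus normalised to proportions (N about 77.8%,
A about 2.11%).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np

from .models import CLASS_SYMBOLS

__all__ = [
    "Wave", "BeatTemplate", "SynthConfig", "BeatSet", "DEFAULT_TEMPLATES",
    "DEFAULT_PROPORTIONS", "make_beat", "make_dataset", "add_noise",
    "largest_remainder_counts",
]


class Wave(NamedTuple):
    name: str        # 'P','Q','R','S','T',... ; exactly one 'R' per template
    center: float    # fraction of the window
    width: float     # fraction of the window
    amplitude: float  # mV


@dataclass(frozen=True)
class BeatTemplate:
    class_symbol: str
    waves: tuple[Wave, ...]

    def __post_init__(self):
        if self.class_symbol not in CLASS_SYMBOLS:
            raise ValueError(f"unknown class symbol {self.class_symbol!r}")
        names = [w.name for w in self.waves]
        if names.count("R") != 1:
            raise ValueError("template must designate exactly one R wave")
        r_amp = abs(next(w.amplitude for w in self.waves if w.name == "R"))
        if any(abs(w.amplitude) >= r_amp for w in self.waves if w.name != "R"):
            raise ValueError("R wave must have the largest |amplitude|")
        centers = [w.center for w in self.waves]
        if any(b <= a for a, b in zip(centers, centers[1:])):
            raise ValueError("wave centers must be strictly increasing")
        if any(w.width <= 0 for w in self.waves):
            raise ValueError("wave widths must be positive")

    def evaluate(self, window_len: int) -> np.ndarray:
        """Noiseless template on the sample grid (R at the window midpoint)."""
        t = np.arange(window_len) / window_len
        r_center = next(w.center for w in self.waves if w.name == "R")
        shift = 0.5 - r_center  # centre R mid-window
        out = np.zeros(window_len)
        for w in self.waves:
            out += w.amplitude * np.exp(-0.5 * ((t - (w.center + shift)) / w.width) ** 2)
        return out


DEFAULT_TEMPLATES: dict[str, BeatTemplate] = {
    "N": BeatTemplate("N", (
        Wave("P", 0.30, 0.025, 0.15),
        Wave("Q", 0.45, 0.010, -0.10),
        Wave("R", 0.50, 0.018, 1.00),
        Wave("S", 0.55, 0.012, -0.20),
        Wave("T", 0.70, 0.045, 0.30),
    )),
    "A": BeatTemplate("A", (
        Wave("P", 0.25, 0.022, 0.22),
        Wave("Q", 0.45, 0.010, -0.10),
        Wave("R", 0.50, 0.018, 0.98),
        Wave("S", 0.55, 0.012, -0.20),
        Wave("T", 0.70, 0.045, 0.29),
    )),
    "V": BeatTemplate("V", (
        Wave("Q", 0.42, 0.030, -0.25),
        Wave("R", 0.50, 0.060, 0.90),
        Wave("T", 0.72, 0.050, -0.40),
    )),
    "L": BeatTemplate("L", (
        Wave("P", 0.28, 0.025, 0.12),
        Wave("R", 0.49, 0.040, 0.85),
        Wave("R2", 0.58, 0.025, 0.45),
        Wave("T", 0.75, 0.045, -0.20),
    )),
    "R": BeatTemplate("R", (
        Wave("P", 0.28, 0.025, 0.12),
        Wave("R1", 0.42, 0.025, 0.45),
        Wave("R", 0.51, 0.040, 0.85),
        Wave("S", 0.60, 0.020, -0.35),
        Wave("T", 0.75, 0.045, 0.20),
    )),
}

# five-class beat frequencies of the standard arrhythmia corpus, normalised
MITDB_FIVE_CLASS_COUNTS = {"N": 71732, "A": 1950, "V": 6974, "L": 6578, "R": 4967}
_TOTAL = sum(MITDB_FIVE_CLASS_COUNTS.values())
DEFAULT_PROPORTIONS = {k: v / _TOTAL for k, v in MITDB_FIVE_CLASS_COUNTS.items()}


@dataclass
class SynthConfig:
    window_len: int = 300
    fs: float = 360.0
    patient_count: int = 20
    amplitude_jitter_sd: float = 0.10   # lognormal sigma, per beat
    wave_center_jitter_sd: float = 0.008  # per-wave timing jitter, window fraction
    wave_amp_jitter_sd: float = 0.15    # per-wave lognormal amplitude jitter
    patient_scale_sd: float = 0.15      # lognormal sigma, per patient
    patient_offset_sd: float = 0.05     # mV, per patient
    baseline_wander_amp: float = 0.10   # mV
    baseline_wander_hz: float = 0.5
    noise_sd: float = 0.05              # mV white noise
    powerline_hz: float = 60.0
    powerline_amp: float = 0.02         # mV
    r_offset: int = 0                   # shift of R from the window midpoint
    seed: int = 0

    def __post_init__(self):
        if self.window_len < 32:
            raise ValueError("window_len must be >= 32")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for name in ("amplitude_jitter_sd", "wave_center_jitter_sd",
                     "wave_amp_jitter_sd", "patient_scale_sd",
                     "patient_offset_sd", "baseline_wander_amp", "noise_sd",
                     "powerline_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.patient_count < 1:
            raise ValueError("patient_count must be >= 1")


@dataclass
class BeatSet:
    """Fixed-length beat windows with labels and patient ids."""

    X: np.ndarray                # (n, W) mV
    y: np.ndarray                # (n,) class symbols
    patient_ids: np.ndarray      # (n,)
    fs: float = 360.0

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            self.X = self.X.reshape(len(self.y), -1)
        self.y = np.asarray(self.y, dtype=object)
        self.patient_ids = np.asarray(self.patient_ids)
        if not (len(self.X) == len(self.y) == len(self.patient_ids)):
            raise ValueError("X, y and patient_ids must have equal length")
        if self.X.size and not np.all(np.isfinite(self.X)):
            raise ValueError("beat matrix contains non-finite values")

    def __len__(self):
        return len(self.y)

    @property
    def window_len(self) -> int:
        return self.X.shape[1]

    def class_counts(self) -> dict[str, int]:
        vals, counts = np.unique(self.y.astype(str), return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))

    def subset(self, idx) -> "BeatSet":
        return BeatSet(self.X[idx], self.y[idx], self.patient_ids[idx], self.fs)


def _patient_effects(cfg: SynthConfig, rng: np.random.Generator):
    scales = np.exp(rng.normal(0.0, cfg.patient_scale_sd, size=cfg.patient_count)) \
        if cfg.patient_scale_sd > 0 else np.ones(cfg.patient_count)
    offsets = rng.normal(0.0, cfg.patient_offset_sd, size=cfg.patient_count) \
        if cfg.patient_offset_sd > 0 else np.zeros(cfg.patient_count)
    return scales, offsets


def make_beat(template: BeatTemplate, cfg: SynthConfig,
              rng: np.random.Generator, patient_scale: float = 1.0,
              patient_offset: float = 0.0) -> np.ndarray:
    """One clean beat: jittered template x patient scale + patient offset.

    Each wave's timing and amplitude are jittered independently per beat
    (beat-to-beat morphological variability); a global lognormal amplitude
    jitter sits on top.  With all jitter parameters zero the beat equals
    the noiseless template on the window grid.
    """
    if cfg.wave_center_jitter_sd == 0 and cfg.wave_amp_jitter_sd == 0:
        base = template.evaluate(cfg.window_len)
    else:
        t = np.arange(cfg.window_len) / cfg.window_len
        r_center = next(w.center for w in template.waves if w.name == "R")
        shift = 0.5 - r_center
        base = np.zeros(cfg.window_len)
        for w in template.waves:
            c = w.center + shift + rng.normal(0.0, cfg.wave_center_jitter_sd)
            a = w.amplitude * np.exp(rng.normal(0.0, cfg.wave_amp_jitter_sd))
            base += a * np.exp(-0.5 * ((t - c) / w.width) ** 2)
    if cfg.r_offset:
        base = np.roll(base, cfg.r_offset)
    jitter = np.exp(rng.normal(0.0, cfg.amplitude_jitter_sd)) \
        if cfg.amplitude_jitter_sd > 0 else 1.0
    return base * jitter * patient_scale + patient_offset


def add_noise(beat: np.ndarray, cfg: SynthConfig,
              rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt a beat; returns (noisy, clean) so denoisers can be scored.

    noisy = clean + white Gaussian + baseline-wander sinusoid (< 1 Hz)
    + powerline sinusoid at ``cfg.powerline_hz`` (random phases).
    """
    beat = np.asarray(beat, dtype=np.float64)
    if not np.all(np.isfinite(beat)):
        raise ValueError("beat contains non-finite values")
    if cfg.noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    t = np.arange(len(beat)) / cfg.fs
    noisy = beat.copy()
    if cfg.noise_sd > 0:
        noisy = noisy + rng.normal(0.0, cfg.noise_sd, size=len(beat))
    if cfg.baseline_wander_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        noisy = noisy + cfg.baseline_wander_amp * np.sin(
            2 * np.pi * cfg.baseline_wander_hz * t + phase)
    if cfg.powerline_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        noisy = noisy + cfg.powerline_amp * np.sin(
            2 * np.pi * cfg.powerline_hz * t + phase)
    return noisy, beat


def largest_remainder_counts(n: int, proportions: dict[str, float]) -> dict[str, int]:
    """Apportion ``n`` to classes by the largest-remainder rule."""
    if any(p < 0 for p in proportions.values()):
        raise ValueError("proportions must be >= 0")
    total = sum(proportions.values())
    if total == 0 or n == 0:
        return {k: 0 for k in proportions}
    quotas = {k: n * p / total for k, p in proportions.items()}
    counts = {k: int(np.floor(q)) for k, q in quotas.items()}
    short = n - sum(counts.values())
    # hand the leftovers to the largest fractional remainders (ties: class order)
    order = sorted(proportions, key=lambda k: quotas[k] - counts[k], reverse=True)
    for k in order[:short]:
        counts[k] += 1
    return counts


def make_dataset(cfg: SynthConfig, n_beats: int | None = None,
                 proportions: dict[str, float] | None = None,
                 templates: dict[str, BeatTemplate] | None = None,
                 noisy: bool = False) -> BeatSet:
    """Generate a labelled beat set with requested class proportions.

    Counts follow largest-remainder rounding of the proportions; patient
    ids are assigned round-robin over ``cfg.patient_count`` patients.  With
    ``noisy=True`` each beat is passed through :func:`add_noise`.
    """
    proportions = DEFAULT_PROPORTIONS if proportions is None else proportions
    templates = DEFAULT_TEMPLATES if templates is None else templates
    n_beats = 1000 if n_beats is None else int(n_beats)
    counts = largest_remainder_counts(n_beats, proportions)
    rng = np.random.default_rng(cfg.seed)
    scales, offsets = _patient_effects(cfg, rng)

    rows, labels, pids = [], [], []
    pid = 0
    for sym in CLASS_SYMBOLS:  # fixed class order for determinism
        for _ in range(counts.get(sym, 0)):
            p = pid % cfg.patient_count
            beat = make_beat(templates[sym], cfg, rng, scales[p], offsets[p])
            if noisy:
                beat, _ = add_noise(beat, cfg, rng)
            rows.append(beat)
            labels.append(sym)
            pids.append(p)
            pid += 1
    X = np.array(rows) if rows else np.zeros((0, cfg.window_len))
    return BeatSet(X, np.array(labels, dtype=object), np.array(pids, dtype=int),
                   fs=cfg.fs)


def save_config(cfg: SynthConfig, path) -> None:
    Path(path).write_text(json.dumps(asdict(cfg), indent=1))


def load_config(path) -> SynthConfig:
    return SynthConfig(**json.loads(Path(path).read_text()))
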