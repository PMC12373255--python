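"""End-to-end orchestration: denoise -> PCA -> two-stage training ->
gated augmentation -> classification -> reports.

Each stage writes its artifact into the run directory and is skipped on
rerun if the artifact already exists (stage-granular resume).  Every JSON
report carries the config hash and seed.  Test-fold rows never reach
training, PCA fitting, or the gate's validation split.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .synth import make_dataset, BeatSet
from .io import load_cohort, save_beatset, load_beatset, MLII_RECORD_IDS
from .preprocess import denoise_beatset
from .pca import fit_pca, minmax_normalize, PcaSpace
from .models import CganBundle, labels_to_indices
from .training import train_cgan
from .augment import plan_augmentation, build_augmented_dataset, GateConfig
from .classifiers import fit_classifier
from .evaluate import (classification_report, distribution_report, nprd,
                       nrmse, nmae, SignalPair)

log = logging.getLogger("cardioaug.pipeline")

__all__ = ["run_pipeline", "PipelineResult"]


class PipelineResult(dict):
    """Dict of stage outputs with attribute access."""

    __getattr__ = dict.__getitem__


def _split_train_test(beatset: BeatSet, fraction: float, seed: int):
    rng = np.random.default_rng(seed)
    y = beatset.y.astype(str)
    test_idx = []
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        n_test = max(int(round(len(members) * fraction)), 1)
        test_idx.append(rng.permutation(members)[:n_test])
    test_idx = np.sort(np.concatenate(test_idx))
    train_mask = np.ones(len(y), dtype=bool)
    train_mask[test_idx] = False
    return np.flatnonzero(train_mask), test_idx


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    cfg.save(out / "config.yaml")
    result = PipelineResult()
    t_start = time.time()

    def report(name: str, payload: dict):
        payload = {**meta, **payload}
        (out / f"{name}.json").write_text(json.dumps(payload, indent=1,
                                                     default=float))
        return payload

    # -- stage: data ---------------------------------------------------------
    beats_csv = out / "beats.csv"
    if beats_csv.exists():
        beatset = load_beatset(beats_csv)
        log.info("data: resumed from %s (%d beats)", beats_csv, len(beatset))
    elif cfg.synthetic:
        beatset = make_dataset(cfg.synth, n_beats=cfg.n_beats, noisy=True)
        save_beatset(beatset, beats_csv)
    else:
        if cfg.data_dir is None or not Path(cfg.data_dir).exists():
            raise FileNotFoundError(
                f"data directory not found: {cfg.data_dir!r} "
                "(set data_dir or use synthetic=true)")
        beatset, rep = load_cohort(cfg.data_dir,
                                   record_ids=None, window_len=300)
        log.info("data: %d beats from %s (%d dropped at boundaries)",
                 len(beatset), cfg.data_dir, rep["dropped"])
        save_beatset(beatset, beats_csv)
    result["beatset"] = beatset

    # -- stage: denoise --------------------------------------------------------
    denoised = denoise_beatset(beatset, cfg.wavelet)
    result["denoised"] = denoised

    # -- stage: split + normalise + PCA ---------------------------------------
    tr_idx, te_idx = _split_train_test(denoised, cfg.test_fraction, cfg.seed)
    X = minmax_normalize(denoised.X) if cfg.normalize == "minmax" else denoised.X
    y = denoised.y.astype(str)
    space = fit_pca(X[tr_idx], k=cfg.pca_k)
    space.save(out / "pca.json")
    Z_tr, Z_te = space.transform(X[tr_idx]), space.transform(X[te_idx])
    y_tr, y_te = y[tr_idx], y[te_idx]
    result.update(space=space, Z_tr=Z_tr, Z_te=Z_te, y_tr=y_tr, y_te=y_te)
    recon = space.inverse_transform(Z_te)
    recon_metrics = {
        "nprd": float(np.mean([nprd(SignalPair(a, b))
                               for a, b in zip(X[te_idx], recon)])),
        "nrmse": float(np.mean([nrmse(SignalPair(a, b))
                                for a, b in zip(X[te_idx], recon)])),
        "nmae": float(np.mean([nmae(SignalPair(a, b))
                               for a, b in zip(X[te_idx], recon)])),
        "cumvar_7": space.cumulative_ratio(7),
    }
    report("pca_report", recon_metrics)

    # -- stage: two-stage CGAN training ---------------------------------------
    ckpt = out / "bundle"
    if ckpt.with_suffix(".npz").exists():
        bundle = CganBundle.load(ckpt, seed=cfg.seed)
        log.info("training: resumed checkpoint %s", ckpt)
    else:
        bundle = train_cgan(Z_tr, labels_to_indices(y_tr), cfg.model,
                            cfg.stage1, cfg.stage2, seed=cfg.seed)
        bundle.save(ckpt)
    _write_losses(out / "losses.csv", bundle)
    result["bundle"] = bundle

    # -- stage: augmentation ---------------------------------------------------
    counts = {c: int(np.sum(y_tr == c)) for c in np.unique(y_tr)}
    target = cfg.target_per_class or max(counts.values())
    plan = plan_augmentation(counts, target)
    plan.save(out / "plan.json")
    augmented = build_augmented_dataset(Z_tr, y_tr, bundle, plan,
                                        gate_cfg=cfg.gate, seed=cfg.seed)
    augmented.save(out / "augmented.csv")
    result.update(plan=plan, augmented=augmented)

    # -- stage: classification before/after ------------------------------------
    clf_cfg = cfg.rf if cfg.classifier == "rf" else cfg.resnet
    model_base = fit_classifier(clf_cfg, Z_tr, y_tr)
    rep_base = classification_report(y_te, model_base.predict(Z_te))
    model_aug = fit_classifier(clf_cfg, augmented.X, augmented.y)
    rep_aug = classification_report(y_te, model_aug.predict(Z_te))
    result.update(report_baseline=rep_base, report_augmented=rep_aug)

    # -- stage: distribution consistency ---------------------------------------
    synth_mask = augmented.source == "synthetic"
    if np.any(synth_mask):
        dist = distribution_report(Z_tr, augmented.X[synth_mask])
    else:
        dist = {"wasserstein_1": float("nan"), "js_divergence": float("nan"),
                "ks_p_value": float("nan")}
    result["distribution"] = dist

    report("report", {
        "elapsed_s": time.time() - t_start,
        "class_counts_train": counts,
        "class_counts_augmented": augmented.class_counts(),
        "baseline": rep_base.as_dict(),
        "augmented": rep_aug.as_dict(),
        "distribution": dist,
        "reconstruction": recon_metrics,
        "mode_collapse": bool(bundle.stage2_history.get("mode_collapse",
                                                        [0.0])[0]),
    })
    return result


def _write_losses(path: Path, bundle: CganBundle) -> None:
    hists = {**{f"stage1_{k}": v for k, v in bundle.stage1_history.items()},
             **{f"stage2_{k}": v for k, v in bundle.stage2_history.items()
                if k != "mode_collapse"}}
    if not hists:
        return
    n = max(len(v) for v in hists.values())
    cols = list(hists)
    with path.open("w") as fh:
        fh.write("epoch," + ",".join(cols) + "\n")
        for i in range(n):
            row = [str(i)] + [repr(hists[c][i]) if i < len(hists[c]) else ""
                              for c in cols]
            fh.write(",".join(row) + "\n")
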