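"""Desk-scale benchmark harness on the synthetic grimace generator.

These are the study conditions used by the test suite and the acceptance
script: six subjects with the published per-rat class imbalance (scaled to
desk size), pose mix 40% frontal / 40% moderate / 20% extreme, pain effect
three times the pixel noise, and a tiny backbone (M=4, K=16 regions) on
64×64 images. Training uses Adam with lr 1e-3, batch 16, 40 epochs — sane
settings for a four-layer CNN at this scale (the full-scale defaults remain
in :class:`painseeker.trainer.TrainConfig`).
"""

from __future__ import annotations

import numpy as np

from .evaluation import run_loro
from .model import PainSeekerModel
from .objectives import PRSCConfig
from .synthetic import (SyntheticConfig, SyntheticDataset, generate_dataset,
                        localization_score, table2_counts)
from .trainer import TrainConfig

BENCH_IMAGE_SIZE = 64
BENCH_SCALE = 0.125          # fraction of the published per-rat counts
BENCH_NOISE_SD = 0.05
BENCH_PAIN_EFFECT = 3 * BENCH_NOISE_SD
POSE_VARIED = {"frontal": 0.4, "moderate": 0.4, "extreme": 0.2}
FRONTAL_ONLY = {"frontal": 1.0, "moderate": 0.0, "extreme": 0.0}


def desk_train_config(seed: int, epochs: int = 40) -> TrainConfig:
    size = BENCH_IMAGE_SIZE
    return TrainConfig(batch_size=16, learning_rate=1e-3, weight_decay=0.01,
                       epochs=epochs, input_size=size,
                       resize_size=round(size * 256 / 224), seed=seed,
                       eval_center_crop=True)


def desk_model_factory(seed: int, attention: bool = True):
    def factory() -> PainSeekerModel:
        return PainSeekerModel(backbone="tiny", input_size=BENCH_IMAGE_SIZE,
                               n_classes=2, seed=seed, attention=attention,
                               width=8, d_x=16)
    return factory


def make_benchmark_dataset(seed: int, pose_weights: dict | None = None,
                           pain_effect: float = BENCH_PAIN_EFFECT,
                           scale: float = BENCH_SCALE) -> SyntheticDataset:
    cfg = SyntheticConfig(
        counts_per_subject=table2_counts(scale=scale),
        image_size=BENCH_IMAGE_SIZE, pain_effect=pain_effect,
        noise_sd=BENCH_NOISE_SD,
        pose_weights=dict(pose_weights or POSE_VARIED), seed=seed)
    return generate_dataset(cfg)


def _mean_localization(report, ds: SyntheticDataset, grid_side: int) -> float:
    scores = [localization_score(attn, ds.masks[image_id], grid_side,
                                 ds.config.image_size)
              for image_id, attn in report.attention.items()
              if any(p["visible"] for p in ds.masks[image_id])]
    return float(np.mean(scores))


def run_attention_comparison(seeds: list[int], epochs: int = 40) -> dict:
    """Pose-varied benchmark: the attention model trained with vs without the
    margin regularizer (λ=0.1, δ=0.2, K_h=5 vs λ=0), one run per seed.

    Returns per-seed pooled F1 and mean attention localization for both arms.
    """
    out = {"f1_prsc": [], "f1_noprsc": [], "loc_prsc": [], "loc_noprsc": []}
    for seed in seeds:
        ds = make_benchmark_dataset(seed)
        train_cfg = desk_train_config(seed, epochs=epochs)
        for key, prsc_cfg in (("prsc", PRSCConfig()),
                              ("noprsc", PRSCConfig(lambda_tradeoff=0.0))):
            report = run_loro(ds.images, desk_model_factory(seed), train_cfg,
                              prsc_cfg, collect_attention=True)
            out[f"f1_{key}"].append(report.pooled_f1)
            out[f"loc_{key}"].append(_mean_localization(report, ds, grid_side=4))
    return out


def run_frontal_recovery(seeds: list[int], epochs: int = 40) -> list[float]:
    """Frontal-only, strong-signal datasets: pooled LORO F1 per seed."""
    out = []
    for seed in seeds:
        ds = make_benchmark_dataset(seed, pose_weights=FRONTAL_ONLY)
        report = run_loro(ds.images, desk_model_factory(seed),
                          desk_train_config(seed, epochs=epochs), PRSCConfig())
        out.append(report.pooled_f1)
    return out


def run_null_signal(seed: int, epochs: int = 40) -> dict:
    """pain_effect = 0: labels carry no pixel signal.

    Under leave-one-subject-out, a label-independent predictor's pooled
    accuracy is a per-fold mixture of class rates: for fold s with pain rate
    p_s it lies in [min(p_s, 1−p_s), max(p_s, 1−p_s)], so the pooled value is
    confined to [Σ w_s·min(...), Σ w_s·max(...)] and can sit below the global
    majority rate (per-subject label priors memorised from training subjects
    anti-generalise), but cannot exceed it beyond sampling noise. All three
    reference rates are returned alongside the measured accuracy.
    """
    ds = make_benchmark_dataset(seed, pain_effect=0.0)
    pain = np.array([im.label.ordinal_score >= 1 for im in ds.images])
    subjects = np.array([im.subject_id for im in ds.images])
    majority = max(pain.mean(), 1 - pain.mean()) * 100.0
    lo = hi = 0.0
    for s in np.unique(subjects):
        p = pain[subjects == s].mean()
        w = (subjects == s).mean()
        lo += w * min(p, 1 - p)
        hi += w * max(p, 1 - p)
    report = run_loro(ds.images, desk_model_factory(seed),
                      desk_train_config(seed, epochs=epochs), PRSCConfig())
    return {"pooled_accuracy": report.pooled_accuracy,
            "majority_rate_percent": float(majority),
            "fold_minority_rate_percent": float(lo * 100),
            "fold_majority_rate_percent": float(hi * 100),
            "n_images": len(ds.images)}
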