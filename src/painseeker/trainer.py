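"""Minibatch training loop with the published augmentation and optimizer
settings (resize 256 → random 224 crop → horizontal flip; Adam, lr 1e-4,
weight decay 0.01, batch 64).

All randomness — shuffling, crop offsets, flips — flows from the single
integer seed in :class:`TrainConfig`, so a run is bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional, Sequence

import numpy as np
from skimage.transform import resize as _sk_resize

from . import nn
from .autograd import Tensor
from .exceptions import (ConfigurationError, InvalidBatchError,
                         InvalidImageError, TrainingDivergedError)
from .model import NORM_MEAN, NORM_STD, FacialImage, PainSeekerModel
from .objectives import PRSCConfig, batch_objective


@dataclasses.dataclass
class TrainConfig:
    batch_size: int = 64
    learning_rate: float = 1e-4
    weight_decay: float = 0.01
    optimizer: str = "adam"
    epochs: int = 30
    input_size: int = 224
    resize_size: int = 256
    seed: int = 0
    static_flip_double: bool = False   # literal dataset doubling instead of p=0.5 flips
    eval_center_crop: bool = False     # resize to resize_size then center-crop

    def __post_init__(self):
        if self.resize_size < self.input_size:
            raise ConfigurationError("resize_size must be >= input_size")
        if min(self.batch_size, self.epochs, self.input_size, self.resize_size) <= 0:
            raise ConfigurationError("batch_size, epochs and sizes must be positive")
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ConfigurationError("learning_rate must be positive, weight_decay >= 0")
        if self.optimizer not in ("adam", "sgd"):
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")


def _resize(pixels: np.ndarray, side: int) -> np.ndarray:
    if pixels.shape[0] == side and pixels.shape[1] == side:
        return pixels
    return _sk_resize(pixels, (side, side), order=1, mode="edge",
                      anti_aliasing=False, preserve_range=True)


def augment(image: FacialImage, rng: np.random.Generator, cfg: TrainConfig,
            force_flip: Optional[bool] = None,
            _resized_cache: Optional[dict] = None) -> FacialImage:
    """Resize → random crop → horizontal flip (training-time augmentation).

    `_resized_cache` (keyed by image identity) lets the training loop reuse
    the deterministic resize across epochs.
    """
    if min(image.pixels.shape[:2]) < 8:
        raise InvalidImageError(
            f"image {image.pixels.shape[:2]} is smaller than 8×8")
    if _resized_cache is not None:
        big = _resized_cache.get(id(image))
        if big is None:
            big = _resize(image.pixels, cfg.resize_size)
            _resized_cache[id(image)] = big
    else:
        big = _resize(image.pixels, cfg.resize_size)
    span = cfg.resize_size - cfg.input_size
    r0, c0 = (int(rng.integers(0, span + 1)), int(rng.integers(0, span + 1))) if span else (0, 0)
    crop = big[r0:r0 + cfg.input_size, c0:c0 + cfg.input_size]
    flip = (rng.random() < 0.5) if force_flip is None else force_flip
    if flip:
        crop = crop[:, ::-1]
    return FacialImage(pixels=np.ascontiguousarray(crop), subject_id=image.subject_id,
                       pose_tag=image.pose_tag, label=image.label, image_id=image.image_id)


def preprocess_eval(image: FacialImage, input_size: int = 224,
                    center_crop: bool = False, resize_size: int = 256) -> FacialImage:
    """Deterministic test-time preprocessing (direct bilinear resize by default)."""
    if min(image.pixels.shape[:2]) < 8:
        raise InvalidImageError(
            f"image {image.pixels.shape[:2]} is smaller than 8×8")
    if center_crop:
        big = _resize(image.pixels, resize_size)
        off = (resize_size - input_size) // 2
        out = big[off:off + input_size, off:off + input_size]
    else:
        out = _resize(image.pixels, input_size)
    return FacialImage(pixels=np.ascontiguousarray(out), subject_id=image.subject_id,
                       pose_tag=image.pose_tag, label=image.label, image_id=image.image_id)


def _to_batch(images: Sequence[FacialImage]) -> Tensor:
    stack = np.stack([im.pixels.transpose(2, 0, 1) for im in images])
    return Tensor((stack - NORM_MEAN) / NORM_STD)


def train(model: PainSeekerModel, dataset: Sequence[FacialImage],
          train_cfg: TrainConfig, prsc_cfg: PRSCConfig,
          log_fn: Optional[Callable[[str], None]] = None
          ) -> tuple[PainSeekerModel, list[dict]]:
    """Optimise the joint objective; returns the model and a per-epoch trace."""
    if not dataset:
        raise InvalidBatchError("training dataset is empty")
    if any(im.label is None for im in dataset):
        raise InvalidBatchError("all training images must be labelled")

    rng = np.random.default_rng(train_cfg.seed)
    if train_cfg.optimizer == "adam":
        opt = nn.Adam(model.parameters(), lr=train_cfg.learning_rate,
                      weight_decay=train_cfg.weight_decay)
    else:
        opt = nn.SGD(model.parameters(), lr=train_cfg.learning_rate,
                     weight_decay=train_cfg.weight_decay)

    # (index, forced-flip) work items; literal doubling duplicates each image
    # with a forced flip, otherwise each image flips with probability 0.5.
    if train_cfg.static_flip_double:
        items = [(i, False) for i in range(len(dataset))] + \
                [(i, True) for i in range(len(dataset))]
    else:
        items = [(i, None) for i in range(len(dataset))]

    model.train()
    trace: list[dict] = []
    resized_cache: dict = {}
    for epoch in range(train_cfg.epochs):
        order = rng.permutation(len(items))
        ce_sum = prsc_sum = total_sum = 0.0
        n_seen = 0
        for start in range(0, len(order), train_cfg.batch_size):
            batch_items = [items[i] for i in order[start:start + train_cfg.batch_size]]
            images = [augment(dataset[i], rng, train_cfg, force_flip=ff,
                              _resized_cache=resized_cache)
                      for i, ff in batch_items]
            x = _to_batch(images)
            onehots = np.stack([im.label.onehot for im in images])
            log_probs, scores = model.forward_batch(x)
            total, ce_val, prsc_val = batch_objective(log_probs, onehots, scores, prsc_cfg)
            if not np.isfinite(total.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}, batch {start // train_cfg.batch_size} "
                    f"(lambda={prsc_cfg.lambda_tradeoff}, delta={prsc_cfg.margin})")
            opt.zero_grad()
            total.backward()
            opt.step()
            nb = len(batch_items)
            ce_sum += ce_val * nb
            prsc_sum += prsc_val * nb
            total_sum += total.item() * nb
            n_seen += nb
        record = {"epoch": epoch, "mean_ce": ce_sum / n_seen,
                  "mean_prsc": prsc_sum / n_seen, "total": total_sum / n_seen}
        trace.append(record)
        if log_fn is not None:
            log_fn(f"epoch {epoch}, {record['mean_ce']:.6f}, "
                   f"{record['mean_prsc']:.6f}, {record['total']:.6f}")
    model.eval()
    return model, trace
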