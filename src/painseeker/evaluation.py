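"""Leave-one-rat-out (LORO) evaluation: subject-disjoint folds, label
binarization, pooled confusion counts, F1/accuracy, and the one-at-a-time
hyper-parameter sweep harness.

Metrics: F1 = 2TP / (2TP + FP + FN) with "Pain" the positive class, and
Accuracy = (TP + TN) / total × 100 (a percentage). The headline "LORO"
numbers are micro-pooled: confusion counts are summed across folds and the
metrics recomputed from the sums; unweighted macro averages over folds are
reported alongside.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ProtocolError, SchemaError
from .model import (NORM_MEAN, NORM_STD, BinaryClass, FacialImage, PainLabel,
                    PainSeekerModel)
from .autograd import Tensor
from .objectives import PRSCConfig
from .trainer import TrainConfig, preprocess_eval, train

# Published sensitivity-analysis grids (one parameter varies, others at defaults)
PUBLISHED_GRIDS = {
    "lambda_tradeoff": [0.05, 0.1, 0.5, 1.0, 1.5],
    "margin": [0.05, 0.1, 0.15, 0.2, 0.5],
    "top_count": [3, 5, 10, 15, 20],
}


@dataclasses.dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def update(self, predicted_pain: bool, actual_pain: bool) -> None:
        if actual_pain:
            if predicted_pain:
                self.tp += 1
            else:
                self.fn += 1
        else:
            if predicted_pain:
                self.fp += 1
            else:
                self.tn += 1


def binarize(label: PainLabel | int) -> BinaryClass:
    """0 → NoPain; 1 or 2 → Pain (moderate and severe are merged)."""
    score = label.ordinal_score if isinstance(label, PainLabel) else label
    if score not in (0, 1, 2):
        raise SchemaError(f"ordinal pain score must be 0, 1 or 2, got {score!r}")
    return BinaryClass.PAIN if score >= 1 else BinaryClass.NO_PAIN


def f1_score(c: ConfusionCounts) -> float:
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        warnings.warn("no positives anywhere (TP=FP=FN=0); defining F1 as 0")
        return 0.0
    return 2 * c.tp / denom


def accuracy(c: ConfusionCounts) -> float:
    if c.total == 0:
        raise ProtocolError("accuracy of an empty evaluation is undefined")
    return (c.tp + c.tn) / c.total * 100.0


@dataclasses.dataclass
class Fold:
    test_subject: str
    train_indices: np.ndarray
    test_indices: np.ndarray


def loro_split(dataset: Sequence[FacialImage]) -> list[Fold]:
    """One fold per subject; fold s tests subject s and trains on the rest."""
    subjects = sorted({im.subject_id for im in dataset})
    if len(subjects) < 2:
        raise ProtocolError("leave-one-rat-out needs at least 2 distinct subjects")
    folds = []
    ids = np.array([im.subject_id for im in dataset])
    for s in subjects:
        test = np.flatnonzero(ids == s)
        train_ = np.flatnonzero(ids != s)
        folds.append(Fold(test_subject=s, train_indices=train_, test_indices=test))
    return folds


def loro_training_counts(per_subject: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Training-set (NoPain, Pain) counts per fold from per-subject totals.

    The fold testing subject s trains on everyone else, so its counts are the
    column sums minus subject s's row.
    """
    total_no = sum(v[0] for v in per_subject.values())
    total_pain = sum(v[1] for v in per_subject.values())
    rows = [{"test_subject": s, "train_no_pain": total_no - no,
             "train_pain": total_pain - pain}
            for s, (no, pain) in sorted(per_subject.items())]
    return pd.DataFrame(rows)


@dataclasses.dataclass
class FoldResult:
    test_subject: str
    f1: float
    accuracy: float
    counts: ConfusionCounts


@dataclasses.dataclass
class LOROReport:
    per_fold: list[FoldResult]
    pooled_counts: ConfusionCounts
    pooled_f1: float
    pooled_accuracy: float
    macro_f1: float
    macro_accuracy: float
    split_table: pd.DataFrame
    attention: Optional[dict] = None   # image_id -> attention score vector

    def to_frame(self) -> pd.DataFrame:
        rows = [{"fold": r.test_subject, "f1": r.f1, "accuracy": r.accuracy,
                 "tp": r.counts.tp, "tn": r.counts.tn,
                 "fp": r.counts.fp, "fn": r.counts.fn} for r in self.per_fold]
        rows.append({"fold": "pooled", "f1": self.pooled_f1,
                     "accuracy": self.pooled_accuracy,
                     "tp": self.pooled_counts.tp, "tn": self.pooled_counts.tn,
                     "fp": self.pooled_counts.fp, "fn": self.pooled_counts.fn})
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        return json.dumps({
            "pooled": {"f1": self.pooled_f1, "accuracy": self.pooled_accuracy},
            "macro": {"f1": self.macro_f1, "accuracy": self.macro_accuracy},
            "per_fold": [{"subject": r.test_subject, "f1": r.f1,
                          "accuracy": r.accuracy} for r in self.per_fold],
        }, indent=2)


def _predict_batch(model: PainSeekerModel, images: list[FacialImage],
                   chunk: int = 64) -> tuple[np.ndarray, list[Optional[np.ndarray]]]:
    """Predicted class indices and attention vectors for preprocessed images."""
    model.eval()
    preds, attn = [], []
    for start in range(0, len(images), chunk):
        part = images[start:start + chunk]
        stack = np.stack([im.pixels.transpose(2, 0, 1) for im in part])
        x = Tensor((stack - NORM_MEAN) / NORM_STD)
        log_probs, scores = model.forward_batch(x)
        preds.append(np.argmax(log_probs.data, axis=1))
        if scores is not None:
            attn.extend(list(scores.data))
        else:
            attn.extend([None] * len(part))
    return np.concatenate(preds), attn


def evaluate_fold(model: PainSeekerModel, test_images: Sequence[FacialImage],
                  eval_center_crop: bool = False,
                  resize_size: int = 256) -> tuple[ConfusionCounts, dict]:
    if not test_images:
        raise ProtocolError("fold has an empty test set")
    processed = [preprocess_eval(im, input_size=model.input_size,
                                 center_crop=eval_center_crop,
                                 resize_size=resize_size) for im in test_images]
    pred_idx, attn = _predict_batch(model, processed)
    counts = ConfusionCounts()
    attention = {}
    for im, p, a in zip(test_images, pred_idx, attn):
        counts.update(predicted_pain=bool(p == 1),
                      actual_pain=binarize(im.label) is BinaryClass.PAIN)
        if a is not None:
            attention[im.image_id] = a
    return counts, attention


def run_loro(dataset: Sequence[FacialImage],
             model_factory: Callable[[], PainSeekerModel],
             train_cfg: TrainConfig, prsc_cfg: PRSCConfig,
             collect_attention: bool = False,
             log_fn: Optional[Callable[[str], None]] = None) -> LOROReport:
    """Train a fresh model per fold and evaluate on the held-out subject.

    Every fold's model starts from the same factory (hence the same seed), so
    fold-to-fold differences reflect the data split, not initialisation.
    """
    folds = loro_split(dataset)
    per_fold: list[FoldResult] = []
    pooled = ConfusionCounts()
    attention: dict = {}
    per_subject: dict[str, tuple[int, int]] = {}
    for im in dataset:
        no, pain = per_subject.get(im.subject_id, (0, 0))
        if binarize(im.label) is BinaryClass.PAIN:
            per_subject[im.subject_id] = (no, pain + 1)
        else:
            per_subject[im.subject_id] = (no + 1, pain)

    for fold in folds:
        model = model_factory()
        train_images = [dataset[i] for i in fold.train_indices]
        model, _ = train(model, train_images, train_cfg, prsc_cfg, log_fn=log_fn)
        counts, attn = evaluate_fold(
            model, [dataset[i] for i in fold.test_indices],
            eval_center_crop=train_cfg.eval_center_crop,
            resize_size=train_cfg.resize_size)
        per_fold.append(FoldResult(fold.test_subject, f1_score(counts),
                                   accuracy(counts), counts))
        pooled = pooled + counts
        if collect_attention:
            attention.update(attn)
        if log_fn is not None:
            log_fn(f"fold {fold.test_subject}: F1={per_fold[-1].f1:.4f} "
                   f"Acc={per_fold[-1].accuracy:.2f}")

    return LOROReport(
        per_fold=per_fold, pooled_counts=pooled,
        pooled_f1=f1_score(pooled), pooled_accuracy=accuracy(pooled),
        macro_f1=float(np.mean([r.f1 for r in per_fold])),
        macro_accuracy=float(np.mean([r.accuracy for r in per_fold])),
        split_table=loro_training_counts(per_subject),
        attention=attention if collect_attention else None)


def sweep(dataset: Sequence[FacialImage],
          model_factory: Callable[[], PainSeekerModel],
          train_cfg: TrainConfig,
          grids: Optional[dict[str, list]] = None,
          defaults: Optional[PRSCConfig] = None,
          log_fn: Optional[Callable[[str], None]] = None) -> pd.DataFrame:
    """One LORO run per grid point, varying one regularizer parameter at a
    time while the other two stay at their defaults."""
    grids = PUBLISHED_GRIDS if grids is None else grids
    defaults = PRSCConfig() if defaults is None else defaults
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ConfigurationError("sweep grids must be nonempty")
    probe = model_factory()
    n_regions = probe.grid_side**2
    rows = []
    for param, values in grids.items():
        if param not in ("lambda_tradeoff", "margin", "top_count"):
            raise ConfigurationError(f"unknown sweep parameter {param!r}")
        for value in values:
            if param == "top_count" and value >= n_regions:
                warnings.warn(f"skipping K_h={value} >= K={n_regions}")
                continue
            cfg = dataclasses.replace(defaults, **{param: value})
            report = run_loro(dataset, model_factory, train_cfg, cfg, log_fn=log_fn)
            rows.append({"parameter": param, "value": value,
                         "pooled_f1": report.pooled_f1,
                         "pooled_accuracy": report.pooled_accuracy})
    return pd.DataFrame(rows)
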