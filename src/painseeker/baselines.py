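"""Classical and plain-CNN comparison methods.

* Grid-wise local binary patterns (LBP) + linear SVM: the image is divided
  into a fixed G×G spatial grid; each cell contributes an L1-normalised
  256-bin histogram of 8-point circular LBP codes at radius R ∈ {1, 3}; the
  concatenated vector feeds a linear-kernel SVM with C = 1. The six
  published variants are the {R1, R3} × {4×4, 8×8, 16×16} product.
* A plain CNN classifier: the same backbone and training settings as the
  attention model, but with uniform mean pooling over regions and no
  attention or margin regularizer.

LBP convention: 8 points sampled counter-clockwise starting at angle 0
(to the right), bilinear interpolation off-grid, bit p set iff the sampled
value is >= the centre; all-equal neighbourhoods therefore code to 255.
Pixels without a full circular neighbourhood (within R of the border) are
skipped.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Callable, Optional, Sequence

import numpy as np
from skimage.color import rgb2gray
from skimage.feature import local_binary_pattern
from sklearn.svm import SVC

from .evaluation import (ConfusionCounts, FoldResult, LOROReport, accuracy,
                         binarize, f1_score, loro_split, loro_training_counts,
                         run_loro)
from .exceptions import ConfigurationError, DimensionError
from .model import BinaryClass, FacialImage, PainSeekerModel
from .objectives import PRSCConfig
from .trainer import TrainConfig

N_POINTS = 8
N_BINS = 2**N_POINTS


@dataclasses.dataclass(frozen=True)
class LBPConfig:
    radius: int = 1
    neighbors: int = N_POINTS
    grid_side: int = 4
    uniform: bool = False   # rotation-invariant uniform patterns (P+2 bins)

    def __post_init__(self):
        if self.neighbors != N_POINTS:
            raise ConfigurationError("only 8-point LBP is supported")
        if self.radius < 1:
            raise ConfigurationError("radius must be >= 1")
        if self.grid_side < 1:
            raise ConfigurationError("grid_side must be >= 1")

    @property
    def n_bins(self) -> int:
        return N_POINTS + 2 if self.uniform else N_BINS


@dataclasses.dataclass(frozen=True)
class SVMConfig:
    C: float = 1.0

    def __post_init__(self):
        if self.C <= 0:
            raise ConfigurationError("SVM penalty C must be positive")


PUBLISHED_LBP_VARIANTS = [LBPConfig(radius=r, grid_side=g)
                          for r in (1, 3) for g in (4, 8, 16)]


def lbp_code(neighborhood: np.ndarray, cfg: LBPConfig) -> int:
    """LBP code of the centre pixel of a (2R+1)×(2R+1) neighbourhood."""
    nb = np.asarray(neighborhood, dtype=np.float64)
    r = cfg.radius
    if nb.shape != (2 * r + 1, 2 * r + 1):
        raise DimensionError(
            f"need a {2 * r + 1}×{2 * r + 1} neighbourhood for radius {r}, got {nb.shape}")
    center = nb[r, r]
    code = 0
    for p in range(N_POINTS):
        angle = 2.0 * np.pi * p / N_POINTS
        rr = r - r * np.sin(angle)   # row axis points down => CCW uses -sin
        cc = r + r * np.cos(angle)
        r0, c0 = int(np.floor(rr)), int(np.floor(cc))
        fr, fc = rr - r0, cc - c0
        r1, c1 = min(r0 + 1, 2 * r), min(c0 + 1, 2 * r)
        sample = ((1 - fr) * (1 - fc) * nb[r0, c0] + (1 - fr) * fc * nb[r0, c1]
                  + fr * (1 - fc) * nb[r1, c0] + fr * fc * nb[r1, c1])
        if sample >= center - 1e-12:
            code |= 1 << p
    return code


def _to_gray_u8(image: FacialImage) -> np.ndarray:
    gray = rgb2gray(image.pixels)
    return np.clip(np.round(gray * 255.0), 0, 255).astype(np.uint8)


def lbp_grid_features(image: FacialImage, cfg: LBPConfig) -> np.ndarray:
    """Concatenated per-cell normalised LBP histograms (length grid²×256,
    or grid²×10 in uniform-pattern mode)."""
    gray = _to_gray_u8(image)
    h, w = gray.shape
    if min(h, w) // cfg.grid_side < 2 * cfg.radius + 1:
        raise ConfigurationError(
            f"grid {cfg.grid_side}×{cfg.grid_side} cells on a {h}×{w} image are "
            f"smaller than the {2 * cfg.radius + 1}-pixel LBP support")
    method = "uniform" if cfg.uniform else "default"
    codes = local_binary_pattern(gray, N_POINTS, cfg.radius, method=method)
    valid = np.zeros_like(gray, dtype=bool)
    valid[cfg.radius:h - cfg.radius, cfg.radius:w - cfg.radius] = True

    row_edges = np.linspace(0, h, cfg.grid_side + 1).round().astype(int)
    col_edges = np.linspace(0, w, cfg.grid_side + 1).round().astype(int)
    feats = []
    for i in range(cfg.grid_side):
        for j in range(cfg.grid_side):
            cell_codes = codes[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
            cell_valid = valid[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]]
            hist = np.bincount(cell_codes[cell_valid].astype(int),
                               minlength=cfg.n_bins).astype(float)
            total = hist.sum()
            if total > 0:
                hist /= total
            else:
                warnings.warn(f"grid cell ({i},{j}) has no interior pixels; zero histogram")
            feats.append(hist)
    return np.concatenate(feats)


class _ConstantPredictor:
    def __init__(self, value: int):
        self.value = value

    def predict(self, x):
        return np.full(len(x), self.value)


def run_lbp_svm_baseline(dataset: Sequence[FacialImage],
                         lbp_cfg: LBPConfig, svm_cfg: SVMConfig = SVMConfig(),
                         features: Optional[np.ndarray] = None) -> LOROReport:
    """Leave-one-rat-out evaluation of grid LBP features + linear SVM."""
    if features is None:
        features = np.stack([lbp_grid_features(im, lbp_cfg) for im in dataset])
    labels = np.array([1 if binarize(im.label) is BinaryClass.PAIN else 0
                       for im in dataset])
    per_subject: dict[str, tuple[int, int]] = {}
    for im, y in zip(dataset, labels):
        no, pain = per_subject.get(im.subject_id, (0, 0))
        per_subject[im.subject_id] = (no + (y == 0), pain + (y == 1))

    per_fold: list[FoldResult] = []
    pooled = ConfusionCounts()
    for fold in loro_split(dataset):
        ytr = labels[fold.train_indices]
        if len(np.unique(ytr)) < 2:
            warnings.warn(f"fold {fold.test_subject}: single-class training set; "
                          "using a constant predictor")
            clf = _ConstantPredictor(int(ytr[0]))
        else:
            clf = SVC(kernel="linear", C=svm_cfg.C)
            clf.fit(features[fold.train_indices], ytr)
        pred = clf.predict(features[fold.test_indices])
        counts = ConfusionCounts()
        for p, y in zip(pred, labels[fold.test_indices]):
            counts.update(predicted_pain=bool(p == 1), actual_pain=bool(y == 1))
        per_fold.append(FoldResult(fold.test_subject, f1_score(counts),
                                   accuracy(counts), counts))
        pooled = pooled + counts
    return LOROReport(per_fold=per_fold, pooled_counts=pooled,
                      pooled_f1=f1_score(pooled), pooled_accuracy=accuracy(pooled),
                      macro_f1=float(np.mean([r.f1 for r in per_fold])),
                      macro_accuracy=float(np.mean([r.accuracy for r in per_fold])),
                      split_table=loro_training_counts(per_subject))


def run_lbp_svm_batch(dataset: Sequence[FacialImage],
                      variants: Sequence[LBPConfig] = tuple(PUBLISHED_LBP_VARIANTS),
                      svm_cfg: SVMConfig = SVMConfig()) -> dict[str, LOROReport]:
    """All LBP variants (skipping those whose cells are too small)."""
    out = {}
    for cfg in variants:
        name = f"LBP_R{cfg.radius}P8_{cfg.grid_side}x{cfg.grid_side}"
        try:
            out[name] = run_lbp_svm_baseline(dataset, cfg, svm_cfg)
        except ConfigurationError as err:
            warnings.warn(f"skipping {name}: {err}")
    return out


def run_cnn_baseline(dataset: Sequence[FacialImage], train_cfg: TrainConfig,
                     model_factory: Optional[Callable[[], PainSeekerModel]] = None,
                     **model_kwargs) -> LOROReport:
    """Plain CNN (mean-pooled backbone, cross-entropy only) under LORO."""
    if model_factory is None:
        def model_factory():
            return PainSeekerModel(attention=False, input_size=train_cfg.input_size,
                                   **model_kwargs)
    cfg = PRSCConfig(lambda_tradeoff=0.0)
    return run_loro(dataset, model_factory, train_cfg, cfg)
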