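"""Core pain-scoring model: regional features, attention scores, fused prediction.

An input face image X ∈ R^{d×d×3} passes through a convolutional backbone f
whose final map (M×M×d_x) is reshaped row-major into K = M² regional feature
vectors x_1..x_K. A single shared affine scorer g maps each region to a
scalar; sigmoids of these scalars, normalised by their sum, are the
pain-contribution (attention) scores β_1..β_K ∈ [0,1], Σβ = 1. The fused
descriptor Σ_j β_j x_j feeds an affine head h and a softmax to produce class
probabilities.

With ``attention=False`` the same architecture degrades to a plain CNN
classifier (uniform mean pooling over regions, no scorer), which serves as
the deep-learning baseline.
"""

from __future__ import annotations

import dataclasses
import enum
import json
from typing import Optional

import numpy as np

from . import nn
from .autograd import Tensor, log_softmax
from .backbones import make_backbone
from .exceptions import DimensionError, InvalidGridError, SchemaError

# Per-channel standardisation applied before the backbone (inputs are in [0,1]).
NORM_MEAN = 0.5
NORM_STD = 0.25


class PoseTag(str, enum.Enum):
    FRONTAL = "frontal"
    MODERATE = "moderate"
    EXTREME = "extreme"
    UNKNOWN = "unknown"


class BinaryClass(str, enum.Enum):
    NO_PAIN = "NoPain"
    PAIN = "Pain"


@dataclasses.dataclass(frozen=True)
class PainLabel:
    """Ordinal grimace-scale score (0 none / 1 moderate / 2 severe)."""

    ordinal_score: int
    n_classes: int = 2

    def __post_init__(self):
        if self.ordinal_score not in (0, 1, 2):
            raise SchemaError(f"ordinal pain score must be 0, 1 or 2, got {self.ordinal_score}")
        if self.n_classes not in (2, 3):
            raise SchemaError("n_classes must be 2 (binary) or 3 (ordinal)")

    @property
    def binary_class(self) -> BinaryClass:
        return BinaryClass.PAIN if self.ordinal_score >= 1 else BinaryClass.NO_PAIN

    @property
    def class_index(self) -> int:
        if self.n_classes == 2:
            return 1 if self.ordinal_score >= 1 else 0
        return self.ordinal_score

    @property
    def onehot(self) -> np.ndarray:
        v = np.zeros(self.n_classes)
        v[self.class_index] = 1.0
        return v


@dataclasses.dataclass
class FacialImage:
    """One RGB face image with subject identity, pose tag and optional label."""

    pixels: np.ndarray  # (d, d, 3) floats in [0, 1]
    subject_id: str
    pose_tag: PoseTag = PoseTag.UNKNOWN
    label: Optional[PainLabel] = None
    image_id: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise DimensionError(
                f"expected an (h, w, 3) RGB array, got shape {self.pixels.shape}")
        if min(self.pixels.shape[:2]) < 1:
            raise DimensionError("image has an empty spatial dimension")
        if not self.subject_id:
            raise SchemaError("subject_id must be nonempty")


@dataclasses.dataclass
class RegionalFeatures:
    """K = M² per-region feature vectors, row-major over the M×M grid."""

    matrix: np.ndarray  # (K, d_x)
    grid_side: int

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise DimensionError("regional features must be a (K, d_x) matrix")
        if self.matrix.shape[0] != self.grid_side**2:
            raise DimensionError(
                f"K={self.matrix.shape[0]} does not equal grid_side²={self.grid_side ** 2}")
        if not np.all(np.isfinite(self.matrix)):
            raise DimensionError("regional features contain non-finite values")

    @property
    def n_regions(self) -> int:
        return self.matrix.shape[0]

    def region_cell(self, j: int) -> tuple[int, int]:
        """Grid cell (row, col) of region index j (row-major)."""
        return divmod(j, self.grid_side)


@dataclasses.dataclass
class AttentionScores:
    """Normalised per-region pain-contribution scores β (Σβ = 1)."""

    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 1:
            raise DimensionError("attention scores must be a flat vector")
        if np.any(self.scores < -1e-12) or np.any(self.scores > 1 + 1e-12):
            raise DimensionError("attention scores must lie in [0, 1]")
        if abs(self.scores.sum() - 1.0) > 1e-6:
            raise DimensionError(f"attention scores must sum to 1, got {self.scores.sum():.8f}")


@dataclasses.dataclass
class Prediction:
    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if abs(self.probs.sum() - 1.0) > 1e-6 or np.any(self.probs < -1e-12):
            raise DimensionError("probabilities must be nonnegative and sum to 1")

    @property
    def predicted_class(self) -> int:
        return int(np.argmax(self.probs))


class PainSeekerModel(nn.Module):
    """Backbone + shared attention scorer + classification head.

    Parameters are a pure function of (config, seed); ``save``/``load`` give a
    bit-exact single-file checkpoint and loading rejects config mismatches.
    """

    def __init__(self, backbone: str = "resnet18-conv", input_size: int = 224,
                 n_classes: int = 2, seed: int = 0, attention: bool = True,
                 scorer_zero_init: bool = False, **backbone_kwargs):
        self.config = {
            "backbone": backbone, "input_size": int(input_size),
            "n_classes": int(n_classes), "seed": int(seed),
            "attention": bool(attention), "scorer_zero_init": bool(scorer_zero_init),
            "backbone_kwargs": dict(backbone_kwargs),
        }
        rng = np.random.default_rng(seed)
        self.backbone = make_backbone(backbone, rng, input_size, **backbone_kwargs)
        d_x = self.backbone.out_channels
        self.scorer = (nn.Linear(d_x, 1, rng, zero_init=scorer_zero_init)
                       if attention else None)
        self.head = nn.Linear(d_x, n_classes, rng)
        self.attention = attention
        self.n_classes = n_classes
        self.input_size = input_size
        self.grid_side = self.backbone.grid_side
        self.d_x = d_x

    # -- batched graph-building paths (used by the trainer) ------------------

    def features_batch(self, x: Tensor) -> Tensor:
        """(N, 3, d, d) -> (N, K, d_x), row-major region order."""
        fmap = self.backbone(x)                      # (N, d_x, M, M)
        n, dx, m, _ = fmap.shape
        return fmap.transpose(0, 2, 3, 1).reshape(n, m * m, dx)

    def scores_batch(self, feats: Tensor) -> Tensor:
        """(N, K, d_x) -> (N, K) normalised attention scores."""
        n, k, dx = feats.shape
        if k < 2:
            raise InvalidGridError(f"need at least 2 regions to normalise scores, got K={k}")
        raw = self.scorer(feats.reshape(n * k, dx)).reshape(n, k)
        sig = raw.sigmoid()
        return sig * (sig.sum(axis=1, keepdims=True) ** -1.0)

    def fuse_batch(self, feats: Tensor, scores: Tensor) -> Tensor:
        n, k, dx = feats.shape
        fused = (feats * scores.reshape(n, k, 1)).sum(axis=1)
        return self.head(fused)                      # logits (N, c)

    def forward_batch(self, x: Tensor) -> tuple[Tensor, Optional[Tensor]]:
        """Returns (log-probabilities (N, c), attention scores (N, K) or None)."""
        feats = self.features_batch(x)
        if self.attention:
            scores = self.scores_batch(feats)
        else:
            n, k, _ = feats.shape
            scores = None
            feats = feats * (1.0 / k)
            logits = self.head(feats.sum(axis=1))
            return log_softmax(logits, axis=1), None
        logits = self.fuse_batch(feats, scores)
        return log_softmax(logits, axis=1), scores

    # -- per-image inference API ---------------------------------------------

    def _to_input(self, image: FacialImage) -> Tensor:
        d = self.input_size
        if image.pixels.shape != (d, d, 3):
            raise DimensionError(
                f"expected a {d}×{d}×3 image, got {image.pixels.shape}")
        x = (image.pixels - NORM_MEAN) / NORM_STD
        return Tensor(x.transpose(2, 0, 1)[None])

    def extract_regional_features(self, image: FacialImage) -> RegionalFeatures:
        self.eval()
        feats = self.features_batch(self._to_input(image))
        return RegionalFeatures(matrix=feats.data[0], grid_side=self.grid_side)

    def score_regions(self, features: RegionalFeatures) -> AttentionScores:
        if not self.attention:
            raise InvalidGridError("this model has no attention scorer")
        if features.n_regions < 2:
            raise InvalidGridError("score normalisation needs K >= 2 regions")
        feats = Tensor(features.matrix[None])
        return AttentionScores(scores=self.scores_batch(feats).data[0])

    def fuse_and_predict(self, features: RegionalFeatures,
                         scores: AttentionScores) -> Prediction:
        if len(scores.scores) != features.n_regions:
            raise DimensionError(
                f"{len(scores.scores)} scores for {features.n_regions} regions")
        logits = self.fuse_batch(Tensor(features.matrix[None]),
                                 Tensor(scores.scores[None]))
        logp = log_softmax(logits, axis=1)
        return Prediction(probs=np.exp(logp.data[0]))

    def forward(self, image: FacialImage) -> tuple[Prediction, AttentionScores]:
        feats = self.extract_regional_features(image)
        scores = self.score_regions(feats)
        return self.fuse_and_predict(feats, scores), scores

    def predict(self, image: FacialImage) -> Prediction:
        """Class probabilities for one image (works with or without attention)."""
        self.eval()
        logp, _ = self.forward_batch(self._to_input(image))
        return Prediction(probs=np.exp(logp.data[0]))

    # -- checkpointing --------------------------------------------------------

    def save(self, path) -> None:
        arrays = self.named_arrays()
        np.savez(path, __config__=np.frombuffer(
            json.dumps(self.config, sort_keys=True).encode(), dtype=np.uint8),
            **{f"param:{k}": v for k, v in arrays.items()})

    @classmethod
    def load(cls, path, expect_config: Optional[dict] = None) -> "PainSeekerModel":
        with np.load(path) as archive:
            config = json.loads(bytes(archive["__config__"]).decode())
            if expect_config is not None:
                mismatched = {k: (expect_config[k], config.get(k))
                              for k in expect_config if config.get(k) != expect_config[k]}
                if mismatched:
                    raise ValueError(f"checkpoint config mismatch: {mismatched}")
            kwargs = dict(config)
            kwargs.update(kwargs.pop("backbone_kwargs"))
            model = cls(**kwargs)
            model.load_arrays({k[len("param:"):]: archive[k]
                               for k in archive.files if k.startswith("param:")})
        return model
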