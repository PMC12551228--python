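"""Training objectives: cross-entropy, the pain-related score calibration
(PRSC) margin regularizer, and their weighted combination.

PRSC is a hinge penalty on the attention scores of one image: let β^h be the
K_h largest scores and β̄^r the mean of the remaining K_r = K − K_h scores;
the loss is

    L_PRSC = (1/K_h) Σ_j max{0, δ − (β^h_j − β̄^r)}

which is minimised when every highly-contributive region outscores the mean
of the rest by at least the margin δ. Since each of the K_h top scores is at
least every non-top score, each gap is nonnegative and the loss lies in
[0, δ]. The joint objective over a batch of N samples is
(1/N) Σ_i [CE_i + λ·PRSC_i].

Tie-breaking in the top-K_h selection favours lower region indices
(stable sort), so results are deterministic.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .autograd import Tensor
from .exceptions import ConfigurationError, DimensionError, InvalidBatchError
from .model import AttentionScores, PainLabel, Prediction

PROB_FLOOR = 1e-12  # clamp for log of predicted probabilities


@dataclasses.dataclass(frozen=True)
class PRSCConfig:
    """Margin regularizer settings: trade-off λ, margin δ, top-region count K_h."""

    lambda_tradeoff: float = 0.1
    margin: float = 0.2
    top_count: int = 5

    def __post_init__(self):
        if self.lambda_tradeoff < 0 or self.margin < 0:
            raise ConfigurationError("lambda and margin must be nonnegative")
        if self.top_count < 1:
            raise ConfigurationError("top_count must be >= 1")


def _top_rest_split(scores_2d: np.ndarray, k_h: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise indices of the K_h largest entries (ties → lower index) and the rest."""
    order = np.argsort(-scores_2d, axis=1, kind="stable")
    return order[:, :k_h], order[:, k_h:]


def prsc_terms(scores: Tensor, cfg: PRSCConfig) -> Tensor:
    """Per-sample PRSC losses for a (N, K) attention-score tensor (differentiable)."""
    n, k = scores.shape
    if cfg.top_count >= k:
        raise ConfigurationError(
            f"top_count K_h={cfg.top_count} must be smaller than K={k}")
    top_idx, rest_idx = _top_rest_split(scores.data, cfg.top_count)
    rows = np.arange(n)[:, None]
    top = scores[rows, top_idx]                      # (N, K_h)
    rest_mean = scores[rows, rest_idx].mean(axis=1)  # (N,)
    gaps = top - rest_mean.reshape(n, 1)
    return (cfg.margin - gaps).relu().mean(axis=1)


def ce_terms(log_probs: Tensor, onehots: np.ndarray) -> Tensor:
    """Per-sample cross-entropy from log-probabilities (N, c) (differentiable)."""
    if log_probs.shape != onehots.shape:
        raise DimensionError(
            f"log-probs {log_probs.shape} vs labels {onehots.shape}")
    return -(log_probs * onehots).sum(axis=1)


def batch_objective(log_probs: Tensor, onehots: np.ndarray,
                    scores: Tensor | None, cfg: PRSCConfig) -> tuple[Tensor, float, float]:
    """Joint loss over one minibatch.

    Returns (differentiable total, mean CE value, mean PRSC value).
    """
    n = log_probs.shape[0]
    if n < 1:
        raise InvalidBatchError("empty batch")
    ce = ce_terms(log_probs, onehots)
    if scores is not None and cfg.lambda_tradeoff > 0:
        prsc = prsc_terms(scores, cfg)
        total = (ce + cfg.lambda_tradeoff * prsc).mean()
        return total, float(ce.data.mean()), float(prsc.data.mean())
    total = ce.mean()
    return total, float(ce.data.mean()), 0.0


# -- plain numeric API (single samples, no graph) ----------------------------


def ce_loss(prediction: Prediction, label: PainLabel) -> float:
    """−Σ_k y_k ln p_k with the true-class probability clamped at 1e-12."""
    if len(prediction.probs) != label.n_classes:
        raise DimensionError(
            f"{len(prediction.probs)} predicted classes vs label with {label.n_classes}")
    p = np.clip(prediction.probs, PROB_FLOOR, None)
    return float(-(label.onehot * np.log(p)).sum())


def prsc_loss(scores: AttentionScores, cfg: PRSCConfig) -> float:
    """PRSC value for one image's attention scores."""
    s = scores.scores[None, :]
    return float(prsc_terms(Tensor(s), cfg).data[0])


def total_objective(predictions: list[Prediction], labels: list[PainLabel],
                    scores: list[AttentionScores], cfg: PRSCConfig) -> float:
    """(1/N) Σ_i [CE_i + λ·PRSC_i] over an aligned batch."""
    if not predictions:
        raise InvalidBatchError("empty batch")
    if not (len(predictions) == len(labels) == len(scores)):
        raise InvalidBatchError("predictions, labels and scores must align")
    if cfg.lambda_tradeoff == 0:
        terms = [ce_loss(p, y) for p, y in zip(predictions, labels)]
    else:
        terms = [ce_loss(p, y) + cfg.lambda_tradeoff * prsc_loss(s, cfg)
                 for p, y, s in zip(predictions, labels, scores)]
    return float(np.mean(terms))
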