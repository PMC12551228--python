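"""Cross-entropy and margin-regularizer arithmetic, with loop oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from painseeker.autograd import Tensor
from painseeker.exceptions import (ConfigurationError, DimensionError,
                                   InvalidBatchError)
from painseeker.model import AttentionScores, PainLabel, Prediction
from painseeker.nn import SGD
from painseeker.objectives import (PRSCConfig, batch_objective, ce_loss,
                                   ce_terms, prsc_loss, prsc_terms,
                                   total_objective)


def prsc_oracle(scores: np.ndarray, margin: float, k_h: int) -> float:
    """Independent re-implementation: stable sort, slice, hinge, mean."""
    order = sorted(range(len(scores)), key=lambda j: (-scores[j], j))
    top = [scores[j] for j in order[:k_h]]
    rest = [scores[j] for j in order[k_h:]]
    rest_mean = sum(rest) / len(rest)
    return sum(max(0.0, margin - (t - rest_mean)) for t in top) / k_h


@pytest.mark.parametrize("probs, true_class, expected", [
    ([1.0, 0.0], 0, 0.0),
    ([0.5, 0.5], 0, np.log(2)),
    ([0.2, 0.2, 0.6], 2, -np.log(0.6)),
])
def test_ce_loss_worked_values(probs, true_class, expected):
    pred = Prediction(probs=np.array(probs))
    label = PainLabel({0: 0, 1: 1, 2: 2}[true_class], n_classes=len(probs))
    assert ce_loss(pred, label) == pytest.approx(expected, abs=1e-10)


def test_ce_loss_clamps_zero_probability():
    pred = Prediction(probs=np.array([1.0, 0.0]))
    val = ce_loss(pred, PainLabel(1))
    assert np.isfinite(val) and val == pytest.approx(-np.log(1e-12))


def test_ce_class_count_mismatch():
    with pytest.raises(DimensionError):
        ce_loss(Prediction(probs=np.array([0.5, 0.5])), PainLabel(2, n_classes=3))


@pytest.mark.parametrize("scores, k_h, expected", [
    (np.full(16, 1 / 16), 5, 0.2),                 # uniform → every gap 0 → δ
    (np.array([0.7, 0.1, 0.1, 0.1]), 1, 0.0),      # gap 0.6 ≥ δ
    (np.array([0.3, 0.3, 0.2, 0.2]), 2, 0.1),      # gaps 0.1, 0.1 → mean 0.1
])
def test_prsc_worked_values(scores, k_h, expected):
    cfg = PRSCConfig(margin=0.2, top_count=k_h)
    assert prsc_loss(AttentionScores(scores), cfg) == pytest.approx(expected)


def test_prsc_rejects_top_count_geq_K():
    with pytest.raises(ConfigurationError):
        prsc_loss(AttentionScores(np.full(4, 0.25)), PRSCConfig(top_count=4))


@settings(max_examples=200, deadline=None)
@given(st.lists(st.floats(0.01, 10.0), min_size=3, max_size=8), st.integers(1, 6),
       st.floats(0.0, 0.5))
def test_prsc_matches_oracle_and_stays_in_range(raw, k_h, margin):
    scores = np.array(raw) / np.sum(raw)
    k_h = min(k_h, len(scores) - 1)
    cfg = PRSCConfig(margin=margin, top_count=k_h)
    val = prsc_loss(AttentionScores(scores), cfg)
    assert val == pytest.approx(prsc_oracle(scores, margin, k_h), abs=1e-9)
    assert -1e-12 <= val <= margin + 1e-12   # top scores never trail the rest-mean


def test_prsc_tie_break_prefers_lower_index():
    # all equal: top-K is the first K_h indices either way; the oracle and the
    # implementation must agree on a half-tied vector too
    scores = np.array([0.25, 0.25, 0.25, 0.25])
    cfg = PRSCConfig(margin=0.1, top_count=2)
    assert prsc_loss(AttentionScores(scores), cfg) == pytest.approx(
        prsc_oracle(scores, 0.1, 2))


def test_prsc_monotone_in_concentration():
    # shifting mass from the non-top scores onto the top score (Σβ = 1 kept)
    # never increases the loss
    cfg = PRSCConfig(margin=0.3, top_count=1)
    prev = np.inf
    for t in np.linspace(0.25, 0.9, 14):
        scores = np.array([t] + [(1 - t) / 3] * 3)
        val = prsc_loss(AttentionScores(scores), cfg)
        assert val <= prev + 1e-12
        prev = val


def test_total_objective_worked_value():
    pred = Prediction(probs=np.array([0.5, 0.5]))
    label = PainLabel(0)
    scores = AttentionScores(np.array([0.3, 0.3, 0.2, 0.2]))
    cfg = PRSCConfig(lambda_tradeoff=0.1, margin=0.2, top_count=2)
    # CE = ln 2 ≈ 0.6931, PRSC = 0.1 → 0.6931 + 0.01
    assert total_objective([pred], [label], [scores], cfg) == pytest.approx(
        np.log(2) + 0.1 * 0.1)


def test_total_objective_lambda_zero_is_mean_ce(rng):
    preds = [Prediction(probs=np.array([p, 1 - p])) for p in (0.3, 0.8, 0.6)]
    labels = [PainLabel(1), PainLabel(0), PainLabel(1)]
    scores = [AttentionScores(rng.dirichlet(np.ones(6))) for _ in range(3)]
    cfg = PRSCConfig(lambda_tradeoff=0.0)
    expected = np.mean([ce_loss(p, y) for p, y in zip(preds, labels)])
    assert total_objective(preds, labels, scores, cfg) == pytest.approx(expected)


def test_total_objective_matches_loop_oracle(rng):
    cfg = PRSCConfig(lambda_tradeoff=0.5, margin=0.2, top_count=2)
    preds, labels, scores = [], [], []
    for _ in range(2):
        p = rng.uniform(0.1, 0.9)
        preds.append(Prediction(probs=np.array([p, 1 - p])))
        labels.append(PainLabel(int(rng.integers(0, 2))))
        scores.append(AttentionScores(rng.dirichlet(np.ones(5))))
    per_sample = [ce_loss(p, y) + cfg.lambda_tradeoff * prsc_loss(s, cfg)
                  for p, y, s in zip(preds, labels, scores)]
    assert total_objective(preds, labels, scores, cfg) == pytest.approx(
        sum(per_sample) / 2)


def test_total_objective_empty_batch():
    with pytest.raises(InvalidBatchError):
        total_objective([], [], [], PRSCConfig())


def test_gradient_step_widens_top_gap():
    """From uniform scores, one step on the joint objective with λ>0 must
    increase (top-K_h mean − rest mean) of the attention scores."""
    rng = np.random.default_rng(0)
    raw = Tensor(np.zeros(8), requires_grad=True)   # uniform after normalisation
    feats = rng.normal(size=(8, 4))
    w = Tensor(rng.normal(size=(2, 4)) * 0.1, requires_grad=True)
    onehot = np.array([[1.0, 0.0]])
    cfg = PRSCConfig(lambda_tradeoff=1.0, margin=0.2, top_count=3)

    def gap(scores):
        s = np.sort(scores)[::-1]
        return s[:3].mean() - s[3:].mean()

    def forward():
        sig = raw.sigmoid()
        beta = (sig * (sig.sum() ** -1.0)).reshape(1, 8)
        fused = (Tensor(feats[None]) * beta.reshape(1, 8, 1)).sum(axis=1)
        logits = fused @ w.T
        from painseeker.autograd import log_softmax
        return log_softmax(logits, axis=1), beta

    logp, beta = forward()
    before = gap(beta.data[0])
    total, _, _ = batch_objective(logp, onehot, beta, cfg)
    total.backward()
    SGD([raw, w], lr=0.5).step()
    _, beta_after = forward()
    assert gap(beta_after.data[0]) > before


def test_ce_terms_matches_scalar_ce(rng):
    probs = rng.dirichlet(np.ones(3), size=4)
    onehots = np.eye(3)[rng.integers(0, 3, size=4)]
    lp = Tensor(np.log(probs))
    vals = ce_terms(lp, onehots).data
    for i in range(4):
        expected = -np.log(probs[i][np.argmax(onehots[i])])
        assert vals[i] == pytest.approx(expected)
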