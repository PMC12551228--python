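"""Regional feature extraction, attention scoring and fused prediction."""

import numpy as np
import pytest

from painseeker.autograd import Tensor
from painseeker.exceptions import DimensionError, InvalidGridError
from painseeker.model import (AttentionScores, FacialImage, PainLabel,
                              PainSeekerModel, Prediction, RegionalFeatures)

from conftest import make_image


class StubBackbone:
    """Backbone returning a fixed feature map (for reshape-convention tests)."""

    def __init__(self, fmap):
        self.fmap = np.asarray(fmap, dtype=float)     # (d_x, M, M)
        self.out_channels = self.fmap.shape[0]
        self.grid_side = self.fmap.shape[1]

    def __call__(self, x):
        n = x.shape[0]
        return Tensor(np.broadcast_to(self.fmap, (n,) + self.fmap.shape).copy())

    def eval(self):
        pass

    def train(self):
        pass


def stubbed_model(fmap, **kwargs):
    model = PainSeekerModel(backbone="tiny", input_size=32, n_classes=2,
                            seed=0, width=8, d_x=np.asarray(fmap).shape[0], **kwargs)
    model.backbone = StubBackbone(fmap)
    model.grid_side = model.backbone.grid_side
    return model


def test_region_reshape_is_row_major():
    # cell (r, c) holds the vector [r, c, r+c]
    fmap = np.zeros((3, 2, 2))
    for r in range(2):
        for c in range(2):
            fmap[:, r, c] = [r, c, r + c]
    model = stubbed_model(fmap)
    feats = model.extract_regional_features(make_image(np.zeros((32, 32, 3))))
    expected = [[0, 0, 0], [0, 1, 1], [1, 0, 1], [1, 1, 2]]
    assert np.array_equal(feats.matrix, expected)
    assert feats.region_cell(2) == (1, 0)


def test_constant_feature_map_gives_identical_rows():
    v = np.array([1.5, -2.0, 0.25])
    fmap = np.tile(v[:, None, None], (1, 3, 3))
    model = stubbed_model(fmap)
    feats = model.extract_regional_features(make_image(np.zeros((32, 32, 3))))
    assert feats.matrix.shape == (9, 3)
    assert np.allclose(feats.matrix, v)


def test_resnet18_shape_probe():
    # 224×224 input through the ResNet-18 conv stack: M=7 (K=49), d_x=512
    model = PainSeekerModel(backbone="resnet18-conv", input_size=224, seed=0)
    feats = model.extract_regional_features(
        make_image(np.random.default_rng(0).random((224, 224, 3))))
    assert feats.matrix.shape == (49, 512)
    assert feats.grid_side == 7


def test_tiny_backbone_shapes(tiny_model):
    image = make_image(np.random.default_rng(1).random((32, 32, 3)))
    pred, scores = tiny_model.forward(image)
    assert len(scores.scores) == 16           # M=4
    assert tiny_model.d_x == 8
    assert pred.probs.shape == (2,)


def test_wrong_input_size_raises(tiny_model):
    with pytest.raises(DimensionError, match="32"):
        tiny_model.extract_regional_features(make_image(np.zeros((16, 16, 3))))


def test_identical_scorer_outputs_give_uniform_scores():
    model = PainSeekerModel(backbone="tiny", input_size=32, seed=0,
                            width=8, d_x=8, scorer_zero_init=True)
    feats = model.extract_regional_features(
        make_image(np.random.default_rng(2).random((32, 32, 3))))
    scores = model.score_regions(feats)
    assert np.allclose(scores.scores, 1 / 16)


def test_two_region_analytic_scores(tiny_model):
    # g outputs (0, ln 3) → sigmoids (1/2, 3/4) → β = (0.4, 0.6)
    tiny_model.scorer.weight.data[:] = 1.0
    tiny_model.scorer.bias.data[:] = 0.0
    feats = Tensor(np.array([[[0.0], [np.log(3.0)]]]))
    tiny_model.scorer.weight.data = np.ones((1, 1))
    beta = tiny_model.scores_batch(feats).data[0]
    assert np.allclose(beta, [0.4, 0.6])


def test_score_invariants_hold(tiny_model, rng):
    feats = tiny_model.extract_regional_features(make_image(rng.random((32, 32, 3))))
    beta = tiny_model.score_regions(feats).scores
    assert beta.min() >= 0
    assert abs(beta.sum() - 1) <= 1e-6


def test_scorer_permutation_equivariance(tiny_model, rng):
    feats = rng.normal(size=(1, 16, 8))
    beta = tiny_model.scores_batch(Tensor(feats)).data[0]
    perm = rng.permutation(16)
    beta_perm = tiny_model.scores_batch(Tensor(feats[:, perm])).data[0]
    assert np.allclose(beta_perm, beta[perm])


def test_fusion_matches_loop_oracle_and_is_linear(tiny_model, rng):
    feats = rng.normal(size=(16, 8))
    b1 = rng.dirichlet(np.ones(16))
    b2 = rng.dirichlet(np.ones(16))
    alpha = 0.3

    def fused(beta):
        n_feats = Tensor(feats[None])
        return (n_feats * Tensor(beta[None]).reshape(1, 16, 1)).sum(axis=1).data[0]

    loop = sum(b1[j] * feats[j] for j in range(16))
    assert np.allclose(fused(b1), loop, atol=1e-6)
    mix = alpha * b1 + (1 - alpha) * b2
    assert np.allclose(fused(mix), alpha * fused(b1) + (1 - alpha) * fused(b2))


def test_onehot_scores_select_single_region(tiny_model, rng):
    feats = RegionalFeatures(matrix=rng.normal(size=(16, 8)), grid_side=4)
    onehot = np.zeros(16)
    onehot[5] = 1.0
    pred = tiny_model.fuse_and_predict(feats, AttentionScores(onehot))
    # fused vector is exactly region 5: compare against head applied directly
    logits = tiny_model.head(Tensor(feats.matrix[5][None])).data[0]
    expected = np.exp(logits - logits.max())
    expected /= expected.sum()
    assert np.allclose(pred.probs, expected)


def test_uniform_scores_average_identical_regions(tiny_model):
    v = np.full(8, 0.7)
    feats = RegionalFeatures(matrix=np.tile(v, (16, 1)), grid_side=4)
    pred = tiny_model.fuse_and_predict(feats, AttentionScores(np.full(16, 1 / 16)))
    logits = tiny_model.head(Tensor(v[None])).data[0]
    expected = np.exp(logits - logits.max())
    expected /= expected.sum()
    assert np.allclose(pred.probs, expected)


def test_score_length_mismatch_raises(tiny_model, rng):
    feats = RegionalFeatures(matrix=rng.normal(size=(16, 8)), grid_side=4)
    with pytest.raises(DimensionError):
        tiny_model.fuse_and_predict(feats, AttentionScores(np.full(4, 0.25)))


def test_forward_is_deterministic(tiny_model, rng):
    image = make_image(rng.random((32, 32, 3)))
    p1, s1 = tiny_model.forward(image)
    p2, s2 = tiny_model.forward(image)
    assert np.array_equal(p1.probs, p2.probs)
    assert np.array_equal(s1.scores, s2.scores)


def test_same_seed_same_parameters():
    m1 = PainSeekerModel(backbone="tiny", input_size=32, seed=11, width=8, d_x=8)
    m2 = PainSeekerModel(backbone="tiny", input_size=32, seed=11, width=8, d_x=8)
    for k, v in m1.named_arrays().items():
        assert np.array_equal(v, m2.named_arrays()[k]), k


def test_checkpoint_roundtrip_and_mismatch(tmp_path, tiny_model, rng):
    image = make_image(rng.random((32, 32, 3)))
    before = tiny_model.predict(image).probs
    path = tmp_path / "ckpt.npz"
    tiny_model.save(path)
    loaded = PainSeekerModel.load(path)
    assert np.array_equal(loaded.predict(image).probs, before)
    with pytest.raises(ValueError, match="mismatch"):
        PainSeekerModel.load(path, expect_config={"input_size": 224})


def test_label_and_prediction_invariants():
    lab = PainLabel(2, n_classes=3)
    assert lab.onehot.tolist() == [0, 0, 1]
    assert lab.binary_class.value == "Pain"
    assert PainLabel(0).binary_class.value == "NoPain"
    with pytest.raises(DimensionError):
        Prediction(probs=np.array([0.5, 0.2]))
    with pytest.raises(InvalidGridError):
        PainSeekerModel(backbone="tiny", input_size=32, seed=0,
                        width=8, d_x=8, attention=False).score_regions(
            RegionalFeatures(matrix=np.zeros((16, 8)), grid_side=4))
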