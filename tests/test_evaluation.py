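"""LORO protocol, confusion metrics, split arithmetic, sweep harness."""

import dataclasses

import numpy as np

import pytest
from sklearn.metrics import accuracy_score, f1_score as sk_f1

from painseeker import ratspain
from painseeker.evaluation import (PUBLISHED_GRIDS, ConfusionCounts, accuracy,
                                   binarize, f1_score, loro_split,
                                   loro_training_counts, run_loro, sweep)
from painseeker.exceptions import ProtocolError, SchemaError
from painseeker.model import BinaryClass, FacialImage, PainLabel, PainSeekerModel
from painseeker.objectives import PRSCConfig
from painseeker.trainer import TrainConfig

from conftest import make_image


@pytest.mark.parametrize("ordinal, expected", [
    (0, BinaryClass.NO_PAIN), (1, BinaryClass.PAIN), (2, BinaryClass.PAIN)])
def test_binarize(ordinal, expected):
    assert binarize(PainLabel(ordinal)) is expected
    assert binarize(ordinal) is expected


def test_binarize_rejects_out_of_range():
    with pytest.raises(SchemaError):
        binarize(3)


@pytest.mark.parametrize("counts, expected", [
    (ConfusionCounts(tp=10, fp=2, fn=3), 0.8),
    (ConfusionCounts(tp=5), 1.0),
    (ConfusionCounts(tp=0, fp=4, fn=3), 0.0),
])
def test_f1_worked_values(counts, expected):
    assert f1_score(counts) == pytest.approx(expected)


def test_f1_degenerate_no_positives_warns():
    with pytest.warns(UserWarning):
        assert f1_score(ConfusionCounts(tn=5)) == 0.0


@pytest.mark.parametrize("counts, expected", [
    (ConfusionCounts(tp=3, tn=4, fp=2, fn=1), 70.0),
    (ConfusionCounts(tp=7, tn=3), 100.0),
    (ConfusionCounts(fp=2, fn=8), 0.0),
])
def test_accuracy_worked_values(counts, expected):
    assert accuracy(counts) == pytest.approx(expected)


def test_accuracy_empty_raises():
    with pytest.raises(ProtocolError):
        accuracy(ConfusionCounts())


def test_metrics_match_pairwise_oracle(rng):
    """1,000 random confusion tables against sklearn on expanded pairs."""
    for _ in range(1000):
        tp, tn, fp, fn = rng.integers(0, 30, size=4)
        if tp + fn + fp == 0 or tp + tn + fp + fn == 0:
            continue
        truth = [1] * tp + [0] * fp + [1] * fn + [0] * tn
        pred = [1] * tp + [1] * fp + [0] * fn + [0] * tn
        c = ConfusionCounts(tp=int(tp), tn=int(tn), fp=int(fp), fn=int(fn))
        assert f1_score(c) == pytest.approx(
            sk_f1(truth, pred, pos_label=1, zero_division=0))
        assert accuracy(c) == pytest.approx(accuracy_score(truth, pred) * 100)


def _images_for(counts: dict[str, tuple[int, int]]) -> list[FacialImage]:
    out = []
    for subject, (no, pain) in counts.items():
        for i in range(no):
            out.append(make_image(np.zeros((8, 8, 3)), subject=subject,
                                  ordinal=0, image_id=f"{subject}_n{i}"))
        for i in range(pain):
            out.append(make_image(np.zeros((8, 8, 3)), subject=subject,
                                  ordinal=1, image_id=f"{subject}_p{i}"))
    return out


def test_loro_split_structure():
    images = _images_for({"a": (2, 1), "b": (1, 2)})
    folds = loro_split(images)
    assert [f.test_subject for f in folds] == ["a", "b"]
    for fold in folds:
        assert len(fold.train_indices) + len(fold.test_indices) == len(images)
        assert set(fold.train_indices).isdisjoint(fold.test_indices)
    all_test = np.concatenate([f.test_indices for f in folds])
    assert sorted(all_test) == list(range(len(images)))   # exhaustive, disjoint


def test_loro_single_subject_raises():
    with pytest.raises(ProtocolError):
        loro_split(_images_for({"a": (2, 2)}))


def test_published_split_table_reproduced():
    """The per-fold training counts implied by the published per-rat totals."""
    table = loro_training_counts(ratspain.binary_counts()).set_index("test_subject")
    expected = {
        "Rat1": (485, 432), "Rat2": (439, 489), "Rat3": (393, 547),
        "Rat4": (403, 505), "Rat5": (478, 478), "Rat6": (507, 534),
    }
    for subject, (no, pain) in expected.items():
        assert table.loc[subject, "train_no_pain"] == no
        assert table.loc[subject, "train_pain"] == pain


def test_split_table_matches_actual_split_counting():
    counts = {"a": (3, 1), "b": (2, 4), "c": (5, 5)}
    images = _images_for(counts)
    table = loro_training_counts(counts).set_index("test_subject")
    for fold in loro_split(images):
        train = [images[i] for i in fold.train_indices]
        n_pain = sum(binarize(im.label) is BinaryClass.PAIN for im in train)
        assert table.loc[fold.test_subject, "train_pain"] == n_pain
        assert table.loc[fold.test_subject, "train_no_pain"] == len(train) - n_pain


def _fast_cfg(seed=0, epochs=2):
    return TrainConfig(batch_size=8, learning_rate=1e-3, weight_decay=0.0,
                       epochs=epochs, input_size=32, resize_size=36, seed=seed)


def _fac(seed=0):
    return lambda: PainSeekerModel(backbone="tiny", input_size=32, n_classes=2,
                                   seed=seed, width=8, d_x=8)


def test_run_loro_structure_and_pooling(small_dataset):
    report = run_loro(small_dataset.images, _fac(), _fast_cfg(),
                      PRSCConfig(top_count=5))
    assert len(report.per_fold) == 3
    summed = ConfusionCounts()
    for r in report.per_fold:
        summed = summed + r.counts
    assert dataclasses.astuple(summed) == dataclasses.astuple(report.pooled_counts)
    assert report.pooled_f1 == pytest.approx(f1_score(summed))
    assert report.pooled_accuracy == pytest.approx(accuracy(summed))
    assert 0 <= report.pooled_f1 <= 1 and 0 <= report.pooled_accuracy <= 100
    assert report.pooled_counts.total == len(small_dataset.images)
    frame = report.to_frame()
    assert list(frame["fold"]) == ["s1", "s2", "s3", "pooled"]


def test_constant_predictor_scores_majority_rate(small_dataset):
    """A model that always answers 'Pain' gets the pain-class base rate."""
    class AlwaysPain:
        input_size = 32
        attention = False

        def eval(self):
            pass

        def forward_batch(self, x):
            from painseeker.autograd import Tensor
            n = x.shape[0]
            logp = np.tile(np.log([[1e-9, 1 - 1e-9]]), (n, 1))
            return Tensor(logp), None

    from painseeker.evaluation import evaluate_fold
    counts, _ = evaluate_fold(AlwaysPain(), small_dataset.images)
    pain_rate = np.mean([binarize(im.label) is BinaryClass.PAIN
                         for im in small_dataset.images])
    assert accuracy(counts) == pytest.approx(pain_rate * 100)


def test_sweep_single_point_equals_run_loro(small_dataset):
    cfg = PRSCConfig(lambda_tradeoff=0.1, margin=0.2, top_count=5)
    report = run_loro(small_dataset.images, _fac(), _fast_cfg(), cfg)
    table = sweep(small_dataset.images, _fac(), _fast_cfg(),
                  grids={"lambda_tradeoff": [0.1]}, defaults=cfg)
    assert len(table) == 1
    assert table.loc[0, "pooled_f1"] == pytest.approx(report.pooled_f1)
    assert table.loc[0, "pooled_accuracy"] == pytest.approx(report.pooled_accuracy)


def test_sweep_grid_shape_and_skip(small_dataset):
    table = sweep(small_dataset.images, _fac(), _fast_cfg(epochs=1),
                  grids={"margin": [0.1, 0.2], "top_count": [3, 99]})
    # K = 16, so K_h = 99 is skipped with a warning
    assert len(table) == 3
    assert set(table["parameter"]) == {"margin", "top_count"}


def test_published_grids_contents():
    assert PUBLISHED_GRIDS["lambda_tradeoff"] == [0.05, 0.1, 0.5, 1.0, 1.5]
    assert PUBLISHED_GRIDS["margin"] == [0.05, 0.1, 0.15, 0.2, 0.5]
    assert PUBLISHED_GRIDS["top_count"] == [3, 5, 10, 15, 20]
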