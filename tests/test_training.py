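"""Training loop, evaluation metrics, and stratified cross-validation."""

import numpy as np
import pytest

from mircnn.io import FamilyDataset, RnaSequence
from mircnn.models import OneHotCnnSpec
from mircnn.synthetic import make_benchmark
from mircnn.training import (
    TrainConfig,
    TrainedClassifier,
    encode_dataset,
    evaluate,
    kfold_cv,
    load_classifier,
    save_classifier,
    train,
)

TINY_SPEC = dict(
    input_len=80, filter_widths=(4, 8), kernels_per_width=16, fc_units=(32,)
)


@pytest.fixture(scope="module")
def tiny_benchmark():
    """2 disjoint-motif families x 30 members; separable by construction."""
    return make_benchmark(n_families=2, per_family=30, mu=0.05, seed=3).dataset


def test_separable_families_reach_high_heldout_accuracy(tiny_benchmark):
    ds = tiny_benchmark
    rng = np.random.default_rng(0)
    y = np.array(ds.labels())
    tr, te = [], []
    for c in range(2):
        ci = np.flatnonzero(y == c)
        rng.shuffle(ci)
        te += list(ci[:6])
        tr += list(ci[6:])
    spec = OneHotCnnSpec(classes=2, **TINY_SPEC)
    # small dataset: small batches so Adam gets several updates per epoch
    cfg = TrainConfig(epochs=40, batch_size=8, seed=0, encoding="onehot", L=80,
                      patience=40)
    clf = train(ds.subset(tr), spec, cfg)
    report = evaluate(clf, ds.subset(te))
    assert report.accuracy >= 0.98
    assert report.macro_fscore == pytest.approx(report.accuracy, abs=0.05)


def test_training_is_deterministic_under_a_seed(tiny_benchmark):
    spec = OneHotCnnSpec(classes=2, **TINY_SPEC)
    cfg = TrainConfig(epochs=3, seed=11, encoding="onehot", L=80)
    a = train(tiny_benchmark, spec, cfg)
    b = train(tiny_benchmark, spec, cfg)
    assert a.loss_history[-1] == pytest.approx(b.loss_history[-1], abs=1e-6)
    for pa, pb in zip(a.model.params(), b.model.params()):
        assert np.allclose(pa.value, pb.value)


def test_single_class_dataset_rejected():
    seqs = [RnaSequence(f"s{i}", "ACGUACGU", "only") for i in range(4)]
    ds = FamilyDataset(seqs, {"only": 0})
    with pytest.raises(ValueError, match="at least 2 classes"):
        train(ds, OneHotCnnSpec(classes=2, **TINY_SPEC), TrainConfig(L=80))


def test_class_count_mismatch_rejected(tiny_benchmark):
    spec = OneHotCnnSpec(classes=5, **TINY_SPEC)
    with pytest.raises(ValueError, match="classes"):
        train(tiny_benchmark, spec, TrainConfig(L=80))


class _StubModel:
    """Returns canned softmax rows; lets metric arithmetic be tested exactly."""

    def __init__(self, probs):
        self.probs = np.asarray(probs)

    def predict_proba(self, X, batch_size=0):
        return self.probs[: len(X)]


def _stub_classifier(probs, families):
    clf = TrainedClassifier.__new__(TrainedClassifier)
    clf.model = _StubModel(probs)
    clf.label_index = {f: i for i, f in enumerate(families)}
    clf.config = TrainConfig(encoding="onehot", L=4)
    clf.loss_history = []
    clf.rejection_threshold = 0.977
    return clf


def _dataset(labels):
    seqs = [RnaSequence(f"s{i}", "ACGU", fam) for i, fam in enumerate(labels)]
    index = {f: i for i, f in enumerate(sorted(set(labels)))}
    return FamilyDataset(seqs, index, max_len=4)


def test_evaluate_accuracy_arithmetic():
    # 10 sequences, 9 predicted correctly
    true = ["a"] * 5 + ["b"] * 5
    pred = [0, 0, 0, 0, 0, 1, 1, 1, 1, 0]
    probs = np.eye(2)[pred]
    clf = _stub_classifier(probs, ["a", "b"])
    rep = evaluate(clf, _dataset(true), X=np.zeros((10, 4, 4)))
    assert rep.accuracy == pytest.approx(0.9)


def test_evaluate_per_class_precision_recall_fscore():
    # class a: TP=9, FP=1, FN=1 -> precision = recall = F = 0.9
    true = ["a"] * 10 + ["b"] * 10
    pred = [0] * 9 + [1] + [0] + [1] * 9
    probs = np.eye(2)[pred]
    clf = _stub_classifier(probs, ["a", "b"])
    rep = evaluate(clf, _dataset(true), X=np.zeros((20, 4, 4)))
    row_a = rep.per_class[0]
    assert (row_a["TP"], row_a["FP"], row_a["FN"]) == (9, 1, 1)
    assert row_a["precision"] == pytest.approx(0.9)
    assert row_a["recall"] == pytest.approx(0.9)
    assert row_a["fscore"] == pytest.approx(0.9)


def test_evaluate_zero_denominator_yields_zero():
    # class b never predicted and has no members in test: TP=FP=0 -> 0, not NaN
    true = ["a"] * 4
    probs = np.eye(2)[[0, 0, 0, 0]]
    clf = _stub_classifier(probs, ["a", "b"])
    rep = evaluate(clf, _dataset(true).subset(range(4)), X=np.zeros((4, 4, 4)))
    row_b = rep.per_class[1]
    assert row_b["precision"] == row_b["recall"] == row_b["fscore"] == 0.0
    assert 0.0 <= rep.macro_fscore <= 1.0


def test_evaluate_rejects_unseen_family():
    clf = _stub_classifier(np.eye(2), ["a", "b"])
    with pytest.raises(ValueError, match="unseen"):
        evaluate(clf, _dataset(["a", "zz"]), X=np.zeros((2, 4, 4)))


class TestKFold:
    def test_folds_partition_and_stratify(self, tiny_benchmark):
        spec = OneHotCnnSpec(classes=2, **TINY_SPEC)
        cfg = TrainConfig(epochs=1, seed=0, encoding="onehot", L=80)
        reports = kfold_cv(tiny_benchmark, spec, cfg, k=5)
        assert len(reports) == 5
        # 30 per class / 5 folds -> 6 test sequences per class per fold
        assert all(rep.n_test == 12 for rep in reports)

    def test_k_below_two_rejected(self, tiny_benchmark):
        with pytest.raises(ValueError, match="k must be"):
            kfold_cv(tiny_benchmark, OneHotCnnSpec(classes=2, **TINY_SPEC),
                     TrainConfig(L=80), k=1)

    def test_class_smaller_than_k_rejected(self):
        seqs = [RnaSequence(f"a{i}", "ACGUACGU", "a") for i in range(10)]
        seqs += [RnaSequence(f"b{i}", "GGCCGGCC", "b") for i in range(3)]
        ds = FamilyDataset(seqs, {"a": 0, "b": 1})
        with pytest.raises(ValueError, match="smaller than k"):
            kfold_cv(ds, OneHotCnnSpec(classes=2, **TINY_SPEC),
                     TrainConfig(L=80), k=5)


def test_stratified_fold_indices_cover_dataset_exactly_once(tiny_benchmark):
    from sklearn.model_selection import StratifiedKFold

    y = np.array(tiny_benchmark.labels())
    skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=0)
    seen = []
    for _, te in skf.split(np.zeros(len(y)), y):
        counts = np.bincount(y[te], minlength=2)
        assert abs(counts[0] - counts[1]) <= 1
        seen += list(te)
    assert sorted(seen) == list(range(len(y)))


def test_save_load_round_trip(tmp_path, tiny_benchmark):
    spec = OneHotCnnSpec(classes=2, **TINY_SPEC)
    cfg = TrainConfig(epochs=2, seed=0, encoding="onehot", L=80)
    clf = train(tiny_benchmark, spec, cfg)
    save_classifier(clf, tmp_path / "model")
    back = load_classifier(tmp_path / "model")
    X, _ = encode_dataset(tiny_benchmark, "onehot", L=80)
    assert np.allclose(clf.predict_proba(X), back.predict_proba(X))
    assert back.label_index == clf.label_index
    assert back.rejection_threshold == clf.rejection_threshold


def test_input_shape_mismatch_detected(tiny_benchmark):
    spec = OneHotCnnSpec(classes=2, **TINY_SPEC)
    clf = train(tiny_benchmark, spec, TrainConfig(epochs=1, encoding="onehot", L=80))
    with pytest.raises(ValueError, match="does not match"):
        clf.predict_proba(np.zeros((3, 200, 4)))
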