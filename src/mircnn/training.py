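"""Training, evaluation, and stratified cross-validation.

``train`` encodes a labelled dataset with the configured encoding,
optimizes the network with Adam on mini-batches, and returns a
:class:`TrainedClassifier` bundling weights, label map, encoding
parameters, and the open-set rejection threshold. ``evaluate`` computes
accuracy and per-family precision/recall/F-score; ``kfold_cv`` runs
stratified k-fold cross-validation.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from . import encoding as enc
from .io import FamilyDataset
from .models import (
    OneHotCnn,
    OneHotCnnSpec,
    StructCnn,
    StructCnnSpec,
    build_onehot_cnn,
    build_struct_cnn,
)
from .nn import Adam, softmax_cross_entropy
from .structure import FoldParams, mccaskill_bppm

#: Shipped-model default for open-set rejection on the max softmax value.
DEFAULT_SOFTMAX_THRESHOLD = 0.977


@dataclass(frozen=True)
class TrainConfig:
    """Knobs of one training run.

    ``encoding`` is one of probability/pair/mixed/onehot; T and the
    ordered flag apply to the structure encodings only. Early stopping
    watches the training loss (patience epochs without improvement).
    """

    epochs: int = 50
    batch_size: int | None = None  # None -> the spec's default (32 struct / 64 one-hot)
    learning_rate: float = 0.001
    seed: int = 0
    encoding: str = "onehot"
    T: float = enc.DEFAULT_T
    ordered: bool = True
    L: int = enc.DEFAULT_L
    patience: int = 5
    min_delta: float = 1e-4

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size is not None and self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.encoding not in enc.ENCODING_KINDS:
            raise ValueError(f"unknown encoding {self.encoding!r}")


def encode_dataset(
    dataset: FamilyDataset,
    kind: str = "onehot",
    T: float = enc.DEFAULT_T,
    ordered: bool = True,
    L: int = enc.DEFAULT_L,
    fold_params: FoldParams | None = None,
    bppms: list | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Encode every sequence; returns (X, y) arrays.

    For the structure encodings, pairing probabilities are computed with
    the built-in partition function unless precomputed ``bppms`` (one per
    sequence, in order) are supplied.
    """
    y = np.asarray(dataset.labels(), dtype=np.int64)
    if kind == "onehot":
        X = np.stack([enc.one_hot(s, L).grid for s in dataset.sequences])
        return X, y
    if bppms is None:
        fp = fold_params or FoldParams()
        bppms = [mccaskill_bppm(s, fp) for s in dataset.sequences]
    grids = []
    for s, bpp in zip(dataset.sequences, bppms):
        if kind == "probability":
            grids.append(enc.probability_matrix(bpp, T, L).grid)
        elif kind == "pair":
            grids.append(enc.pair_matrix(s, bpp, T, ordered, L).grid)
        elif kind == "mixed":
            grids.append(enc.mixed_matrix(s, bpp, T, ordered, L).grid)
        else:
            raise ValueError(f"unknown encoding kind {kind!r}")
    return np.stack(grids), y


@dataclass
class TrainedClassifier:
    """A trained network plus everything needed to apply it consistently."""

    model: StructCnn | OneHotCnn
    label_index: dict[str, int]
    config: TrainConfig
    loss_history: list[float] = field(default_factory=list)
    rejection_threshold: float = DEFAULT_SOFTMAX_THRESHOLD

    @property
    def families(self) -> list[str]:
        return [f for f, _ in sorted(self.label_index.items(), key=lambda kv: kv[1])]

    def encode(self, dataset: FamilyDataset, **kw) -> tuple[np.ndarray, np.ndarray]:
        c = self.config
        return encode_dataset(dataset, c.encoding, c.T, c.ordered, c.L, **kw)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        self._check_input(X)
        return self.model.predict_proba(X)

    def _check_input(self, X: np.ndarray) -> None:
        kind = self.config.encoding
        if kind == "onehot":
            ok = X.ndim == 3 and X.shape[1:] == (self.config.L, 4)
        elif kind == "mixed":
            ok = X.ndim == 4 and X.shape[1:] == (self.config.L, self.config.L, 2)
        else:
            ok = X.ndim >= 3 and X.shape[1] == X.shape[2] == self.config.L
        if not ok:
            raise ValueError(
                f"input shape {X.shape} does not match the {kind!r} encoding "
                f"this classifier was trained on (L={self.config.L})"
            )


def train(
    dataset: FamilyDataset,
    spec: StructCnnSpec | OneHotCnnSpec,
    config: TrainConfig,
    X: np.ndarray | None = None,
    verbose: bool = False,
) -> TrainedClassifier:
    """Fit a classifier on an encoded dataset.

    Pre-encoded inputs may be passed as ``X`` (rows in dataset order) to
    avoid recomputing structure matrices. Deterministic under
    ``config.seed`` on a fixed platform.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    if dataset.n_classes < 2:
        raise ValueError("need at least 2 classes to train")
    if dataset.n_classes != spec.classes:
        raise ValueError(
            f"dataset has {dataset.n_classes} classes but spec declares {spec.classes}"
        )
    if X is None:
        X, y = encode_dataset(
            dataset, config.encoding, config.T, config.ordered, config.L
        )
    else:
        y = np.asarray(dataset.labels(), dtype=np.int64)
        if len(X) != len(y):
            raise ValueError("pre-encoded X does not match dataset size")

    if isinstance(spec, StructCnnSpec):
        model = build_struct_cnn(spec, seed=config.seed)
    else:
        model = build_onehot_cnn(spec, seed=config.seed)
    batch = config.batch_size or spec.batch_size
    opt = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]).generate_state(1)[0])

    history: list[float] = []
    best = np.inf
    stale = 0
    n = len(y)
    for epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch):
            idx = order[start : start + batch]
            opt.zero_grad()
            logits = model.forward(X[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, y[idx])
            model.backward(dlogits)
            opt.step()
            losses.append(loss * len(idx))
        epoch_loss = float(np.sum(losses) / n)
        history.append(epoch_loss)
        if verbose:
            print(f"epoch {epoch + 1}: loss {epoch_loss:.4f}")
        if epoch_loss < best - config.min_delta:
            best = epoch_loss
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                break
    return TrainedClassifier(model, dict(dataset.label_index), config, history)


@dataclass
class EvalReport:
    """Accuracy plus per-family precision/recall/F-score."""

    accuracy: float
    per_class: list[dict]  # family, TP, FP, FN, precision, recall, fscore
    macro_fscore: float
    n_test: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.per_class)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def summary(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_fscore": self.macro_fscore,
            "n_test": self.n_test,
        }


def _safe_div(num: float, den: float) -> float:
    return num / den if den > 0 else 0.0


def evaluate(
    classifier: TrainedClassifier,
    test: FamilyDataset,
    X: np.ndarray | None = None,
) -> EvalReport:
    """Closed-set evaluation: argmax prediction, no rejection."""
    unseen = set(test.label_index) - set(classifier.label_index)
    if unseen:
        raise ValueError(f"test set contains families unseen in training: {sorted(unseen)}")
    if X is None:
        X, _ = classifier.encode(test)
    probs = classifier.predict_proba(X)
    pred = probs.argmax(axis=1)  # ties -> lowest class id
    true = np.asarray([classifier.label_index[s.family] for s in test.sequences])

    accuracy = float(np.mean(pred == true))
    per_class = []
    fscores = []
    for family, cid in sorted(classifier.label_index.items(), key=lambda kv: kv[1]):
        tp = int(np.sum((pred == cid) & (true == cid)))
        fp = int(np.sum((pred == cid) & (true != cid)))
        fn = int(np.sum((pred != cid) & (true == cid)))
        precision = _safe_div(tp, tp + fp)
        recall = _safe_div(tp, tp + fn)
        fscore = _safe_div(2 * precision * recall, precision + recall)
        per_class.append(
            {"family": family, "TP": tp, "FP": fp, "FN": fn,
             "precision": precision, "recall": recall, "fscore": fscore}
        )
        fscores.append(fscore)
    return EvalReport(accuracy, per_class, float(np.mean(fscores)), len(true))


def kfold_cv(
    dataset: FamilyDataset,
    spec: StructCnnSpec | OneHotCnnSpec,
    config: TrainConfig,
    k: int = 5,
) -> list[EvalReport]:
    """Stratified k-fold cross-validation; one report per fold."""
    if k < 2:
        raise ValueError("k must be >= 2")
    y = np.asarray(dataset.labels())
    counts = np.bincount(y, minlength=dataset.n_classes)
    small = [dataset.families[i] for i in np.flatnonzero(counts < k)]
    if small:
        raise ValueError(f"families smaller than k={k}: {small}")
    # Encode once; folds reuse rows.
    X, _ = encode_dataset(dataset, config.encoding, config.T, config.ordered, config.L)
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=config.seed)
    reports = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        clf = train(dataset.subset(train_idx), spec, config, X=X[train_idx])
        reports.append(evaluate(clf, dataset.subset(test_idx), X=X[test_idx]))
    return reports


def save_classifier(clf: TrainedClassifier, prefix: str | Path) -> None:
    """Persist weights (.npz) plus a JSON sidecar with spec/labels/threshold."""
    prefix = Path(prefix)
    arrays = {f"p{i}": p.value for i, p in enumerate(clf.model.params())}
    np.savez_compressed(prefix.with_suffix(".npz"), **arrays)
    spec = clf.model.spec
    sidecar = {
        "spec_type": type(spec).__name__,
        "spec": dataclasses.asdict(spec),
        "label_index": clf.label_index,
        "config": dataclasses.asdict(clf.config),
        "rejection_threshold": clf.rejection_threshold,
        "loss_history": clf.loss_history,
    }
    prefix.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_classifier(prefix: str | Path) -> TrainedClassifier:
    prefix = Path(prefix)
    sidecar = json.loads(prefix.with_suffix(".json").read_text())
    spec_dict = sidecar["spec"]
    if sidecar["spec_type"] == "StructCnnSpec":
        spec_dict["conv_kernels"] = tuple(tuple(k) for k in spec_dict["conv_kernels"])
        spec_dict["fc_units"] = tuple(spec_dict["fc_units"])
        spec = StructCnnSpec(**spec_dict)
        model = build_struct_cnn(spec)
    else:
        spec_dict["filter_widths"] = tuple(spec_dict["filter_widths"])
        spec_dict["fc_units"] = tuple(spec_dict["fc_units"])
        spec = OneHotCnnSpec(**spec_dict)
        model = build_onehot_cnn(spec)
    with np.load(prefix.with_suffix(".npz")) as z:
        for i, p in enumerate(model.params()):
            p.value[...] = z[f"p{i}"]
    config = TrainConfig(**sidecar["config"])
    clf = TrainedClassifier(
        model, dict(sidecar["label_index"]), config,
        list(sidecar["loss_history"]), float(sidecar["rejection_threshold"]),
    )
    return clf
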