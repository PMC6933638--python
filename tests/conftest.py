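"""Shared fixtures: the synthetic benchmark and classifiers trained on it.

Training fixtures are session-scoped so the open-set, motif, and
classification tests reuse the same fitted models. Problem sizes are
desk-scale: 10 hairpin families x 60 members at substitution rate 0.05
for classification/open-set, and a 4-family divergent-background
benchmark (rate 0.25) for motif recovery.
"""

from __future__ import annotations

import numpy as np
import pytest

from mircnn.encoding import one_hot
from mircnn.io import FamilyDataset
from mircnn.models import OneHotCnnSpec, StructCnnSpec
from mircnn.synthetic import make_benchmark
from mircnn.training import TrainConfig, encode_dataset, train

BENCH_SEED = 1
MOTIF_SEED = 5
STRUCT_L = 80

ONEHOT_SPEC = dict(input_len=200, kernels_per_width=64, fc_units=(256,))
STRUCT_SPEC = dict(input_len=STRUCT_L, conv_kernels=((2, 16), (2, 32)), fc_units=(64, 32))


def stratified_split(dataset: FamilyDataset, test_per_class: int, seed: int = 0):
    """Deterministic per-class split; returns (train_idx, test_idx)."""
    rng = np.random.default_rng(seed)
    y = np.asarray(dataset.labels())
    tr, te = [], []
    for c in range(dataset.n_classes):
        ci = np.flatnonzero(y == c)
        rng.shuffle(ci)
        te += list(ci[:test_per_class])
        tr += list(ci[test_per_class:])
    return tr, te


def encode_onehot_seqs(seqs, L: int = 200) -> np.ndarray:
    return np.stack([one_hot(s, L).grid for s in seqs])


@pytest.fixture(scope="session")
def benchmark():
    """10 families x 60 members, mu = 0.05, plus decoy sets."""
    return make_benchmark(n_families=10, per_family=60, mu=0.05, seed=BENCH_SEED)


@pytest.fixture(scope="session")
def benchmark_split(benchmark):
    return stratified_split(benchmark.dataset, test_per_class=12, seed=0)


@pytest.fixture(scope="session")
def onehot_classifier(benchmark, benchmark_split):
    """One-hot CNN fitted on the 80% training split."""
    tr, _ = benchmark_split
    spec = OneHotCnnSpec(classes=benchmark.dataset.n_classes, **ONEHOT_SPEC)
    cfg = TrainConfig(epochs=40, seed=0, encoding="onehot", patience=15)
    return train(benchmark.dataset.subset(tr), spec, cfg)

@pytest.fixture(scope="session")
def struct_encoded(benchmark):
    """Ordered pair matrices for the whole benchmark at L=80."""
    X, y = encode_dataset(benchmark.dataset, "pair", L=STRUCT_L)
    return X


@pytest.fixture(scope="session")
def struct_classifier(benchmark, benchmark_split, struct_encoded):
    tr, _ = benchmark_split
    spec = StructCnnSpec(classes=benchmark.dataset.n_classes, **STRUCT_SPEC)
    cfg = TrainConfig(epochs=15, seed=0, encoding="pair", L=STRUCT_L, patience=15)
    return train(benchmark.dataset.subset(tr), spec, cfg, X=struct_encoded[tr])


@pytest.fixture(scope="session")
def motif_benchmark():
    """Divergent-background benchmark for plant-and-recover motif tests."""
    return make_benchmark(n_families=4, per_family=60, mu=0.25, seed=MOTIF_SEED)


@pytest.fixture(scope="session")
def motif_classifier(motif_benchmark):
    spec = OneHotCnnSpec(classes=4, **ONEHOT_SPEC)
    cfg = TrainConfig(epochs=80, seed=0, encoding="onehot", patience=80)
    return train(motif_benchmark.dataset, spec, cfg)
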