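"""The four input encodings and their algebraic relations."""

import numpy as np
import pytest

from mircnn.encoding import (
    DEFAULT_T,
    ORDERED_PAIR_CODE,
    UNORDERED_PAIR_CODE,
    load_grid,
    mixed_matrix,
    one_hot,
    pair_matrix,
    percentile_thresholds,
    probability_matrix,
    save_grid,
)
from mircnn.io import RnaSequence
from mircnn.structure import BasePairProbabilities, mccaskill_bppm
from mircnn.synthetic import make_family, make_template


def bpp(n, pairs):
    return BasePairProbabilities(n, pairs)


class TestProbabilityMatrix:
    def test_symmetric_fill_above_threshold(self):
        enc = probability_matrix(bpp(10, {(0, 8): 0.9}), T=0.0001, L=10)
        assert enc.grid[0, 8] == enc.grid[8, 0] == 0.9
        assert enc.grid.sum() == pytest.approx(1.8)

    def test_below_threshold_dropped(self):
        enc = probability_matrix(bpp(10, {(0, 8): 0.00005}), T=0.0001, L=10)
        assert not enc.grid.any()

    def test_empty_pairs_all_zero_and_padding(self):
        enc = probability_matrix(bpp(5, {}), L=8)
        assert enc.grid.shape == (8, 8)
        assert not enc.grid.any()

    def test_sequence_longer_than_grid_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            probability_matrix(bpp(10, {}), L=5)


class TestPairMatrix:
    SEQ = RnaSequence("x", "AGCUUGGCA")  # handy mixed-base sequence

    def test_ordered_codes_orientation(self):
        seq = RnaSequence("x", "A" + "G" * 7 + "U" + "G")
        enc = pair_matrix(seq, bpp(10, {(0, 8): 0.9}), ordered=True, L=10)
        assert enc.grid[0, 8] == pytest.approx(1 / 6)  # s_i s_j = AU
        assert enc.grid[8, 0] == pytest.approx(2 / 6)  # s_j s_i = UA

    def test_unordered_wobble_code(self):
        seq = RnaSequence("x", "U" + "A" * 7 + "G" + "A")
        enc = pair_matrix(seq, bpp(10, {(0, 8): 0.9}), ordered=False, L=10)
        assert enc.grid[0, 8] == enc.grid[8, 0] == pytest.approx(1.0)  # 3/3

    def test_below_threshold_zero(self):
        seq = RnaSequence("x", "A" + "G" * 7 + "U" + "G")
        enc = pair_matrix(seq, bpp(10, {(0, 8): 1e-9}), T=DEFAULT_T, L=10)
        assert not enc.grid.any()

    def test_noncanonical_stored_pair_is_contract_violation(self):
        seq = RnaSequence("x", "A" + "G" * 8 + "A")
        with pytest.raises(ValueError, match="non-canonical"):
            pair_matrix(seq, bpp(10, {(0, 9): 0.9}), L=10)

    def test_all_ordered_codes_cover_six_values(self):
        assert sorted(ORDERED_PAIR_CODE.values()) == pytest.approx(
            [k / 6 for k in range(1, 7)]
        )
        assert sorted(set(UNORDERED_PAIR_CODE.values())) == pytest.approx(
            [1 / 3, 2 / 3, 1.0]
        )


def test_mixed_matrix_composes_the_two_channels():
    seq = RnaSequence("x", "A" + "G" * 7 + "U" + "G")
    probs = bpp(10, {(0, 8): 0.9})
    enc = mixed_matrix(seq, probs, ordered=True, L=12)
    assert enc.grid.shape == (12, 12, 2)
    assert np.array_equal(enc.grid[..., 0], probability_matrix(probs, L=12).grid)
    assert np.array_equal(enc.grid[..., 1], pair_matrix(seq, probs, L=12).grid)
    assert enc.grid[0, 8, 0] == 0.9
    assert enc.grid[0, 8, 1] == pytest.approx(1 / 6)


def test_mixed_matrix_empty_is_all_zero():
    enc = mixed_matrix(RnaSequence("x", "AAAA"), bpp(4, {}), L=6)
    assert enc.grid.shape == (6, 6, 2)
    assert not enc.grid.any()


class TestOneHot:
    def test_acgu_is_identity_pattern(self):
        enc = one_hot(RnaSequence("x", "ACGU"), L=200)
        assert np.array_equal(enc.grid[:4], np.eye(4))
        assert not enc.grid[4:].any()

    def test_unknown_base_row_is_zero(self):
        enc = one_hot(RnaSequence("x", "N"), L=4)
        assert not enc.grid[0].any()

    def test_row_sums(self):
        enc = one_hot(RnaSequence("x", "ACNGU"), L=8)
        sums = enc.grid.sum(axis=1)
        assert sums.max() <= 1
        assert list(sums[:5]) == [1, 1, 0, 1, 1]

    def test_invertible_on_unpadded_region(self):
        residues = "ACGUUGCA"
        enc = one_hot(RnaSequence("x", residues), L=16)
        decoded = "".join("ACGU"[k] for k in enc.grid[: len(residues)].argmax(axis=1))
        assert decoded == residues

    def test_too_long_rejected(self):
        with pytest.raises(ValueError, match="exceeds"):
            one_hot(RnaSequence("x", "ACGU"), L=3)


class TestPercentileThresholds:
    def test_constant_pool(self):
        pool = [bpp(10, {(0, 8): 0.5, (1, 7): 0.5}), bpp(10, {(0, 9): 0.5})]
        assert percentile_thresholds(pool, [0, 50]) == [0.5, 0.5]

    def test_percentile_zero_is_minimum(self):
        pairs = {(0, i + 4): (i + 1) / 10 for i in range(6)}
        pairs.update({(1, i + 5): (i + 7) / 10 for i in range(4)})
        assert percentile_thresholds([bpp(12, pairs)], [0]) == [0.1]

    def test_floor_excludes_small_probabilities(self):
        pool = [bpp(10, {(0, 8): 0.00005, (1, 7): 0.4})]
        assert percentile_thresholds(pool, [0], floor=0.0001) == [0.4]

    def test_empty_pool_is_an_error(self):
        with pytest.raises(ValueError, match="floor"):
            percentile_thresholds([bpp(10, {})], [0])


@pytest.fixture(scope="module")
def hairpin_bppms():
    """20 synthetic hairpins (~46 nt) with their pairing probabilities."""
    out = []
    for k in range(20):
        tpl = make_template(f"h{k}", seed=100 + k, arm_len=18, loop_len=10, motif_len=10)
        (seq,) = make_family(tpl, 1, seed=k)
        out.append((seq, mccaskill_bppm(seq)))
    return out


def test_ordered_to_unordered_value_mapping(hairpin_bppms):
    # collapsing {1/6,2/6}->1/3, {3/6,4/6}->2/3, {5/6,6/6}->1 recovers unordered
    collapse = {0: 0.0, 1: 1 / 3, 2: 1 / 3, 3: 2 / 3, 4: 2 / 3, 5: 1.0, 6: 1.0}
    for seq, probs in hairpin_bppms:
        L = len(seq)
        ordered = pair_matrix(seq, probs, ordered=True, L=L).grid
        unordered = pair_matrix(seq, probs, ordered=False, L=L).grid
        sixths = np.round(ordered * 6).astype(int)
        mapped = np.vectorize(collapse.get)(sixths)
        assert np.allclose(mapped, unordered)


def test_support_symmetry_and_monotone_threshold_sweep(hairpin_bppms):
    seqs, probs = zip(*hairpin_bppms)
    thresholds = percentile_thresholds(probs, [0, 10, 20, 30, 40])
    assert thresholds == sorted(thresholds)
    for seq, p in hairpin_bppms[:5]:
        last = None
        for T in thresholds:
            grid = pair_matrix(seq, p, T=T, L=len(seq)).grid
            assert np.array_equal(grid != 0, (grid != 0).T)  # support symmetry
            nnz = int((grid != 0).sum())
            if last is not None:
                assert nnz <= last
            last = nnz


def test_grid_archive_round_trip(tmp_path):
    seq = RnaSequence("x", "A" + "G" * 7 + "U" + "G")
    enc = pair_matrix(seq, bpp(10, {(0, 8): 0.9}), L=10)
    save_grid(enc, tmp_path / "g.npz")
    back = load_grid(tmp_path / "g.npz")
    assert back.kind == "pair" and back.ordered is True and back.seq_id == "x"
    assert np.array_equal(back.grid, enc.grid)
    assert back.T == enc.T
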