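"""Fixed-size numeric encodings of sequences and their pairing structure.

Four encodings feed the classifiers:

* **probability matrix** — L x L grid holding p(i,j) where p >= T, else 0;
* **pair matrix** — L x L grid holding a pair-identity code where
  p >= T: ordered AU 1/6, UA 2/6, CG 3/6, GC 4/6, GU 5/6, UG 6/6, or
  unordered AU/UA 1/3, CG/GC 2/3, GU/UG 3/3;
* **mixed matrix** — L x L x 2, probability channel stacked on the pair
  channel;
* **one-hot** — L x 4 indicator rows in column order A, C, G, U.

Sequences shorter than L are zero-padded at the end; every grid value
lies in [0, 1]. An ordered pair matrix is support-symmetric but
value-asymmetric: cell (i,j) reads the bases in order (s_i, s_j) while
(j,i) reads (s_j, s_i).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import ALPHABET, RnaSequence
from .structure import CANONICAL_PAIRS, BasePairProbabilities

#: Probability threshold below which a pairing is not encoded.
DEFAULT_T = 0.0001

#: Padded grid side length (matches the 200 nt sequence cap).
DEFAULT_L = 200

ENCODING_KINDS = ("probability", "pair", "mixed", "onehot")

ORDERED_PAIR_CODE = {
    "AU": 1 / 6, "UA": 2 / 6, "CG": 3 / 6, "GC": 4 / 6, "GU": 5 / 6, "UG": 6 / 6,
}
UNORDERED_PAIR_CODE = {
    "AU": 1 / 3, "UA": 1 / 3, "CG": 2 / 3, "GC": 2 / 3, "GU": 3 / 3, "UG": 3 / 3,
}

_BASE_COLUMN = {b: k for k, b in enumerate(ALPHABET)}


@dataclass
class EncodedInput:
    """One encoded sequence: the grid plus the encoding metadata."""

    grid: np.ndarray
    kind: str
    L: int
    T: float | None = None
    ordered: bool | None = None
    seq_id: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ENCODING_KINDS:
            raise ValueError(f"unknown encoding kind {self.kind!r}")


def _check_fits(n: int, L: int) -> None:
    if n > L:
        raise ValueError(f"sequence length {n} exceeds grid size L={L}")


def probability_matrix(
    bpp: BasePairProbabilities, T: float = DEFAULT_T, L: int = DEFAULT_L
) -> EncodedInput:
    """L x L grid of pairing probabilities, thresholded at T."""
    _check_fits(bpp.n, L)
    if not (0.0 <= T <= 1.0):
        raise ValueError("T must be in [0, 1]")
    grid = np.zeros((L, L))
    for (i, j), p in bpp.pairs.items():
        if p >= T:
            grid[i, j] = grid[j, i] = p
    return EncodedInput(grid, "probability", L, T=T)


def pair_matrix(
    seq: RnaSequence,
    bpp: BasePairProbabilities,
    T: float = DEFAULT_T,
    ordered: bool = True,
    L: int = DEFAULT_L,
) -> EncodedInput:
    """L x L grid of base-pair identity codes for pairings with p >= T."""
    _check_fits(bpp.n, L)
    if len(seq) != bpp.n:
        raise ValueError("sequence length and bpp.n disagree")
    code = ORDERED_PAIR_CODE if ordered else UNORDERED_PAIR_CODE
    grid = np.zeros((L, L))
    for (i, j), p in bpp.pairs.items():
        if p < T:
            continue
        fwd = seq.residues[i] + seq.residues[j]
        if fwd not in CANONICAL_PAIRS:
            raise ValueError(
                f"stored pair ({i},{j}) = {fwd} of {seq.id!r} is non-canonical"
            )
        grid[i, j] = code[fwd]
        grid[j, i] = code[fwd[::-1]]
    return EncodedInput(grid, "pair", L, T=T, ordered=ordered, seq_id=seq.id)


def mixed_matrix(
    seq: RnaSequence,
    bpp: BasePairProbabilities,
    T: float = DEFAULT_T,
    ordered: bool = True,
    L: int = DEFAULT_L,
) -> EncodedInput:
    """L x L x 2 grid: probability channel 0, pair-identity channel 1."""
    prob = probability_matrix(bpp, T, L)
    pair = pair_matrix(seq, bpp, T, ordered, L)
    grid = np.stack([prob.grid, pair.grid], axis=-1)
    return EncodedInput(grid, "mixed", L, T=T, ordered=ordered, seq_id=seq.id)


def one_hot(seq: RnaSequence, L: int = DEFAULT_L) -> EncodedInput:
    """L x 4 one-hot rows (columns A, C, G, U); N rows and padding are zero."""
    _check_fits(len(seq), L)
    grid = np.zeros((L, 4))
    for i, base in enumerate(seq.residues):
        col = _BASE_COLUMN.get(base)
        if col is not None:
            grid[i, col] = 1.0
    return EncodedInput(grid, "onehot", L, seq_id=seq.id)


def percentile_thresholds(
    bppms: Iterable[BasePairProbabilities],
    percentiles: Sequence[float],
    floor: float = DEFAULT_T,
) -> list[float]:
    """Data-driven threshold values for the T sweep.

    Pools every pairing probability strictly greater than ``floor`` across
    all inputs, sorts ascending, and reads off the requested percentiles
    with the nearest-rank convention (percentile 0 is the pooled minimum).
    """
    pool = np.sort(
        [p for bpp in bppms for p in bpp.pairs.values() if p > floor]
    )
    if pool.size == 0:
        raise ValueError(f"no pairing probabilities above floor={floor}")
    out = []
    for q in percentiles:
        if not (0 <= q <= 100):
            raise ValueError(f"percentile {q} outside [0, 100]")
        # nearest-rank: smallest value with cumulative fraction >= q/100
        rank = max(1, int(np.ceil(q / 100 * pool.size)))
        out.append(float(pool[rank - 1]))
    return out


def save_grid(enc: EncodedInput, path: str | Path) -> None:
    """Archive an encoded grid with its metadata (.npz)."""
    np.savez_compressed(
        path,
        grid=enc.grid,
        kind=enc.kind,
        L=enc.L,
        T=-1.0 if enc.T is None else enc.T,
        ordered=-1 if enc.ordered is None else int(enc.ordered),
        seq_id=enc.seq_id or "",
    )


def load_grid(path: str | Path) -> EncodedInput:
    with np.load(path) as z:
        T = float(z["T"])
        ordered = int(z["ordered"])
        return EncodedInput(
            z["grid"],
            str(z["kind"]),
            int(z["L"]),
            T=None if T < 0 else T,
            ordered=None if ordered < 0 else bool(ordered),
            seq_id=str(z["seq_id"]) or None,
        )


def save_grid_png(enc: EncodedInput, path: str | Path) -> None:
    """Render a grid as a grayscale (2D) or two-channel (mixed) PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.image as mimg

    g = enc.grid
    if g.ndim == 3:  # mixed: probability -> green, pair -> blue
        rgb = np.zeros((*g.shape[:2], 3))
        rgb[..., 1] = g[..., 0]
        rgb[..., 2] = g[..., 1]
        mimg.imsave(str(path), np.clip(rgb, 0, 1))
    elif enc.kind == "onehot":
        mimg.imsave(str(path), 1.0 - g.T, cmap="gray", vmin=0, vmax=1)
    else:
        mimg.imsave(str(path), 1.0 - g, cmap="gray", vmin=0, vmax=1)
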