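"""Base-pairing probabilities for RNA sequences.

The structure encodings downstream consume only equilibrium base-pairing
probabilities ``p(i,j)``, so this module computes them under a simplified
pair-additive energy model: every nested secondary structure (canonical
Watson-Crick plus G-U wobble pairs, hairpin loops of at least ``min_loop``
unpaired bases) is weighted by the product of its pairs' Boltzmann
factors, and ``p(i,j)`` is the weighted fraction of structures containing
the pair (i, j). The partition function and pair probabilities are
computed exactly by inside/outside dynamic programming (McCaskill-style);
a brute-force enumerator over all nested structures serves as an
independent oracle for short sequences. Probabilities computed by an
external folding engine (e.g. RNAfold dot plots converted to a triplet
text dialect) can be imported instead via :func:`read_bpp_file`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import RnaSequence

#: Pairs that may stack in an RNA helix: Watson-Crick plus the G-U wobble.
CANONICAL_PAIRS = {"AU", "UA", "CG", "GC", "GU", "UG"}

_ORACLE_MAX_N = 22


@dataclass(frozen=True)
class FoldParams:
    """Parameters of the pair-additive folding model.

    ``pair_scores`` maps an unordered pair kind to a free energy (negative
    = favorable, arbitrary units); the Boltzmann weight of a pair is
    ``exp(-energy / temperature_scale)``. Defaults make CG the strongest
    pair, AU intermediate, and the G-U wobble weakest.
    """

    pair_scores: dict = field(
        default_factory=lambda: {"AU": -2.0, "CG": -3.0, "GU": -1.0}
    )
    min_loop: int = 3
    temperature_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.min_loop < 0:
            raise ValueError("min_loop must be >= 0")
        if self.temperature_scale <= 0:
            raise ValueError("temperature_scale must be positive")
        allowed = {"AU", "CG", "GU"}
        extra = set(self.pair_scores) - allowed
        if extra:
            raise ValueError(f"non-canonical pair kinds in pair_scores: {sorted(extra)}")

    def weight(self, a: str, b: str) -> float:
        """Boltzmann factor of pairing bases a-b; 0 if not pairable."""
        key = a + b
        if key not in CANONICAL_PAIRS:
            return 0.0
        kind = key if key in self.pair_scores else key[::-1]
        return math.exp(-self.pair_scores[kind] / self.temperature_scale)


@dataclass
class BasePairProbabilities:
    """Sparse symmetric base-pairing probabilities for one sequence.

    ``pairs`` maps (i, j) with 0-based i < j to a probability.
    """

    n: int
    pairs: dict[tuple[int, int], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (i, j), p in self.pairs.items():
            if not (0 <= i < j < self.n):
                raise ValueError(f"pair ({i},{j}) out of range for n={self.n}")
            if not (-1e-12 <= p <= 1.0 + 1e-9):
                raise ValueError(f"probability {p} for pair ({i},{j}) outside [0,1]")

    def to_dense(self) -> np.ndarray:
        """Dense symmetric n x n probability matrix."""
        m = np.zeros((self.n, self.n))
        for (i, j), p in self.pairs.items():
            m[i, j] = m[j, i] = p
        return m

    def row_sums(self) -> np.ndarray:
        """Total pairing probability per base (must be <= 1 for a valid ensemble)."""
        return self.to_dense().sum(axis=1)


def _pair_weight_matrix(residues: str, params: FoldParams, scale: float) -> np.ndarray:
    n = len(residues)
    ws = np.zeros((n, n))
    s2 = scale * scale
    for i in range(n):
        for j in range(i + params.min_loop + 1, n):
            w = params.weight(residues[i], residues[j])
            if w:
                ws[i, j] = w / s2
    return ws


def _inside(n: int, ws: np.ndarray, scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Scaled inside recursion.

    ``ZP[i, j+1]`` holds Z(i..j)/scale^(j-i+1) for j >= i-1 (the empty
    segment Z(i..i-1) sits on the diagonal and equals 1); entries below
    the diagonal are 0 so matrix products naturally skip invalid spans.
    ``Zb[i, j]`` is the scaled pair-closed partition function.
    """
    ZP = np.zeros((n + 1, n + 1))
    np.fill_diagonal(ZP, 1.0)
    Zb = np.zeros((n, n))
    for j in range(n):
        Zb[: j + 1, j] = ws[: j + 1, j] * ZP[1 : j + 2, j]
        col = ZP[: j + 1, : j + 1] @ Zb[: j + 1, j]
        ZP[: j + 1, j + 1] = ZP[: j + 1, j] / scale + col
    return ZP, Zb


def _mccaskill_scaled(residues: str, params: FoldParams, scale: float) -> dict | None:
    """One inside/outside pass at a fixed scale; None on over/underflow."""
    n = len(residues)
    ws = _pair_weight_matrix(residues, params, scale)
    ZP, Zb = _inside(n, ws, scale)
    total = ZP[0, n]
    if not np.isfinite(total) or total <= 0 or not np.isfinite(ZP).all():
        return None

    # Outside pass, descending span: every pair enclosing (i,j) strictly
    # has a larger span, so M[k,l] = ws[k,l] * O(k,l) is already filled
    # for all relevant (k,l) when (i,j) is reached.
    M = np.zeros((n, n))
    pairs: dict[tuple[int, int], float] = {}
    ok = True
    for d in range(n - 1, params.min_loop, -1):
        for i in range(0, n - d):
            j = i + d
            if Zb[i, j] == 0.0:
                continue
            outer = ZP[0, i] * ZP[j + 1, n]
            if i > 0 and j < n - 1:
                u = ZP[1 : i + 1, i]  # Z(k+1, i-1) for k < i
                v = ZP[j + 1, j + 1 : n]  # Z(j+1, l-1) for l > j
                outer += u @ M[:i, j + 1 :] @ v
            if not np.isfinite(outer):
                ok = False
                break
            M[i, j] = ws[i, j] * outer
            p = Zb[i, j] * outer / total
            if p > 1e-12:
                pairs[(i, j)] = min(p, 1.0)
        if not ok:
            break
    if not ok:
        return None
    return {"n": n, "pairs": pairs}


def mccaskill_bppm(seq: RnaSequence, params: FoldParams | None = None) -> BasePairProbabilities:
    """Exact pair probabilities under the pair-additive Boltzmann ensemble.

    Adaptive per-base rescaling keeps the partition function in double
    range for sequences up to the 200 nt cap. N residues never pair.
    """
    params = params or FoldParams()
    scale = 1.0
    for _ in range(60):
        result = _mccaskill_scaled(seq.residues, params, scale)
        if result is not None:
            return BasePairProbabilities(result["n"], result["pairs"])
        scale *= 2.0
    raise ArithmeticError(f"partition function for {seq.id!r} did not stabilize")


def _enumerate_structures(residues: str, params: FoldParams, i: int, j: int):
    """Yield (weight, pairs) over all nested structures on residues[i:j]."""
    if j - i <= 0:
        yield 1.0, []
        return
    # base i unpaired
    for w, ps in _enumerate_structures(residues, params, i + 1, j):
        yield w, ps
    # base i paired with k
    for k in range(i + params.min_loop + 1, j):
        wk = params.weight(residues[i], residues[k])
        if wk == 0.0:
            continue
        for w1, ps1 in _enumerate_structures(residues, params, i + 1, k):
            for w2, ps2 in _enumerate_structures(residues, params, k + 1, j):
                yield wk * w1 * w2, [(i, k)] + ps1 + ps2


def enumerate_bppm_oracle(
    seq: RnaSequence, params: FoldParams | None = None
) -> BasePairProbabilities:
    """Pair probabilities by explicit enumeration of every nested structure.

    Exponential-time reference used to validate :func:`mccaskill_bppm`;
    refuses sequences longer than 22 nt.
    """
    params = params or FoldParams()
    n = len(seq)
    if n > _ORACLE_MAX_N:
        raise ValueError(f"enumeration oracle limited to n <= {_ORACLE_MAX_N}, got {n}")
    total = 0.0
    acc: dict[tuple[int, int], float] = {}
    for w, ps in _enumerate_structures(seq.residues, params, 0, n):
        total += w
        for pair in ps:
            acc[pair] = acc.get(pair, 0.0) + w
    pairs = {pair: w / total for pair, w in acc.items() if w / total > 1e-12}
    return BasePairProbabilities(n, pairs)


def cached_bppm(
    seq: RnaSequence, params: FoldParams | None = None, cache_dir: str | Path | None = None
) -> BasePairProbabilities:
    """mccaskill_bppm with an on-disk cache keyed by sequence and model.

    Cache files use the triplet dialect, named by a digest of the residue
    string and folding parameters, so re-encoding a dataset never refolds
    unchanged sequences.
    """
    if cache_dir is None:
        return mccaskill_bppm(seq, params)
    import hashlib

    params = params or FoldParams()
    key_src = f"{seq.residues}|{sorted(params.pair_scores.items())}|{params.min_loop}|{params.temperature_scale}"
    key = hashlib.sha1(key_src.encode()).hexdigest()
    cache_dir = Path(cache_dir)
    cache_dir.mkdir(parents=True, exist_ok=True)
    path = cache_dir / f"{key}.bpp.tsv"
    if path.exists():
        return read_bpp_file(path, len(seq))
    bpp = mccaskill_bppm(seq, params)
    write_bpp_file(bpp, path)
    return bpp


def read_bpp_file(path: str | Path, n: int) -> BasePairProbabilities:
    """Load pairing probabilities from the triplet text dialect.

    Lines are ``<i>\\t<j>\\t<p>`` with 1-based indices (dot-plot
    convention); ``#`` starts a comment. Entries are reordered to i < j
    and validated; duplicate pairs are an error.
    """
    pairs: dict[tuple[int, int], float] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected '<i> <j> <p>'")
            i1, j1 = int(parts[0]), int(parts[1])
            p = float(parts[2])
            if not (1 <= i1 <= n and 1 <= j1 <= n):
                raise ValueError(f"{path}:{lineno}: index out of [1, {n}]")
            if i1 == j1:
                raise ValueError(f"{path}:{lineno}: self-pair ({i1},{j1})")
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{path}:{lineno}: probability {p} outside [0,1]")
            i, j = min(i1, j1) - 1, max(i1, j1) - 1
            if (i, j) in pairs:
                raise ValueError(f"{path}:{lineno}: duplicate pair ({i1},{j1})")
            pairs[(i, j)] = p
    return BasePairProbabilities(n, pairs)


def write_bpp_file(bpp: BasePairProbabilities, path: str | Path) -> None:
    """Write probabilities in the triplet dialect (1-based, i < j)."""
    with open(path, "w") as fh:
        fh.write("# <i>\t<j>\t<p>  (1-based)\n")
        for (i, j) in sorted(bpp.pairs):
            fh.write(f"{i + 1}\t{j + 1}\t{bpp.pairs[(i, j)]:.10g}\n")
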