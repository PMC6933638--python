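"""Synthetic hairpin-family benchmarks and out-of-distribution decoys.

Each family is defined by a consensus pre-miRNA-like hairpin: a random
5' arm carrying a planted "mature" motif, a loop, and a 3' arm that is
the reverse complement of the 5' arm with a configurable fraction of
positions relaxed to G-U wobbles. Members are drawn by independent
per-base substitution at rate mu (the motif region mutates at a reduced
rate, mimicking mature-arm conservation). Decoy generators provide
composition-preserving shuffles, i.i.d. random sequences, and
cloverleaf-shaped (tRNA-like) sequences; ``add_flanks`` reproduces the
extra-bases robustness protocol (5/10/15/20 random nucleotides split
around a test sequence). Everything is a pure function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io import ALPHABET, DEFAULT_MAX_LEN, FamilyDataset, RnaSequence, build_dataset

_COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}

#: Default per-family study conditions (realistic ~66 nt pre-miRNA hairpin).
DEFAULT_ARM_LEN = 28
DEFAULT_LOOP_LEN = 10
DEFAULT_MOTIF_LEN = 16
DEFAULT_WOBBLE_FRACTION = 0.1
DEFAULT_MU = 0.05
DEFAULT_MOTIF_MU_SCALE = 0.25


def _child_rng(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *tags]).generate_state(1)[0])


def _random_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(ALPHABET), size=n))


def reverse_complement(s: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(s))


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance needs equal lengths")
    return sum(x != y for x, y in zip(a, b))


@dataclass(frozen=True)
class FamilyTemplate:
    """Consensus hairpin of one synthetic family."""

    name: str
    consensus: str
    planted_motif: str
    motif_offset: int
    arm_len: int
    loop_len: int
    mutation_rate: float = DEFAULT_MU
    motif_mu_scale: float = DEFAULT_MOTIF_MU_SCALE

    def __post_init__(self) -> None:
        if not (0.0 <= self.mutation_rate < 1.0):
            raise ValueError("mutation_rate must be in [0, 1)")
        end = self.motif_offset + len(self.planted_motif)
        if self.consensus[self.motif_offset : end] != self.planted_motif:
            raise ValueError("planted motif does not occur at its offset")
        # stem closure: every arm position must pair canonically (incl. G-U)
        n = len(self.consensus)
        for k in range(self.arm_len):
            a, b = self.consensus[k], self.consensus[n - 1 - k]
            if a + b not in {"AU", "UA", "CG", "GC", "GU", "UG"}:
                raise ValueError(f"stem position {k} does not pair ({a}-{b})")

    @property
    def length(self) -> int:
        return len(self.consensus)

    def stem_pairs(self) -> list[tuple[int, int]]:
        """The designed (i, j) pairs of the stem."""
        n = len(self.consensus)
        return [(k, n - 1 - k) for k in range(self.arm_len)]


def make_template(
    name: str,
    seed: int,
    arm_len: int = DEFAULT_ARM_LEN,
    loop_len: int = DEFAULT_LOOP_LEN,
    motif: str | None = None,
    motif_len: int = DEFAULT_MOTIF_LEN,
    wobble_fraction: float = DEFAULT_WOBBLE_FRACTION,
    mutation_rate: float = DEFAULT_MU,
    motif_mu_scale: float = DEFAULT_MOTIF_MU_SCALE,
) -> FamilyTemplate:
    """Draw a random hairpin consensus with a planted motif in the 5' arm."""
    rng = _child_rng(seed, 11)
    if motif is None:
        motif = _random_bases(rng, motif_len)
    if len(motif) > arm_len:
        raise ValueError("motif longer than the 5' arm")
    offset = int(rng.integers(0, arm_len - len(motif) + 1))
    arm5 = list(_random_bases(rng, arm_len))
    arm5[offset : offset + len(motif)] = list(motif)
    arm5 = "".join(arm5)
    loop = _random_bases(rng, loop_len)
    arm3 = list(reverse_complement(arm5))
    # relax a fraction of stem positions to G-U wobbles where the 5' base allows
    for k in range(arm_len):
        if arm5[k] in "GU" and rng.random() < wobble_fraction:
            arm3[arm_len - 1 - k] = "U" if arm5[k] == "G" else "G"
    consensus = arm5 + loop + "".join(arm3)
    return FamilyTemplate(
        name, consensus, motif, offset, arm_len, loop_len, mutation_rate, motif_mu_scale
    )


def make_family(template: FamilyTemplate, n: int, seed: int) -> list[RnaSequence]:
    """Draw n members by independent per-base substitution at rate mu.

    Bases inside the planted motif mutate at ``mu * motif_mu_scale``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _child_rng(seed, 13)
    mu = np.full(template.length, template.mutation_rate)
    mu[template.motif_offset : template.motif_offset + len(template.planted_motif)] *= (
        template.motif_mu_scale
    )
    bases = np.array(list(ALPHABET))
    cons = np.array(list(template.consensus))
    out = []
    for i in range(n):
        seq = cons.copy()
        hit = rng.random(template.length) < mu
        for pos in np.flatnonzero(hit):
            alternatives = [b for b in ALPHABET if b != seq[pos]]
            seq[pos] = alternatives[rng.integers(0, 3)]
        out.append(RnaSequence(f"{template.name}_{i}", "".join(seq), template.name))
    return out


def make_ood(
    kind: str,
    n: int,
    seed: int,
    reference: Sequence[RnaSequence] | None = None,
) -> list[RnaSequence]:
    """Out-of-distribution decoys: shuffle, random, or cloverleaf.

    ``shuffle`` permutes the residues of (sampled) reference sequences,
    preserving composition; ``random`` draws i.i.d. uniform bases with
    lengths matched to the reference (or 55-90 nt without one);
    ``cloverleaf`` builds a tRNA-like shape — an acceptor stem enclosing
    three stem-loop arms — structurally distinct from a hairpin.
    """
    rng = _child_rng(seed, 17)
    if kind == "shuffle":
        if not reference:
            raise ValueError("shuffle decoys require a reference dataset")
        picks = rng.integers(0, len(reference), size=n)
        out = []
        for i, ridx in enumerate(picks):
            residues = list(reference[ridx].residues)
            rng.shuffle(residues)
            out.append(RnaSequence(f"shuffle_{i}", "".join(residues), None))
        return out
    if kind == "random":
        if reference:
            lengths = [len(reference[ridx]) for ridx in rng.integers(0, len(reference), size=n)]
        else:
            lengths = rng.integers(55, 91, size=n).tolist()
        return [
            RnaSequence(f"random_{i}", _random_bases(rng, ln), None)
            for i, ln in enumerate(lengths)
        ]
    if kind == "cloverleaf":
        out = []
        for i in range(n):
            acc = _random_bases(rng, 7)
            arms = []
            for _ in range(3):
                stem = _random_bases(rng, 5)
                loop = _random_bases(rng, 7)
                arms.append(stem + loop + reverse_complement(stem))
            spacer = lambda: _random_bases(rng, int(rng.integers(0, 3)))
            residues = acc + spacer() + arms[0] + spacer() + arms[1] + spacer() + arms[2] + reverse_complement(acc)
            if len(residues) > DEFAULT_MAX_LEN:
                raise ValueError("cloverleaf decoy exceeds the length cap")
            out.append(RnaSequence(f"cloverleaf_{i}", residues, None))
        return out
    raise ValueError(f"unknown decoy kind {kind!r}")


def add_flanks(seq: RnaSequence, k: int, seed: int) -> RnaSequence:
    """Add k random bases around a sequence, split 5'/3' by a uniform draw."""
    if k < 0:
        raise ValueError("k must be >= 0")
    if len(seq) + k > DEFAULT_MAX_LEN:
        raise ValueError(f"flanked length {len(seq) + k} exceeds {DEFAULT_MAX_LEN} nt")
    if k == 0:
        return seq
    rng = _child_rng(seed, 19)
    left = int(rng.integers(0, k + 1))
    residues = _random_bases(rng, left) + seq.residues + _random_bases(rng, k - left)
    return RnaSequence(seq.id, residues, seq.family)


def _distinct_motifs(
    rng: np.random.Generator, count: int, motif_len: int, min_dist: int
) -> list[str]:
    motifs: list[str] = []
    attempts = 0
    while len(motifs) < count:
        attempts += 1
        if attempts > 5000 * count:
            raise ValueError("motif space exhausted; relax min distance or length")
        cand = _random_bases(rng, motif_len)
        if all(hamming(cand, m) >= min_dist for m in motifs):
            motifs.append(cand)
    return motifs


@dataclass
class SyntheticBenchmark:
    """A labelled hairpin benchmark plus matched decoy and unseen-family sets."""

    dataset: FamilyDataset
    ood: dict[str, list[RnaSequence]]
    templates: list[FamilyTemplate]
    unseen_templates: list[FamilyTemplate] = field(default_factory=list)


def make_benchmark(
    n_families: int = 10,
    per_family: int = 60,
    mu: float = DEFAULT_MU,
    seed: int = 0,
    arm_len: int = DEFAULT_ARM_LEN,
    loop_len: int = DEFAULT_LOOP_LEN,
    motif_len: int = DEFAULT_MOTIF_LEN,
    n_unseen: int = 3,
    ood_n: int | None = None,
) -> SyntheticBenchmark:
    """Build a labelled benchmark with mutually distinct planted motifs.

    Motifs are pairwise at Hamming distance >= motif_len // 2; stems are
    independent across families. Decoy sets (shuffle / random /
    cloverleaf / unseen hairpin families) are sized ``ood_n``
    (default: ``per_family``).
    """
    if n_families < 2:
        raise ValueError("need at least 2 families")
    ood_n = ood_n or per_family
    rng = _child_rng(seed, 23)
    motifs = _distinct_motifs(rng, n_families + n_unseen, motif_len, motif_len // 2)

    templates, seqs = [], []
    for f in range(n_families):
        tpl = make_template(
            f"fam{f:02d}", seed=int(rng.integers(0, 2**31 - 1)),
            arm_len=arm_len, loop_len=loop_len, motif=motifs[f], mutation_rate=mu,
        )
        templates.append(tpl)
        seqs.extend(make_family(tpl, per_family, seed=int(rng.integers(0, 2**31 - 1))))
    dataset = build_dataset(seqs)

    unseen_templates, unseen_seqs = [], []
    for u in range(n_unseen):
        tpl = make_template(
            f"unseen{u:02d}", seed=int(rng.integers(0, 2**31 - 1)),
            arm_len=arm_len, loop_len=loop_len, motif=motifs[n_families + u],
            mutation_rate=mu,
        )
        unseen_templates.append(tpl)
        unseen_seqs.extend(make_family(tpl, max(1, ood_n // max(1, n_unseen)),
                                       seed=int(rng.integers(0, 2**31 - 1))))

    ref = dataset.sequences
    ood = {
        "shuffle": make_ood("shuffle", ood_n, int(rng.integers(0, 2**31 - 1)), reference=ref),
        "random": make_ood("random", ood_n, int(rng.integers(0, 2**31 - 1)), reference=ref),
        "cloverleaf": make_ood("cloverleaf", ood_n, int(rng.integers(0, 2**31 - 1))),
        "unseen": unseen_seqs,
    }
    return SyntheticBenchmark(dataset, ood, templates, unseen_templates)
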