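"""Motif extraction from the convolution filters of a trained one-hot CNN.

Convolution filters that respond strongly and consistently across a
family's sequences behave like position-specific scanners; harvesting
the subsequence under each filter's maximal response and tabulating a
position-frequency matrix recovers the conserved region (typically part
of the mature miRNA). A filter counts as "frequently activated" for a
sequence when its pooled (global-max) activation ranks in the top
fraction (default 5%) of all filters for that sequence and is positive.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoding import one_hot
from .io import ALPHABET, RnaSequence
from .models import OneHotCnn
from .training import TrainedClassifier

DEFAULT_TOP_FRACTION = 0.05


@dataclass
class MotifProfile:
    """A position-frequency matrix harvested from one convolution filter."""

    filter_id: tuple[int, int]  # (width, filter index within that width)
    width: int
    pfm: np.ndarray  # width x 4, rows sum to 1 over A,C,G,U
    support: int
    activation_freq: float

    def __post_init__(self) -> None:
        if self.support < 1:
            raise ValueError("a motif profile needs at least one contributing subsequence")
        if self.pfm.shape != (self.width, 4):
            raise ValueError("pfm must be width x 4")
        if not np.allclose(self.pfm.sum(axis=1), 1.0, atol=1e-4):
            raise ValueError("pfm rows must sum to 1")

    def consensus(self) -> str:
        return "".join(ALPHABET[k] for k in self.pfm.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (0 = uniform, 2 = point mass)."""
        with np.errstate(divide="ignore", invalid="ignore"):
            ent = -np.nansum(
                np.where(self.pfm > 0, self.pfm * np.log2(self.pfm), 0.0), axis=1
            )
        return 2.0 - ent


def _require_onehot(classifier: TrainedClassifier) -> OneHotCnn:
    if not isinstance(classifier.model, OneHotCnn):
        raise TypeError(
            "motif extraction is defined for the one-hot CNN only; "
            "got a structure-matrix classifier"
        )
    return classifier.model


def filter_activation_table(
    classifier: TrainedClassifier, seqs: list[RnaSequence]
) -> dict[int, dict[str, np.ndarray]]:
    """Per (sequence, filter): position and value of the maximal response.

    Returns, per filter width, ``positions`` and ``values`` arrays of
    shape (n_seqs, n_filters). Only windows fully inside the unpadded
    sequence are scanned; ties go to the leftmost position. Post-ReLU
    activations are used (the values global max pooling would see).
    """
    model = _require_onehot(classifier)
    L = classifier.config.L
    X = np.stack([one_hot(s, L).grid for s in seqs])
    lengths = np.array([len(s) for s in seqs])
    acts = model.conv_activations(X)
    table: dict[int, dict[str, np.ndarray]] = {}
    for w, a in acts.items():  # a: (B, L - w + 1, F)
        n_windows = lengths - w + 1  # valid windows per sequence
        masked = a.copy()
        for b in range(len(seqs)):
            if n_windows[b] < a.shape[1]:
                masked[b, max(n_windows[b], 0) :, :] = -np.inf
        positions = masked.argmax(axis=1)
        values = np.take_along_axis(masked, positions[:, None, :], axis=1)[:, 0, :]
        table[w] = {"positions": positions, "values": values}
    return table


def extract_motifs(
    classifier: TrainedClassifier,
    seqs: list[RnaSequence],
    top_k: int = 5,
    top_fraction: float = DEFAULT_TOP_FRACTION,
) -> list[MotifProfile]:
    """PFMs of the ``top_k`` most frequently activated filters on a family.

    Ranks every filter (across all widths) by the fraction of sequences
    for which its pooled activation is positive and within the top
    ``top_fraction`` of filters for that sequence, then tabulates the
    w-mers under each chosen filter's maximal responses.
    """
    if not seqs:
        raise ValueError("empty family")
    model = _require_onehot(classifier)
    table = filter_activation_table(classifier, seqs)
    widths = sorted(table)
    n_seqs = len(seqs)

    # Stack pooled values (n_seqs, total_filters) with (width, idx) key per column.
    keys: list[tuple[int, int]] = []
    cols = []
    for w in widths:
        vals = table[w]["values"]
        cols.append(vals)
        keys += [(w, f) for f in range(vals.shape[1])]
    pooled = np.concatenate(cols, axis=1)
    total = pooled.shape[1]
    k_top = max(1, int(np.ceil(top_fraction * total)))

    counts = np.zeros(total)
    order = np.argsort(-pooled, axis=1, kind="stable")
    for b in range(n_seqs):
        top_cols = order[b, :k_top]
        top_cols = top_cols[pooled[b, top_cols] > 0]
        counts[top_cols] += 1
    freqs = counts / n_seqs

    ranked = np.argsort(-freqs, kind="stable")[: min(top_k, total)]
    base_col = {b: k for k, b in enumerate(ALPHABET)}
    profiles: list[MotifProfile] = []
    for col in ranked:
        w, f = keys[col]
        positions = table[w]["positions"][:, f]
        values = table[w]["values"][:, f]
        counts_mat = np.zeros((w, 4))
        support = 0
        for b, s in enumerate(seqs):
            if values[b] <= 0 or len(s) < w:
                continue
            kmer = s.residues[positions[b] : positions[b] + w]
            support += 1
            for pos, base in enumerate(kmer):
                if base in base_col:
                    counts_mat[pos, base_col[base]] += 1
        if support == 0:
            continue
        row_sums = counts_mat.sum(axis=1, keepdims=True)
        row_sums[row_sums == 0] = 1.0  # all-N column: leave the row zero-safe
        pfm = counts_mat / row_sums
        pfm = pfm / pfm.sum(axis=1, keepdims=True)
        profiles.append(MotifProfile((w, f), w, pfm, support, float(freqs[col])))
    return profiles


def write_meme(motifs: list[MotifProfile], path: str | Path) -> None:
    """Write profiles in MEME minimal motif format (alphabet ACGU)."""
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGU\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 U 0.25\n\n")
        for m in motifs:
            name = f"filter_w{m.filter_id[0]}_{m.filter_id[1]}"
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} nsites= {m.support}\n"
            )
            for row in m.pfm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> list[MotifProfile]:
    """Parse a MEME minimal file written by :func:`write_meme`."""
    profiles = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("MOTIF "):
            name = line.split()[1]
            i += 1
            header = lines[i].split()
            w = int(header[header.index("w=") + 1])
            nsites = int(header[header.index("nsites=") + 1])
            rows = []
            for k in range(w):
                i += 1
                rows.append([float(v) for v in lines[i].split()])
            pfm = np.asarray(rows)
            if name.startswith("filter_w"):
                wpart, fpart = name[len("filter_w") :].split("_")
                fid = (int(wpart), int(fpart))
            else:
                fid = (w, 0)
            profiles.append(MotifProfile(fid, w, pfm, nsites, 0.0))
        i += 1
    return profiles
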