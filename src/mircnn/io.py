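"""Sequence and label I/O.

Reads RNA sequences from FASTA (labels from a sidecar TSV or an
``id|family`` header convention), normalizes the alphabet to {A,C,G,U,N},
removes exact-duplicate sequences, and assembles labelled datasets with a
maximum-length policy (sequences longer than the cap are dropped; shorter
ones are zero-padded downstream, at encoding time).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

#: Canonical RNA alphabet; everything else becomes N.
ALPHABET = "ACGU"

DEFAULT_MAX_LEN = 200


class FastaParseError(ValueError):
    """A FASTA record could not be parsed."""


def normalize_residues(raw: str) -> str:
    """Uppercase, T->U, and map any non-ACGU character to N."""
    out = []
    for ch in raw.upper():
        if ch == "T":
            ch = "U"
        out.append(ch if ch in ALPHABET else "N")
    return "".join(out)


@dataclass(frozen=True)
class RnaSequence:
    """A single RNA sequence with an optional family label.

    ``residues`` is always uppercase over {A,C,G,U,N}; construction
    rejects anything else (use :func:`normalize_residues` on raw input).
    """

    id: str
    residues: str
    family: str | None = None

    def __post_init__(self) -> None:
        if len(self.residues) < 1:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues) - set(ALPHABET + "N")
        if bad:
            raise ValueError(
                f"sequence {self.id!r} has unnormalized characters {sorted(bad)}; "
                "pass residues through normalize_residues() first"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def with_family(self, family: str) -> "RnaSequence":
        return RnaSequence(self.id, self.residues, family)


@dataclass
class FamilyDataset:
    """A labelled set of sequences plus a contiguous family -> class-id map."""

    sequences: list[RnaSequence]
    label_index: dict[str, int]
    max_len: int = DEFAULT_MAX_LEN

    def __post_init__(self) -> None:
        ids = sorted(self.label_index.values())
        if ids != list(range(len(ids))):
            raise ValueError("class ids must be contiguous from 0")
        for seq in self.sequences:
            if seq.family not in self.label_index:
                raise ValueError(f"sequence {seq.id!r} has unknown family {seq.family!r}")
            if len(seq) > self.max_len:
                raise ValueError(f"sequence {seq.id!r} longer than max_len={self.max_len}")

    @property
    def n_classes(self) -> int:
        return len(self.label_index)

    @property
    def families(self) -> list[str]:
        """Family names ordered by class id."""
        return [f for f, _ in sorted(self.label_index.items(), key=lambda kv: kv[1])]

    def labels(self) -> list[int]:
        return [self.label_index[s.family] for s in self.sequences]

    def subset(self, indices: Sequence[int]) -> "FamilyDataset":
        """Same label_index, a subset of the sequences (for CV folds)."""
        return FamilyDataset(
            [self.sequences[i] for i in indices], dict(self.label_index), self.max_len
        )

    def __len__(self) -> int:
        return len(self.sequences)


def _read_labels_tsv(path: Path) -> dict[str, str]:
    labels: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            labels[parts[0]] = parts[1]
    return labels


def read_fasta(path: str | Path, labels: str | Path | None = None) -> list[RnaSequence]:
    """Read a FASTA file, normalizing residues to uppercase {A,C,G,U,N}.

    Family labels are attached from the two-column TSV ``labels``
    (``<seq_id>\\t<family>``) when given; otherwise a header of the form
    ``id|family`` is split on the last ``|``. Label-file ids that do not
    occur in the FASTA are warned about and skipped.
    """
    path = Path(path)
    label_map = _read_labels_tsv(Path(labels)) if labels is not None else {}

    seqs: list[RnaSequence] = []
    seen_ids: set[str] = set()
    try:
        records = list(SeqIO.parse(str(path), "fasta"))
    except Exception as exc:  # Biopython raises bare ValueError on bad records
        raise FastaParseError(f"cannot parse FASTA {path}: {exc}") from exc
    for rec in records:
        if not rec.id:
            raise FastaParseError(f"{path}: record with empty id")
        residues = normalize_residues(str(rec.seq))
        if not residues:
            raise FastaParseError(f"{path}: record {rec.id!r} has an empty sequence")
        family = label_map.get(rec.id)
        if family is None and "|" in rec.id:
            head, _, tail = rec.id.rpartition("|")
            seqs.append(RnaSequence(head, residues, tail))
        else:
            seqs.append(RnaSequence(rec.id, residues, family))
        seen_ids.add(rec.id)
    for sid in label_map:
        if sid not in seen_ids:
            logger.warning("label for %r has no matching FASTA record; skipped", sid)
    return seqs


def write_fasta(seqs: Iterable[RnaSequence], path: str | Path, with_family: bool = False) -> None:
    """Write sequences as FASTA; ``with_family`` uses the ``id|family`` header."""
    records = []
    for s in seqs:
        rid = f"{s.id}|{s.family}" if (with_family and s.family) else s.id
        records.append(SeqRecord(Seq(s.residues), id=rid, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_labels(seqs: Iterable[RnaSequence], path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            if s.family is not None:
                fh.write(f"{s.id}\t{s.family}\n")


def deduplicate(seqs: Sequence[RnaSequence]) -> tuple[list[RnaSequence], int]:
    """Drop sequences whose residue string was already seen.

    Deduplication is global (across families); the first occurrence wins
    and input order is otherwise preserved. Returns (kept, n_removed).
    """
    seen: set[str] = set()
    kept: list[RnaSequence] = []
    removed = 0
    for s in seqs:
        if s.residues in seen:
            logger.info("duplicate sequence %r removed", s.id)
            removed += 1
            continue
        seen.add(s.residues)
        kept.append(s)
    return kept, removed


def build_dataset(
    seqs: Sequence[RnaSequence], max_len: int = DEFAULT_MAX_LEN
) -> FamilyDataset:
    """Assemble a FamilyDataset, dropping sequences longer than ``max_len``.

    Class ids are assigned by sorted family name. Raises if any sequence
    is unlabelled or no sequence survives the length cut.
    """
    unlabelled = [s.id for s in seqs if s.family is None]
    if unlabelled:
        raise ValueError(f"unlabelled sequences: {unlabelled[:5]}")
    kept = [s for s in seqs if len(s) <= max_len]
    n_dropped = len(seqs) - len(kept)
    if n_dropped:
        logger.info("dropped %d sequences longer than %d nt", n_dropped, max_len)
    if not kept:
        raise ValueError("no sequences survive the length cut")
    families = sorted({s.family for s in kept})
    label_index = {fam: i for i, fam in enumerate(families)}
    return FamilyDataset(list(kept), label_index, max_len)
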