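"""Protein records, dataset splits, cross-split deduplication and label filtering.

A dataset split carries train/validation/test protein lists plus the ordered
label vocabulary the classifiers are trained against.  Identical sequences
appearing in more than one split leak information, so they are removed in a
fixed order that always preserves the test set; the vocabulary is then
restricted to terms carried by enough training proteins to be learnable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ProteinRecord",
    "DatasetSplit",
    "read_fasta",
    "write_fasta",
    "read_annotations",
    "write_annotations",
    "deduplicate",
    "filter_labels",
]


@dataclass
class ProteinRecord:
    """A protein: identifier, amino-acid sequence, and its GO term set."""

    id: str
    sequence: str
    terms: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"protein {self.id!r} has an empty sequence")
        self.sequence = self.sequence.upper()
        self.terms = frozenset(self.terms)


@dataclass
class DatasetSplit:
    """Train/validation/test protein lists and the ordered label vocabulary."""

    train: list
    valid: list
    test: list
    label_vocabulary: list = field(default_factory=list)

    def all_records(self):
        return [*self.train, *self.valid, *self.test]


def read_fasta(path) -> list:
    """Read a FASTA file into :class:`ProteinRecord` objects (no terms).

    Wrapped sequence lines are concatenated.  Duplicate ids and empty
    records are rejected.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path) -> None:
    SeqIO.write(
        (SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records),
        str(path),
        "fasta",
    )


def read_annotations(path) -> dict:
    """Read a two-column (protein_id <tab> term_id) TSV into a map
    protein -> set of terms.  Lines starting with '#' are skipped."""
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            out.setdefault(parts[0], set()).add(parts[1])
    return out


def write_annotations(annotations: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for protein in sorted(annotations):
            for term in sorted(annotations[protein]):
                fh.write(f"{protein}\t{term}\n")


def attach_annotations(records: Iterable[ProteinRecord], annotations: Mapping) -> list:
    """Return copies of ``records`` with term sets taken from ``annotations``."""
    return [
        replace(r, terms=frozenset(annotations.get(r.id, ()))) for r in records
    ]


def deduplicate(split: DatasetSplit) -> tuple:
    """Remove cross-split duplicate sequences in three ordered steps.

    (1) drop train records whose sequence occurs in test;
    (2) drop valid records whose sequence occurs in test;
    (3) drop valid records whose sequence occurs in the (already reduced)
    training set.  The test set is never modified.  Duplicates within a
    single split are retained.

    Returns ``(split, removed)`` where ``removed`` counts drops per step.
    """
    test_seqs = {r.sequence for r in split.test}
    train = [r for r in split.train if r.sequence not in test_seqs]
    n1 = len(split.train) - len(train)
    valid = [r for r in split.valid if r.sequence not in test_seqs]
    n2 = len(split.valid) - len(valid)
    train_seqs = {r.sequence for r in train}
    valid2 = [r for r in valid if r.sequence not in train_seqs]
    n3 = len(valid) - len(valid2)
    out = DatasetSplit(
        train=train,
        valid=valid2,
        test=list(split.test),
        label_vocabulary=list(split.label_vocabulary),
    )
    return out, {"train_vs_test": n1, "valid_vs_test": n2, "valid_vs_train": n3}


def filter_labels(split: DatasetSplit, min_proteins: int = 50) -> DatasetSplit:
    """Keep only terms annotated in at least ``min_proteins`` training proteins.

    Counting uses the training split only (term sets are expected to be
    propagated).  Every record's term set is then intersected with the
    resulting vocabulary.  Raises ``ValueError`` if nothing survives.
    """
    counts: dict = {}
    for r in split.train:
        for t in r.terms:
            counts[t] = counts.get(t, 0) + 1
    vocab = sorted(t for t, c in counts.items() if c >= min_proteins)
    if not vocab:
        raise ValueError(
            f"no term is carried by >= {min_proteins} training proteins"
        )
    keep = frozenset(vocab)

    def _restrict(records):
        return [replace(r, terms=r.terms & keep) for r in records]

    return DatasetSplit(
        train=_restrict(split.train),
        valid=_restrict(split.valid),
        test=_restrict(split.test),
        label_vocabulary=vocab,
    )
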