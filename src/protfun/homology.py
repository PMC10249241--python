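"""Homology-based GO term transfer from local-alignment hit tables.

Running the aligner is out of scope; this module consumes BLAST tabular
(outfmt 6) output.  Three scoring routes are provided:

* bitscore-weighted transfer: for a query ``p`` with retained training hits
  ``E``, ``S(p, f) = sum_{s in E, f in T_s} bitscore(p, s) / sum_{s in E}
  bitscore(p, s)`` — a convex combination over hit subjects, so each score
  lies in (0, 1] and equals 1 exactly when every retained hit carries ``f``;
* the top-hit baseline: every term of the single best-bitscore subject at
  score 1.0;
* the naive baseline: each term scored by its training relative frequency,
  identically for every query.

Hits are filtered at ``evalue <= evalue_max`` (default 0.001); multiple HSPs
for the same (query, subject) pair are collapsed to their maximum bitscore
before weighting, so one homolog is never double-counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

__all__ = [
    "HitTable",
    "read_blast_tabular",
    "bitscore_transfer",
    "top_hit_transfer",
    "naive_baseline",
]

logger = logging.getLogger(__name__)

OUTFMT6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


@dataclass(frozen=True)
class HitTable:
    """Local-alignment hits: (query, subject, e-value, bitscore) rows.

    (query, subject) pairs may repeat — one row per HSP.
    """

    rows: tuple  # of (query_id, subject_id, evalue, bitscore)

    def __post_init__(self):
        for q, s, e, b in self.rows:
            if b <= 0:
                raise ValueError(f"bitscore must be > 0, got {b} for ({q!r}, {s!r})")
            if e < 0:
                raise ValueError(f"e-value must be >= 0, got {e} for ({q!r}, {s!r})")

    def __len__(self):
        return len(self.rows)

    def filtered(self, evalue_max: float, exclude_self: bool = False) -> "HitTable":
        rows = tuple(
            r for r in self.rows
            if r[2] <= evalue_max and not (exclude_self and r[0] == r[1])
        )
        return HitTable(rows)

    def best_bitscore_per_subject(self) -> dict:
        """query -> {subject: (max bitscore, min e-value among its HSPs)}."""
        out: dict = {}
        for q, s, e, b in self.rows:
            d = out.setdefault(q, {})
            if s not in d:
                d[s] = (b, e)
            else:
                b0, e0 = d[s]
                d[s] = (max(b0, b), min(e0, e))
        return out


def read_blast_tabular(path) -> HitTable:
    """Parse BLAST outfmt-6 output (12+ tab-separated columns; '#' comment
    lines skipped; columns beyond the 12th ignored)."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}:{lineno}: expected >= 12 tab-separated columns, got {len(parts)}"
                )
            try:
                evalue = float(parts[10])
                bitscore = float(parts[11])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric evalue/bitscore "
                    f"({parts[10]!r}, {parts[11]!r})"
                ) from None
            rows.append((parts[0], parts[1], evalue, bitscore))
    return HitTable(tuple(rows))


def write_blast_tabular(hits: HitTable, path) -> None:
    """Write a minimal outfmt-6 table (alignment detail columns zero-filled)."""
    with open(path, "w") as fh:
        for q, s, e, b in hits.rows:
            fh.write(f"{q}\t{s}\t0\t0\t0\t0\t0\t0\t0\t0\t{e:g}\t{b:g}\n")


def _retained(hits, train_annotations, evalue_max, exclude_self):
    kept = hits.filtered(evalue_max, exclude_self=exclude_self)
    per_query = kept.best_bitscore_per_subject()
    for q, subjects in per_query.items():
        known = {}
        for s, (b, e) in subjects.items():
            if s in train_annotations:
                known[s] = (b, e)
            else:
                logger.warning("subject %r (hit of %r) has no annotations; skipped", s, q)
        per_query[q] = known
    return {q: d for q, d in per_query.items() if d}


def bitscore_transfer(
    hits: HitTable,
    train_annotations: Mapping[str, Iterable[str]],
    evalue_max: float = 0.001,
    exclude_self: bool = False,
) -> dict:
    """Bitscore-weighted annotation transfer.

    ``train_annotations`` must be propagated term sets; because they are
    upward-closed the output is automatically ancestor-monotone.  Queries
    with no retained hit are absent from the result.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be > 0")
    preds: dict = {}
    for q, subjects in _retained(hits, train_annotations, evalue_max, exclude_self).items():
        total = sum(b for b, _ in subjects.values())
        scores: dict = {}
        for s, (b, _) in subjects.items():
            for f in train_annotations[s]:
                scores[f] = scores.get(f, 0.0) + b
        preds[q] = {f: min(v / total, 1.0) for f, v in scores.items()}
    return preds


def top_hit_transfer(
    hits: HitTable,
    train_annotations: Mapping[str, Iterable[str]],
    evalue_max: float = 0.001,
    exclude_self: bool = False,
) -> dict:
    """Every term of the best-bitscore subject at score 1.0.

    Ties on bitscore break by lowest e-value, then lexicographic subject id.
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be > 0")
    preds: dict = {}
    for q, subjects in _retained(hits, train_annotations, evalue_max, exclude_self).items():
        best = min(subjects.items(), key=lambda kv: (-kv[1][0], kv[1][1], kv[0]))[0]
        preds[q] = {f: 1.0 for f in train_annotations[best]}
    return preds


def naive_baseline(
    train_annotations: Mapping[str, Iterable[str]],
    query_ids: Iterable[str],
    vocabulary: Iterable[str],
) -> dict:
    """Every query scores each vocabulary term by its training relative
    frequency."""
    vocabulary = list(vocabulary)
    if not vocabulary:
        raise ValueError("vocabulary must be non-empty")
    n = len(train_annotations)
    counts = {f: 0 for f in vocabulary}
    for ts in train_annotations.values():
        for f in ts:
            if f in counts:
                counts[f] += 1
    base = {f: (counts[f] / n if n else 0.0) for f in vocabulary}
    return {q: dict(base) for q in query_ids}
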