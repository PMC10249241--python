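"""Deterministic synthetic fixtures: toy DAGs, proteins, hit tables, embeddings.

Everything downstream of real data — ontology structure, annotated
sequences, local-alignment hit tables, planted-signal embeddings — can be
generated at desk scale from a single seeded configuration, so the whole
pipeline is testable without downloads.  Generators are pure functions of
:class:`SynthConfig` (same config, same bytes) and every artifact satisfies
the invariants of the module that consumes it.

The generated world is deliberately simple: random rooted DAGs rather than
real GO structure, i.i.d. sequences with Dayhoff-like residue composition
rather than evolutionarily related families, and linear-additive embedding
signal rather than learned representations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus import DatasetSplit, ProteinRecord
from .homology import HitTable
from .ontology import GoDag, propagate_annotations

__all__ = [
    "SynthConfig",
    "DAYHOFF_FREQUENCIES",
    "make_dag",
    "make_proteins",
    "random_sequence",
    "make_hits",
    "make_planted_embeddings",
]

# Dayhoff amino-acid background composition (order ARNDCQEGHILKMFPSTWYV)
DAYHOFF_FREQUENCIES = {
    "A": 0.087, "R": 0.041, "N": 0.040, "D": 0.047, "C": 0.033,
    "Q": 0.038, "E": 0.050, "G": 0.089, "H": 0.034, "I": 0.037,
    "L": 0.085, "K": 0.081, "M": 0.015, "F": 0.040, "P": 0.051,
    "S": 0.070, "T": 0.058, "W": 0.010, "Y": 0.030, "V": 0.065,
}


@dataclass(frozen=True)
class SynthConfig:
    seed: int = 0
    n_terms: int = 12
    n_proteins: int = 60
    max_parents: int = 2
    length_range: tuple = (100, 1000)
    annotation_rate: float = 0.15
    hit_rate: float = 0.3
    noise_sigma: float = 0.1
    train_frac: float = 0.6
    valid_frac: float = 0.2

    def __post_init__(self):
        if self.n_terms < 1 or self.n_proteins < 1 or self.max_parents < 1:
            raise ValueError("counts must be positive")
        lo, hi = self.length_range
        if not (1 <= lo <= hi):
            raise ValueError("invalid length_range")
        if not (0 < self.annotation_rate < 1):
            raise ValueError("annotation_rate must lie in (0, 1)")
        if self.hit_rate < 0 or self.noise_sigma < 0:
            raise ValueError("hit_rate and noise_sigma must be >= 0")
        if not (0 < self.train_frac and 0 <= self.valid_frac
                and self.train_frac + self.valid_frac < 1):
            raise ValueError("split fractions must leave room for a test set")


def _rng(cfg: SynthConfig, stage: str):
    # independent, named stream per stage so fixtures are individually stable
    import zlib

    salt = zlib.crc32(stage.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence((cfg.seed, salt)))


def make_dag(cfg: SynthConfig) -> GoDag:
    """Single-root random DAG: term i > 0 picks 1..max_parents parents among
    terms 0..i-1."""
    rng = _rng(cfg, "dag")
    terms = [f"T:{i:04d}" for i in range(cfg.n_terms)]
    parents = {terms[0]: frozenset()}
    for i in range(1, cfg.n_terms):
        k = int(rng.integers(1, min(cfg.max_parents, i) + 1))
        ps = rng.choice(i, size=k, replace=False)
        parents[terms[i]] = frozenset(terms[j] for j in ps)
    return GoDag(
        terms=frozenset(terms),
        parents=parents,
        namespace="SYN",
        root=terms[0],
    )


def random_sequence(rng, length: int) -> str:
    letters = np.array(list(DAYHOFF_FREQUENCIES))
    probs = np.array(list(DAYHOFF_FREQUENCIES.values()))
    probs = probs / probs.sum()
    return "".join(rng.choice(letters, size=length, p=probs))


def make_proteins(cfg: SynthConfig, dag: GoDag) -> DatasetSplit:
    """Annotated proteins split into train/valid/test with disjoint sequences.

    Raw annotations are sampled per (protein, non-root term) at
    ``annotation_rate`` (a protein drawing none gets one random term), then
    propagated.  The label vocabulary is every term seen in training.
    """
    rng = _rng(cfg, "proteins")
    non_root = sorted(dag.terms - {dag.root})
    lo, hi = cfg.length_range

    records = []
    seen = set()
    raw = {}
    for i in range(cfg.n_proteins):
        pid = f"P{i:05d}"
        while True:
            seq = random_sequence(rng, int(rng.integers(lo, hi + 1)))
            if seq not in seen:
                seen.add(seq)
                break
        if non_root:
            mask = rng.random(len(non_root)) < cfg.annotation_rate
            terms = {t for t, m_ in zip(non_root, mask) if m_}
            if not terms:
                terms = {non_root[int(rng.integers(len(non_root)))]}
        else:
            terms = {dag.root}
        raw[pid] = terms
        records.append(ProteinRecord(id=pid, sequence=seq))

    propagated = propagate_annotations(dag, raw)
    records = [
        ProteinRecord(id=r.id, sequence=r.sequence, terms=propagated[r.id])
        for r in records
    ]
    n = len(records)
    n_train = max(1, int(round(cfg.train_frac * n)))
    n_valid = int(round(cfg.valid_frac * n))
    train = records[:n_train]
    valid = records[n_train:n_train + n_valid]
    test = records[n_train + n_valid:]
    vocab = sorted({t for r in train for t in r.terms})
    return DatasetSplit(train=train, valid=valid, test=test, label_vocabulary=vocab)


def make_hits(cfg: SynthConfig, split: DatasetSplit) -> HitTable:
    """Hits from valid/test queries to training subjects.

    The hit probability grows with label-set overlap (Jaccard); a query
    sharing its full label set with a training protein is hit almost surely
    at moderate ``hit_rate``.  Bitscores increase with overlap and e-values
    decrease with bitscore.  ``hit_rate = 0`` yields an empty table.
    """
    rng = _rng(cfg, "hits")
    rows = []
    if cfg.hit_rate == 0:
        return HitTable(())
    for query in [*split.valid, *split.test]:
        for subject in split.train:
            union = query.terms | subject.terms
            jac = len(query.terms & subject.terms) / len(union) if union else 0.0
            p_hit = 1.0 - (1.0 - cfg.hit_rate) ** (1.0 + 9.0 * jac)
            if rng.random() < p_hit:
                bitscore = float(50.0 + 400.0 * jac + rng.gamma(2.0, 5.0))
                evalue = float(10.0 ** (-bitscore / 20.0))
                rows.append((query.id, subject.id, evalue, bitscore))
    return HitTable(tuple(rows))


def make_planted_embeddings(cfg: SynthConfig, split: DatasetSplit, dim: int = 64):
    """Linear-additive planted-signal embeddings.

    Each term gets a fixed random direction; a protein's embedding is the
    sum of its terms' directions plus isotropic Gaussian noise of scale
    ``noise_sigma``.  Returns ``(embeddings, directions)`` where
    ``embeddings`` maps protein id -> vector and ``directions`` maps
    term -> direction (reusable as a mock-embedder signal).
    """
    if dim < 1:
        raise ValueError("dim must be >= 1")
    rng = _rng(cfg, "embeddings")
    terms = sorted({t for r in split.all_records() for t in r.terms})
    directions = {
        t: rng.standard_normal(dim) / np.sqrt(dim) for t in terms
    }
    embeddings = {}
    for r in split.all_records():
        v = np.zeros(dim)
        for t in sorted(r.terms):
            v += directions[t]
        v += cfg.noise_sigma * rng.standard_normal(dim)
        embeddings[r.id] = v
    return embeddings, directions
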