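"""Embedder contract, deterministic mock embedder, and per-protein aggregation.

A protein language model maps each sequence slice to a fixed-length vector
(the classification-token representation of the encoder's last block,
1024-dimensional for the full-scale backbone).  This module abstracts that
step behind a minimal contract — ``dim`` plus a deterministic
``embed(sequence, terms=()) -> vector`` — so that the rest of the pipeline
can be exercised with a cheap, fully deterministic mock.  Per-protein
representations are the elementwise mean over all of the protein's slices,
standard and additional weighted equally.

A real transformer backbone plugs in by implementing the same contract; the
reference fine-tuning recipe for such an adapter (multi-label head on slice
labels, binary cross-entropy, Adam, 10 epochs with early stopping) is
recorded in :data:`BACKBONE_ADAPTER_CONFIG` for interchange, but no
transformer is shipped here.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Embedder",
    "MockEmbedder",
    "mock_embedder",
    "ProteinEmbedding",
    "embed_slices",
    "aggregate_mean",
    "write_embeddings",
    "read_embeddings",
]

DEFAULT_DIM = 1024

# Documented config schema for a pluggable fine-tuned transformer adapter.
# Shipping/fine-tuning such a backbone is out of scope; these defaults record
# the intended training protocol for anyone wiring one in.
BACKBONE_ADAPTER_CONFIG = {
    "name": "transformer-cls",
    "dim": DEFAULT_DIM,
    "fine_tune": {
        "epochs": 10,
        "early_stopping": True,
        "loss": "binary_cross_entropy",
        "optimizer": "adam",
        "head": "sigmoid-per-label",
    },
    "l2_normalize": False,
}


class Embedder:
    """Contract: a deterministic map from a slice sequence to a vector.

    Implementations expose ``dim`` and ``embed(sequence, terms=())``;
    ``terms`` is optional slice metadata that label-aware test doubles may
    use and real sequence encoders ignore.
    """

    dim: int

    def embed(self, sequence: str, terms=()) -> np.ndarray:
        raise NotImplementedError


@dataclass(frozen=True)
class ProteinEmbedding:
    protein_id: str
    vector: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.vector, dtype=float)
        if not np.isfinite(v).all():
            raise ValueError(f"non-finite embedding for {self.protein_id!r}")
        object.__setattr__(self, "vector", v)


class MockEmbedder(Embedder):
    """Deterministic hash-based embedder for desk-scale testing.

    Each 3-mer of the input is hashed (seed-salted CRC32) to a Gaussian
    feature vector; the slice embedding is the mean of its k-mer features,
    so single-residue changes perturb the output.  If a ``signal`` map
    (term -> direction vector) is supplied, the directions of the terms in
    the slice's metadata are added, planting recoverable label structure for
    downstream learning tests.
    """

    def __init__(self, dim: int = 64, seed: int = 0, signal=None, k: int = 3):
        if dim < 1:
            raise ValueError("dim must be >= 1")
        self.dim = int(dim)
        self.seed = int(seed)
        self.k = int(k)
        self.signal = None
        if signal is not None:
            self.signal = {t: np.asarray(v, dtype=float) for t, v in signal.items()}
            for t, v in self.signal.items():
                if v.shape != (self.dim,):
                    raise ValueError(f"signal vector for {t!r} has wrong length")
        self._kmer_cache: dict = {}

    def _kmer_vector(self, kmer: str) -> np.ndarray:
        v = self._kmer_cache.get(kmer)
        if v is None:
            h = zlib.crc32(f"{self.seed}:{kmer}".encode()) & 0x7FFFFFFF
            v = np.random.default_rng(h).standard_normal(self.dim)
            self._kmer_cache[kmer] = v
        return v

    def embed(self, sequence: str, terms=()) -> np.ndarray:
        seq = sequence.upper()
        k = min(self.k, len(seq))
        kmers = [seq[i:i + k] for i in range(len(seq) - k + 1)]
        out = np.mean([self._kmer_vector(m) for m in kmers], axis=0)
        if self.signal is not None:
            for t in terms:
                d = self.signal.get(t)
                if d is not None:
                    out = out + d
        return out


def mock_embedder(dim: int = 64, seed: int = 0, signal=None) -> MockEmbedder:
    """Factory alias for :class:`MockEmbedder`."""
    return MockEmbedder(dim=dim, seed=seed, signal=signal)


def embed_slices(slices, embedder: Embedder) -> dict:
    """Embed every slice; returns slice_id -> vector.

    Raises if the embedder violates its dimension contract.
    """
    out = {}
    for sl in slices:
        v = np.asarray(embedder.embed(sl.sequence, terms=sl.terms), dtype=float)
        if v.shape != (embedder.dim,):
            raise ValueError(
                f"embedder contract violation: slice {sl.id!r} got shape "
                f"{v.shape}, expected ({embedder.dim},)"
            )
        out[sl.id] = v
    return out


def aggregate_mean(slice_vectors: dict, slice_parents: dict) -> list:
    """Per-protein elementwise mean over all its slice vectors.

    Standard and additional slices are weighted equally.  Every slice id in
    ``slice_vectors`` must appear in ``slice_parents``; a protein named in
    ``slice_parents`` with no vectors is an error.
    """
    grouped: dict = {}
    for sid, vec in slice_vectors.items():
        if sid not in slice_parents:
            raise KeyError(f"slice {sid!r} has no parent protein")
        grouped.setdefault(slice_parents[sid], []).append(np.asarray(vec, dtype=float))
    missing = set(slice_parents.values()) - set(grouped)
    if missing:
        raise ValueError(f"proteins with zero slices: {sorted(missing)}")
    return [
        ProteinEmbedding(pid, np.mean(vecs, axis=0))
        for pid, vecs in sorted(grouped.items())
    ]


def write_embeddings(embeddings, path) -> None:
    """Persist embeddings keyed by protein id.

    ``.h5``/``.hdf5`` paths use an HDF5 container with one dataset per id;
    anything else is a TSV fallback (id followed by ``dim`` floats).
    """
    items = (
        [(e.protein_id, e.vector) for e in embeddings]
        if not isinstance(embeddings, dict)
        else sorted(embeddings.items())
    )
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "w") as fh:
            for pid, vec in items:
                fh.create_dataset(pid, data=np.asarray(vec, dtype=float))
    else:
        with open(path, "w") as fh:
            for pid, vec in items:
                fh.write(pid + "\t" + "\t".join(f"{x:.8g}" for x in vec) + "\n")


def read_embeddings(path) -> dict:
    path = str(path)
    out = {}
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as fh:
            for pid in fh:
                out[pid] = fh[pid][()]
    else:
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                out[parts[0]] = np.array([float(x) for x in parts[1:]])
    return out
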