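"""Training-set augmentation by PAM-guided point substitution.

For each training protein a mutated copy is generated by applying
``round(L * k)`` substitution events, where ``L`` is the sequence length and
``k`` tunes the intensity.  Each event picks a position uniformly at random
(with replacement) and redraws its residue from the PAM column of the
residue currently at that position, modelling sequential point-accepted
mutations.  Because the PAM1 diagonal dominates (a residue most likely
"mutates" to itself, ~99% per event), ``k = 2`` changes roughly 2% of the
positions of a typical protein.

The bundled matrix (``data/pam1_synthetic.txt``) is a synthetic PAM1-style
matrix: it carries Dayhoff's published per-residue retention probabilities on
the diagonal, with off-diagonal mass allocated by amino-acid background
frequency.  Any column-stochastic 20x20 matrix with a dominant diagonal is
accepted in its place.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources

import numpy as np

__all__ = [
    "PamMatrix",
    "AugmentConfig",
    "load_pam",
    "default_pam",
    "augment_sequence",
    "augment_training_set",
]

AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
# ambiguity / non-standard codes: substitution events landing here are skipped
NON_STANDARD = set("XBZJUO*")


@dataclass(frozen=True)
class PamMatrix:
    """A column-stochastic amino-acid substitution probability matrix.

    ``prob[i, j]`` is the probability that amino acid ``alphabet[j]`` is
    replaced by ``alphabet[i]`` in one mutation event.
    """

    alphabet: str
    prob: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.prob, dtype=float)
        if p.shape != (20, 20) or len(self.alphabet) != 20:
            raise ValueError(f"expected a 20x20 matrix, got shape {p.shape}")
        if (p < 0).any():
            raise ValueError("substitution probabilities must be >= 0")
        sums = p.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError(f"columns must sum to 1, got {sums}")
        if (p.argmax(axis=0) != np.arange(20)).any():
            raise ValueError("each diagonal entry must be the maximum of its column")
        object.__setattr__(self, "prob", p)
        # cumulative columns for fast inverse-CDF sampling
        object.__setattr__(self, "_cum", np.cumsum(p, axis=0))
        object.__setattr__(
            self, "_index", {a: i for i, a in enumerate(self.alphabet)}
        )


@dataclass(frozen=True)
class AugmentConfig:
    """Substitution intensity ``k`` (events per residue), RNG seed, and the
    number of augmented copies per protein."""

    k: float = 2.0
    seed: int = 0
    copies: int = 1

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be >= 0")
        if self.copies < 0:
            raise ValueError("copies must be >= 0")


def load_pam(path) -> PamMatrix:
    """Load a whitespace-delimited 20x20 substitution matrix.

    Expects a header row of the 20 amino-acid letters and one row per
    replacement residue, optionally led by its letter.  Comment lines
    starting with '#' are skipped.  Columns whose sum deviates from 1 by at
    most 1e-3 are renormalized; larger deviations are an error.
    """
    rows = []
    header = None
    row_letters = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if header is None:
                if len(parts) != 20 or any(len(p) != 1 for p in parts):
                    raise ValueError(
                        f"{path}:{lineno}: expected a header of 20 amino-acid letters"
                    )
                header = "".join(parts)
                continue
            if len(parts) == 21 and len(parts[0]) == 1 and parts[0].isalpha():
                row_letters.append(parts[0])
                parts = parts[1:]
            if len(parts) != 20:
                raise ValueError(f"{path}:{lineno}: expected 20 numeric entries")
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric entry ({exc})") from None
    if header is None or len(rows) != 20:
        raise ValueError(f"{path}: expected a header plus 20 matrix rows, got {len(rows)}")
    if row_letters and "".join(row_letters) != header:
        raise ValueError(f"{path}: row letters disagree with the header order")
    p = np.array(rows)
    if (p < 0).any():
        raise ValueError(f"{path}: negative substitution probabilities")
    sums = p.sum(axis=0)
    off = np.abs(sums - 1.0)
    if (off > 1e-3).any():
        bad = [header[j] for j in np.nonzero(off > 1e-3)[0]]
        raise ValueError(f"{path}: columns {bad} do not sum to 1 (sums {sums[off > 1e-3]})")
    return PamMatrix(alphabet=header, prob=p / sums)


def default_pam() -> PamMatrix:
    """The bundled synthetic PAM1-style matrix (see module docstring)."""
    with resources.as_file(
        resources.files("protfun.data") / "pam1_synthetic.txt"
    ) as path:
        return load_pam(path)


def augment_sequence(seq: str, pam: PamMatrix, cfg: AugmentConfig, rng=None) -> str:
    """Apply ``round(len(seq) * k)`` substitution events to one sequence.

    Events pick positions uniformly with replacement; the replacement
    residue is drawn from the PAM column of the residue *currently* at the
    position (so later events see earlier mutations).  Events landing on
    non-standard letters are consumed without effect.  Length is preserved.
    """
    if not seq:
        raise ValueError("cannot augment an empty sequence")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    L = len(seq)
    n_events = int(round(L * cfg.k))
    if n_events == 0:
        return seq
    residues = list(seq.upper())
    index = pam._index
    cum = pam._cum
    alphabet = pam.alphabet
    positions = rng.integers(0, L, size=n_events)
    draws = rng.random(n_events)
    for pos, u in zip(positions, draws):
        cur = residues[pos]
        j = index.get(cur)
        if j is None:  # non-standard residue: event consumed, no change
            continue
        residues[pos] = alphabet[int(np.searchsorted(cum[:, j], u))]
    return "".join(residues)


def augment_training_set(records, pam: PamMatrix, cfg: AugmentConfig) -> list:
    """Return the original records plus ``cfg.copies`` mutated copies each.

    Copies get derived ids (``<id>#aug<n>``) and carry the original's labels
    verbatim.  Reproducible from ``cfg.seed``.
    """
    existing = {r.id for r in records}
    out = list(records)
    # one child RNG stream per (record, copy) so generation order is immaterial
    streams = np.random.SeedSequence(cfg.seed).spawn(len(records) * max(cfg.copies, 1))
    for i, rec in enumerate(records):
        for c in range(cfg.copies):
            new_id = f"{rec.id}#aug{c + 1}"
            if new_id in existing:
                raise ValueError(f"augmented id {new_id!r} collides with an existing record")
            existing.add(new_id)
            rng = np.random.default_rng(streams[i * max(cfg.copies, 1) + c])
            out.append(
                replace(rec, id=new_id,
                        sequence=augment_sequence(rec.sequence, pam, cfg, rng=rng))
            )
    return out
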