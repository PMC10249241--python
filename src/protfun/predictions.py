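"""The prediction-score container shared by all scoring routes.

A *prediction set* is a plain nested mapping ``protein -> term -> score``
with every score in [0, 1].  It is the common currency between the
meta-classifier, homology transfer, the ensemble, and evaluation, and it
round-trips through a three-column TSV (protein_id, term_id, score).
"""

from __future__ import annotations

from typing import Mapping

__all__ = ["validate_predictions", "read_predictions", "write_predictions"]

PredictionSet = Mapping[str, Mapping[str, float]]


def validate_predictions(preds: PredictionSet, terms=None) -> None:
    """Raise ``ValueError`` on scores outside [0, 1] or, if ``terms`` is
    given, on terms outside that collection."""
    for protein, scores in preds.items():
        for term, s in scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(f"score {s} for ({protein!r}, {term!r}) outside [0, 1]")
            if terms is not None and term not in terms:
                raise ValueError(f"predicted term {term!r} not in the ontology")


def read_predictions(path) -> dict:
    out: dict = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated columns")
            try:
                score = float(parts[2])
            except ValueError:
                raise ValueError(f"{path}:{lineno}: non-numeric score {parts[2]!r}") from None
            out.setdefault(parts[0], {})[parts[1]] = score
    validate_predictions(out)
    return out


def write_predictions(preds: PredictionSet, path) -> None:
    with open(path, "w") as fh:
        for protein in sorted(preds):
            for term in sorted(preds[protein]):
                fh.write(f"{protein}\t{term}\t{preds[protein][term]:.6g}\n")
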