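"""Sliding-window slicing of protein sequences for length-limited encoders.

Transformer encoders with quadratic attention cannot ingest arbitrarily long
proteins, so each sequence is cut into consecutive non-overlapping *standard*
windows of at most 500 residues.  To avoid losing signal at window
boundaries, an *additional* bridging slice is emitted for every consecutive
pair of standard slices that are both long enough: it takes the last
``bridge`` residues of the first window and the first ``bridge`` residues of
the second.  Every slice inherits the parent protein's labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus import ProteinRecord

__all__ = ["Slice", "slice_sequence", "slice_records"]

WINDOW = 500
BRIDGE = 250


@dataclass(frozen=True)
class Slice:
    """A windowed subsequence with 0-based half-open coordinates."""

    parent_id: str
    start: int
    end: int
    sequence: str
    kind: str  # "standard" | "additional"
    terms: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if not (1 <= self.end - self.start):
            raise ValueError("slice must be non-empty")
        if len(self.sequence) != self.end - self.start:
            raise ValueError("slice sequence length does not match coordinates")
        if self.kind not in ("standard", "additional"):
            raise ValueError(f"unknown slice kind {self.kind!r}")

    @property
    def id(self) -> str:
        tag = "s" if self.kind == "standard" else "a"
        return f"{self.parent_id}|{tag}{self.start}-{self.end}"


def slice_sequence(record: ProteinRecord, window: int = WINDOW, bridge: int = BRIDGE) -> list:
    """Split one protein into standard windows plus bridging slices.

    Standard slices are the consecutive windows ``[0,w), [w,2w), ...``; the
    last may be shorter.  For each consecutive pair of standard slices that
    BOTH have length >= ``bridge`` (only the final window can be short, so
    the condition binds only on the last pair), one additional slice of
    length exactly ``2 * bridge`` spans the boundary.  Standard slices come
    first in coordinate order, then additional slices.
    """
    if window != 2 * bridge:
        raise ValueError("window must equal 2 * bridge")
    seq = record.sequence
    if not seq:
        raise ValueError(f"protein {record.id!r} has an empty sequence")
    L = len(seq)

    standard = [
        Slice(record.id, s, min(s + window, L), seq[s:min(s + window, L)],
              "standard", record.terms)
        for s in range(0, L, window)
    ]
    additional = []
    for a, b in zip(standard, standard[1:]):
        if (a.end - a.start) >= bridge and (b.end - b.start) >= bridge:
            start = a.end - bridge
            end = b.start + bridge
            additional.append(
                Slice(a.parent_id, start, end, seq[start:end], "additional",
                      record.terms)
            )
    return standard + additional


def slice_records(records, window: int = WINDOW, bridge: int = BRIDGE) -> list:
    """Slice every record; returns a flat list of slices."""
    out = []
    for r in records:
        out.extend(slice_sequence(r, window=window, bridge=bridge))
    return out
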