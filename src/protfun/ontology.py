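"""Gene Ontology DAG handling: loading, ancestor closure, propagation, information content.

The Gene Ontology is a rooted directed acyclic graph per namespace (Biological
Process, Cellular Component, Molecular Function).  The true-path rule states
that a protein annotated with a term is implicitly annotated with every
ancestor up to the namespace root, and a predictor's output set at any score
threshold must respect the same closure.  This module provides the DAG
container, annotation/score propagation, and the conditional-probability
information content used by the semantic-distance metric Smin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "GoDag",
    "IcTable",
    "load_obo",
    "propagate_annotations",
    "propagate_scores",
    "estimate_ic",
]

# OBO namespace tags -> conventional short codes
_NAMESPACE_CODES = {
    "biological_process": "BP",
    "cellular_component": "CC",
    "molecular_function": "MF",
}


class OboParseError(ValueError):
    """Raised when an OBO file cannot be parsed or fails validation."""


@dataclass(frozen=True)
class GoDag:
    """An ontology namespace as a rooted DAG of terms.

    Parameters
    ----------
    terms
        All term identifiers in the namespace (obsolete terms excluded).
    parents
        Map from each term to its set of direct parents.  The root maps to
        the empty set; every other term has at least one parent.
    namespace
        Short namespace code, e.g. ``"BP"``, ``"CC"`` or ``"MF"``.
    root
        The unique term with no parents.
    alt_ids
        Secondary identifiers mapped to their canonical term id.
    """

    terms: frozenset
    parents: Mapping[str, frozenset]
    namespace: str
    root: str
    alt_ids: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for term, ps in self.parents.items():
            unknown = ps - self.terms
            if unknown:
                raise ValueError(f"term {term!r} has parents outside the DAG: {sorted(unknown)}")
        if self.parents.get(self.root):
            raise ValueError(f"root {self.root!r} must have no parents")
        for term in self.terms:
            if term != self.root and not self.parents.get(term):
                raise ValueError(f"non-root term {term!r} has no parents")
        g = nx.DiGraph((child, p) for child, ps in self.parents.items() for p in ps)
        if g.number_of_nodes() and not nx.is_directed_acyclic_graph(g):
            raise ValueError("parent relation contains a cycle")
        # per-instance memo for ancestor closures
        object.__setattr__(self, "_anc_cache", {})

    def resolve(self, term: str) -> str:
        """Map an alt_id to its canonical id; canonical ids pass through."""
        if term in self.terms:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise KeyError(f"unknown term {term!r} in namespace {self.namespace}")

    def ancestors(self, term: str) -> frozenset:
        """All terms reachable from ``term`` via parent edges, including
        ``term`` itself (and therefore always the root)."""
        if term not in self.terms:
            raise KeyError(f"unknown term {term!r} in namespace {self.namespace}")
        cache = self._anc_cache
        got = cache.get(term)
        if got is not None:
            return got
        closure = {term}
        stack = list(self.parents.get(term, ()))
        while stack:
            t = stack.pop()
            if t not in closure:
                closure.add(t)
                stack.extend(self.parents.get(t, ()))
        result = frozenset(closure)
        cache[term] = result
        return result

    def children(self) -> dict:
        """Inverse of ``parents``: term -> set of direct children."""
        inv: dict = {t: set() for t in self.terms}
        for child, ps in self.parents.items():
            for p in ps:
                inv[p].add(child)
        return inv


def ancestors(dag: GoDag, term: str) -> frozenset:
    """Functional alias for :meth:`GoDag.ancestors`."""
    return dag.ancestors(term)


@dataclass(frozen=True)
class IcTable:
    """Per-term information content ``IC(f) = -log Pb(f | parents(f))``."""

    ic: Mapping[str, float]
    log_base: float = math.e

    def __post_init__(self):
        if self.log_base <= 1:
            raise ValueError("log_base must be > 1")
        bad = {t: v for t, v in self.ic.items() if v < 0 or not math.isfinite(v)}
        if bad:
            raise ValueError(f"information content must be finite and >= 0, got {bad}")

    def __getitem__(self, term: str) -> float:
        try:
            return self.ic[term]
        except KeyError:
            raise KeyError(f"no information content for term {term!r}") from None


def load_obo(path, use_part_of: bool = False) -> dict:
    """Load an OBO 1.2 file into one :class:`GoDag` per namespace present.

    Obsolete terms are excluded and ``alt_id`` aliases are recorded on the
    DAG.  Only ``is_a`` edges define the parent relation by default;
    ``use_part_of=True`` additionally treats ``part_of`` relationships as
    parent edges.

    Returns a dict mapping namespace code (``BP``/``CC``/``MF``, or the raw
    namespace string for non-GO ontologies) to :class:`GoDag`.
    """
    import obonet

    try:
        graph = obonet.read_obo(str(path), ignore_obsolete=True)
    except Exception as exc:  # obonet raises ValueError with line context
        raise OboParseError(f"failed to parse OBO file {path}: {exc}") from exc

    relations = {"is_a"} | ({"part_of"} if use_part_of else set())

    by_ns: dict = {}
    for node, data in graph.nodes(data=True):
        ns = data.get("namespace", "unknown")
        code = _NAMESPACE_CODES.get(ns, ns)
        by_ns.setdefault(code, []).append((node, data))

    dags = {}
    for code, nodes in by_ns.items():
        terms = {n for n, _ in nodes}
        parents = {n: set() for n in terms}
        alt_ids = {}
        for n, data in nodes:
            for alt in data.get("alt_id", []):
                alt_ids[alt] = n
        # obonet edges run child -> parent keyed by relationship type
        for child, parent, rel in graph.edges(keys=True):
            if rel in relations and child in terms and parent in terms:
                parents[child].add(parent)
        roots = sorted(t for t in terms if not parents[t])
        if len(roots) != 1:
            raise OboParseError(
                f"namespace {code} must have exactly one root, found {roots}"
            )
        dags[code] = GoDag(
            terms=frozenset(terms),
            parents={t: frozenset(ps) for t, ps in parents.items()},
            namespace=code,
            root=roots[0],
            alt_ids=alt_ids,
        )
    return dags


def propagate_annotations(dag: GoDag, raw: Mapping[str, Iterable[str]]) -> dict:
    """Close each protein's term set upward (true-path rule).

    Idempotent; never removes terms.  Raises ``ValueError`` listing every
    (protein, term) pair whose term is not in the DAG.
    """
    offending = [
        (p, t) for p, ts in raw.items() for t in ts if t not in dag.terms
    ]
    if offending:
        raise ValueError(f"unknown terms in annotations: {offending}")
    return {
        p: frozenset().union(*(dag.ancestors(t) for t in ts)) if ts else frozenset()
        for p, ts in raw.items()
    }


def propagate_scores(dag: GoDag, preds: Mapping[str, Mapping[str, float]]) -> dict:
    """Make prediction scores ancestor-monotone by the max rule.

    Each term's score becomes the max of its own score and the scores of all
    its scored descendants, so the predicted set at any threshold is
    upward-closed.  Idempotent; never lowers a score.
    """
    out = {}
    for protein, scores in preds.items():
        new: dict = {}
        for term, s in scores.items():
            if not (0.0 <= s <= 1.0):
                raise ValueError(
                    f"score {s} for ({protein!r}, {term!r}) outside [0, 1]"
                )
            for anc in dag.ancestors(term):
                if s > new.get(anc, 0.0):
                    new[anc] = s
        out[protein] = new
    return out


def estimate_ic(
    dag: GoDag,
    annotations: Mapping[str, Iterable[str]],
    log_base: float = math.e,
) -> IcTable:
    """Estimate information content from propagated annotation counts.

    ``Pb(f | parents(f))`` is the fraction of proteins carrying all direct
    parents of ``f`` that also carry ``f``; for the root it is the fraction
    of all proteins carrying the root.  ``IC(f) = -log Pb`` in ``log_base``.

    Add-one smoothing is applied when either count is zero, keeping IC
    finite on sparse data.  Input must be propagated: a child observed more
    often than the conjunction of its parents indicates an unpropagated map
    and raises ``ValueError``.
    """
    ann = {p: set(ts) for p, ts in annotations.items()}
    n_proteins = len(ann)
    count = {t: 0 for t in dag.terms}
    for ts in ann.values():
        for t in ts:
            if t in count:
                count[t] += 1

    ic = {}
    log_b = math.log(log_base)
    for term in dag.terms:
        c_f = count[term]
        if term == dag.root:
            c_par = n_proteins
        else:
            ps = dag.parents[term]
            c_par = sum(1 for ts in ann.values() if ps <= ts)
        if c_f > c_par:
            raise ValueError(
                f"term {term!r} counted in {c_f} proteins but its parent "
                f"conjunction only in {c_par}: annotations are not propagated"
            )
        if c_f == 0 or c_par == 0:
            pb = (c_f + 1) / (c_par + 1)
        else:
            pb = c_f / c_par
        ic[term] = max(0.0, -math.log(pb) / log_b)
    return IcTable(ic=ic, log_base=log_base)
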