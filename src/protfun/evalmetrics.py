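"""Protein-centric evaluation over a threshold grid: Fmax, AuPRC, IAuPRC, Smin.

All metrics walk the 101-point threshold grid tau = 0.00, 0.01, ..., 1.00.
At each tau a protein's predicted set is every term scored >= tau (at
tau = 0 this is the whole vocabulary).  Precision at tau averages per-protein
precision over the m(tau) proteins with at least one prediction; recall
averages per-protein recall over all n_e evaluated proteins (those with a
non-empty ground truth in the namespace).  Fmax is the best harmonic mean of
the two across the grid.

AuPRC is the trapezoidal area under the (recall, precision) points of that
grid, over the observed recall range only.  IAuPRC first replaces each
precision by the maximum precision attained at equal-or-greater recall
(right-to-left running max) and then integrates the same way; it therefore
never falls below AuPRC and does not penalize predictors confined to the
high-precision/high-recall corner of the plane.

Smin is the minimal Euclidean norm of remaining uncertainty (ru: summed
information content of missed true terms) and misinformation (mi: summed IC
of falsely predicted terms) across the grid.

The ontology root is excluded from predicted and true sets by default (it is
trivially true for every protein); predictions are expected to be
score-propagated so threshold slices are upward-closed — use
:func:`protfun.ontology.propagate_scores` or the :func:`evaluate` wrapper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .ontology import GoDag, IcTable, propagate_scores

__all__ = [
    "TAU_GRID",
    "PrCurve",
    "EvalResult",
    "pr_rc_curve",
    "fmax",
    "auprc",
    "iauprc",
    "auprc_points",
    "iauprc_points",
    "smin",
    "frequency_restricted_iauprc",
    "evaluate",
]

logger = logging.getLogger(__name__)

TAU_GRID = np.round(np.linspace(0.0, 1.0, 101), 2)


@dataclass(frozen=True)
class PrCurve:
    """Per-threshold precision/recall along the 101-point grid.

    ``m`` counts proteins with >= 1 prediction at each threshold; ``n_e`` is
    the number of evaluated proteins.
    """

    taus: np.ndarray
    pr: np.ndarray
    rc: np.ndarray
    m: np.ndarray
    n_e: int

    def __post_init__(self):
        for name in ("taus", "pr", "rc", "m"):
            object.__setattr__(self, name, np.asarray(getattr(self, name)))
        if not (len(self.taus) == len(self.pr) == len(self.rc) == len(self.m)):
            raise ValueError("curve arrays must have equal length")
        if ((self.pr < 0) | (self.pr > 1) | (self.rc < 0) | (self.rc > 1)).any():
            raise ValueError("precision and recall must lie in [0, 1]")
        if (np.diff(self.rc) > 1e-12).any():
            raise ValueError("recall must be non-increasing in tau")


@dataclass(frozen=True)
class EvalResult:
    fmax: float
    tau_at_fmax: float
    auprc: float
    iauprc: float
    smin: float
    tau_at_smin: float
    curve: PrCurve
    ru: np.ndarray
    mi: np.ndarray

    def as_dict(self) -> dict:
        return {
            "fmax": self.fmax,
            "tau_at_fmax": self.tau_at_fmax,
            "auprc": self.auprc,
            "iauprc": self.iauprc,
            "smin": self.smin,
            "tau_at_smin": self.tau_at_smin,
            "n_e": int(self.curve.n_e),
        }


def _effective_vocabulary(dag, vocabulary, include_root):
    if vocabulary is not None:
        vocab = set(vocabulary)
    elif dag is not None:
        vocab = set(dag.terms)
    else:
        raise ValueError("either dag or vocabulary must be given")
    if dag is not None and not include_root:
        vocab.discard(dag.root)
    return vocab


def _evaluated(preds, truth, vocab):
    """Yield (protein, true-set, score-dict) for proteins with non-empty
    vocabulary-restricted truth; warn about the rest."""
    items = []
    for protein, true_terms in truth.items():
        T = set(true_terms) & vocab
        if not T:
            logger.warning(
                "protein %r has no ground-truth terms in the evaluated "
                "vocabulary; excluded", protein,
            )
            continue
        scores = {
            t: s for t, s in preds.get(protein, {}).items() if t in vocab
        }
        items.append((protein, T, scores))
    return items


def pr_rc_curve(preds, truth, dag: GoDag = None, vocabulary=None,
                include_root: bool = False) -> PrCurve:
    """Precision/recall along the threshold grid.

    ``preds`` must be score-propagated and ``truth`` annotation-propagated.
    Proteins with empty (vocabulary-restricted) truth are excluded from
    ``n_e`` with a warning.  At tau = 0 every vocabulary term counts as
    predicted for every protein.
    """
    vocab = _effective_vocabulary(dag, vocabulary, include_root)
    items = _evaluated(preds, truth, vocab)
    n_e = len(items)
    taus = TAU_GRID
    n_tau = len(taus)

    sum_prec = np.zeros(n_tau)
    sum_rec = np.zeros(n_tau)
    m = np.zeros(n_tau, dtype=int)
    V = len(vocab)

    for _protein, T, scores in items:
        svals = np.fromiter(scores.values(), dtype=float, count=len(scores))
        struth = np.fromiter(
            (scores.get(t, -1.0) for t in T), dtype=float, count=len(T)
        )
        svals.sort()
        struth.sort()
        # counts of scores >= tau for tau > 0
        n_pred = len(svals) - np.searchsorted(svals, taus, side="left")
        n_tp = len(struth) - np.searchsorted(struth, taus, side="left")
        # tau = 0: the whole vocabulary is predicted
        n_pred[0] = V
        n_tp[0] = len(T)
        has_pred = n_pred > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            prec = np.where(has_pred, n_tp / np.where(has_pred, n_pred, 1), 0.0)
        sum_prec += prec
        sum_rec += n_tp / len(T)
        m += has_pred

    with np.errstate(invalid="ignore", divide="ignore"):
        pr = np.where(m > 0, sum_prec / np.where(m > 0, m, 1), 0.0)
    rc = sum_rec / n_e if n_e else np.zeros(n_tau)
    return PrCurve(taus=taus.copy(), pr=pr, rc=rc, m=m, n_e=n_e)


def fmax(curve: PrCurve):
    """Maximum harmonic mean of precision and recall across the grid.

    Thresholds with no predicting protein (m = 0) or with pr + rc = 0 are
    skipped; ties break toward the smallest threshold.  Returns
    ``(fmax, tau)``; an all-degenerate curve gives ``(0.0, 0.0)``.
    """
    best, best_tau = 0.0, 0.0
    for tau, p, r, mt in zip(curve.taus, curve.pr, curve.rc, curve.m):
        if mt == 0 or p + r == 0:
            continue
        f = 2 * p * r / (p + r)
        if f > best + 1e-15:
            best, best_tau = float(f), float(tau)
    return best, best_tau


def _collapse(rc, pr):
    """Collapse duplicate recall values by max precision; sort by recall."""
    byrc: dict = {}
    for r, p in zip(rc, pr):
        r = float(r)
        if p > byrc.get(r, -1.0):
            byrc[r] = float(p)
    rs = np.array(sorted(byrc))
    return rs, np.array([byrc[r] for r in rs])


def auprc_points(rc, pr) -> float:
    """Trapezoidal area under (recall, precision) points over the observed
    recall range; duplicate recalls collapse to their best precision.
    Fewer than two distinct recall values give area 0."""
    rs, ps = _collapse(rc, pr)
    if len(rs) < 2:
        return 0.0
    return float(np.trapezoid(ps, rs))


def iauprc_points(rc, pr) -> float:
    """Interpolated area: precision at each point becomes the running max of
    precisions at equal-or-greater recall, then integrate as in
    :func:`auprc_points`.  Always >= the un-interpolated area."""
    rc = np.asarray(rc, dtype=float)
    pr = np.asarray(pr, dtype=float)
    order = np.argsort(rc, kind="stable")
    interp = np.empty_like(pr)
    running = -np.inf
    for i in order[::-1]:  # from the highest recall downward
        running = max(running, pr[i])
        interp[i] = running
    return auprc_points(rc, interp)


def auprc(curve: PrCurve) -> float:
    return auprc_points(curve.rc, curve.pr)


def iauprc(curve: PrCurve) -> float:
    return iauprc_points(curve.rc, curve.pr)


def smin(preds, truth, ic: IcTable, dag: GoDag = None, vocabulary=None,
         include_root: bool = False):
    """Semantic-distance minimum over the threshold grid.

    ``ru(tau)`` averages over evaluated proteins the summed IC of true terms
    not predicted at tau; ``mi(tau)`` the summed IC of predicted non-true
    terms.  Returns ``(smin, tau, ru_curve, mi_curve)``; ties break toward
    the smallest threshold.  A term without an IC entry raises ``KeyError``
    naming it.
    """
    vocab = _effective_vocabulary(dag, vocabulary, include_root)
    items = _evaluated(preds, truth, vocab)
    n_e = len(items)
    taus = TAU_GRID
    ru = np.zeros(len(taus))
    mi = np.zeros(len(taus))

    for _protein, T, scores in items:
        ic_true = np.array([ic[t] for t in T])
        s_true = np.array([scores.get(t, -1.0) for t in T])
        false_terms = [t for t in scores if t not in T]
        ic_false = np.array([ic[t] for t in false_terms])
        s_false = np.array([scores[t] for t in false_terms])
        # vocabulary terms never scored: always missed for tau > 0, and
        # falsely predicted at tau = 0
        ic_unscored_false = sum(
            ic[t] for t in vocab if t not in scores and t not in T
        )
        pred_true = (s_true[None, :] >= taus[:, None]) if len(T) else np.zeros(
            (len(taus), 0), dtype=bool
        )
        pred_false = (
            (s_false[None, :] >= taus[:, None])
            if false_terms
            else np.zeros((len(taus), 0), dtype=bool)
        )
        ru_i = ((~pred_true) * ic_true).sum(axis=1)
        mi_i = (pred_false * ic_false).sum(axis=1)
        # tau = 0 predicts the whole vocabulary
        ru_i[0] = 0.0
        mi_i[0] = ic_false.sum() + ic_unscored_false
        ru += ru_i
        mi += mi_i

    if n_e:
        ru /= n_e
        mi /= n_e
    s = np.sqrt(ru ** 2 + mi ** 2)
    best = int(np.argmin(s))  # argmin takes the first (smallest tau) on ties
    return float(s[best]), float(taus[best]), ru, mi


def frequency_restricted_iauprc(preds, truth, dag: GoDag, train_annotations,
                                percentile: float, include_root: bool = False):
    """IAuPRC restricted to rare terms.

    The vocabulary is cut to terms whose training relative frequency is at
    most ``percentile``/100; predictions and truth are restricted
    accordingly.  Returns ``None`` when no term qualifies (or no protein has
    truth left).
    """
    if not (0 < percentile <= 100):
        raise ValueError("percentile must be in (0, 100]")
    n = len(train_annotations)
    counts: dict = {}
    for ts in train_annotations.values():
        for t in ts:
            counts[t] = counts.get(t, 0) + 1
    cutoff = percentile / 100.0
    vocab = {
        t for t in dag.terms
        if (counts.get(t, 0) / n if n else 0.0) <= cutoff
    }
    if not include_root:
        vocab.discard(dag.root)
    if not vocab:
        return None
    if not any(set(ts) & vocab for ts in truth.values()):
        return None
    curve = pr_rc_curve(preds, truth, dag=dag, vocabulary=vocab,
                        include_root=include_root)
    return iauprc(curve)


def evaluate(preds, truth, dag: GoDag, ic: IcTable = None,
             include_root: bool = False, propagate: bool = True) -> EvalResult:
    """One-stop evaluation: propagate scores, then Fmax, AuPRC, IAuPRC and
    (if ``ic`` is given) Smin."""
    if propagate:
        preds = propagate_scores(dag, preds)
    curve = pr_rc_curve(preds, truth, dag=dag, include_root=include_root)
    f, tau_f = fmax(curve)
    a = auprc(curve)
    ia = iauprc(curve)
    if ic is not None:
        s, tau_s, ru, mi = smin(preds, truth, ic, dag=dag, include_root=include_root)
    else:
        s, tau_s, ru, mi = float("nan"), float("nan"), np.array([]), np.array([])
    return EvalResult(
        fmax=f, tau_at_fmax=tau_f, auprc=a, iauprc=ia,
        smin=s, tau_at_smin=tau_s, curve=curve, ru=ru, mi=mi,
    )
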