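"""Linear ensembling of two prediction sets and validation-Fmax grid search.

The combined score is ``S(p, f) = alpha * y_A + (1 - alpha) * y_B`` over the
union of (protein, term) keys, with a side missing a key contributing 0.
``alpha`` is chosen by exhaustive grid search maximizing Fmax on a held-out
validation set; because 0 and 1 are on the grid, the tuned ensemble never
scores below either component there.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evalmetrics import fmax, pr_rc_curve
from .ontology import GoDag, propagate_scores

__all__ = ["EnsembleConfig", "combine", "grid_search_alpha"]


@dataclass(frozen=True)
class EnsembleConfig:
    alpha: float = 0.5
    grid_step: float = 0.01

    def __post_init__(self):
        if not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")
        if not (0.0 < self.grid_step <= 1.0):
            raise ValueError("grid_step must lie in (0, 1]")


def combine(pred_a, pred_b, alpha: float) -> dict:
    """``alpha * pred_a + (1 - alpha) * pred_b`` over the union of keys.

    At ``alpha`` 1 (or 0) the result equals ``pred_a`` (``pred_b``) exactly,
    including its key set.
    """
    if not (0.0 <= alpha <= 1.0):
        raise ValueError("alpha must lie in [0, 1]")
    if alpha == 1.0:
        return {p: dict(ts) for p, ts in pred_a.items()}
    if alpha == 0.0:
        return {p: dict(ts) for p, ts in pred_b.items()}
    out: dict = {}
    for protein in set(pred_a) | set(pred_b):
        sa = pred_a.get(protein, {})
        sb = pred_b.get(protein, {})
        out[protein] = {
            t: alpha * sa.get(t, 0.0) + (1.0 - alpha) * sb.get(t, 0.0)
            for t in set(sa) | set(sb)
        }
    return out


def grid_search_alpha(pred_a, pred_b, truth, dag: GoDag, step: float = 0.01):
    """Pick alpha maximizing validation Fmax over {0, step, ..., 1}.

    Raw scores are combined first and propagated before evaluation.  Ties
    break toward the smallest alpha.  Returns ``(alpha, fmax)``.
    """
    if not truth:
        raise ValueError("validation truth must be non-empty")
    alphas = np.round(np.arange(0.0, 1.0 + step / 2, step), 10)
    alphas[-1] = min(alphas[-1], 1.0)
    best_alpha, best_f = 0.0, -1.0
    for alpha in alphas:
        merged = propagate_scores(dag, combine(pred_a, pred_b, float(alpha)))
        f, _ = fmax(pr_rc_curve(merged, truth, dag=dag))
        if f > best_f + 1e-12:
            best_alpha, best_f = float(alpha), f
    return best_alpha, best_f
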