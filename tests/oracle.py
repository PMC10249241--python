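"""Independent brute-force re-implementations used as test oracles.

Everything here is computed with plain Python sets and loops, deliberately
sharing no code with the package: reachability by explicit BFS, metrics by
literal translation of their definitions over the 101-threshold grid.
"""

import math


def brute_ancestors(parents, term):
    seen = {term}
    frontier = [term]
    while frontier:
        t = frontier.pop()
        for p in parents.get(t, ()):
            if p not in seen:
                seen.add(p)
                frontier.append(p)
    return seen


def brute_propagate_scores(parents, preds):
    out = {}
    for protein, scores in preds.items():
        new = {}
        for term, s in scores.items():
            for anc in brute_ancestors(parents, term):
                new[anc] = max(new.get(anc, 0.0), s)
        out[protein] = new
    return out


TAUS = [round(i / 100, 2) for i in range(101)]


def brute_curve(preds, truth, vocab, root):
    """pr/rc/m per threshold by direct set arithmetic; tau=0 predicts the
    whole vocabulary."""
    vocab = set(vocab) - {root}
    items = []
    for protein, ts in truth.items():
        T = set(ts) & vocab
        if T:
            items.append((T, {t: s for t, s in preds.get(protein, {}).items()
                              if t in vocab}))
    n_e = len(items)
    pr, rc, m = [], [], []
    for tau in TAUS:
        precs, recs = [], []
        for T, scores in items:
            if tau == 0:
                P = set(vocab)
            else:
                P = {t for t, s in scores.items() if s >= tau}
            if P:
                precs.append(len(P & T) / len(P))
            recs.append(len(P & T) / len(T))
        m.append(len(precs))
        pr.append(sum(precs) / len(precs) if precs else 0.0)
        rc.append(sum(recs) / n_e if n_e else 0.0)
    return pr, rc, m, n_e


def brute_fmax(pr, rc, m):
    best, best_tau = 0.0, 0.0
    for tau, p, r, mt in zip(TAUS, pr, rc, m):
        if mt == 0 or p + r == 0:
            continue
        f = 2 * p * r / (p + r)
        if f > best + 1e-15:
            best, best_tau = f, tau
    return best, best_tau


def _trapezoid(points):
    """points: iterable of (rc, pr); collapse duplicate rc by max pr."""
    byrc = {}
    for r, p in points:
        byrc[r] = max(byrc.get(r, -1.0), p)
    rs = sorted(byrc)
    if len(rs) < 2:
        return 0.0
    area = 0.0
    for a, b in zip(rs, rs[1:]):
        area += (b - a) * (byrc[a] + byrc[b]) / 2
    return area


def brute_auprc(pr, rc):
    return _trapezoid(zip(rc, pr))


def brute_iauprc(pr, rc):
    interp = [
        max(p2 for r2, p2 in zip(rc, pr) if r2 >= r - 1e-12) for r in rc
    ]
    return _trapezoid(zip(rc, interp))


def brute_smin(preds, truth, ic, vocab, root):
    vocab = set(vocab) - {root}
    items = []
    for protein, ts in truth.items():
        T = set(ts) & vocab
        if T:
            items.append((T, {t: s for t, s in preds.get(protein, {}).items()
                              if t in vocab}))
    n_e = len(items)
    best, best_tau = math.inf, 0.0
    for tau in TAUS:
        ru = mi = 0.0
        for T, scores in items:
            if tau == 0:
                P = set(vocab)
            else:
                P = {t for t, s in scores.items() if s >= tau}
            ru += sum(ic[f] for f in T - P)
            mi += sum(ic[f] for f in P - T)
        ru /= n_e
        mi /= n_e
        s = math.sqrt(ru ** 2 + mi ** 2)
        if s < best - 1e-15:
            best, best_tau = s, tau
    return best, best_tau
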