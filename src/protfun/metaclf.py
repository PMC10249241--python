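"""Multi-label meta-classifier over aggregated protein embeddings.

Architecture: one hidden layer of 1000 rectified-linear units followed by an
independent sigmoid per ontology term, trained with mean binary
cross-entropy and the Adam optimizer.  Training monitors validation loss,
reduces the learning rate on plateau, stops early, and restores the weights
of the best validation epoch.  Implemented directly in numpy: the model is
two affine maps, which keeps the dependency surface small and the training
protocol fully explicit and seed-reproducible.

Also provides the "no meta-classifier" ablation path: per-slice score
vectors averaged per protein.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "TrainConfig",
    "MetaClassifier",
    "train_meta",
    "predict_meta",
    "backbone_mode_predict",
    "save_checkpoint",
    "load_checkpoint",
]

_EPS = 1e-7


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol knobs.

    Early stopping waits ``patience_stop`` epochs without validation-loss
    improvement; the learning rate is multiplied by ``lr_factor`` after
    ``patience_lr`` stagnant epochs.
    """

    max_epochs: int = 100
    patience_stop: int = 5
    patience_lr: int = 3
    lr: float = 1e-3
    lr_factor: float = 0.1
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.max_epochs < 0:
            raise ValueError("max_epochs must be >= 0")
        for name in ("patience_stop", "patience_lr", "batch_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.lr and 0 < self.lr_factor <= 1):
            raise ValueError("lr must be positive and lr_factor in (0, 1]")


class MetaClassifier:
    """input -> ReLU(hidden) -> sigmoid per label."""

    def __init__(self, input_dim: int, labels, hidden_dim: int = 1000, seed: int = 0):
        self.input_dim = int(input_dim)
        self.hidden_dim = int(hidden_dim)
        self.labels = list(labels)
        rng = np.random.default_rng(seed)
        # He initialization for the ReLU layer, Glorot-ish for the head
        self.W1 = rng.standard_normal((self.input_dim, self.hidden_dim)) * np.sqrt(
            2.0 / self.input_dim
        )
        self.b1 = np.zeros(self.hidden_dim)
        self.W2 = rng.standard_normal((self.hidden_dim, len(self.labels))) * np.sqrt(
            1.0 / self.hidden_dim
        )
        self.b2 = np.zeros(len(self.labels))

    @property
    def params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def set_params(self, params):
        self.W1, self.b1, self.W2, self.b2 = [p.copy() for p in params]

    def forward(self, X: np.ndarray):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"embedding dim {X.shape[1]} does not match model input_dim {self.input_dim}"
            )
        H = np.maximum(X @ self.W1 + self.b1, 0.0)
        Z = H @ self.W2 + self.b2
        # numerically stable sigmoid
        P = np.where(Z >= 0, 1.0 / (1.0 + np.exp(-Z)), np.exp(Z) / (1.0 + np.exp(Z)))
        return H, P

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self.forward(X)[1]


def _bce(P: np.ndarray, Y: np.ndarray) -> float:
    P = np.clip(P, _EPS, 1.0 - _EPS)
    return float(-np.mean(Y * np.log(P) + (1.0 - Y) * np.log(1.0 - P)))


def train_meta(
    train,
    valid,
    cfg: TrainConfig,
    labels=None,
    hidden_dim: int = 1000,
) -> MetaClassifier:
    """Fit the meta-classifier on (X, Y) arrays.

    ``train`` and ``valid`` are ``(X, Y)`` pairs: embeddings of shape
    (n, dim) and 0/1 label matrices of shape (n, n_labels) over a fixed
    vocabulary (pass ``labels`` to name the columns).  Returns the model with
    the weights of the best validation-loss epoch.
    """
    Xtr, Ytr = (np.asarray(a, dtype=float) for a in train)
    Xva, Yva = (np.asarray(a, dtype=float) for a in valid)
    if Xtr.shape[0] == 0:
        raise ValueError("training set is empty")
    n_labels = Ytr.shape[1]
    if labels is None:
        labels = [f"label_{i}" for i in range(n_labels)]
    if len(labels) != n_labels:
        raise ValueError(
            f"label vocabulary size {len(labels)} does not match Y width {n_labels}"
        )
    if Yva.shape[1] != n_labels:
        raise ValueError("train/valid label matrices have different widths")
    if not np.isin(Ytr, (0.0, 1.0)).all() or not np.isin(Yva, (0.0, 1.0)).all():
        raise ValueError("label matrices must be 0/1")

    model = MetaClassifier(Xtr.shape[1], labels, hidden_dim=hidden_dim, seed=cfg.seed)
    rng = np.random.default_rng(cfg.seed + 1)

    # Adam state
    ms = [np.zeros_like(p) for p in model.params]
    vs = [np.zeros_like(p) for p in model.params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    t = 0
    lr = cfg.lr

    best_loss = np.inf
    best_params = [p.copy() for p in model.params]
    stale_stop = stale_lr = 0

    n = Xtr.shape[0]
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            Xb, Yb = Xtr[idx], Ytr[idx]
            H, P = model.forward(Xb)
            # d(mean BCE)/dZ = (P - Y) / (batch * n_labels)
            dZ = (P - Yb) / (Xb.shape[0] * n_labels)
            gW2 = H.T @ dZ
            gb2 = dZ.sum(axis=0)
            dH = (dZ @ model.W2.T) * (H > 0)
            gW1 = Xb.T @ dH
            gb1 = dH.sum(axis=0)
            t += 1
            for p, m, v, g in zip(model.params, ms, vs, (gW1, gb1, gW2, gb2)):
                m[...] = beta1 * m + (1 - beta1) * g
                v[...] = beta2 * v + (1 - beta2) * g * g
                mhat = m / (1 - beta1 ** t)
                vhat = v / (1 - beta2 ** t)
                p -= lr * mhat / (np.sqrt(vhat) + eps)

        val_loss = _bce(model.predict_proba(Xva), Yva) if Xva.shape[0] else _bce(
            model.predict_proba(Xtr), Ytr
        )
        if not np.isfinite(val_loss):
            raise FloatingPointError("training diverged: non-finite validation loss")
        if val_loss < best_loss - 1e-9:
            best_loss = val_loss
            best_params = [p.copy() for p in model.params]
            stale_stop = stale_lr = 0
        else:
            stale_stop += 1
            stale_lr += 1
            if stale_lr >= cfg.patience_lr:
                lr *= cfg.lr_factor
                stale_lr = 0
            if stale_stop >= cfg.patience_stop:
                break

    model.set_params(best_params)
    return model


def predict_meta(model: MetaClassifier, embeddings) -> dict:
    """Score proteins: embeddings (list of ProteinEmbedding or dict
    id -> vector) -> prediction set ``protein -> term -> score``."""
    if isinstance(embeddings, dict):
        items = sorted(embeddings.items())
    else:
        items = [(e.protein_id, e.vector) for e in embeddings]
    if not items:
        return {}
    X = np.vstack([np.asarray(v, dtype=float) for _, v in items])
    P = model.predict_proba(X)
    return {
        pid: dict(zip(model.labels, map(float, row)))
        for (pid, _), row in zip(items, P)
    }


def backbone_mode_predict(slice_scores: dict, slice_parents: dict, labels) -> dict:
    """Ablation path without the meta-classifier: per-protein elementwise
    mean of per-slice score vectors over the label vocabulary."""
    labels = list(labels)
    grouped: dict = {}
    for sid, vec in slice_scores.items():
        if sid not in slice_parents:
            raise KeyError(f"slice {sid!r} has no parent protein")
        v = np.asarray(vec, dtype=float)
        if v.shape != (len(labels),):
            raise ValueError(f"slice {sid!r} score vector has wrong length")
        grouped.setdefault(slice_parents[sid], []).append(v)
    missing = set(slice_parents.values()) - set(grouped)
    if missing:
        raise ValueError(f"proteins with zero slices: {sorted(missing)}")
    return {
        pid: dict(zip(labels, map(float, np.mean(vecs, axis=0))))
        for pid, vecs in sorted(grouped.items())
    }


def save_checkpoint(model: MetaClassifier, path) -> None:
    np.savez(
        str(path),
        W1=model.W1, b1=model.b1, W2=model.W2, b2=model.b2,
        labels=np.array(model.labels, dtype=object),
    )


def load_checkpoint(path) -> MetaClassifier:
    data = np.load(str(path), allow_pickle=True)
    labels = [str(x) for x in data["labels"]]
    model = MetaClassifier(data["W1"].shape[0], labels, hidden_dim=data["W1"].shape[1])
    model.set_params([data["W1"], data["b1"], data["W2"], data["b2"]])
    return model
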