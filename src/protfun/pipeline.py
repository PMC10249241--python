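"""End-to-end orchestration of the annotation pipeline.

Modes
-----
``meta_embedding``
    slice -> embed -> per-protein mean -> meta-classifier.
``meta_plus_homology``
    the ``meta_embedding`` route linearly ensembled with bitscore homology
    transfer; alpha fixed or tuned on validation Fmax.
``backbone_only``
    ablation without the meta-classifier: a slice-level classifier's score
    vectors are averaged per protein.
``homology_only`` / ``top_hit`` / ``naive``
    the three alignment/frequency baselines.

A run takes either a synthetic-world config (everything generated in
memory) or paths to FASTA/annotation/OBO/hit-table files, executes the
mode's stage graph with per-stage seeds derived from one global seed, and
returns predictions plus a full evaluation.  With an output directory set,
predictions, the evaluation report and a run manifest (config, seed,
package version, output checksums) are persisted.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field

from . import __version__
from .augment import AugmentConfig, augment_training_set, default_pam
from .corpus import (DatasetSplit, attach_annotations, deduplicate,
                     filter_labels, read_annotations, read_fasta)
from .embed import MockEmbedder, aggregate_mean, embed_slices
from .ensemble import combine, grid_search_alpha
from .evalmetrics import EvalResult, evaluate
from .homology import (HitTable, bitscore_transfer, naive_baseline,
                       read_blast_tabular, top_hit_transfer)
from .metaclf import (TrainConfig, backbone_mode_predict, predict_meta,
                      train_meta)
from .ontology import estimate_ic, load_obo, propagate_annotations
from .predictions import write_predictions
from .slicer import slice_records
from .synth import SynthConfig, make_dag, make_hits, make_planted_embeddings, make_proteins

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "stage_seed"]

MODES = ("meta_embedding", "meta_plus_homology", "backbone_only", "homology_only", "naive", "top_hit")


def stage_seed(seed: int, stage: str) -> int:
    """Derive a per-stage seed from the global one (stable, < 2**31)."""
    return (seed * 2654435761 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    mode: str = "meta_embedding"
    seed: int = 0
    synth: SynthConfig = None
    paths: dict = field(default_factory=dict)
    augment: AugmentConfig = None  # None disables augmentation
    train: TrainConfig = None
    hidden_dim: int = 1000
    embed_dim: int = 64
    min_label_proteins: int = 50
    evalue_max: float = 0.001
    alpha: float = None  # None -> grid search on validation
    out_dir: str = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}; expected one of {MODES}")
        if self.synth is None and not self.paths:
            raise ValueError("either a synth config or input paths are required")
        needs_hits = self.mode in ("meta_plus_homology", "homology_only", "top_hit")
        if self.synth is None:
            required = {"train_fasta", "valid_fasta", "test_fasta", "annotations", "obo"}
            if needs_hits:
                required.add("hits")
            missing = required - set(self.paths)
            if missing:
                raise ValueError(f"mode {self.mode!r} requires paths: {sorted(missing)}")


@dataclass
class PipelineResult:
    predictions: dict  # raw (un-propagated) test predictions
    result: EvalResult
    alpha: float = None
    manifest: dict = None


def _load_world(cfg: PipelineConfig):
    """Returns (dag, split, hits, signal_directions)."""
    if cfg.synth is not None:
        syn = dataclasses.replace(cfg.synth, seed=stage_seed(cfg.seed, "synth"))
        dag = make_dag(syn)
        split = make_proteins(syn, dag)
        hits = make_hits(syn, split)
        _, directions = make_planted_embeddings(syn, split, dim=cfg.embed_dim)
        return dag, split, hits, directions
    dags = load_obo(cfg.paths["obo"])
    if len(dags) != 1:
        ns = cfg.paths.get("namespace")
        if ns is None or ns not in dags:
            raise ValueError(
                f"OBO has namespaces {sorted(dags)}; set paths['namespace']"
            )
        dag = dags[ns]
    else:
        (dag,) = dags.values()
    raw = read_annotations(cfg.paths["annotations"])
    ann = propagate_annotations(dag, raw)
    split = DatasetSplit(
        train=attach_annotations(read_fasta(cfg.paths["train_fasta"]), ann),
        valid=attach_annotations(read_fasta(cfg.paths["valid_fasta"]), ann),
        test=attach_annotations(read_fasta(cfg.paths["test_fasta"]), ann),
    )
    hits = (
        read_blast_tabular(cfg.paths["hits"]) if "hits" in cfg.paths else HitTable(())
    )
    return dag, split, hits, None


def _label_matrix(records, vocab):
    import numpy as np

    index = {t: j for j, t in enumerate(vocab)}
    Y = np.zeros((len(records), len(vocab)))
    for i, r in enumerate(records):
        for t in r.terms:
            j = index.get(t)
            if j is not None:
                Y[i, j] = 1.0
    return Y


def _embedding_route(cfg, split, directions, records_by_split):
    """Slice, embed and aggregate each requested sub-split; returns
    split name -> (ordered records, X matrix)."""
    import numpy as np

    embedder = MockEmbedder(
        dim=cfg.embed_dim, seed=stage_seed(cfg.seed, "embed"), signal=directions
    )
    out = {}
    for name, records in records_by_split.items():
        slices = slice_records(records)
        vectors = embed_slices(slices, embedder)
        parents = {s.id: s.parent_id for s in slices}
        per_protein = {e.protein_id: e.vector for e in aggregate_mean(vectors, parents)}
        X = np.vstack([per_protein[r.id] for r in records])
        out[name] = (records, X)
    return out


def _meta_route(cfg: PipelineConfig, split: DatasetSplit, directions):
    train_records = split.train
    if cfg.augment is not None and cfg.augment.copies > 0:
        aug = dataclasses.replace(cfg.augment, seed=stage_seed(cfg.seed, "augment"))
        train_records = augment_training_set(train_records, default_pam(), aug)
    routes = _embedding_route(
        cfg, split, directions,
        {"train": train_records, "valid": split.valid, "test": split.test},
    )
    vocab = split.label_vocabulary
    tcfg = cfg.train or TrainConfig()
    tcfg = dataclasses.replace(tcfg, seed=stage_seed(cfg.seed, "metaclf"))
    (rtr, Xtr), (rva, Xva), (rte, Xte) = routes["train"], routes["valid"], routes["test"]
    model = train_meta(
        (Xtr, _label_matrix(rtr, vocab)),
        (Xva, _label_matrix(rva, vocab)),
        tcfg, labels=vocab, hidden_dim=cfg.hidden_dim,
    )
    valid_preds = predict_meta(model, {r.id: x for r, x in zip(rva, Xva)})
    test_preds = predict_meta(model, {r.id: x for r, x in zip(rte, Xte)})
    return model, valid_preds, test_preds


def _backbone_route(cfg: PipelineConfig, split: DatasetSplit, directions):
    """Slice-level classifier whose per-slice scores are averaged per protein."""
    import numpy as np

    embedder = MockEmbedder(
        dim=cfg.embed_dim, seed=stage_seed(cfg.seed, "embed"), signal=directions
    )
    vocab = split.label_vocabulary

    def slice_xy(records):
        slices = slice_records(records)
        vecs = embed_slices(slices, embedder)
        X = np.vstack([vecs[s.id] for s in slices])
        Y = _label_matrix(slices, vocab)
        return slices, X, Y

    tr_slices, Xtr, Ytr = slice_xy(split.train)
    va_slices, Xva, Yva = slice_xy(split.valid)
    te_slices, Xte, _ = slice_xy(split.test)
    tcfg = cfg.train or TrainConfig()
    tcfg = dataclasses.replace(tcfg, seed=stage_seed(cfg.seed, "backbone"))
    model = train_meta((Xtr, Ytr), (Xva, Yva), tcfg, labels=vocab,
                       hidden_dim=cfg.hidden_dim)

    def mean_preds(slices, X):
        P = model.predict_proba(X)
        return backbone_mode_predict(
            {s.id: P[i] for i, s in enumerate(slices)},
            {s.id: s.parent_id for s in slices},
            vocab,
        )

    return mean_preds(va_slices, Xva), mean_preds(te_slices, Xte)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    dag, split, hits, directions = _load_world(cfg)
    split, _removed = deduplicate(split)
    split = filter_labels(split, min_proteins=cfg.min_label_proteins)

    train_ann = {r.id: r.terms for r in split.train}
    valid_truth = {r.id: r.terms for r in split.valid}
    test_truth = {r.id: r.terms for r in split.test}
    vocab = split.label_vocabulary
    alpha = None

    if cfg.mode == "naive":
        test_preds = naive_baseline(train_ann, list(test_truth), vocab)
    elif cfg.mode == "homology_only":
        test_preds = bitscore_transfer(hits, train_ann, evalue_max=cfg.evalue_max)
        test_preds = {p: s for p, s in test_preds.items() if p in test_truth}
    elif cfg.mode == "top_hit":
        test_preds = top_hit_transfer(hits, train_ann, evalue_max=cfg.evalue_max)
        test_preds = {p: s for p, s in test_preds.items() if p in test_truth}
    elif cfg.mode == "meta_embedding":
        _, _, test_preds = _meta_route(cfg, split, directions)
    elif cfg.mode == "backbone_only":
        _, test_preds = _backbone_route(cfg, split, directions)
    elif cfg.mode == "meta_plus_homology":
        _, valid_meta, test_meta = _meta_route(cfg, split, directions)
        homol = bitscore_transfer(hits, train_ann, evalue_max=cfg.evalue_max)
        valid_hom = {p: s for p, s in homol.items() if p in valid_truth}
        test_hom = {p: s for p, s in homol.items() if p in test_truth}
        if cfg.alpha is not None:
            alpha = cfg.alpha
        else:
            alpha, _f = grid_search_alpha(valid_meta, valid_hom, valid_truth, dag)
        test_preds = combine(test_meta, test_hom, alpha)
    else:  # pragma: no cover - guarded by PipelineConfig
        raise ValueError(cfg.mode)

    ic = estimate_ic(dag, train_ann)
    result = evaluate(test_preds, test_truth, dag, ic=ic)

    manifest = None
    if cfg.out_dir is not None:
        manifest = _persist(cfg, test_preds, result, alpha)
    return PipelineResult(predictions=test_preds, result=result, alpha=alpha,
                          manifest=manifest)


def _persist(cfg: PipelineConfig, preds, result: EvalResult, alpha):
    from pathlib import Path

    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pred_path = out / "predictions.tsv"
    write_predictions(preds, pred_path)
    report_path = out / "evaluation.json"
    report = result.as_dict()
    if alpha is not None:
        report["alpha"] = alpha
    report_path.write_text(json.dumps(report, indent=2))

    def sha256(p):
        return hashlib.sha256(p.read_bytes()).hexdigest()

    manifest = {
        "version": __version__,
        "mode": cfg.mode,
        "seed": cfg.seed,
        "config": {
            k: v for k, v in dataclasses.asdict(cfg).items() if k != "out_dir"
        },
        "outputs": {
            "predictions.tsv": sha256(pred_path),
            "evaluation.json": sha256(report_path),
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
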