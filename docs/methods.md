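# Methods notes

This note records the models and procedures protfun implements, the
parameters that matter, the choices made where the design was genuinely
open, and what the synthetic test world does and does not establish.

## Ontology handling

GO namespaces are rooted DAGs; a protein annotated with a term implicitly
carries every ancestor (true-path rule), and a predictor's output must obey
the same closure at every score threshold.

* **Parent relation.** Only `is_a` edges define parenthood by default.
  `part_of` can be enabled (`load_obo(..., use_part_of=True)`) but is off
  because the two relations have different semantics and most
  protein-centric benchmarks propagate over `is_a` alone.
* **Score propagation** uses the max rule: each term's score becomes the
  maximum over itself and all scored descendants. This is the minimal
  monotone repair — it is idempotent, never lowers a score, and makes every
  threshold slice upward-closed.
* **Information content.** IC(f) = −log Pb(f | parents(f)), where Pb is the
  fraction of proteins carrying all direct parents of f that also carry f,
  estimated from propagated training annotations. The log is natural by
  default (configurable; base 2 gives bits). When either count is zero,
  add-one smoothing ((c+1)/(n+1)) keeps IC finite, which keeps Smin finite
  on sparse toy data. IC is clamped at ≥ 0; note that conditional IC need
  not decrease along parent edges, and we assert only non-negativity.

## Corpus preparation

Cross-split duplicate sequences (exact string equality on uppercased
sequences) are removed in a fixed order that always preserves the test
set: train-vs-test first, then valid-vs-test, then valid-vs-train.
Within-split duplicates are retained. The label vocabulary keeps terms
annotated (after propagation) in at least `min_proteins` training proteins
— 50 by default, the value appropriate for corpora of tens of thousands of
proteins; desk-scale synthetic runs lower it proportionally (the pipeline
exposes `min_label_proteins`). Counting propagated rather than raw
annotations matches the closure semantics the evaluation uses.

## Slicing

Windows of `window` = 500 residues without overlap; the last window may be
short. A bridging ("additional") slice of exactly `2 × bridge` = 500
residues spans each boundary whose two windows both have length ≥ `bridge`
= 250 — since only the final window can be short, the condition binds only
on the last pair (a 200-residue tail therefore produces no bridge). All
slices inherit the parent's labels. Bridges are built only between
consecutive windows.

## PAM augmentation

Each augmented copy of a length-L protein receives `round(L × k)`
substitution events. An event picks a position uniformly **with
replacement** and redraws the residue from the substitution-matrix column
of the residue **currently** there, so later events see earlier mutations —
the natural reading of sequential point-accepted mutations. Identity draws
count as events (the matrix diagonal dominates at ≈ 0.99), so k = 2 changes
≈ 2% of positions: per site approximately 1 − exp(−k·q) with q ≈ 0.01 the
per-event change probability. Events landing on non-standard letters
(X, B, Z, J, U, O) are consumed without effect. Augmentation is offline
(copies materialized once, ids suffixed `#augN`, labels copied verbatim)
and reproducible from the config seed via per-copy spawned RNG streams.

The bundled matrix (`data/pam1_synthetic.txt`) is a **synthetic**
PAM1-style matrix: Dayhoff's published per-residue retention probabilities
on the diagonal (these alone fix the ≈ 1% expected change per event under
Dayhoff composition, hence the ≈ 2% regime at k = 2), with off-diagonal
mass allocated proportionally to amino-acid background frequency rather
than Dayhoff's empirical exchange counts. Any column-stochastic 20×20
matrix with a dominant diagonal is accepted in its place; statistics that
depend only on column off-diagonal mass are unaffected by the synthetic
off-diagonal structure.

## Embedding

The embedder is a contract — `dim` plus deterministic
`embed(sequence, terms=()) → R^dim` — so the pipeline is independent of any
particular encoder. The shipped `MockEmbedder` hashes 3-mers into seeded
Gaussian features and can add per-term "signal" directions from slice
metadata, which plants recoverable structure for learning tests. Protein
representations are the unweighted elementwise mean over all slices;
bridging slices count equally (they are legitimate views of the sequence).
Embeddings are not L2-normalized before averaging (no normalization flag is
baked into the mean; an adapter may normalize internally). A config schema
for a real fine-tuned transformer adapter is recorded in
`embed.BACKBONE_ADAPTER_CONFIG`; shipping one is out of scope.

## Meta-classifier

One hidden layer of `hidden_dim` = 1000 ReLU units, sigmoid output per
label, mean binary cross-entropy, Adam. Unstated protocol details are fixed
at common defaults: lr 1e−3, batch size 32, early-stopping patience 5,
LR-on-plateau patience 3 with factor 0.1, validation loss as the monitored
quantity, best-validation weights restored. `max_epochs` = 100. The
implementation is plain numpy (forward, hand-derived gradients, Adam);
at these layer sizes that is fast, dependency-light, and bit-reproducible
from the seed. No threshold is baked into the model — thresholding belongs
to the evaluation grid. The "backbone only" ablation path trains the same
architecture on slice embeddings with inherited slice labels and averages
per-slice score vectors per protein.

## Homology transfer

Hits are consumed from BLAST outfmt-6 tables (running the aligner is
external; the reference setting is `blastp ... -outfmt 6 -evalue 0.001`).
Retained hits satisfy E ≤ `evalue_max` (default 0.001); multiple HSPs per
(query, subject) collapse to the maximum bitscore so a single homolog is
not double-counted; self-hits can be excluded by id (recommended when
scoring training-set queries). The bitscore-weighted score is a convex
combination over retained subjects, so S(p, f) ∈ (0, 1] with S = 1 iff
every retained hit carries f, and propagated subject annotations make the
output automatically ancestor-monotone. The top-hit baseline assigns 1.0 to
every term of the best subject (ties: lowest e-value, then lexicographic
id); the naive baseline scores each term by its training relative
frequency.

## Ensemble

S = α·y_A + (1−α)·y_B over the union of keys, missing side treated as 0 —
conservative for the support mismatch between a closed classifier
vocabulary and open homology transfer. α ∈ {0, 0.01, …, 1} by grid search
on validation Fmax (ties toward smaller α, for reproducibility); raw scores
are combined first and propagated before evaluation. Endpoints return the
corresponding component bit-exactly.

## Evaluation conventions

* τ grid 0.00 … 1.00, step 0.01; at τ = 0 every vocabulary term counts as
  predicted for every protein.
* The namespace root is excluded from predicted and true sets (it is
  trivially true); a flag restores it.
* pr(τ) averages over the m(τ) proteins with ≥ 1 prediction; where
  m(τ) = 0, pr is reported as 0 and the threshold is skipped in the Fmax
  search (0/0 is undefined).
* n_e counts only proteins with ≥ 1 ground-truth term in the evaluated
  namespace; others are excluded with a warning.
* AuPRC integrates over the observed recall range only, collapsing
  duplicate recalls to their best precision; curves with a single distinct
  recall get area 0 (this makes a perfect predictor's area degenerate —
  Fmax and Smin are the limits to check there). IAuPRC applies the
  right-to-left precision running max before the identical integration, so
  IAuPRC ≥ AuPRC on every curve.
* Fmax and Smin ties break toward the smallest threshold.

## Synthetic world

`synth` generates: single-root random DAGs (each term parented by 1–2
earlier terms); i.i.d. sequences with Dayhoff background composition,
lengths uniform in a configurable range; Bernoulli per-(protein, term)
annotations at `annotation_rate` = 0.15, propagated; hit tables whose hit
probability rises with label-set Jaccard overlap (1 − (1 − hit_rate)^(1+9J),
so a label twin is hit almost surely) with bitscores increasing and
e-values decreasing in overlap; and linear-additive planted embeddings
(sum of per-term directions plus Gaussian noise, σ = 0.1 by default).
All generators are pure functions of the seeded config.

What this world does **not** emulate: real GO topology and depth, sequence
homology (sequences are i.i.d., so the mock embedder carries label signal
only through planted directions), evidence codes, and realistic annotation
sparsity. Passing tests therefore certify the algorithmic machinery —
closure semantics, metric definitions, training protocol, ensembling — not
predictive performance on real proteomes.

## Problem sizes

Defaults used in tests and examples are desk-scale by design: toy DAGs of
≤ 30 terms, tens to hundreds of proteins, embedding dimension 32–128,
hidden layers 100–1000. The oracle-equivalence suites run 100 randomized
instances; the augmentation-rate estimate uses 1,000 proteins of lengths
100–1,000. These sizes make every check exact or tightly statistical while
keeping the full suite in seconds to minutes.

## Known limitations

* No real transformer backbone is shipped; the embedder contract is the
  seam where one plugs in.
* OBO support covers the 1.2 flat-file core (id, name, namespace, is_a,
  alt_id, is_obsolete, optional part_of); cross-namespace links and
  evidence codes are out of scope.
* The IC estimator's parent-conjunction count is O(proteins × terms) in the
  worst case — fine at corpus scale, not tuned for the full GO with
  millions of annotations.
* Whether summed (rather than best) HSP bitscores should weight homology
  transfer is an open modelling question; best-HSP is the default here.
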