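# Methods

This note records the models, procedures, and design choices behind
`cause-al`: what the package computes, under which assumptions, and what the
synthetic experiments can and cannot show.

## Problem setting

The target task is clinical named-entity recognition (NER): locating and
typing mentions of *problems*, *treatments*, and *tests* in pre-tokenized
clinical sentences, encoded with BIO tags. Building such taggers requires
expensive expert annotation, so the package implements pool-based active
learning (AL): the learner repeatedly chooses which unlabeled sentences an
annotator should label next, aiming for a better model at a fixed annotation
budget than passive (random) sampling would give.

Three querying engines are provided:

- **Random** — uniform sampling without replacement; the passive baseline.
- **Uncertainty** — least-confidence (LC) sampling: rank unlabeled sentences
  by `LC(x) = 1 − P(y* | x)`, the complement of the conditional probability
  of the Viterbi-best tag sequence under the current model, and take the top
  batch.
- **CAUSE** (Clustering And Uncertainty Sampling Engine) — uncertainty plus
  representativeness. A fixed clustering of the pool is computed once before
  the loop. At each round, every cluster with at least one unlabeled
  sentence receives a score — the mean LC of its unlabeled members (AUCS,
  the default), their max (MUCS), or a random value (RCS) — and the top `x`
  clusters (`x` = batch size) each contribute their single most-uncertain
  unlabeled sentence, ordered by cluster rank. A batch therefore never
  contains two sentences from the same cluster, which plain LC sampling
  cannot guarantee on pools full of near-duplicate sentences.

## The CRF tagger

The tagger is a linear-chain conditional random field written directly on
numpy/scipy, because the querying engines need the exact normalized
probability of the best path — not just a decoded sequence.

- **Parameterization.** Per-token indicator features with one weight per
  (feature, label); a shared label-transition matrix; a start-of-sentence
  bias. Illegal BIO transitions (`I-x` not preceded by `B-x`/`I-x`) carry
  hard `−inf` masks in both training and decoding, so predictions are
  well-formed by construction.
- **Features.** The full set: lowercased word forms in a ±2 window with
  boundary markers, 3/4-character prefixes and suffixes, and orthographic
  flags (capitalized, all-digits, contains-digit, punctuation). A reduced
  set (±1 window plus flags) is used for large simulation sweeps where
  hundreds of retrains are needed.
- **Training.** L2-penalized maximum conditional likelihood via L-BFGS
  (penalty weight 0.1 by default — AL training sets are small, so the
  regularization is kept light), with exact forward–backward gradients.
  Training is deterministic given the input order and hyperparameters.
  Inside the AL loop each retrain warm-starts from the previous weights
  with a lower iteration cap (default 25; 12 in the large sweeps), since
  the training set grows by only one small batch per round.
- **Confidence.** `best_path_prob = exp(score(y*) − log Z)` with `log Z`
  from the forward recursion. LC is `1 − best_path_prob`, unnormalized by
  length; a length-normalized variant (`1 − P^{1/L}`) is available behind a
  flag for sensitivity analysis, since whole-sequence probabilities decay
  mechanically with sentence length.

Decode probabilities are verified against exhaustive path enumeration on
small label sets to 1e−9.

## Pool clustering

Clustering is a one-time preprocessing step over unlabeled text only:

1. **Topic estimation**: latent Dirichlet allocation (scikit-learn, batch
   variational EM) fitted on whole documents — document-level samples give
   more coherent topics than individual ~11-word sentences. The number of
   topics `K` defaults to 50 and should be set near the expected number of
   semantic themes; the synthetic experiments use `K` slightly above the
   number of generating topics.
2. **Sentence inference**: each sentence is mapped to a K-dimensional topic
   probability vector; out-of-vocabulary tokens are ignored, and an
   entirely-OOV sentence receives the uniform vector with an explicit flag.
3. **Similarity**: cosine similarity between all sentence pairs
   (symmetrized, unit diagonal).
4. **Affinity propagation** over the similarity matrix, preference set to
   the median pairwise similarity and damping 0.9 (retried once at 0.95 on
   non-convergence, then failing loudly). AP chooses exemplars and the
   cluster count on its own, which suits pools whose number of sentence
   families is unknown a priori.

The clustering is never updated during the AL loop. Cluster quality is
tracked only qualitatively (majority-vote purity against the generator's
latent topics on synthetic pools, with a 0.6 regression floor); no
quantitative cluster tuning is attempted.

## Simulation protocol

One run mimics a 120-minute annotation session at roughly one word per
second:

- start from 5 sentences chosen without a model (uniformly for
  Random/Uncertainty; for CAUSE, by repeatedly drawing a random cluster
  without replacement and a random sentence within it);
- loop: query a batch of 5, reveal gold annotations (the simulated
  annotator is error-free by default; an optional span-boundary jitter
  supports robustness studies), retrain the CRF, re-score the remaining
  pool for LC, and measure exact-match F on a held-out test set;
- stop after the first retrain whose training set reaches ≥ 7,200 words.

Annotation cost is the cumulative word count of the training set. The test
set is never queried, trained on, or LC-scored. Cluster scores are computed
over *unlabeled* cluster members only — scoring over already-annotated
sentences would keep re-selecting exhausted clusters. If fewer clusters than
the batch size still hold unlabeled sentences, the remainder of the batch
falls back to plain LC ranking. All ties (LC, cluster score) break by
ascending sentence id for determinism, and each run draws from a single
seeded generator.

K-fold cross-validation (default 5 folds of near-equal size from the
deduplicated corpus) runs each fold as test against the remaining folds as
pool, then averages the fold curves by linear interpolation onto the union
of their cost grids, restricted to the range covered by every fold — fold
batch word counts differ, so curves are not defined on a common grid
natively.

## Evaluation

- **F-measure** uses exact span matching: a predicted span is correct only
  if start, end, and entity type all match a gold span, each gold span
  matched at most once (the primary criterion of the i2b2-era shared
  tasks). An overlap-based variant is deliberately not implemented.
- **ALC** (area under the learning curve) is the trapezoidal area of the
  curve between its first and last cost points divided by a maximum area:
  the same cost span times the best achievable F-measure, 0.75 by default —
  a model trained within a 120-minute budget does not approach perfect F,
  so normalizing by 1.0 would compress all scores. Note ALC can exceed 1
  when a curve runs above `best_f`, as happens on the easier synthetic
  task.
- **Session metrics** aggregate timed annotation logs into counts, speed
  (entities/min, words/min), density, and quality (exact-match F against
  gold). Ratios are kept at full precision internally; reporting rounds
  half-up to 2 decimals.

## Synthetic corpus generator

Real clinical corpora are access-restricted, so the generator produces a
stand-in whose *structure* matches what the querying engines rely on:
recurring sentence families ("Dulcolax 10 mg p.o. q. day") that differ
mainly in their entity fillers.

- Each of `n_topics` (default 10) latent topics owns a context vocabulary,
  per-type entity lexicons, and `templates_per_topic` (default 4) fixed
  slot templates in one of three styles (medication list, problem
  statement, lab result). Sentences instantiate a template, filling entity
  slots from the topic lexicon and numeric slots from a dose/value list;
  a small per-token noise rate (2%) substitutes context words.
- Entity lexicon entries carry type-specific morphology — capitalized drug
  names in -ol/-ine/-ax, disorders in -itis/-emia/-osis, analytes in
  -in/-ase/-crit — mirroring the orthographic cues real clinical NER
  models exploit, and giving affix features a way to generalize to unseen
  fillers.
- Documents draw 2–3 topics by Zipf-skewed popularity with Dirichlet
  mixture weights, so a few sentence families dominate the pool — the
  regime where diversity-aware querying should pay off.
- Target statistics default to a typical clinical concept corpus profile:
  11 words/sentence, 1.27 entities/sentence, entity density 0.24. After
  templates are built, an init-time calibration computes the *expected*
  corpus statistics analytically (over templates weighted by the marginal
  sentence-topic distribution) and nudges slot lengths and context-word
  counts until expectations sit on the targets; realized corpora land
  within a few percent.

What the generator does **not** emulate: real clinical vocabulary and
spelling variation, annotation-guideline boundary subtleties, sentence
families without any latent-topic signature, and annotator disagreement.
Consequently the synthetic NER task is easier than the real one (F-measures
saturate near 0.99 within a 7,200-word budget, where real clinical text at a
comparable budget typically sits near 0.7), and simulation results support
*qualitative* conclusions — ordering and shape of learning curves — not
absolute F or ALC levels. Deduplication also enriches entity-bearing
sentences (duplicates are disproportionately short boilerplate), so a
deduplicated pool runs slightly denser than the raw generation targets.

## Problem sizes

The shipped experiments use: a ~5,000-sentence deduplicated pool with a
~1,000-sentence test split for the full-budget (7,200-word) five-seed
CAUSE-vs-Random comparison with the reduced feature set; and a
~2,000-sentence pool with a 3,000-word budget and three seeds per method in
the acceptance script, which additionally runs the Uncertainty baseline.
These sizes keep a full desk run in the minutes range while leaving the
pool 7–8× larger than the number of sentences ever annotated.

## Known limitations

- LC is length-biased (longer sentences get higher LC); the original
  engines share this property, and the optional normalized variant exists
  for exactly this analysis.
- AP on an M×M similarity matrix costs O(M²) memory and time per iteration;
  pools beyond ~20k sentences need a different clustering backend.
- Warm-started retrains cap L-BFGS iterations, so late-loop models can be
  slightly under-converged relative to a cold fit; cold and warm fits agree
  on predictions when run to convergence.
- The annotator model is noise-free and cost-free per word; real annotation
  time varies per sentence and annotator, which simulation word budgets do
  not capture.
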