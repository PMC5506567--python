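"""Pool-based active-learning simulation and cross-validation harness.

One simulation run plays the annotation study with a perfect oracle: start
from a handful of randomly selected sentences, then loop — query a batch
with the chosen engine, reveal the gold spans (simulating the annotator),
retrain the CRF, score the remaining pool for least confidence, and measure
test-set F.  Annotation cost is the number of words in the training set, and
the run stops after the first retrain at or beyond the word budget (the
default 7,200 words mimics a 120-minute session at roughly one word per
second).

The test set is never queried, never trained on, and never used for LC
scoring.  An optional annotator-noise model (span boundary jitter) supports
robustness studies; the default oracle is error-free.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from . import crf, querying
from .clustering import Clustering, ClusteringParams
from .corpus import Corpus, EntitySpan, LabeledSentence, bio_decode, dedup_and_split
from .crf import CRFHyperparams
from .evaluation import LearningCurve, average_curves, evaluate_ner

METHODS = ("random", "uncertainty", "cause")


@dataclass
class SimulationConfig:
    """Protocol parameters for one simulated annotation study."""

    method: str = "random"
    schema: str = "AUCS"  # cluster scoring, cause only
    batch_size: int = 5
    initial_size: int = 5
    stop_word_budget: int = 7200
    k_folds: int = 5
    seed: int = 0
    length_normalized_lc: bool = False
    annotator_noise: float = 0.0  # per-span boundary jitter probability
    tagger: CRFHyperparams = field(default_factory=CRFHyperparams)
    clustering: ClusteringParams = field(default_factory=ClusteringParams)

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"unknown method {self.method!r}; expected one of {METHODS}")
        if self.schema not in querying.SCHEMAS:
            raise ValueError(f"unknown schema {self.schema!r}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.initial_size < 1:
            raise ValueError("initial_size must be >= 1")
        if self.stop_word_budget < 0:
            raise ValueError("stop_word_budget must be nonnegative")


@dataclass
class SimulationResult:
    curve: LearningCurve
    query_log: list[dict]
    config: SimulationConfig


def _noisy_spans(
    sentence: LabeledSentence, noise: float, rng: np.random.Generator
) -> list[EntitySpan]:
    """Jitter span boundaries by ±1 token with probability ``noise`` per span."""
    out: list[EntitySpan] = []
    n = len(sentence.tokens)
    last_end = 0
    for sp in sentence.spans:
        start, end = sp.start, sp.end
        if noise and rng.random() < noise:
            start = max(last_end, start + int(rng.integers(-1, 2)))
            end = min(n, max(start + 1, end + int(rng.integers(-1, 2))))
        out.append(EntitySpan(start, end, sp.etype))
        last_end = end
    return out


def run_simulation(
    pool: Corpus,
    test: Corpus,
    cfg: SimulationConfig,
    clustering: Clustering | None = None,
) -> SimulationResult:
    """Run one active-learning simulation and return its learning curve.

    ``clustering`` (precomputed over the pool) is required when
    ``cfg.method == "cause"``.  Deterministic under a fixed config.
    """
    pool_ids = {s.sid for s in pool}
    if pool_ids & {s.sid for s in test}:
        raise ValueError("pool and test sets must be disjoint")
    if cfg.method == "cause" and clustering is None:
        raise ValueError("method 'cause' needs a precomputed pool clustering")

    rng = np.random.default_rng(cfg.seed)
    by_sid = pool.by_sid()
    test_sents = list(test)
    state = querying.QueryState.fresh(pool_ids, clustering=clustering, rng_seed=cfg.seed)

    # Fixed feature vocabulary over all unlabeled text (pool + test), so the
    # integer feature arrays can be indexed once and reused across retrains.
    feature_index: dict[str, int] = {}
    pool_sents = list(pool)
    pool_idx = dict(
        zip(
            (s.sid for s in pool_sents),
            crf.index_sentences(pool_sents, feature_index, cfg.tagger.feature_set),
        )
    )
    test_idx = crf.index_sentences(test_sents, feature_index, cfg.tagger.feature_set)

    init_mode = "cause" if cfg.method == "cause" else "random"
    initial = querying.initial_sample(state, cfg.initial_size, mode=init_mode, rng=rng)
    state.mark_labeled(initial)

    # the training set only grows; feature bags are sentence-intrinsic
    train_sents: list[LabeledSentence] = []
    train_idx: list = []

    def annotate(sids: list[str]) -> None:
        for sid in sids:
            s = by_sid[sid]
            if cfg.annotator_noise:
                s = replace(s, spans=_noisy_spans(s, cfg.annotator_noise, rng))
            train_sents.append(s)
            train_idx.append(pool_idx[sid])

    def retrain(prev=None):
        return crf.train(
            train_sents,
            cfg.tagger,
            init_model=prev,
            feature_index=feature_index,
            pre_indexed=train_idx,
        )

    annotate(initial)
    model = retrain()

    def test_f() -> float:
        preds = crf.decode_indexed(model, test_idx)
        pred_sents = [
            replace(s, spans=bio_decode(p.tags)) for s, p in zip(test_sents, preds)
        ]
        return evaluate_ner(test_sents, pred_sents).f_measure

    words = sum(s.n_words for s in train_sents)
    points: list[tuple[float, float]] = [(float(words), test_f())]
    query_log: list[dict] = [
        {
            "iteration": 0,
            "method": cfg.method,
            "schema": cfg.schema if cfg.method == "cause" else "",
            "sid": sid,
            "cluster": clustering.labels[sid] if clustering else -1,
            "lc": float("nan"),
            "n_words": by_sid[sid].n_words,
        }
        for sid in initial
    ]

    iteration = 0
    while words < cfg.stop_word_budget and state.unlabeled_ids:
        iteration += 1
        if cfg.method in ("uncertainty", "cause"):
            unlabeled = sorted(state.unlabeled_ids)
            preds = crf.decode_indexed(model, [pool_idx[sid] for sid in unlabeled])
            state.uncertainty = {
                sid: crf.least_confidence(p, cfg.length_normalized_lc)
                for sid, p in zip(unlabeled, preds)
            }
        x = min(cfg.batch_size, len(state.unlabeled_ids))
        if cfg.method == "cause":
            batch = querying.select_batch_cause(state, x, schema=cfg.schema, rng=rng)
        elif cfg.method == "uncertainty":
            batch = querying.select_batch_uncertainty(state, x)
        else:
            batch = querying.select_batch_random(state, x, rng=rng)

        for sid in batch:
            query_log.append(
                {
                    "iteration": iteration,
                    "method": cfg.method,
                    "schema": cfg.schema if cfg.method == "cause" else "",
                    "sid": sid,
                    "cluster": clustering.labels[sid] if clustering else -1,
                    "lc": state.uncertainty.get(sid, float("nan")),
                    "n_words": by_sid[sid].n_words,
                }
            )
        state.mark_labeled(batch)
        annotate(batch)
        model = retrain(prev=model)
        words = sum(s.n_words for s in train_sents)
        points.append((float(words), test_f()))

    if words < cfg.stop_word_budget:
        warnings.warn(
            f"pool exhausted at {words} words, short of the "
            f"{cfg.stop_word_budget}-word budget; curve ends early"
        )
    return SimulationResult(
        curve=LearningCurve(points=points, cost_unit="words"),
        query_log=query_log,
        config=cfg,
    )


def cross_validate(
    corpus: Corpus,
    cfg: SimulationConfig,
    clusterings: list[Clustering] | None = None,
) -> tuple[list[SimulationResult], LearningCurve]:
    """K-fold protocol: each fold serves once as test, the rest as pool.

    Returns the per-fold results and the fold-averaged curve (linear
    interpolation onto the union cost grid, restricted to the range covered
    by every fold).  For ``method="cause"`` pass one precomputed pool
    clustering per fold, in fold order.
    """
    if cfg.k_folds < 2:
        raise ValueError("need at least 2 folds")
    folds = dedup_and_split(corpus, cfg.k_folds, cfg.seed)
    results: list[SimulationResult] = []
    for i, fold in enumerate(folds):
        test = corpus.subset(fold)
        pool_ids = [sid for j, f in enumerate(folds) if j != i for sid in f]
        pool = corpus.subset(pool_ids)
        clustering = clusterings[i] if clusterings is not None else None
        fold_cfg = replace(cfg, seed=cfg.seed + i)
        results.append(run_simulation(pool, test, fold_cfg, clustering=clustering))
    averaged = average_curves([r.curve for r in results])
    return results, averaged
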