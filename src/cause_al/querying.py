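"""Querying engines: Random, Uncertainty (LC), and CAUSE.

CAUSE (Clustering And Uncertainty Sampling Engine) combines uncertainty with
representativeness.  Plain uncertainty sampling tends to fill a batch with
near-duplicate sentences that share both context and uncertainty score;
annotating several of them in one batch is wasted effort.  CAUSE instead

1. scores each cluster of the precomputed pool clustering from the LC
   uncertainty of its sentences (MUCS: cluster max; AUCS: cluster average;
   RCS: a random score),
2. takes the top ``x`` clusters (``x`` = batch size), and
3. returns each cluster's most uncertain sentence as its representative,
   ordered by cluster rank —

so a batch never contains two sentences from the same cluster (while at
least ``x`` clusters still hold unlabeled sentences).

Cluster scores are computed over unlabeled sentences only: scoring over
already-annotated ones would keep re-selecting exhausted clusters.  All ties
(equal LC, equal cluster score) break by ascending id for determinism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .clustering import Clustering


@dataclass
class QueryState:
    """Labeled/unlabeled partition of the pool plus per-sentence LC scores."""

    labeled_ids: set[str]
    unlabeled_ids: set[str]
    uncertainty: dict[str, float] = field(default_factory=dict)
    clustering: Clustering | None = None
    rng_seed: int = 0

    def __post_init__(self) -> None:
        overlap = self.labeled_ids & self.unlabeled_ids
        if overlap:
            raise ValueError(f"ids both labeled and unlabeled: {sorted(overlap)[:5]}")

    @classmethod
    def fresh(
        cls,
        pool_ids,
        clustering: Clustering | None = None,
        rng_seed: int = 0,
    ) -> "QueryState":
        return cls(
            labeled_ids=set(),
            unlabeled_ids=set(pool_ids),
            clustering=clustering,
            rng_seed=rng_seed,
        )

    def mark_labeled(self, sids) -> None:
        sids = list(sids)
        missing = [s for s in sids if s not in self.unlabeled_ids]
        if missing:
            raise KeyError(f"not in unlabeled pool: {missing[:5]}")
        self.unlabeled_ids.difference_update(sids)
        self.labeled_ids.update(sids)


@dataclass
class ClusterScore:
    cluster_id: int
    score: float
    schema: str


SCHEMAS = ("MUCS", "AUCS", "RCS")


def _rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def _unlabeled_by_cluster(state: QueryState) -> dict[int, list[str]]:
    if state.clustering is None:
        raise ValueError("CAUSE requires a precomputed pool clustering")
    out: dict[int, list[str]] = {}
    for sid in sorted(state.unlabeled_ids):
        out.setdefault(state.clustering.labels[sid], []).append(sid)
    return out


def score_clusters(
    state: QueryState, schema: str = "AUCS", rng=None
) -> list[ClusterScore]:
    """One score per cluster that still holds unlabeled sentences.

    MUCS: highest LC among the cluster's unlabeled sentences.
    AUCS: average LC over the cluster's unlabeled sentences.
    RCS:  uniform random score (every cluster equally important).
    """
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; expected one of {SCHEMAS}")
    by_cluster = _unlabeled_by_cluster(state)
    if not by_cluster:
        raise ValueError("no unlabeled sentences left to score")
    gen = _rng(state.rng_seed if rng is None else rng)
    scores: list[ClusterScore] = []
    for cid in sorted(by_cluster):
        sids = by_cluster[cid]
        if schema == "RCS":
            val = float(gen.random())
        else:
            lcs = [state.uncertainty[sid] for sid in sids]
            val = max(lcs) if schema == "MUCS" else float(np.mean(lcs))
        scores.append(ClusterScore(cluster_id=cid, score=val, schema=schema))
    return scores


def select_batch_cause(
    state: QueryState, x: int, schema: str = "AUCS", rng=None
) -> list[str]:
    """CAUSE batch: representatives of the top-``x`` clusters.

    Clusters are ranked by schema score (descending, ties by ascending
    cluster id); each contributes its highest-LC unlabeled sentence (ties by
    ascending sid).  If fewer than ``x`` clusters still hold unlabeled
    sentences, the remainder is filled by plain LC ranking — graceful
    degradation at pool exhaustion.
    """
    if x <= 0:
        raise ValueError("batch size must be >= 1")
    by_cluster = _unlabeled_by_cluster(state)
    scores = score_clusters(state, schema=schema, rng=rng)
    ranked = sorted(scores, key=lambda cs: (-cs.score, cs.cluster_id))

    batch: list[str] = []
    for cs in ranked[:x]:
        members = by_cluster[cs.cluster_id]
        batch.append(min(members, key=lambda sid: (-state.uncertainty[sid], sid)))
    if len(batch) < x:
        chosen = set(batch)
        rest = sorted(
            (sid for sid in state.unlabeled_ids if sid not in chosen),
            key=lambda sid: (-state.uncertainty[sid], sid),
        )
        batch.extend(rest[: x - len(batch)])
    return batch


def select_batch_uncertainty(state: QueryState, x: int) -> list[str]:
    """Top-``x`` unlabeled sentences by descending LC (ties by ascending sid)."""
    if x <= 0:
        raise ValueError("batch size must be >= 1")
    if not state.unlabeled_ids:
        raise ValueError("no unlabeled sentences left")
    ranked = sorted(state.unlabeled_ids, key=lambda sid: (-state.uncertainty[sid], sid))
    if x > len(ranked):
        warnings.warn(
            f"requested batch of {x} but only {len(ranked)} unlabeled sentences remain"
        )
    return ranked[:x]


def select_batch_random(state: QueryState, x: int, rng=None) -> list[str]:
    """Uniform sample without replacement from the unlabeled pool."""
    if x <= 0:
        raise ValueError("batch size must be >= 1")
    pool = sorted(state.unlabeled_ids)
    if not pool:
        raise ValueError("no unlabeled sentences left")
    if x > len(pool):
        warnings.warn(
            f"requested batch of {x} but only {len(pool)} unlabeled sentences remain"
        )
        x = len(pool)
    gen = _rng(state.rng_seed if rng is None else rng)
    idx = gen.choice(len(pool), size=x, replace=False)
    return [pool[i] for i in idx]


def initial_sample(
    state: QueryState, n: int, mode: str = "random", rng=None
) -> list[str]:
    """Seed selection before any model (and hence any LC score) exists.

    mode="random": uniform ``n`` sentences.  mode="cause": repeat ``n``
    times — pick a uniformly random cluster (without replacement across
    draws while unused clusters remain), then a uniformly random unlabeled
    sentence within it.
    """
    if n > len(state.unlabeled_ids):
        raise ValueError(f"cannot draw {n} sentences from a pool of {len(state.unlabeled_ids)}")
    gen = _rng(state.rng_seed if rng is None else rng)
    if mode == "random":
        pool = sorted(state.unlabeled_ids)
        idx = gen.choice(len(pool), size=n, replace=False)
        return [pool[i] for i in idx]
    if mode != "cause":
        raise ValueError(f"unknown initial sampling mode {mode!r}")

    by_cluster = _unlabeled_by_cluster(state)
    chosen: list[str] = []
    unused: set[int] = set()
    for _ in range(n):
        nonempty = sorted(c for c in by_cluster if by_cluster[c])
        if not nonempty:
            break
        candidates = sorted(c for c in unused if by_cluster[c])
        if not candidates:  # every cluster used once (or exhausted): start over
            unused = set(nonempty)
            candidates = nonempty
        cid = candidates[int(gen.integers(0, len(candidates)))]
        unused.discard(cid)
        members = by_cluster[cid]
        sid = members[int(gen.integers(0, len(members)))]
        members.remove(sid)
        chosen.append(sid)
    return chosen
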