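"""Topic-based sentence clustering: the preprocessing stage of CAUSE.

The pipeline groups semantically similar sentences so that a querying batch
can draw at most one representative per group:

1. LDA topic estimation on whole documents (document-level samples give more
   coherent topics than individual short sentences);
2. LDA inference assigning each sentence a K-dimensional topic-probability
   vector;
3. cosine similarity between every sentence pair;
4. affinity propagation (AP) over the similarity matrix, which picks
   exemplars and assigns every sentence to one.

Only unlabeled text is used throughout — no annotation leaks into the
clustering.  The clustering is computed once over the full pool before the
active-learning loop starts and is never updated.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import AffinityPropagation
from sklearn.decomposition import LatentDirichletAllocation
from sklearn.exceptions import ConvergenceWarning
from sklearn.metrics.pairwise import cosine_similarity

from .corpus import Corpus, LabeledSentence


@dataclass
class TopicModel:
    """Fitted LDA model plus the vocabulary it was estimated with."""

    K: int
    vocabulary: dict[str, int]
    lda: LatentDirichletAllocation
    corpus_fingerprint: str

    @property
    def topic_word(self) -> np.ndarray:
        """(K, V) per-topic word distributions, rows summing to 1."""
        comp = self.lda.components_
        return comp / comp.sum(axis=1, keepdims=True)


@dataclass
class TopicVector:
    """Per-sentence probabilistic topic assignment."""

    probs: np.ndarray
    oov: bool = False  # true when the sentence had no in-vocabulary token

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if (self.probs < -1e-12).any() or abs(self.probs.sum() - 1.0) > 1e-8:
            raise ValueError("topic vector must be a probability distribution")


@dataclass
class SimilarityMatrix:
    """Symmetric pairwise cosine similarities with a sentence-id index."""

    values: np.ndarray
    sids: list[str]

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] != v.shape[1] or v.shape[0] != len(self.sids):
            raise ValueError("similarity matrix shape does not match index")


@dataclass
class Clustering:
    """Partition of pool sentences into exemplar-led clusters."""

    labels: dict[str, int]
    exemplars: dict[int, str]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for cid, sid in self.exemplars.items():
            if self.labels.get(sid) != cid:
                raise ValueError(f"exemplar {sid!r} not labeled with its own cluster {cid}")

    @property
    def n_clusters(self) -> int:
        return len(self.exemplars)

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for sid in sorted(self.labels):
            out.setdefault(self.labels[sid], []).append(sid)
        return out


@dataclass
class ClusteringParams:
    """Topic-model and AP settings for the preprocessing stage."""

    n_topics: int = 50
    lda_max_iter: int = 30
    damping: float = 0.9
    retry_damping: float = 0.95
    ap_max_iter: int = 300
    ap_convergence_iter: int = 15
    preference: float | None = None  # None -> median pairwise similarity
    seed: int = 0


# ---------------------------------------------------------------------------
# Topic modeling
# ---------------------------------------------------------------------------

def _count_matrix(
    token_lists: Sequence[Sequence[str]], vocabulary: dict[str, int]
) -> np.ndarray:
    X = np.zeros((len(token_lists), len(vocabulary)))
    for i, toks in enumerate(token_lists):
        for tok in toks:
            j = vocabulary.get(tok.lower())
            if j is not None:
                X[i, j] += 1.0
    return X


def fit_topics(corpus: Corpus, K: int, seed: int, lda_max_iter: int = 30) -> TopicModel:
    """Estimate K topics on whole documents (batch variational EM).

    Deterministic under a fixed seed.  Raises if K exceeds the vocabulary
    size, since no K-topic model is identifiable then.
    """
    if K < 2:
        raise ValueError("need at least 2 topics")
    if not corpus.documents:
        raise ValueError("need at least 1 document")
    by_sid = corpus.by_sid()
    doc_tokens = [
        [t.lower() for sid in sids for t in by_sid[sid].tokens]
        for sids in corpus.documents.values()
    ]
    vocabulary: dict[str, int] = {}
    for toks in doc_tokens:
        for tok in toks:
            vocabulary.setdefault(tok, len(vocabulary))
    if K > len(vocabulary):
        raise ValueError(f"K={K} exceeds vocabulary size {len(vocabulary)}")
    X = _count_matrix(doc_tokens, vocabulary)
    lda = LatentDirichletAllocation(
        n_components=K,
        learning_method="batch",
        max_iter=lda_max_iter,
        random_state=seed,
    )
    lda.fit(X)
    fingerprint = hashlib.sha256(
        ("|".join(corpus.documents) + f"|{int(X.sum())}").encode()
    ).hexdigest()[:16]
    return TopicModel(K=K, vocabulary=vocabulary, lda=lda, corpus_fingerprint=fingerprint)


def infer_topics(
    model: TopicModel, sentences: Sequence[LabeledSentence]
) -> list[TopicVector]:
    """Sentence-level LDA inference (batched).

    Out-of-vocabulary tokens are ignored; a sentence that is entirely OOV
    gets the uniform 1/K vector with its ``oov`` flag set.
    """
    X = _count_matrix([s.tokens for s in sentences], model.vocabulary)
    empty = X.sum(axis=1) == 0
    probs = np.full((len(sentences), model.K), 1.0 / model.K)
    if (~empty).any():
        probs[~empty] = model.lda.transform(X[~empty])
    probs /= probs.sum(axis=1, keepdims=True)
    return [TopicVector(probs[i], oov=bool(empty[i])) for i in range(len(sentences))]


def infer_sentence_topics(model: TopicModel, sentence: LabeledSentence) -> TopicVector:
    """Topic-probability vector for a single sentence."""
    return infer_topics(model, [sentence])[0]


# ---------------------------------------------------------------------------
# Similarity and clustering
# ---------------------------------------------------------------------------

def cosine_matrix(
    vectors: Sequence[TopicVector], sids: Sequence[str] | None = None
) -> SimilarityMatrix:
    """Pairwise cosine similarity of topic vectors (symmetric, unit diagonal)."""
    if len(vectors) < 2:
        raise ValueError("need at least 2 vectors")
    V = np.stack([v.probs for v in vectors])
    norms = np.linalg.norm(V, axis=1)
    if (norms == 0).any():
        raise ValueError("zero vector has no direction; cosine undefined")
    M = cosine_similarity(V)
    M = np.clip((M + M.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(M, 1.0)
    if sids is None:
        sids = [str(i) for i in range(len(vectors))]
    return SimilarityMatrix(values=M, sids=list(sids))


def cluster_pool(sim: SimilarityMatrix, params: ClusteringParams | None = None) -> Clustering:
    """Affinity propagation over a precomputed similarity matrix.

    The preference defaults to the median pairwise similarity.  On
    non-convergence the fit is retried once with stronger damping, then fails
    loudly with diagnostics.
    """
    params = params or ClusteringParams()
    M = sim.values
    pref = params.preference
    if pref is None:
        pref = float(np.median(M[np.triu_indices_from(M, k=1)]))

    tried: list[float] = []
    for damping in (params.damping, params.retry_damping):
        tried.append(damping)
        ap = AffinityPropagation(
            affinity="precomputed",
            damping=damping,
            preference=pref,
            max_iter=params.ap_max_iter,
            convergence_iter=params.ap_convergence_iter,
            random_state=params.seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            ap.fit(M)
        centers = getattr(ap, "cluster_centers_indices_", None)
        if centers is not None and len(centers) > 0 and not (ap.labels_ == -1).any():
            labels = {sid: int(ap.labels_[i]) for i, sid in enumerate(sim.sids)}
            exemplars = {c: sim.sids[int(idx)] for c, idx in enumerate(centers)}
            return Clustering(
                labels=labels,
                exemplars=exemplars,
                params={"damping": damping, "preference": pref, "seed": params.seed},
            )
    raise RuntimeError(
        "affinity propagation failed to converge "
        f"(n={M.shape[0]}, preference={pref:.4f}, dampings tried={tried}); "
        "consider lowering the preference or raising ap_max_iter"
    )


def cluster_corpus(
    pool: Corpus,
    params: ClusteringParams,
    topic_corpus: Corpus | None = None,
) -> tuple[Clustering, TopicModel, list[TopicVector]]:
    """Full preprocessing pipeline over a pool.

    Topic estimation may use a larger unlabeled corpus (``topic_corpus``,
    e.g. pool + test text) while clustering covers the pool only.
    """
    model = fit_topics(
        topic_corpus or pool, params.n_topics, params.seed, params.lda_max_iter
    )
    sentences = list(pool)
    vectors = infer_topics(model, sentences)
    sim = cosine_matrix(vectors, sids=[s.sid for s in sentences])
    clustering = cluster_pool(sim, params)
    return clustering, model, vectors


# ---------------------------------------------------------------------------
# Sidecar persistence
# ---------------------------------------------------------------------------

def save_sidecar(
    path: str | Path,
    clustering: Clustering,
    vectors: Sequence[TopicVector],
    sids: Sequence[str],
) -> None:
    """Persist cluster assignments and topic vectors as a TSV sidecar."""
    K = len(vectors[0].probs)
    rows = {
        "sid": list(sids),
        "cluster": [clustering.labels[sid] for sid in sids],
        "exemplar": [int(clustering.exemplars[clustering.labels[sid]] == sid) for sid in sids],
    }
    for k in range(K):
        rows[f"topic_{k}"] = [float(v.probs[k]) for v in vectors]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def load_sidecar(path: str | Path) -> tuple[Clustering, dict[str, np.ndarray]]:
    """Load a clustering sidecar written by :func:`save_sidecar`."""
    df = pd.read_csv(path, sep="\t")
    labels = dict(zip(df["sid"].astype(str), df["cluster"].astype(int)))
    exemplars = {
        int(row["cluster"]): str(row["sid"])
        for _, row in df[df["exemplar"] == 1].iterrows()
    }
    topic_cols = [c for c in df.columns if c.startswith("topic_")]
    vectors = {
        str(row["sid"]): row[topic_cols].to_numpy(dtype=float)
        for _, row in df.iterrows()
    }
    return Clustering(labels=labels, exemplars=exemplars), vectors
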