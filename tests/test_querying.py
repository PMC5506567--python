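"""Querying engines: cluster scoring, batch selection, initial sampling.

The CAUSE selector is checked against an independently written brute-force
reference on random small pools.
"""

import numpy as np
import pytest

from cause_al import (
    QueryState,
    initial_sample,
    score_clusters,
    select_batch_cause,
    select_batch_random,
    select_batch_uncertainty,
)
from cause_al.clustering import Clustering


def _state(lcs: dict[str, float], labels: dict[str, int] | None = None, labeled=()):
    clustering = None
    if labels is not None:
        exemplars = {}
        for sid, cid in labels.items():
            exemplars.setdefault(cid, sid)
        clustering = Clustering(labels=labels, exemplars=exemplars)
    return QueryState(
        labeled_ids=set(labeled),
        unlabeled_ids=set(lcs) - set(labeled),
        uncertainty=lcs,
        clustering=clustering,
    )


def _reference_cause(lcs, labels, labeled, x, schema="AUCS"):
    """Literal re-implementation of the selection steps: rank clusters by
    score, take top x, pick each cluster's most uncertain unlabeled sentence."""
    unlabeled = {s: lcs[s] for s in lcs if s not in labeled}
    clusters = {}
    for sid in unlabeled:
        clusters.setdefault(labels[sid], []).append(sid)
    scored = []
    for cid, sids in clusters.items():
        vals = [unlabeled[s] for s in sids]
        score = max(vals) if schema == "MUCS" else sum(vals) / len(vals)
        scored.append((cid, score))
    scored.sort(key=lambda t: (-t[1], t[0]))
    batch = []
    for cid, _ in scored[:x]:
        batch.append(min(sorted(clusters[cid]), key=lambda s: (-unlabeled[s], s)))
    if len(batch) < x:
        rest = sorted(
            (s for s in unlabeled if s not in batch),
            key=lambda s: (-unlabeled[s], s),
        )
        batch += rest[: x - len(batch)]
    return batch


class TestScoreClusters:
    def test_mucs_and_aucs_definitions(self):
        state = _state({"a": 0.2, "b": 0.8}, {"a": 0, "b": 0})
        (m,) = score_clusters(state, "MUCS")
        (a,) = score_clusters(state, "AUCS")
        assert m.score == pytest.approx(0.8)
        assert a.score == pytest.approx(0.5)

    def test_rcs_reproducible_under_seed(self):
        state = _state({"a": 0.2, "b": 0.8}, {"a": 0, "b": 1})
        s1 = [c.score for c in score_clusters(state, "RCS", rng=7)]
        s2 = [c.score for c in score_clusters(state, "RCS", rng=7)]
        assert s1 == s2

    def test_fully_labeled_cluster_absent(self):
        state = _state(
            {"a": 0.2, "b": 0.8, "c": 0.5},
            {"a": 0, "b": 1, "c": 1},
            labeled=["a"],
        )
        scores = score_clusters(state, "AUCS")
        assert [c.cluster_id for c in scores] == [1]

    def test_no_unlabeled_sentences_rejected(self):
        state = _state({"a": 0.1}, {"a": 0}, labeled=["a"])
        with pytest.raises(ValueError):
            score_clusters(state, "AUCS")


class TestSelectBatchCause:
    def test_direct_algorithm_trace(self):
        # three clusters with AUCS scores 0.9 / 0.5 / 0.1
        lcs = {"a1": 0.9, "a2": 0.9, "b1": 0.6, "b2": 0.4, "c1": 0.1}
        labels = {"a1": 1, "a2": 1, "b1": 2, "b2": 2, "c1": 3}
        state = _state(lcs, labels)
        batch = select_batch_cause(state, 2, schema="AUCS")
        assert batch == ["a1", "b1"]  # a1 wins its tie by ascending sid

    def test_one_sentence_per_cluster_when_x_equals_clusters(self):
        lcs = {f"s{i}": i / 10 for i in range(6)}
        labels = {f"s{i}": i % 3 for i in range(6)}
        state = _state(lcs, labels)
        batch = select_batch_cause(state, 3)
        assert len({labels[s] for s in batch}) == 3

    def test_matches_bruteforce_reference_on_random_pools(self):
        rng = np.random.default_rng(0)
        for trial in range(120):
            n = int(rng.integers(2, 31))
            n_clusters = int(rng.integers(1, 7))
            sids = [f"s{i:02d}" for i in range(n)]
            lcs = {s: float(np.round(rng.random(), 3)) for s in sids}
            labels = {s: int(rng.integers(0, n_clusters)) for s in sids}
            labeled = set(
                s for s in sids if rng.random() < 0.3
            )
            if len(labeled) == n:
                labeled.pop()
            x = int(rng.integers(1, 8))
            schema = ["MUCS", "AUCS"][int(rng.integers(0, 2))]
            state = _state(lcs, labels, labeled)
            got = select_batch_cause(state, x, schema=schema)
            want = _reference_cause(lcs, labels, labeled, x, schema)
            assert got == want, f"trial {trial}"

    def test_never_two_sentences_from_same_cluster(self):
        rng = np.random.default_rng(1)
        for _ in range(30):
            n = 24
            sids = [f"s{i}" for i in range(n)]
            lcs = {s: float(rng.random()) for s in sids}
            labels = {s: int(rng.integers(0, 8)) for s in sids}
            state = _state(lcs, labels)
            batch = select_batch_cause(state, 5)
            assert len({labels[s] for s in batch}) == len(batch)

    def test_single_cluster_degenerates_to_uncertainty_for_x1(self):
        lcs = {"a": 0.3, "b": 0.9, "c": 0.5}
        state_c = _state(lcs, {s: 0 for s in lcs})
        state_u = _state(lcs)
        assert select_batch_cause(state_c, 1) == select_batch_uncertainty(state_u, 1)

    def test_nonpositive_batch_rejected(self):
        state = _state({"a": 0.5}, {"a": 0})
        with pytest.raises(ValueError):
            select_batch_cause(state, 0)


class TestSelectBatchUncertainty:
    def test_top_x_by_descending_lc(self):
        state = _state({"a": 0.9, "b": 0.1, "c": 0.5})
        assert select_batch_uncertainty(state, 2) == ["a", "c"]

    def test_equal_scores_break_by_sid(self):
        state = _state({"c": 0.5, "a": 0.5, "b": 0.5})
        assert select_batch_uncertainty(state, 2) == ["a", "b"]

    def test_matches_sort_oracle_on_random_scores(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            sids = [f"s{i:03d}" for i in range(int(rng.integers(3, 40)))]
            lcs = {s: float(np.round(rng.random(), 2)) for s in sids}
            x = int(rng.integers(1, len(sids) + 1))
            want = sorted(sids, key=lambda s: (-lcs[s], s))[:x]
            assert select_batch_uncertainty(_state(lcs), x) == want

    def test_oversized_batch_warns_and_returns_all(self):
        state = _state({"a": 0.5, "b": 0.2})
        with pytest.warns(UserWarning):
            got = select_batch_uncertainty(state, 5)
        assert got == ["a", "b"]


class TestSelectBatchRandom:
    def test_reproducible_under_seed(self):
        state = _state({f"s{i}": 0.0 for i in range(20)})
        assert select_batch_random(state, 5, rng=3) == select_batch_random(
            state, 5, rng=3
        )

    def test_first_pick_frequency_uniform(self):
        sids = [f"s{i}" for i in range(10)]
        state = _state({s: 0.0 for s in sids})
        rng = np.random.default_rng(0)
        counts = {s: 0 for s in sids}
        n = 10000
        for _ in range(n):
            counts[select_batch_random(state, 1, rng=rng)[0]] += 1
        for s in sids:
            assert abs(counts[s] / n - 0.1) < 0.01

    def test_full_pool_draw_is_permutation(self):
        sids = {f"s{i}" for i in range(8)}
        state = _state({s: 0.0 for s in sids})
        assert set(select_batch_random(state, 8, rng=1)) == sids


class TestInitialSample:
    def test_cause_mode_covers_all_clusters_without_replacement(self):
        labels = {f"s{i}": i % 5 for i in range(25)}
        state = _state({s: 0.0 for s in labels}, labels)
        chosen = initial_sample(state, 5, mode="cause", rng=0)
        assert len({labels[s] for s in chosen}) == 5

    def test_random_mode_reproducible(self):
        state = _state({f"s{i}": 0.0 for i in range(30)})
        assert initial_sample(state, 5, mode="random", rng=9) == initial_sample(
            state, 5, mode="random", rng=9
        )

    def test_cluster_first_pick_frequency_uniform(self):
        # clusters of very different sizes must be drawn uniformly
        labels = {f"s{i}": (0 if i < 40 else 1 if i < 48 else 2) for i in range(50)}
        state = _state({s: 0.0 for s in labels}, labels)
        counts = {0: 0, 1: 0, 2: 0}
        n = 6000
        rng = np.random.default_rng(5)
        for _ in range(n):
            first = initial_sample(state, 1, mode="cause", rng=rng)[0]
            counts[labels[first]] += 1
        for c in counts:
            assert abs(counts[c] / n - 1 / 3) < 0.02

    def test_oversized_request_rejected(self):
        state = _state({"a": 0.0})
        with pytest.raises(ValueError):
            initial_sample(state, 2, mode="random", rng=0)
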