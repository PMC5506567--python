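"""CRF tagger: decode probabilities vs. exhaustive enumeration, training
behaviour, least-confidence properties."""

import itertools

import numpy as np
import pytest

from cause_al import (
    CRFHyperparams,
    LabeledSentence,
    SequencePrediction,
    TaggerModel,
    decode,
    decode_many,
    evaluate_ner,
    extract_features,
    least_confidence,
    train,
)
from cause_al.corpus import bio_decode
from cause_al.crf import CLINICAL_LABELS, sentence_potentials
from dataclasses import replace


def _sent(tokens, spans=(), sid="s0"):
    return LabeledSentence(sid, "d0", list(tokens), list(spans))


def _toy_model(rng, labels=("A", "B", "C"), tokens=("x", "y", "z")):
    """Hand-set random weights over the features of a tiny vocabulary."""
    feats = sorted({f for tok in tokens for f in extract_features(_sent([tok]))[0]})
    # add window features for multi-token contexts
    all_feats = sorted(
        {
            f
            for n in range(1, 4)
            for s in itertools.product(tokens, repeat=n)
            for bag in extract_features(_sent(list(s)))
            for f in bag
        }
    )
    fi = {f: i for i, f in enumerate(all_feats)}
    n = len(labels)
    return TaggerModel(
        labels=list(labels),
        feature_index=fi,
        emission=rng.normal(scale=1.0, size=(len(fi), n)),
        transition=rng.normal(scale=1.0, size=(n, n)),
        start=rng.normal(scale=1.0, size=n),
    )


def _enumerate_paths(model, sentence):
    """Brute-force path scores: returns (best_tags, best_prob, logZ)."""
    phi, Tm, b0m = sentence_potentials(model, sentence)
    L, Y = phi.shape
    scores = {}
    for path in itertools.product(range(Y), repeat=L):
        s = b0m[path[0]] + phi[0, path[0]]
        for t in range(1, L):
            s += Tm[path[t - 1], path[t]] + phi[t, path[t]]
        scores[path] = s
    vals = np.array(list(scores.values()))
    finite = vals[np.isfinite(vals)]
    logZ = np.log(np.sum(np.exp(finite - finite.max()))) + finite.max()
    best = max(scores, key=scores.get)
    return [model.labels[i] for i in best], float(np.exp(scores[best] - logZ)), logZ


class TestDecodeOracle:
    @pytest.mark.parametrize("length", [1, 2, 3])
    def test_best_path_prob_matches_enumeration(self, length):
        rng = np.random.default_rng(length)
        for trial in range(10):
            model = _toy_model(rng)
            toks = [["x", "y", "z"][rng.integers(0, 3)] for _ in range(length)]
            s = _sent(toks)
            pred = decode(model, s)
            tags, prob, _ = _enumerate_paths(model, s)
            assert pred.tags == tags
            assert pred.best_path_prob == pytest.approx(prob, abs=1e-9)

    def test_bio_constraints_respected_in_enumeration_and_decode(self):
        # clinical label set with BIO masks: decode equals constrained enumeration
        rng = np.random.default_rng(5)
        feats = sorted(
            {f for bag in extract_features(_sent(["mg", "po"])) for f in bag}
        )
        fi = {f: i for i, f in enumerate(feats)}
        n = len(CLINICAL_LABELS)
        model = TaggerModel(
            labels=list(CLINICAL_LABELS),
            feature_index=fi,
            emission=rng.normal(size=(len(fi), n)),
            transition=rng.normal(size=(n, n)),
            start=rng.normal(size=n),
        )
        s = _sent(["mg", "po"])
        pred = decode(model, s)
        tags, prob, _ = _enumerate_paths(model, s)
        assert pred.tags == tags
        assert pred.best_path_prob == pytest.approx(prob, abs=1e-9)
        # a predicted I- tag never follows an incompatible tag
        for prev, cur in zip(pred.tags, pred.tags[1:]):
            if cur.startswith("I-"):
                assert prev in (f"B-{cur[2:]}", f"I-{cur[2:]}")

    def test_zero_weights_give_uniform_path_probability(self):
        labels = ["A", "B", "C"]
        model = TaggerModel(
            labels=labels,
            feature_index={"bias": 0},
            emission=np.zeros((1, 3)),
            transition=np.zeros((3, 3)),
            start=np.zeros(3),
        )
        for length in (1, 2, 3):
            pred = decode(model, _sent(["x"] * length))
            assert pred.best_path_prob == pytest.approx(3.0 ** -length)

    def test_lc_ranking_matches_enumeration_ranking(self):
        rng = np.random.default_rng(11)
        model = _toy_model(rng)
        sents = [
            _sent([["x", "y", "z"][rng.integers(0, 3)] for _ in range(rng.integers(1, 4))], sid=f"s{i}")
            for i in range(10)
        ]
        lcs = [least_confidence(decode(model, s)) for s in sents]
        oracle = [1.0 - _enumerate_paths(model, s)[1] for s in sents]
        assert np.argsort(lcs).tolist() == np.argsort(oracle).tolist()


class TestFeatures:
    def test_single_token_uses_boundary_markers(self):
        bags = extract_features(_sent(["aspirin"]))
        assert "w-1=<s>" in bags[0] and "w+1=</s>" in bags[0]

    def test_digit_token_sets_alldigit_flag(self):
        bags = extract_features(_sent(["dose", "500"]))
        assert "alldigit" in bags[1] and "hasdigit" in bags[1]
        assert "alldigit" not in bags[0]

    def test_deterministic(self):
        s = _sent(["Lasix", "40", "mg"])
        assert extract_features(s) == extract_features(s)


class TestTraining:
    def test_memorizes_single_training_sentence(self):
        from cause_al import EntitySpan

        s = _sent(["Dulcolax", "10", "mg", "given"], [EntitySpan(0, 3, "treatment")])
        model = train([s], CRFHyperparams(max_iter=100))
        pred = decode(model, s)
        assert bio_decode(pred.tags) == s.spans

    def test_generalizes_to_held_out_template_sentences(self, small_corpus):
        # unseen entity fillers must be recovered from shared template context
        rng = np.random.default_rng(0)
        idx = rng.permutation(len(small_corpus.sentences))
        train_set = [small_corpus.sentences[i] for i in idx[:200]]
        seen_templates = {s.meta["template"] for s in train_set}
        held_out = [
            small_corpus.sentences[i]
            for i in idx[200:400]
            if small_corpus.sentences[i].meta["template"] in seen_templates
        ]
        model = train(train_set, CRFHyperparams(max_iter=100))
        preds = decode_many(model, held_out)
        pred_sents = [replace(s, spans=bio_decode(p.tags)) for s, p in zip(held_out, preds)]
        assert evaluate_ner(held_out, pred_sents).f_measure > 0.8

    def test_training_deterministic(self, tiny_corpus):
        sents = tiny_corpus.sentences[:60]
        probe = tiny_corpus.sentences[60:100]
        m1 = train(sents, CRFHyperparams(max_iter=50))
        m2 = train(sents, CRFHyperparams(max_iter=50))
        p1 = [p.tags for p in decode_many(m1, probe)]
        p2 = [p.tags for p in decode_many(m2, probe)]
        assert p1 == p2

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            train([])

    def test_probabilities_bounded_on_many_sentences(self, small_corpus):
        model = train(small_corpus.sentences[:80], CRFHyperparams(max_iter=40, feature_set="reduced"))
        preds = decode_many(model, small_corpus.sentences[:1000])
        assert all(0.0 <= p.best_path_prob <= 1.0 for p in preds)

    def test_warm_start_same_optimum_as_cold(self, tiny_corpus):
        # warm start changes the path, not the destination (same objective)
        sents = tiny_corpus.sentences[:40]
        cold = train(sents, CRFHyperparams(max_iter=200))
        warm = train(
            sents, CRFHyperparams(max_iter=200, refit_max_iter=200), init_model=cold
        )
        probe = tiny_corpus.sentences[40:80]
        t1 = [p.tags for p in decode_many(cold, probe)]
        t2 = [p.tags for p in decode_many(warm, probe)]
        assert t1 == t2


class TestLeastConfidence:
    def test_exact_values(self):
        assert least_confidence(SequencePrediction(["O"], 1.0)) == 0.0
        assert least_confidence(SequencePrediction(["O"], 0.4)) == pytest.approx(0.6)

    def test_antitone_in_probability(self):
        probs = np.linspace(0.01, 0.99, 20)
        lcs = [least_confidence(SequencePrediction(["O"], p)) for p in probs]
        assert all(a > b for a, b in zip(lcs, lcs[1:]))

    def test_length_normalized_variant(self):
        pred = SequencePrediction(["O"] * 4, 0.5 ** 4)
        assert least_confidence(pred, length_normalized=True) == pytest.approx(0.5)

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError):
            SequencePrediction(["O"], 1.5)


class TestModelPersistence:
    def test_save_load_round_trip(self, tiny_corpus, tmp_path):
        sents = tiny_corpus.sentences[:40]
        model = train(sents, CRFHyperparams(max_iter=40, feature_set="reduced"))
        path = tmp_path / "model.crf"
        model.save(path)
        loaded = TaggerModel.load(path)
        probe = tiny_corpus.sentences[40:70]
        assert [p.tags for p in decode_many(model, probe)] == [
            p.tags for p in decode_many(loaded, probe)
        ]

    def test_superset_training_does_not_raise_lc_on_memorized_sentences(
        self, tiny_corpus
    ):
        # regression bound, not a theorem: more data from the same
        # distribution should leave memorized sentences at least as certain
        base = tiny_corpus.sentences[:40]
        extra = tiny_corpus.sentences[40:120]
        hp = CRFHyperparams(max_iter=120)
        m_small = train(base, hp)
        m_large = train(base + extra, hp)
        lc_small = np.mean(
            [least_confidence(p) for p in decode_many(m_small, base)]
        )
        lc_large = np.mean(
            [least_confidence(p) for p in decode_many(m_large, base)]
        )
        assert lc_large <= lc_small + 0.02
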