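"""Synthetic topic-structured clinical corpora with gold entity annotations.

Real clinical note corpora mix a small number of recurring sentence families:
medication-list lines ("Dulcolax 10 mg p.o. q. day"), problem statements, lab
result lines, and so on.  Within a family, sentences share a template-like
context and differ mainly in the entity fillers — which is exactly the
structure a cluster-then-sample querying strategy exploits: one annotated
representative teaches the tagger the shared context, and the context then
identifies the unseen fillers in every cluster-mate.

The generator reproduces that structure by construction.  Each latent topic
owns a context vocabulary, per-type entity lexicons and a handful of fixed
slot templates; documents draw a skewed topic mixture; sentences instantiate a
template by filling entity/number slots.  Default targets mirror a typical
clinical concept-annotation corpus: ~11 words per sentence, ~1.27 entities per
sentence and entity density ~0.24.

Every sentence records its generating topic and template in
``LabeledSentence.meta`` so that clustering and querying behaviour can be
scored against the known latent structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import Corpus, EntitySpan, LabeledSentence, deduplicate

# Shared clinical-register function words appearing across all topics.
_SHARED_WORDS = [
    "the", "was", "is", "on", "with", "and", "of", "in", "for", "to",
    "noted", "stable", "daily", "given", "after", "no", "her", "his",
    "at", "per", "continued", "started", "exam", "day", "level",
]

_NUM_LEXICON = ["2", "4", "5", "10", "20", "25", "40", "50", "100", "250", "500"]

# Morphological cues per entity type, echoing clinical register: capitalized
# drug names ending in -ol/-ine/-ax, disorders in -itis/-emia/-osis, lab
# analytes in -in/-ase/-crit.  These give character-affix features something
# to generalize on for unseen lexicon entries, as in real clinical text.
_ETYPE_SUFFIXES = {
    "treatment": ["ol", "ine", "ax", "il", "one", "ide"],
    "problem": ["itis", "emia", "osis", "algia", "pathy", "oma"],
    "test": ["in", "ase", "crit", "ium", "ose"],
}

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"

def _balanced_counts(n: int, mean: float, lo: int, hi: int) -> list[int]:
    """Integer sequence in [lo, hi] whose running sum tracks ``mean`` per item.

    Used instead of independent draws so that per-topic aggregates stay on
    target even when topic popularity is heavily skewed.
    """
    counts: list[int] = []
    for i in range(1, n + 1):
        c = int(round(mean * i)) - sum(counts)
        counts.append(max(lo, min(hi, c)))
    return counts


def _pseudoword(rng: np.random.Generator, n_syll: int) -> str:
    return "".join(
        rng.choice(list(_CONSONANTS)) + rng.choice(list(_VOWELS))
        for _ in range(n_syll)
    )


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus generator.

    The word/entity targets are soft: templates are sized so that expected
    sentence length and entity density land on them; realized corpus
    statistics fluctuate a few percent around the targets.
    """

    n_documents: int = 300
    sentences_per_document: tuple[int, int] = (12, 28)
    n_topics: int = 10
    templates_per_topic: int = 4
    entity_lexicon_size: int = 60
    context_vocab_size: int = 25
    target_words_per_sentence: float = 11.0
    target_entities_per_sentence: float = 1.27
    target_entity_density: float = 0.24
    noise_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "n_documents", "n_topics", "templates_per_topic",
            "entity_lexicon_size", "context_vocab_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ValueError("noise_rate must lie in [0, 1]")
        if self.target_entity_density >= 1.0 or self.target_entity_density < 0:
            raise ValueError("target_entity_density must lie in [0, 1)")
        if self.target_words_per_sentence < 3:
            raise ValueError("target_words_per_sentence too small for templates")


# A template item is ("lit", word), ("ent", etype, n_words) or ("num",).
TemplateItem = tuple


@dataclass
class TopicSpec:
    """Latent topic: its lexicons and slot templates."""

    index: int
    style: str  # medication | problem | lab
    context_words: list[str]
    entity_lexicons: dict[str, list[str]]
    templates: list[list[TemplateItem]] = field(default_factory=list)


_STYLE_ETYPE = {"medication": "treatment", "problem": "problem", "lab": "test"}


class SyntheticGenerator:
    """Builds the latent world (topics, lexicons, templates) from a config.

    Deterministic: the same config (including seed) always produces the same
    world and the same corpus.
    """

    def __init__(self, cfg: GeneratorConfig):
        self.cfg = cfg
        self.rng = np.random.default_rng(cfg.seed)
        self.topics = [self._build_topic(t) for t in range(cfg.n_topics)]
        # Zipf-like topic popularity: early topics dominate the pool.
        ranks = np.arange(1, cfg.n_topics + 1, dtype=float)
        self.topic_popularity = (1.0 / ranks) / (1.0 / ranks).sum()
        self._marginal = self._estimate_sentence_topic_marginal()
        self._calibrate()

    # -- world construction -------------------------------------------------

    def _build_topic(self, t: int) -> TopicSpec:
        cfg, rng = self.cfg, self.rng
        style = ("medication", "problem", "lab")[t % 3]
        context = [
            f"{_pseudoword(rng, int(rng.integers(2, 4)))}"
            for _ in range(cfg.context_vocab_size)
        ]
        def entity_word(et: str) -> str:
            stem = _pseudoword(rng, int(rng.integers(1, 3)))
            word = stem + str(rng.choice(_ETYPE_SUFFIXES[et]))
            return word.capitalize() if et == "treatment" else word

        lexicons = {
            et: [entity_word(et) for _ in range(cfg.entity_lexicon_size)]
            for et in ("problem", "treatment", "test")
        }
        spec = TopicSpec(t, style, context, lexicons)

        # Quasi-balanced entity counts per template (with an entity-free
        # template when there is room) and slot word-lengths per topic, so
        # corpus-level entities/sentence and entity density hit the targets.
        n_ent_per_template = _balanced_counts(
            cfg.templates_per_topic, cfg.target_entities_per_sentence, 0, 3
        )
        if cfg.templates_per_topic >= 3 and min(n_ent_per_template) > 0:
            i = int(np.argmin(n_ent_per_template))
            j = (i + 1) % cfg.templates_per_topic
            n_ent_per_template[j] += n_ent_per_template[i]
            n_ent_per_template[i] = 0
        rng.shuffle(n_ent_per_template)
        mean_len = (
            cfg.target_entity_density
            * cfg.target_words_per_sentence
            / max(cfg.target_entities_per_sentence, 1e-9)
        )
        slot_lengths = _balanced_counts(
            sum(n_ent_per_template), float(np.clip(mean_len, 1.0, 3.0)), 1, 3
        )
        rng.shuffle(slot_lengths)
        it = iter(slot_lengths)
        for n_ent in n_ent_per_template:
            spec.templates.append(
                self._build_template(spec, [next(it) for _ in range(n_ent)])
            )
        return spec

    def _build_template(
        self, topic: TopicSpec, slot_lengths: list[int]
    ) -> list[TemplateItem]:
        cfg, rng = self.cfg, self.rng
        main_etype = _STYLE_ETYPE[topic.style]
        ent_items: list[TemplateItem] = []
        for j, n_words in enumerate(slot_lengths):
            # first slot carries the topic's dominant type; extras vary
            etype = main_etype if j == 0 else str(rng.choice(list(_STYLE_ETYPE.values())))
            ent_items.append(("ent", etype, int(n_words)))
        n_num = int(rng.integers(0, 2)) + (1 if topic.style in ("medication", "lab") else 0)
        if not ent_items:
            # entity-free lines keep a numeric slot so they are not verbatim
            # boilerplate that deduplication would collapse wholesale
            n_num = max(n_num, 1)
        total_words = int(
            np.clip(
                rng.integers(
                    round(cfg.target_words_per_sentence) - 3,
                    round(cfg.target_words_per_sentence) + 4,
                ),
                3,
                None,
            )
        )
        ent_words = sum(it[2] for it in ent_items)
        n_context = max(2, total_words - ent_words - n_num)
        lit_pool = topic.context_words + _SHARED_WORDS
        lit_probs = np.concatenate(
            [
                np.full(len(topic.context_words), 0.8 / len(topic.context_words)),
                np.full(len(_SHARED_WORDS), 0.2 / len(_SHARED_WORDS)),
            ]
        )
        lits: list[TemplateItem] = [
            ("lit", str(rng.choice(lit_pool, p=lit_probs))) for _ in range(n_context)
        ]
        nums: list[TemplateItem] = [("num",)] * n_num
        # Interleave: entity and number slots at fixed random positions.
        items = lits
        for slot in ent_items + nums:
            pos = int(rng.integers(0, len(items) + 1))
            items.insert(pos, slot)
        return items

    # -- target calibration -------------------------------------------------

    def _estimate_sentence_topic_marginal(self) -> np.ndarray:
        """Marginal P(sentence topic), accounting for the document mixtures.

        Documents draw a few topics without replacement by popularity, which
        flattens the raw Zipf skew; estimated by Monte Carlo with a dedicated
        rng so the corpus stream is untouched.
        """
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed + 987654321 if cfg.seed < 2**30 else 17)
        counts = np.zeros(cfg.n_topics)
        for _ in range(3000):
            k = min(cfg.n_topics, int(rng.integers(2, 4)))
            doc_topics = rng.choice(
                cfg.n_topics, size=k, replace=False, p=self.topic_popularity
            )
            weights = rng.dirichlet(np.full(k, 2.0))
            counts[doc_topics] += weights
        return counts / counts.sum()

    def _expected_stats(self) -> tuple[float, float]:
        """Expected (words/sentence, entity words/sentence) over templates."""
        wps = epw = 0.0
        for topic, p in zip(self.topics, self._marginal):
            t_words = t_ent = 0.0
            for tpl in topic.templates:
                t_words += sum(it[2] if it[0] == "ent" else 1 for it in tpl)
                t_ent += sum(it[2] for it in tpl if it[0] == "ent")
            wps += p * t_words / len(topic.templates)
            epw += p * t_ent / len(topic.templates)
        return wps, epw

    def _weighted_template(self) -> tuple[TopicSpec, int]:
        t = int(self.rng.choice(self.cfg.n_topics, p=self._marginal))
        topic = self.topics[t]
        return topic, int(self.rng.integers(0, len(topic.templates)))

    def _calibrate(self) -> None:
        """Nudge templates until expected stats hit the configured targets.

        First entity words per sentence (grow/shrink entity slots), then
        total words per sentence (add/remove context literals); adjustments
        pick templates by sentence-topic weight so each step moves the
        expectation measurably.
        """
        cfg = self.cfg
        target_epw = cfg.target_entity_density * cfg.target_words_per_sentence
        for _ in range(600):
            _, epw = self._expected_stats()
            if abs(epw - target_epw) < 0.02:
                break
            topic, ti = self._weighted_template()
            tpl = topic.templates[ti]
            slots = [
                i
                for i, it in enumerate(tpl)
                if it[0] == "ent" and (it[2] < 3 if epw < target_epw else it[2] > 1)
            ]
            if not slots:
                continue
            i = slots[int(self.rng.integers(0, len(slots)))]
            d = 1 if epw < target_epw else -1
            tpl[i] = ("ent", tpl[i][1], tpl[i][2] + d)
        for _ in range(600):
            wps, _ = self._expected_stats()
            if abs(wps - cfg.target_words_per_sentence) < 0.05:
                break
            topic, ti = self._weighted_template()
            tpl = topic.templates[ti]
            if wps > cfg.target_words_per_sentence:
                lits = [i for i, it in enumerate(tpl) if it[0] == "lit"]
                if len(lits) <= 2:
                    continue
                tpl.pop(lits[int(self.rng.integers(0, len(lits)))])
            else:
                pool = topic.context_words + _SHARED_WORDS
                word = str(self.rng.choice(pool))
                tpl.insert(int(self.rng.integers(0, len(tpl) + 1)), ("lit", word))

    # -- corpus generation --------------------------------------------------

    def _fill_sentence(
        self, sid: str, doc_id: str, topic: TopicSpec, template_idx: int
    ) -> LabeledSentence:
        rng = self.rng
        tokens: list[str] = []
        spans: list[EntitySpan] = []
        all_context = topic.context_words + _SHARED_WORDS
        for item in topic.templates[template_idx]:
            if item[0] == "lit":
                word = item[1]
                if self.cfg.noise_rate and rng.random() < self.cfg.noise_rate:
                    word = str(rng.choice(all_context))
                tokens.append(word)
            elif item[0] == "num":
                tokens.append(str(rng.choice(_NUM_LEXICON)))
            else:
                _, etype, n_words = item
                start = len(tokens)
                lex = topic.entity_lexicons[etype]
                head = int(rng.integers(0, len(lex)))
                for w in range(n_words):
                    tokens.append(lex[(head + w) % len(lex)])
                spans.append(EntitySpan(start, start + n_words, etype))
        return LabeledSentence(
            sid,
            doc_id,
            tokens,
            spans,
            meta={"topic": topic.index, "template": f"{topic.index}.{template_idx}"},
        )

    def generate(self) -> Corpus:
        cfg, rng = self.cfg, self.rng
        lo, hi = cfg.sentences_per_document
        sentences: list[LabeledSentence] = []
        documents: dict[str, list[str]] = {}
        for d in range(cfg.n_documents):
            doc_id = f"doc{d:04d}"
            # Each document mixes a few topics drawn by global popularity.
            k = min(cfg.n_topics, int(rng.integers(2, 4)))
            doc_topics = rng.choice(
                cfg.n_topics, size=k, replace=False, p=self.topic_popularity
            )
            weights = rng.dirichlet(np.full(k, 2.0))
            n_sent = int(rng.integers(lo, hi + 1))
            documents[doc_id] = []
            for i in range(n_sent):
                topic = self.topics[int(rng.choice(doc_topics, p=weights))]
                template_idx = int(rng.integers(0, len(topic.templates)))
                sid = f"{doc_id}:{i}"
                sentences.append(self._fill_sentence(sid, doc_id, topic, template_idx))
                documents[doc_id].append(sid)
        return Corpus(sentences, documents)


def generate_corpus(cfg: GeneratorConfig) -> Corpus:
    """Generate a synthetic annotated corpus from ``cfg`` (deterministic)."""
    return SyntheticGenerator(cfg).generate()


def generate_pool_and_test(
    cfg: GeneratorConfig, test_fraction: float, seed: int
) -> tuple[Corpus, Corpus]:
    """Generate, deduplicate, and split into disjoint pool and test corpora.

    The split is stratified by generating topic so that the test set mirrors
    the pool's topic composition.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    corpus = deduplicate(generate_corpus(cfg))
    rng = np.random.default_rng(seed)
    by_topic: dict[int, list[str]] = {}
    for s in corpus:
        by_topic.setdefault(s.meta.get("topic", -1), []).append(s.sid)
    test_ids: list[str] = []
    for sids in by_topic.values():
        order = rng.permutation(len(sids))
        n_test = int(round(test_fraction * len(sids)))
        test_ids.extend(sids[i] for i in order[:n_test])
    test_set = set(test_ids)
    pool_ids = [s.sid for s in corpus if s.sid not in test_set]
    return corpus.subset(pool_ids), corpus.subset(test_ids)
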