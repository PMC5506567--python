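"""Data model and I/O for annotated clinical sentence corpora.

The atomic unit is the :class:`LabeledSentence`: a pre-tokenized sentence with
typed entity spans over token indices (0-based, end-exclusive).  Entity types
follow the clinical concept-extraction convention: ``problem``, ``treatment``
and ``test``.  Corpora are read and written in the CoNLL-style token-per-line
BIO format, with a blank line between sentences and ``-DOCSTART- <doc_id>``
lines marking document boundaries.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

ENTITY_TYPES = ("problem", "treatment", "test")

DOCSTART = "-DOCSTART-"


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round to ``ndigits`` decimals with ties going away from zero.

    Used only at reporting time; all internal ratios are kept at full
    precision.
    """
    q = decimal.Decimal(10) ** -ndigits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class EntitySpan:
    """A typed entity mention over token indices [start, end)."""

    start: int
    end: int
    etype: str

    def __post_init__(self) -> None:
        if self.etype not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type {self.etype!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid span boundaries ({self.start}, {self.end})")

    @property
    def n_words(self) -> int:
        return self.end - self.start


@dataclass
class LabeledSentence:
    """A tokenized sentence with non-overlapping typed entity spans.

    ``meta`` carries generator provenance (e.g. the latent topic a synthetic
    sentence was drawn from) and is excluded from equality so that round-trips
    through plain-text formats compare clean.
    """

    sid: str
    doc_id: str
    tokens: list[str]
    spans: list[EntitySpan] = field(default_factory=list)
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.tokens:
            raise ValueError(f"sentence {self.sid!r} has no tokens")
        for tok in self.tokens:
            if not tok or any(c.isspace() for c in tok):
                raise ValueError(f"bad token {tok!r} in sentence {self.sid!r}")
        n = len(self.tokens)
        prev_end = -1
        for sp in sorted(self.spans, key=lambda s: s.start):
            if sp.end > n:
                raise ValueError(f"span {sp} exceeds sentence length {n}")
            if sp.start < prev_end:
                raise ValueError(f"overlapping spans in sentence {self.sid!r}")
            prev_end = sp.end
        self.spans = sorted(self.spans, key=lambda s: s.start)

    @property
    def text(self) -> str:
        return " ".join(self.tokens)

    @property
    def n_words(self) -> int:
        return len(self.tokens)

    @property
    def n_entity_words(self) -> int:
        return sum(sp.n_words for sp in self.spans)


@dataclass
class Corpus:
    """An ordered collection of sentences grouped into documents."""

    sentences: list[LabeledSentence]
    documents: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.documents:
            docs: dict[str, list[str]] = {}
            for s in self.sentences:
                docs.setdefault(s.doc_id, []).append(s.sid)
            self.documents = docs
        seen: set[str] = set()
        for sids in self.documents.values():
            for sid in sids:
                if sid in seen:
                    raise ValueError(f"sentence id {sid!r} in more than one document")
                seen.add(sid)

    def __len__(self) -> int:
        return len(self.sentences)

    def __iter__(self):
        return iter(self.sentences)

    def by_sid(self) -> dict[str, LabeledSentence]:
        return {s.sid: s for s in self.sentences}

    def subset(self, sids: Iterable[str]) -> "Corpus":
        """Sub-corpus restricted to ``sids``, preserving sentence order."""
        keep = set(sids)
        sentences = [s for s in self.sentences if s.sid in keep]
        documents = {
            d: [sid for sid in sids_ if sid in keep]
            for d, sids_ in self.documents.items()
        }
        documents = {d: s for d, s in documents.items() if s}
        return Corpus(sentences, documents)


@dataclass
class CorpusStats:
    """Aggregate corpus characteristics: counts and derived ratios.

    ``entity_density`` is the number of words inside entity spans divided by
    the total number of words.
    """

    sentence_count: int
    word_count: int
    entity_count: int
    entity_word_count: int
    words_per_sentence: float
    entities_per_sentence: float
    entity_density: float

    @classmethod
    def from_counts(
        cls,
        sentence_count: int,
        word_count: int,
        entity_count: int,
        entity_word_count: int,
    ) -> "CorpusStats":
        if sentence_count <= 0:
            raise ValueError("ratio statistics undefined for an empty corpus")
        if word_count <= 0:
            raise ValueError("ratio statistics undefined for zero words")
        return cls(
            sentence_count=sentence_count,
            word_count=word_count,
            entity_count=entity_count,
            entity_word_count=entity_word_count,
            words_per_sentence=word_count / sentence_count,
            entities_per_sentence=entity_count / sentence_count,
            entity_density=entity_word_count / word_count,
        )

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        """Presentation view: ratios rounded half-up, counts untouched."""
        return {
            "sentence_count": self.sentence_count,
            "word_count": self.word_count,
            "entity_count": self.entity_count,
            "entity_word_count": self.entity_word_count,
            "words_per_sentence": round_half_up(self.words_per_sentence, ndigits),
            "entities_per_sentence": round_half_up(self.entities_per_sentence, ndigits),
            "entity_density": round_half_up(self.entity_density, ndigits),
        }


# ---------------------------------------------------------------------------
# BIO encoding / decoding
# ---------------------------------------------------------------------------

def bio_encode(sentence: LabeledSentence) -> list[str]:
    """Encode entity spans as a BIO tag sequence, one tag per token."""
    tags = ["O"] * len(sentence.tokens)
    for sp in sentence.spans:
        tags[sp.start] = f"B-{sp.etype}"
        for i in range(sp.start + 1, sp.end):
            tags[i] = f"I-{sp.etype}"
    return tags


def bio_decode(tags: Sequence[str]) -> list[EntitySpan]:
    """Reconstruct spans from a BIO tag sequence.

    An I- tag without a preceding compatible B-/I- tag opens a new span
    (conventional repair).
    """
    spans: list[EntitySpan] = []
    start, etype = None, None
    for i, tag in enumerate(tags):
        if tag == "O":
            if start is not None:
                spans.append(EntitySpan(start, i, etype))
                start, etype = None, None
            continue
        if "-" not in tag or tag.split("-", 1)[0] not in ("B", "I"):
            raise ValueError(f"malformed BIO tag {tag!r}")
        prefix, t = tag.split("-", 1)
        if t not in ENTITY_TYPES:
            raise ValueError(f"unknown entity type in tag {tag!r}")
        if prefix == "B" or start is None or t != etype:
            if start is not None:
                spans.append(EntitySpan(start, i, etype))
            start, etype = i, t
    if start is not None:
        spans.append(EntitySpan(start, len(tags), etype))
    return spans


def read_bio(path: str | Path) -> Corpus:
    """Read a token-per-line BIO file into a :class:`Corpus`.

    Sentence ids are assigned as ``<doc_id>:<index>`` in document order, so
    corpora written by :func:`write_bio` round-trip exactly.
    """
    path = Path(path)
    sentences: list[LabeledSentence] = []
    documents: dict[str, list[str]] = {}
    doc_id = "doc0"
    sent_idx = 0
    tokens: list[str] = []
    tags: list[str] = []

    def flush(lineno: int) -> None:
        nonlocal tokens, tags, sent_idx
        if not tokens:
            return
        sid = f"{doc_id}:{sent_idx}"
        try:
            spans = bio_decode(tags)
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
        sentences.append(LabeledSentence(sid, doc_id, tokens, spans))
        documents.setdefault(doc_id, []).append(sid)
        sent_idx += 1
        tokens, tags = [], []

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if line.startswith(DOCSTART):
                flush(lineno)
                parts = line.split(None, 1)
                doc_id = parts[1].strip() if len(parts) > 1 else f"doc{len(documents)}"
                documents.setdefault(doc_id, [])
                sent_idx = 0
                continue
            if not line.strip():
                flush(lineno)
                continue
            cols = line.split("\t") if "\t" in line else line.split()
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'token<TAB>tag', got {line!r}")
            tok, tag = cols
            if tag != "O" and not (
                tag.startswith(("B-", "I-")) and tag[2:] in ENTITY_TYPES
            ):
                raise ValueError(f"{path}:{lineno}: unknown tag label {tag!r}")
            tokens.append(tok)
            tags.append(tag)
        flush(lineno if tokens else 0)
    documents = {d: s for d, s in documents.items() if s}
    return Corpus(sentences, documents)


def write_bio(corpus: Corpus, path: str | Path) -> None:
    """Write a corpus in token-per-line BIO format, one block per document."""
    path = Path(path)
    by_sid = corpus.by_sid()
    with open(path, "w") as fh:
        for doc_id, sids in corpus.documents.items():
            fh.write(f"{DOCSTART} {doc_id}\n")
            for sid in sids:
                s = by_sid[sid]
                for tok, tag in zip(s.tokens, bio_encode(s)):
                    fh.write(f"{tok}\t{tag}\n")
                fh.write("\n")


# ---------------------------------------------------------------------------
# Statistics and fold splitting
# ---------------------------------------------------------------------------

def corpus_stats(corpus: Corpus) -> CorpusStats:
    """Sentence/word/entity counts and their derived ratios."""
    if len(corpus) == 0:
        raise ValueError("ratio statistics undefined for an empty corpus")
    return CorpusStats.from_counts(
        sentence_count=len(corpus),
        word_count=sum(s.n_words for s in corpus),
        entity_count=sum(len(s.spans) for s in corpus),
        entity_word_count=sum(s.n_entity_words for s in corpus),
    )


def deduplicate(corpus: Corpus) -> Corpus:
    """Keep the first occurrence of each distinct surface string.

    Uniqueness is exact match of the whitespace-joined token string.
    """
    seen: set[str] = set()
    keep: list[str] = []
    for s in corpus:
        if s.text not in seen:
            seen.add(s.text)
            keep.append(s.sid)
    return corpus.subset(keep)


def dedup_and_split(corpus: Corpus, k: int, seed: int) -> list[list[str]]:
    """Deduplicate and randomly partition sentence ids into ``k`` folds.

    Fold sizes differ by at most one; the split is deterministic under a
    fixed seed.
    """
    if k < 2:
        raise ValueError("need at least 2 folds")
    unique = deduplicate(corpus)
    sids = [s.sid for s in unique]
    if k > len(sids):
        raise ValueError(f"cannot split {len(sids)} sentences into {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(sids))
    return [[sids[i] for i in chunk] for chunk in np.array_split(order, k)]
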