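"""NER scoring, the ALC learning-curve score, and annotation-session metrics.

Span matching is exact: a predicted span counts as a true positive only when
its start, end, and entity type all equal a gold span's, and each gold span
can be matched at most once.  (Since spans within a sentence are
non-overlapping and typed, set intersection on (start, end, etype) triples
realizes the maximum bipartite matching exactly.)

ALC is the area under a learning curve divided by a maximum area: the cost
span of the observed curve times the best F-measure achievable under the
study's budget (0.75 by default — models do not reach perfect F within a
120-minute annotation session).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import Corpus, EntitySpan, LabeledSentence, round_half_up


@dataclass
class PRF:
    """Precision / recall / F-measure with the counts behind them."""

    true_positives: int
    false_positives: int
    false_negatives: int
    precision: float = field(init=False)
    recall: float = field(init=False)
    f_measure: float = field(init=False)

    def __post_init__(self) -> None:
        tp, fp, fn = self.true_positives, self.false_positives, self.false_negatives
        self.precision = tp / (tp + fp) if tp + fp else 0.0
        self.recall = tp / (tp + fn) if tp + fn else 0.0
        p, r = self.precision, self.recall
        self.f_measure = 2 * p * r / (p + r) if p + r else 0.0


def evaluate_ner(
    gold: Sequence[LabeledSentence], pred: Sequence[LabeledSentence]
) -> PRF:
    """Exact span+type matching between aligned gold and predicted sentences."""
    if len(gold) != len(pred):
        raise ValueError(f"{len(gold)} gold vs {len(pred)} predicted sentences")
    tp = fp = fn = 0
    for g, p in zip(gold, pred):
        if g.sid != p.sid:
            raise ValueError(f"sentence id mismatch: {g.sid!r} vs {p.sid!r}")
        if g.tokens != p.tokens:
            raise ValueError(f"token sequences differ for sentence {g.sid!r}")
        gset = {(s.start, s.end, s.etype) for s in g.spans}
        pset = {(s.start, s.end, s.etype) for s in p.spans}
        hit = len(gset & pset)
        tp += hit
        fp += len(pset) - hit
        fn += len(gset) - hit
    return PRF(tp, fp, fn)


# ---------------------------------------------------------------------------
# Learning curves and ALC
# ---------------------------------------------------------------------------

@dataclass
class LearningCurve:
    """Ordered (annotation cost, test F-measure) points for one run.

    Cost is words annotated (simulation) or minutes spent (user sessions).
    """

    points: list[tuple[float, float]]
    cost_unit: str = "words"

    def __post_init__(self) -> None:
        costs = [c for c, _ in self.points]
        if any(b <= a for a, b in zip(costs, costs[1:])):
            raise ValueError("curve costs must be strictly increasing")
        if any(not (0.0 <= f <= 1.0) for _, f in self.points):
            raise ValueError("F-measures must lie in [0, 1]")

    @property
    def costs(self) -> np.ndarray:
        return np.array([c for c, _ in self.points], dtype=float)

    @property
    def f_measures(self) -> np.ndarray:
        return np.array([f for _, f in self.points], dtype=float)


def alc_score(curve: LearningCurve, best_f: float = 0.75) -> float:
    """Area under the curve / (cost span × best achievable F).

    Trapezoidal integration from the first to the last observed cost point;
    the same span normalizes the maximum area, so a curve pinned at
    ``best_f`` scores exactly 1.
    """
    if len(curve.points) < 2:
        raise ValueError("ALC needs at least 2 curve points")
    costs, fs = curve.costs, curve.f_measures
    actual = float(np.trapezoid(fs, costs))
    maximum = (costs[-1] - costs[0]) * best_f
    return actual / maximum


def average_curves(curves: Sequence[LearningCurve]) -> LearningCurve:
    """Average fold/seed curves by linear interpolation onto a shared grid.

    The grid is the union of all curves' cost points restricted to the cost
    range covered by every curve, so no curve is ever extrapolated.
    """
    if not curves:
        raise ValueError("no curves to average")
    lo = max(c.costs[0] for c in curves)
    hi = min(c.costs[-1] for c in curves)
    if hi <= lo:
        raise ValueError("curves share no common cost range")
    grid = np.unique(np.concatenate([c.costs for c in curves]))
    grid = grid[(grid >= lo) & (grid <= hi)]
    if grid.size == 0 or grid[0] > lo:
        grid = np.concatenate([[lo], grid])
    if grid[-1] < hi:
        grid = np.concatenate([grid, [hi]])
    mean_f = np.mean(
        [np.interp(grid, c.costs, c.f_measures) for c in curves], axis=0
    )
    return LearningCurve(
        points=list(zip(grid.tolist(), mean_f.tolist())),
        cost_unit=curves[0].cost_unit,
    )


# ---------------------------------------------------------------------------
# Annotation-session metrics
# ---------------------------------------------------------------------------

@dataclass
class SessionRecord:
    """One annotated sentence in a session: what was marked, and when."""

    sid: str
    n_words: int
    spans: list[EntitySpan]
    elapsed_min: float


@dataclass
class SessionLog:
    """Chronological record of one annotation session."""

    records: list[SessionRecord]
    duration_min: float

    def __post_init__(self) -> None:
        times = [r.elapsed_min for r in self.records]
        if any(t < 0 for t in times) or any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("elapsed times must be nonnegative and nondecreasing")


@dataclass
class SessionMetrics:
    """Counts, speed and quality of one annotation session.

    Mirrors the standard report for a timed annotation study: sentence /
    word / entity counts, per-minute and per-sentence rates, entity density,
    and annotation quality as F-measure against gold.
    """

    annotated_sentences: int
    words: int
    entities: int
    entity_words: int
    duration_min: float
    sentences_per_min: float = field(init=False)
    words_per_sentence: float = field(init=False)
    words_per_min: float = field(init=False)
    entities_per_min: float = field(init=False)
    entities_per_sentence: float = field(init=False)
    entity_density: float = field(init=False)
    annotation_quality_f: float | None = None

    def __post_init__(self) -> None:
        if self.duration_min <= 0:
            raise ValueError("session duration must be positive")
        d, s = self.duration_min, self.annotated_sentences
        self.sentences_per_min = s / d
        self.words_per_min = self.words / d
        self.entities_per_min = self.entities / d
        self.words_per_sentence = self.words / s if s else 0.0
        self.entities_per_sentence = self.entities / s if s else 0.0
        self.entity_density = self.entity_words / self.words if self.words else float("nan")

    def rounded(self, ndigits: int = 2) -> dict[str, float]:
        out = {
            "annotated_sentences": self.annotated_sentences,
            "words": self.words,
            "entities": self.entities,
            "entity_words": self.entity_words,
            "sentences_per_min": round_half_up(self.sentences_per_min, ndigits),
            "words_per_sentence": round_half_up(self.words_per_sentence, ndigits),
            "words_per_min": round_half_up(self.words_per_min, ndigits),
            "entities_per_min": round_half_up(self.entities_per_min, ndigits),
            "entities_per_sentence": round_half_up(self.entities_per_sentence, ndigits),
            "entity_density": round_half_up(self.entity_density, ndigits)
            if self.words
            else float("nan"),
        }
        if self.annotation_quality_f is not None:
            out["annotation_quality_f"] = round_half_up(self.annotation_quality_f, ndigits)
        return out


def write_session_log(log: SessionLog, path) -> None:
    """Persist a session as line-delimited JSON records plus a header line."""
    import json

    with open(path, "w") as fh:
        fh.write(json.dumps({"duration_min": log.duration_min}) + "\n")
        for r in log.records:
            fh.write(
                json.dumps(
                    {
                        "sid": r.sid,
                        "n_words": r.n_words,
                        "spans": [[s.start, s.end, s.etype] for s in r.spans],
                        "elapsed_min": r.elapsed_min,
                    }
                )
                + "\n"
            )


def read_session_log(path) -> SessionLog:
    """Load a session log written by :func:`write_session_log`."""
    import json

    with open(path) as fh:
        header = json.loads(fh.readline())
        records = [
            SessionRecord(
                sid=d["sid"],
                n_words=d["n_words"],
                spans=[EntitySpan(a, b, t) for a, b, t in d["spans"]],
                elapsed_min=d["elapsed_min"],
            )
            for d in map(json.loads, fh)
        ]
    return SessionLog(records=records, duration_min=header["duration_min"])


def session_metrics(log: SessionLog, gold: Corpus) -> SessionMetrics:
    """Aggregate a session log; quality is exact-match F against gold spans."""
    by_sid = gold.by_sid()
    words = sum(r.n_words for r in log.records)
    entities = sum(len(r.spans) for r in log.records)
    entity_words = sum(sp.n_words for r in log.records for sp in r.spans)
    metrics = SessionMetrics(
        annotated_sentences=len(log.records),
        words=words,
        entities=entities,
        entity_words=entity_words,
        duration_min=log.duration_min,
    )
    scored = [r for r in log.records if r.sid in by_sid]
    if scored:
        gold_sents = [by_sid[r.sid] for r in scored]
        pred_sents = [
            LabeledSentence(r.sid, by_sid[r.sid].doc_id, by_sid[r.sid].tokens, r.spans)
            for r in scored
        ]
        metrics.annotation_quality_f = evaluate_ner(gold_sents, pred_sents).f_measure
    return metrics
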