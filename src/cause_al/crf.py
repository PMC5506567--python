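"""Linear-chain CRF sequence tagger with exact best-path probabilities.

The tagger scores a tag sequence y for a token sequence of length L as

    score(y) = sum_t  phi(t, y_t)  +  sum_{t>0}  T[y_{t-1}, y_t]  +  b0[y_0]

where phi(t, y) is a sum of per-token indicator-feature weights, T is a
shared transition matrix and b0 a start-of-sentence bias.  Training maximizes
the L2-penalized conditional log-likelihood with L-BFGS; gradients come from
exact forward-backward marginals.  Decoding is Viterbi, and the confidence
attached to a prediction is the true normalized path probability
exp(score(y*) - log Z), which feeds the least-confidence (LC) uncertainty
score 1 - P(y* | x) used by the querying engines.

Illegal BIO transitions (I-x not preceded by B-x/I-x) are excluded by hard
transition constraints applied in both training and decoding, so predicted
sequences are always well-formed without post-hoc repair.  Label sets whose
names do not follow the B-/I-/O convention get no constraints, which keeps
the model usable for small enumeration oracles.

Performance notes: sentences are grouped by length so every inner loop is a
numpy operation over (batch, labels, labels) arrays; gradient scatter goes
through ``bincount``; and callers that decode the same sentences against a
sequence of retrained models (the active-learning loop) can index features
once against a fixed vocabulary and reuse the integer arrays.
"""

from __future__ import annotations

import pickle
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .corpus import ENTITY_TYPES, LabeledSentence, bio_decode, bio_encode

FORMAT_VERSION = "cause-al-crf-1"

#: Default label set for the clinical concept task.
CLINICAL_LABELS = ["O"] + [f"{p}-{t}" for t in ENTITY_TYPES for p in ("B", "I")]

_PUNCT = set(".,;:()[]/-+%'\"")

# Feature bags indexed against a vocabulary: one list of feature ids per token.
IndexedSentence = list


@dataclass
class CRFHyperparams:
    """Training knobs.

    l2            — L2 penalty weight on all parameters (sum of squares).
    max_iter      — L-BFGS iteration cap for a cold start.
    refit_max_iter— iteration cap when warm-starting from a previous model,
                    as in the active-learning loop where the training set
                    grows by one small batch at a time.
    feature_set   — "full" (±2 word window, affixes, shape flags) or
                    "reduced" (±1 window and shape flags), the latter for
                    large simulation sweeps.
    """

    l2: float = 0.1
    max_iter: int = 120
    refit_max_iter: int = 25
    feature_set: str = "full"


@dataclass
class TaggerModel:
    """A trained (or hand-constructed) linear-chain CRF."""

    labels: list[str]
    feature_index: dict[str, int]
    emission: np.ndarray  # (n_features, n_labels)
    transition: np.ndarray  # (n_labels, n_labels)
    start: np.ndarray  # (n_labels,)
    feature_set: str = "full"
    version: str = FORMAT_VERSION
    trans_mask: np.ndarray = field(default=None)  # type: ignore[assignment]
    start_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.trans_mask is None or self.start_mask is None:
            tm, sm = bio_constraint_masks(self.labels)
            if self.trans_mask is None:
                self.trans_mask = tm
            if self.start_mask is None:
                self.start_mask = sm

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TaggerModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if model.version != FORMAT_VERSION:
            raise ValueError(f"unsupported model version {model.version!r}")
        return model


@dataclass
class SequencePrediction:
    """Viterbi decoding result for one sentence."""

    tags: list[str]
    best_path_prob: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.best_path_prob <= 1.0 + 1e-9):
            raise ValueError(f"best_path_prob {self.best_path_prob} outside [0, 1]")
        self.best_path_prob = float(min(self.best_path_prob, 1.0))


def least_confidence(pred: SequencePrediction, length_normalized: bool = False) -> float:
    """LC uncertainty: 1 - P(best path | sentence); higher = more uncertain.

    ``length_normalized`` uses 1 - P^(1/L) instead, discounting the mechanical
    decay of whole-sequence probability with sentence length.
    """
    p = pred.best_path_prob
    if length_normalized:
        p = p ** (1.0 / max(len(pred.tags), 1))
    return 1.0 - p


def bio_constraint_masks(labels: Sequence[str]) -> tuple[np.ndarray, np.ndarray]:
    """(transition, start) masks of 0 / -inf enforcing BIO well-formedness."""
    n = len(labels)
    trans = np.zeros((n, n))
    start = np.zeros(n)
    for j, lab in enumerate(labels):
        if lab.startswith("I-"):
            etype = lab[2:]
            start[j] = -np.inf
            for i, prev in enumerate(labels):
                if prev not in (f"B-{etype}", f"I-{etype}"):
                    trans[i, j] = -np.inf
    return trans, start


def _lse(a: np.ndarray, axis: int) -> np.ndarray:
    """log-sum-exp along ``axis``; tolerates -inf blocks without warnings."""
    m = np.max(a, axis=axis, keepdims=True)
    mm = np.where(np.isfinite(m), m, 0.0)
    with np.errstate(divide="ignore"):
        return np.log(np.sum(np.exp(a - mm), axis=axis)) + np.squeeze(mm, axis)


# ---------------------------------------------------------------------------
# Feature extraction and indexing
# ---------------------------------------------------------------------------

def _shape_flags(tok: str) -> list[str]:
    flags = []
    if tok[0].isupper():
        flags.append("cap")
    if tok.isdigit():
        flags.append("alldigit")
    if any(c.isdigit() for c in tok):
        flags.append("hasdigit")
    if all(c in _PUNCT for c in tok):
        flags.append("punct")
    return flags


def extract_features(
    sentence: LabeledSentence, feature_set: str = "full"
) -> list[list[str]]:
    """Per-token feature bags (deterministic).

    The full set uses lowercased word forms in a ±2 window, 3/4-character
    prefixes and suffixes, orthographic flags, and boundary markers; the
    reduced set keeps a ±1 window plus flags.
    """
    toks = sentence.tokens
    low = [t.lower() for t in toks]
    n = len(toks)
    window = 2 if feature_set == "full" else 1

    def ctx(i: int) -> str:
        if i < 0:
            return "<s>"
        if i >= n:
            return "</s>"
        return low[i]

    bags: list[list[str]] = []
    for i in range(n):
        bag = ["bias", f"w0={low[i]}"]
        for off in range(1, window + 1):
            bag.append(f"w-{off}={ctx(i - off)}")
            bag.append(f"w+{off}={ctx(i + off)}")
        if feature_set == "full":
            w = low[i]
            if len(w) >= 3:
                bag.append(f"pre3={w[:3]}")
                bag.append(f"suf3={w[-3:]}")
            if len(w) >= 4:
                bag.append(f"pre4={w[:4]}")
                bag.append(f"suf4={w[-4:]}")
        bag.extend(_shape_flags(toks[i]))
        bags.append(bag)
    return bags


def index_sentences(
    sentences: Sequence[LabeledSentence],
    feature_index: dict[str, int],
    feature_set: str = "full",
    grow: bool = True,
) -> list[IndexedSentence]:
    """Map feature bags to integer ids against ``feature_index``.

    With ``grow=False`` unseen features are dropped (decode-time behaviour);
    with ``grow=True`` they are appended to the vocabulary.
    """
    out = []
    for s in sentences:
        sent = []
        for bag in extract_features(s, feature_set):
            idxs = []
            for f in bag:
                j = feature_index.get(f)
                if j is None:
                    if not grow:
                        continue
                    j = len(feature_index)
                    feature_index[f] = j
                idxs.append(j)
            sent.append(idxs)
        out.append(sent)
    return out


def _group_by_length(
    feat_idx: Sequence[IndexedSentence],
    labels_idx: Sequence[list[int]] | None,
    pad: int,
) -> list[tuple[np.ndarray, np.ndarray | None, np.ndarray]]:
    """Pack sentences of equal length into (F, gold, order) index arrays.

    F has shape (batch, length, max_bag); missing bag slots point at ``pad``,
    a frozen zero-weight row.  ``order`` records original sentence positions.
    """
    buckets: dict[int, list[int]] = {}
    for i, sent in enumerate(feat_idx):
        buckets.setdefault(len(sent), []).append(i)
    groups = []
    for length in sorted(buckets):
        members = buckets[length]
        kmax = max(1, max(len(bag) for i in members for bag in feat_idx[i]))
        F = np.full((len(members), length, kmax), pad, dtype=np.int64)
        for r, i in enumerate(members):
            for t, bag in enumerate(feat_idx[i]):
                F[r, t, : len(bag)] = bag
        gold = None
        if labels_idx is not None:
            gold = np.array([labels_idx[i] for i in members], dtype=np.int64)
        groups.append((F, gold, np.array(members)))
    return groups


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _nll_and_grad(theta, groups, n_feat, n_lab, l2, tmask, smask):
    W = theta[: n_feat * n_lab].reshape(n_feat, n_lab)
    T = theta[n_feat * n_lab : n_feat * n_lab + n_lab * n_lab].reshape(n_lab, n_lab)
    b0 = theta[-n_lab:]
    Wpad = np.vstack([W, np.zeros((1, n_lab))])
    Tm = T + tmask
    b0m = b0 + smask

    nll = l2 * float(theta @ theta)
    gW = np.zeros_like(Wpad)
    gT = np.zeros_like(T)
    gb = np.zeros_like(b0)

    for F, gold, _ in groups:
        N, L, K = F.shape
        phi = Wpad[F].sum(axis=2)  # (N, L, Y)

        alphas = np.empty((L, N, n_lab))
        alphas[0] = phi[:, 0] + b0m
        for t in range(1, L):
            alphas[t] = _lse(alphas[t - 1][:, :, None] + Tm[None], axis=1) + phi[:, t]
        logZ = _lse(alphas[L - 1], axis=1)  # (N,)

        betas = np.empty((L, N, n_lab))
        betas[L - 1] = 0.0
        for t in range(L - 2, -1, -1):
            betas[t] = _lse(Tm[None] + (phi[:, t + 1] + betas[t + 1])[:, None, :], axis=2)

        rows = np.arange(N)
        score_gold = phi[rows[:, None], np.arange(L)[None, :], gold].sum(axis=1)
        score_gold += b0[gold[:, 0]]
        if L > 1:
            score_gold += T[gold[:, :-1], gold[:, 1:]].sum(axis=1)
        nll += float((logZ - score_gold).sum())

        # node marginals -> emission and start gradients
        mu = np.exp(
            alphas.transpose(1, 0, 2) + betas.transpose(1, 0, 2) - logZ[:, None, None]
        )  # (N, L, Y)
        flatF = F.reshape(-1)
        mu_rep = np.repeat(mu.reshape(N * L, n_lab), K, axis=0)
        for y in range(n_lab):
            gW[:, y] += np.bincount(flatF, weights=mu_rep[:, y], minlength=n_feat + 1)
        obs = np.bincount(
            flatF * n_lab + np.repeat(gold.reshape(-1), K),
            minlength=(n_feat + 1) * n_lab,
        ).reshape(n_feat + 1, n_lab)
        gW -= obs
        gb += mu[:, 0, :].sum(axis=0)
        gb -= np.bincount(gold[:, 0], minlength=n_lab).astype(float)

        # pairwise marginals -> transition gradient
        for t in range(1, L):
            lg = (
                alphas[t - 1][:, :, None]
                + Tm[None]
                + (phi[:, t] + betas[t])[:, None, :]
                - logZ[:, None, None]
            )
            gT += np.exp(lg).sum(axis=0)
        if L > 1:
            gT -= np.bincount(
                gold[:, :-1].reshape(-1) * n_lab + gold[:, 1:].reshape(-1),
                minlength=n_lab * n_lab,
            ).reshape(n_lab, n_lab)

    grad = np.concatenate([gW[:-1].ravel(), gT.ravel(), gb])
    grad += 2.0 * l2 * theta
    return nll, grad


def train(
    labeled: Sequence[LabeledSentence],
    hyperparams: CRFHyperparams | None = None,
    init_model: TaggerModel | None = None,
    labels: Sequence[str] | None = None,
    feature_index: dict[str, int] | None = None,
    pre_indexed: Sequence[IndexedSentence] | None = None,
) -> TaggerModel:
    """Fit the CRF on gold-annotated sentences.

    Deterministic under fixed hyperparameters and input order.  Passing
    ``init_model`` warm-starts from a previous fit (weights of features seen
    before are carried over; the iteration cap drops to ``refit_max_iter``),
    which is how the simulation loop retrains after each queried batch.

    ``feature_index`` fixes the vocabulary (e.g. one built over the whole
    pool), letting callers reuse ``pre_indexed`` integer feature arrays from
    :func:`index_sentences` across retrains.
    """
    if not labeled:
        raise ValueError("cannot train on an empty set of labeled sentences")
    hp = hyperparams or CRFHyperparams()
    label_list = list(labels) if labels is not None else list(CLINICAL_LABELS)
    lab_index = {lab: i for i, lab in enumerate(label_list)}

    if feature_index is None:
        feature_index = {}
        feat_idx = index_sentences(labeled, feature_index, hp.feature_set, grow=True)
    elif pre_indexed is not None:
        feat_idx = list(pre_indexed)
    else:
        feat_idx = index_sentences(labeled, feature_index, hp.feature_set, grow=False)
    gold_idx = [[lab_index[t] for t in bio_encode(s)] for s in labeled]

    n_feat, n_lab = len(feature_index), len(label_list)
    tmask, smask = bio_constraint_masks(label_list)

    theta0 = np.zeros(n_feat * n_lab + n_lab * n_lab + n_lab)
    max_iter = hp.max_iter
    if init_model is not None and init_model.labels == label_list:
        W0 = theta0[: n_feat * n_lab].reshape(n_feat, n_lab)
        if init_model.feature_index is feature_index:
            W0[: init_model.emission.shape[0]] = init_model.emission
        else:
            for f, j_old in init_model.feature_index.items():
                j_new = feature_index.get(f)
                if j_new is not None:
                    W0[j_new] = init_model.emission[j_old]
        theta0[n_feat * n_lab : n_feat * n_lab + n_lab * n_lab] = (
            init_model.transition.ravel()
        )
        theta0[-n_lab:] = init_model.start
        max_iter = hp.refit_max_iter

    groups = _group_by_length(feat_idx, gold_idx, pad=n_feat)
    res = minimize(
        _nll_and_grad,
        theta0,
        args=(groups, n_feat, n_lab, hp.l2, tmask, smask),
        method="L-BFGS-B",
        jac=True,
        options={"maxiter": max_iter, "maxcor": 10},
    )
    theta = res.x
    return TaggerModel(
        labels=label_list,
        feature_index=feature_index,
        emission=theta[: n_feat * n_lab].reshape(n_feat, n_lab).copy(),
        transition=theta[n_feat * n_lab : n_feat * n_lab + n_lab * n_lab]
        .reshape(n_lab, n_lab)
        .copy(),
        start=theta[-n_lab:].copy(),
        feature_set=hp.feature_set,
        trans_mask=tmask,
        start_mask=smask,
    )


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def sentence_potentials(
    model: TaggerModel, sentence: LabeledSentence
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(phi, masked transition, masked start) log-potentials for one sentence.

    Exposed so that exhaustive path-enumeration oracles can score the exact
    same potential tables the decoder uses.
    """
    bags = extract_features(sentence, model.feature_set)
    phi = np.zeros((len(bags), model.n_labels))
    for t, bag in enumerate(bags):
        for f in bag:
            j = model.feature_index.get(f)
            if j is not None:
                phi[t] += model.emission[j]
    return phi, model.transition + model.trans_mask, model.start + model.start_mask


def decode_indexed(
    model: TaggerModel, feat_idx: Sequence[IndexedSentence]
) -> list[SequencePrediction]:
    """Viterbi decoding over pre-indexed feature arrays (the fast path)."""
    if model is None:
        raise ValueError("no trained model to decode with")
    n_lab = model.n_labels
    pad = len(model.feature_index)
    Wpad = np.vstack([model.emission, np.zeros((1, n_lab))])
    Tm = model.transition + model.trans_mask
    b0m = model.start + model.start_mask

    preds: list[SequencePrediction | None] = [None] * len(feat_idx)
    for F, _, order in _group_by_length(feat_idx, None, pad=pad):
        N, L, _ = F.shape
        phi = Wpad[F].sum(axis=2)

        # Viterbi
        delta = phi[:, 0] + b0m
        back = np.empty((L, N, n_lab), dtype=np.int64)
        for t in range(1, L):
            m = delta[:, :, None] + Tm[None]
            back[t] = m.argmax(axis=1)
            delta = m.max(axis=1) + phi[:, t]
        best_last = delta.argmax(axis=1)
        best_score = delta[np.arange(N), best_last]

        paths = np.empty((N, L), dtype=np.int64)
        paths[:, L - 1] = best_last
        for t in range(L - 1, 0, -1):
            paths[:, t - 1] = back[t][np.arange(N), paths[:, t]]

        # forward pass for log Z
        alpha = phi[:, 0] + b0m
        for t in range(1, L):
            alpha = _lse(alpha[:, :, None] + Tm[None], axis=1) + phi[:, t]
        logZ = _lse(alpha, axis=1)

        prob = np.exp(np.minimum(best_score - logZ, 0.0))
        for r, i in enumerate(order):
            preds[i] = SequencePrediction(
                tags=[model.labels[j] for j in paths[r]],
                best_path_prob=float(prob[r]),
            )
    return preds  # type: ignore[return-value]


def decode_many(
    model: TaggerModel, sentences: Sequence[LabeledSentence]
) -> list[SequencePrediction]:
    """Viterbi-decode a batch of sentences (grouped by length for speed)."""
    feat_idx = index_sentences(
        sentences, model.feature_index, model.feature_set, grow=False
    )
    return decode_indexed(model, feat_idx)


def decode(model: TaggerModel, sentence: LabeledSentence) -> SequencePrediction:
    """Best tag sequence and its exact conditional probability."""
    return decode_many(model, [sentence])[0]


def predict_sentence(model: TaggerModel, sentence: LabeledSentence) -> LabeledSentence:
    """Decode and return a copy of ``sentence`` carrying the predicted spans."""
    pred = decode(model, sentence)
    return replace(sentence, spans=bio_decode(pred.tags))
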