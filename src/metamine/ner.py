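"""Per-entity sequence labelers: training, model selection, evaluation, decoding.

The default backend is a feature-based first-order conditional sequence
model: an averaged structured perceptron with a Hamming-cost-augmented
Viterbi decode (margin training) over token features (lowercased identity,
shape, 3-character prefix/suffix, neighbours ±2, subword-continuation and
preserved-unknown flags) plus learned B/I/O transition scores.  The
structural constraint that I may not follow O (or start a sentence) is
enforced in the decoder.

Hyperparameter selection follows the conventional fine-tuning grid — five
learning rates {1e-5..5e-5} × seven epoch counts {10..130}; the learning
rate is mapped to the perceptron's step size through a fixed scale so the
grid spans steps 0.2–1.0 against a unit margin.  Each learning rate is
trained once up to the largest epoch count with the model snapshotted at
every grid epoch, which is identical to training each (rate, epochs) pair
from scratch (one seeded shuffle stream) at a fraction of the cost.  A
transformer fine-tuning backend can be plugged in behind the same interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .bio_datasets import (
    EntityDataset,
    SubwordVocabulary,
    TaggedSentence,
    Token,
    TokenizedSentence,
    wordpiece_tokenize,
)
from .corpus_io import Document
from .schema import ENTITY_TYPES, SpanAnnotation

logger = logging.getLogger(__name__)

LABELS = ("O", "B", "I")  # O first: decoder ties resolve to O
_LAB2ID = {lab: i for i, lab in enumerate(LABELS)}
_NEG = -1e9  # structural ban: I after O, I at sentence start

#: grid learning rates are transformer fine-tuning magnitudes; the perceptron
#: step is lr * LR_SCALE, spanning 0.2..1.0 against the unit Hamming margin
LR_SCALE = 2e4


@dataclass
class LabelerConfig:
    backend: str = "feature-sequence"
    learning_rate_grid: tuple[float, ...] = (1e-5, 2e-5, 3e-5, 4e-5, 5e-5)
    epoch_grid: tuple[int, ...] = (10, 30, 50, 70, 90, 110, 130)
    batch_size: int = 32  # interface parity; the perceptron updates online
    max_len: int = 128
    seed: int = 9

    def __post_init__(self) -> None:
        if not self.learning_rate_grid or not self.epoch_grid:
            raise ValueError("hyperparameter grids must be non-empty")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# --- features -----------------------------------------------------------------


def _shape(text: str) -> str:
    out = []
    for ch in text:
        if ch.isupper():
            c = "A"
        elif ch.islower():
            c = "a"
        elif ch.isdigit():
            c = "d"
        else:
            c = "o"
        if not out or out[-1] != c:
            out.append(c)
    return "".join(out)


N_FEATURES_PER_TOKEN = 13


def token_features(tokens: Sequence[Token], t: int) -> list[str]:
    """Fixed-width feature template for token t (13 features)."""
    tok = tokens[t]
    low = tok.text.lower()

    def neigh(off: int, what: str) -> str:
        j = t + off
        if 0 <= j < len(tokens):
            return tokens[j].text.lower() if what == "w" else _shape(tokens[j].text)
        return "<pad>"

    return [
        "bias",
        f"w={low}",
        f"shape={_shape(tok.text)}",
        f"pre3={low[:3]}",
        f"suf3={low[-3:]}",
        f"-1w={neigh(-1, 'w')}",
        f"-2w={neigh(-2, 'w')}",
        f"+1w={neigh(1, 'w')}",
        f"+2w={neigh(2, 'w')}",
        f"-1s={neigh(-1, 's')}",
        f"+1s={neigh(1, 's')}",
        f"cont={int(tok.is_continuation_piece)}",
        f"punk={int(tok.is_preserved_unknown)}",
    ]


def _encode(
    sentences: Sequence[TaggedSentence] | Sequence[TokenizedSentence],
    index: dict[str, int],
    grow: bool,
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Feature-id matrix (n_tokens × 13) and gold label ids per sentence.
    Unknown features map to the reserved zero-weight id 0 when not growing."""
    feats: list[np.ndarray] = []
    golds: list[np.ndarray] = []
    for sent in sentences:
        if isinstance(sent, TaggedSentence):
            tokens = sent.tokenized.tokens
            gold = np.array([_LAB2ID[t] for t in sent.tags], dtype=np.int64)
        else:
            tokens = sent.tokens
            gold = np.zeros(len(tokens), dtype=np.int64)
        ids = np.zeros((len(tokens), N_FEATURES_PER_TOKEN), dtype=np.int64)
        for t in range(len(tokens)):
            for k, f in enumerate(token_features(tokens, t)):
                if grow:
                    fid = index.setdefault(f, len(index))
                else:
                    fid = index.get(f, 0)
                ids[t, k] = fid
        feats.append(ids)
        golds.append(gold)
    return feats, golds


# --- decoding -----------------------------------------------------------------


def _viterbi(E: np.ndarray, T: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Best label path for emissions E (n×3) under transitions T and start S.
    Structural constraints (no initial I, no O→I) are applied here."""
    n = E.shape[0]
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    mask = np.zeros((3, 3))
    mask[_LAB2ID["O"], _LAB2ID["I"]] = _NEG
    start = S.copy()
    start[_LAB2ID["I"]] = _NEG
    delta = E[0] + start
    back = np.zeros((n, 3), dtype=np.int64)
    for t in range(1, n):
        scores = delta[:, None] + T + mask
        back[t] = np.argmax(scores, axis=0)
        delta = E[t] + scores[back[t], np.arange(3)]
    path = np.zeros(n, dtype=np.int64)
    path[-1] = int(np.argmax(delta))
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path


# --- the labeler --------------------------------------------------------------


@dataclass
class SequenceLabeler:
    entity_type: str
    backend: str = "feature-sequence"
    learning_rate: float = 3e-5
    epochs: int = 50
    seed: int = 9
    degenerate: bool = False  # trained without any B tag: predicts all O
    feature_index: dict[str, int] = field(default_factory=dict, repr=False)
    W: np.ndarray | None = field(default=None, repr=False)  # (n_feats, 3)
    T: np.ndarray | None = field(default=None, repr=False)  # (3, 3)
    S: np.ndarray | None = field(default=None, repr=False)  # (3,)

    def _predict_ids(self, feat_ids: np.ndarray) -> np.ndarray:
        E = self.W[feat_ids].sum(axis=1)
        return _viterbi(E, self.T, self.S)

    def predict_tags(self, sentence: TokenizedSentence | TaggedSentence) -> list[str]:
        if isinstance(sentence, TaggedSentence):
            sentence = sentence.tokenized
        feats, _ = _encode([sentence], self.feature_index, grow=False)
        return [LABELS[i] for i in self._predict_ids(feats[0])]


def _snapshot(W, T, S, UW, UT, US, c):
    c = max(c, 1)
    return (W - UW / c, T - UT / c, S - US / c)


def _train_raw(
    feats: list[np.ndarray],
    golds: list[np.ndarray],
    n_feats: int,
    step: float,
    snapshot_epochs: Sequence[int],
    seed: int,
) -> dict[int, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Averaged margin-perceptron training with snapshots at listed epochs."""
    rng = np.random.default_rng(seed)
    W = np.zeros((n_feats, 3))
    T = np.zeros((3, 3))
    S = np.zeros(3)
    UW = np.zeros((n_feats, 3))
    UT = np.zeros((3, 3))
    US = np.zeros(3)
    c = 0
    snapshots: dict[int, tuple] = {}
    max_epoch = max(snapshot_epochs)
    converged = False
    n_sent = len(feats)
    order = np.arange(n_sent)

    for epoch in range(1, max_epoch + 1):
        if converged:
            c += n_sent  # weights frozen; only the averaging clock advances
        else:
            order = rng.permutation(n_sent)
            updates = 0
            for si in order:
                c += 1
                ids, gold = feats[si], golds[si]
                n = len(gold)
                if n == 0:
                    continue
                E = W[ids].sum(axis=1)
                # Hamming-cost-augmented decode: unit margin per wrong token
                cost = np.ones((n, 3))
                cost[np.arange(n), gold] = 0.0
                pred = _viterbi(E + cost, T, S)
                if np.array_equal(pred, gold):
                    continue
                updates += 1
                for t in range(n):
                    if pred[t] != gold[t]:
                        W[ids[t], gold[t]] += step
                        W[ids[t], pred[t]] -= step
                        UW[ids[t], gold[t]] += c * step
                        UW[ids[t], pred[t]] -= c * step
                if pred[0] != gold[0]:
                    S[gold[0]] += step
                    S[pred[0]] -= step
                    US[gold[0]] += c * step
                    US[pred[0]] -= c * step
                for t in range(1, n):
                    gp, pp = (gold[t - 1], gold[t]), (pred[t - 1], pred[t])
                    if gp != pp:
                        T[gp] += step
                        T[pp] -= step
                        UT[gp] += c * step
                        UT[pp] -= c * step
            if updates == 0:
                converged = True
        if epoch in snapshot_epochs:
            snapshots[epoch] = _snapshot(W, T, S, UW, UT, US, c)
    return snapshots


def train_labeler(
    dataset: EntityDataset | Sequence[TaggedSentence],
    learning_rate: float = 3e-5,
    epochs: int = 50,
    config: LabelerConfig | None = None,
) -> SequenceLabeler:
    """Train one labeler at a fixed (learning_rate, epochs) setting."""
    config = config or LabelerConfig()
    train = dataset.train if isinstance(dataset, EntityDataset) else list(dataset)
    if not train:
        raise ValueError("empty training split")
    etype = train[0].entity_type
    index: dict[str, int] = {"<pad>": 0}
    feats, golds = _encode(train, index, grow=True)
    degenerate = not any((g == _LAB2ID["B"]).any() for g in golds)
    if degenerate:
        logger.warning("entity %s: no B tags in training data; "
                       "model will predict all O", etype)
    snaps = _train_raw(
        feats, golds, len(index), learning_rate * LR_SCALE,
        snapshot_epochs=[epochs], seed=config.seed,
    )
    W, T, S = snaps[epochs]
    return SequenceLabeler(
        entity_type=etype, backend=config.backend,
        learning_rate=learning_rate, epochs=epochs, seed=config.seed,
        degenerate=degenerate, feature_index=index, W=W, T=T, S=S,
    )


# --- evaluation ---------------------------------------------------------------


@dataclass
class EvalReport:
    per_class: dict[str, dict[str, float]]  # label -> P/R/F1/support
    macro_precision: float
    macro_recall: float
    macro_f1: float
    n_tokens: int


def _flatten(tags) -> list[str]:
    if tags and isinstance(tags[0], (list, tuple)):
        return [t for seq in tags for t in seq]
    return list(tags)


def evaluate_tokenwise(pred_tags, gold_tags) -> EvalReport:
    """Token-wise per-class and macro P/R/F1 over the B/I/O confusion.

    Accepts aligned tag sequences or lists of sequences.  Macro averages are
    unweighted means over classes present in the gold; per-class F1 is the
    harmonic mean of that class's P and R (0 when both are 0).
    """
    if len(pred_tags) != len(gold_tags):
        raise ValueError("prediction/gold length mismatch")
    if pred_tags and isinstance(pred_tags[0], (list, tuple)):
        for p, g in zip(pred_tags, gold_tags):
            if len(p) != len(g):
                raise ValueError("prediction/gold length mismatch")
    pred = _flatten(pred_tags)
    gold = _flatten(gold_tags)

    per_class: dict[str, dict[str, float]] = {}
    present = [lab for lab in LABELS if lab in gold]
    for lab in present:
        tp = sum(1 for p, g in zip(pred, gold) if p == lab and g == lab)
        fp = sum(1 for p, g in zip(pred, gold) if p == lab and g != lab)
        fn = sum(1 for p, g in zip(pred, gold) if p != lab and g == lab)
        precision = tp / (tp + fp) if tp + fp else 0.0
        recall = tp / (tp + fn) if tp + fn else 0.0
        f1 = (2 * precision * recall / (precision + recall)
              if precision + recall else 0.0)
        per_class[lab] = {
            "precision": precision, "recall": recall, "f1": f1,
            "support": float(gold.count(lab)),
        }
    k = len(present) or 1
    return EvalReport(
        per_class=per_class,
        macro_precision=sum(per_class[l]["precision"] for l in present) / k,
        macro_recall=sum(per_class[l]["recall"] for l in present) / k,
        macro_f1=sum(per_class[l]["f1"] for l in present) / k,
        n_tokens=len(gold),
    )


# --- grid search --------------------------------------------------------------


def grid_search(
    dataset: EntityDataset, config: LabelerConfig | None = None
) -> tuple[SequenceLabeler, list[dict]]:
    """Exhaustive (learning rate × epochs) search on the test split.

    Returns the best labeler (max token-wise macro-F1; ties broken by fewer
    epochs, then lower learning rate) and one report row per combination:
    {entity, learning_rate, epoch, recall, precision, f1}.
    """
    config = config or LabelerConfig()
    if not dataset.train:
        raise ValueError("empty training split")
    etype = dataset.entity_type
    index: dict[str, int] = {"<pad>": 0}
    tr_feats, tr_golds = _encode(dataset.train, index, grow=True)
    te_feats, te_golds = _encode(dataset.test, index, grow=False)
    gold_tags = [[LABELS[i] for i in g] for g in te_golds]
    degenerate = not any((g == _LAB2ID["B"]).any() for g in tr_golds)

    reports: list[dict] = []
    candidates: list[tuple] = []
    for lr in config.learning_rate_grid:
        snaps = _train_raw(
            tr_feats, tr_golds, len(index), lr * LR_SCALE,
            snapshot_epochs=list(config.epoch_grid), seed=config.seed,
        )
        for epochs in config.epoch_grid:
            W, T, S = snaps[epochs]
            labeler = SequenceLabeler(
                entity_type=etype, backend=config.backend,
                learning_rate=lr, epochs=epochs, seed=config.seed,
                degenerate=degenerate, feature_index=index, W=W, T=T, S=S,
            )
            pred_tags = [
                [LABELS[i] for i in labeler._predict_ids(f)] for f in te_feats
            ]
            rep = evaluate_tokenwise(pred_tags, gold_tags)
            reports.append({
                "entity": etype, "learning_rate": lr, "epoch": epochs,
                "recall": rep.macro_recall, "precision": rep.macro_precision,
                "f1": rep.macro_f1,
            })
            candidates.append((rep.macro_f1, epochs, lr, labeler))

    candidates.sort(key=lambda c: (-c[0], c[1], c[2]))
    return candidates[0][3], reports


# --- span decoding ------------------------------------------------------------


@dataclass
class PredictedSpan:
    doc_id: str
    sent_id: str
    entity_type: str
    char_start: int
    char_end: int
    exact_text: str


def decode_spans(tagged: TaggedSentence) -> list[PredictedSpan]:
    """Decode B/I runs back to character spans (an I with no preceding B/I is
    repaired to B and logged)."""
    spans: list[PredictedSpan] = []
    tokens = tagged.tokenized.tokens
    text = tagged.tokenized.text
    run: list[int] = []

    def close_run() -> None:
        if run:
            start = tokens[run[0]].char_start
            end = tokens[run[-1]].char_end
            spans.append(PredictedSpan(
                doc_id=tagged.tokenized.doc_id,
                sent_id=tagged.tokenized.sent_id,
                entity_type=tagged.entity_type,
                char_start=start, char_end=end,
                exact_text=text[start:end],
            ))
            run.clear()

    for i, tag in enumerate(tagged.tags):
        if tag == "B":
            close_run()
            run.append(i)
        elif tag == "I":
            if not run:
                logger.info("sentence %s: I-start at token %d repaired to B",
                            tagged.tokenized.sent_id, i)
            run.append(i)
        else:
            close_run()
    close_run()
    return spans


def predicted_to_annotation(
    span: PredictedSpan, context_chars: int = 30
) -> SpanAnnotation:
    """Convert a predicted span into an anchored annotation (provenance
    "predicted") for distillation training data."""
    return SpanAnnotation(
        doc_id=span.doc_id,
        entity_type=span.entity_type,
        exact_text=span.exact_text,
        sent_id=span.sent_id,
        char_start=span.char_start,
        char_end=span.char_end,
        provenance="predicted",
    )


# --- document annotation --------------------------------------------------------


def annotate_document(
    document: Document,
    labelers: dict[str, SequenceLabeler],
    vocab: SubwordVocabulary,
    section_classifier=None,
) -> list[PredictedSpan]:
    """Annotate a document's methods text with all 16 entity labelers.

    Tagged methods sections are used directly; otherwise the section
    classifier recovers methods-like sections.  Overlapping spans across
    entity types are kept; exact duplicates within a type are dropped.
    """
    missing = [t for t in ENTITY_TYPES if t not in labelers]
    if missing:
        raise ValueError(f"missing labelers for entity types: {missing}")

    sections = document.sections_of_type("methods")
    if not sections and section_classifier is not None:
        from .classify import predict_proba
        sections = []
        for sec in document.sections:
            text = sec.text
            if not text:
                continue
            probs = predict_proba(section_classifier, text)
            if max(sorted(probs), key=lambda c: probs[c]) == "methods":
                sections.append(sec)

    spans: list[PredictedSpan] = []
    seen: set[tuple] = set()
    for section in sections:
        for sent in section.sentences:
            tokenized = wordpiece_tokenize(sent, vocab, doc_id=document.doc_id)
            for etype in ENTITY_TYPES:
                labeler = labelers[etype]
                tags = labeler.predict_tags(tokenized)
                tagged = TaggedSentence(
                    entity_type=etype, tokenized=tokenized, tags=tags
                )
                for span in decode_spans(tagged):
                    key = (span.entity_type, span.sent_id,
                           span.char_start, span.char_end)
                    if key not in seen:
                        seen.add(key)
                        spans.append(span)
    return spans
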