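"""Per-entity BIO training data: tokenization, anchoring, tagging, splitting.

Entity mentions may nest across types, so one BIO dataset is built per entity
type over a shared sentence set: a sentence bearing only a kit mention is an
all-O training example in the fifteen other datasets.  Sentences are
tokenized with a WordPiece tokenizer modified to keep words that cannot be
segmented against the vocabulary (long primers, kit names, chemical states
with unusual characters) as single preserved tokens instead of mapping them
to an unknown-token marker — their surface form stays available to the
sequence models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_io import Document, Sentence
from .distant import split_train_test
from .schema import ENTITY_TYPES, SpanAnnotation, validate_entity_type

logger = logging.getLogger(__name__)

UNK_MARKER = "[UNK]"
SPECIAL_TOKENS = ("[PAD]", "[UNK]", "[CLS]", "[SEP]", "[MASK]")
CONTINUATION_PREFIX = "##"
MAX_LEN = 128


class SubwordVocabulary:
    """Subword vocabulary: one token per line, continuations prefixed "##"."""

    def __init__(self, tokens: Iterable[str]):
        self.tokens: set[str] = set(tokens)
        if not self.tokens - set(SPECIAL_TOKENS):
            raise ValueError("empty subword vocabulary")

    def __contains__(self, piece: str) -> bool:
        return piece in self.tokens

    def __len__(self) -> int:
        return len(self.tokens)

    @classmethod
    def load(cls, path: str | Path) -> "SubwordVocabulary":
        with open(path, encoding="utf-8") as fh:
            return cls(line.rstrip("\n") for line in fh if line.strip())

    @classmethod
    def default(cls) -> "SubwordVocabulary":
        """The packaged fixture vocabulary (synthetic, desk-scale)."""
        text = (
            resources.files("metamine")
            .joinpath("data/wordpiece_vocab.txt")
            .read_text(encoding="utf-8")
        )
        return cls(line for line in text.splitlines() if line.strip())

    def save(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for tok in sorted(self.tokens):
                fh.write(tok + "\n")


@dataclass
class Token:
    text: str  # raw sentence slice (never the UNK marker)
    char_start: int
    char_end: int
    is_continuation_piece: bool = False
    is_preserved_unknown: bool = False


@dataclass
class TokenizedSentence:
    doc_id: str
    sent_id: str
    text: str
    tokens: list[Token] = field(default_factory=list)


@dataclass
class TaggedSentence:
    entity_type: str
    tokenized: TokenizedSentence
    tags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.tags) != len(self.tokenized.tokens):
            raise ValueError("tags and tokens must be equal length")


@dataclass
class EntityDataset:
    entity_type: str
    train: list[TaggedSentence]
    test: list[TaggedSentence]
    max_len: int = MAX_LEN


# --- tokenization -------------------------------------------------------------


def _segment_word(word: str, vocab: SubwordVocabulary) -> list[str] | None:
    """Greedy longest-match-first segmentation of a lowercased word; None if
    the word cannot be fully segmented."""
    pieces: list[str] = []
    pos = 0
    n = len(word)
    while pos < n:
        end = n
        found = None
        while end > pos:
            piece = word[pos:end]
            if pos > 0:
                piece = CONTINUATION_PREFIX + piece
            if piece in vocab:
                found = (piece, end)
                break
            end -= 1
        if found is None:
            return None
        pieces.append(found[0])
        pos = found[1]
    return pieces


def wordpiece_tokenize(
    sentence: Sentence | TokenizedSentence | str,
    vocab: SubwordVocabulary,
    doc_id: str = "",
    sent_id: str = "",
) -> TokenizedSentence:
    """Tokenize a sentence into subword pieces with character offsets.

    Words are whitespace-pretokenized, matched lowercased against the
    vocabulary.  A word that cannot be fully segmented is emitted as one
    token with ``is_preserved_unknown=True`` — never as the UNK marker.
    """
    if isinstance(sentence, Sentence):
        text = sentence.text
        sent_id = sent_id or sentence.sent_id
    elif isinstance(sentence, str):
        text = sentence
    else:
        raise TypeError("expected Sentence or str")

    tokens: list[Token] = []
    pos = 0
    n = len(text)
    while pos < n:
        if text[pos].isspace():
            pos += 1
            continue
        end = pos
        while end < n and not text[end].isspace():
            end += 1
        word = text[pos:end]
        pieces = _segment_word(word.lower(), vocab)
        if pieces is None:
            tokens.append(Token(
                text=word, char_start=pos, char_end=end,
                is_preserved_unknown=True,
            ))
        else:
            off = pos
            for i, piece in enumerate(pieces):
                raw_len = len(piece) - (
                    len(CONTINUATION_PREFIX) if i > 0 else 0
                )
                tokens.append(Token(
                    text=text[off:off + raw_len],
                    char_start=off,
                    char_end=off + raw_len,
                    is_continuation_piece=i > 0,
                ))
                off += raw_len
        pos = end
    return TokenizedSentence(doc_id=doc_id, sent_id=sent_id, text=text, tokens=tokens)


# --- anchoring ----------------------------------------------------------------


class AnchorError(ValueError):
    pass


def _context_score(sent_text: str, start: int, end: int,
                   prefix: str, suffix: str) -> int:
    """Longest suffix-of-prefix + prefix-of-suffix agreement at a candidate."""
    before = sent_text[:start]
    score = 0
    k = min(len(before), len(prefix))
    while score < k and prefix[len(prefix) - 1 - score] == before[len(before) - 1 - score]:
        score += 1
    after = sent_text[end:]
    j = 0
    k = min(len(after), len(suffix))
    while j < k and suffix[j] == after[j]:
        j += 1
    return score + j


def anchor_annotation(document: Document, ann: SpanAnnotation) -> SpanAnnotation:
    """Resolve an annotation's exact text (+ context) to a sentence and
    sentence-relative offsets.  Raises AnchorError when the exact text does
    not occur or remains ambiguous after context matching."""
    if not ann.exact_text:
        raise AnchorError("empty exact text")
    candidates: list[tuple[str, int, int, str]] = []  # sent_id, start, end, text
    for section in document.sections:
        for sent in section.sentences:
            start = sent.text.find(ann.exact_text)
            while start != -1:
                candidates.append(
                    (sent.sent_id, start, start + len(ann.exact_text), sent.text)
                )
                start = sent.text.find(ann.exact_text, start + 1)
    if not candidates:
        raise AnchorError(
            f"{ann.exact_text!r} not found in document {document.doc_id}"
        )
    if len(candidates) > 1:
        scored = [
            (_context_score(text, s, e, ann.prefix, ann.suffix), sid, s, e, text)
            for sid, s, e, text in candidates
        ]
        scored.sort(key=lambda t: -t[0])
        if scored[0][0] == scored[1][0]:
            raise AnchorError(
                f"{ann.exact_text!r} ambiguous in document {document.doc_id}: "
                f"{len(candidates)} occurrences with tied context"
            )
        _, sid, start, end, _ = scored[0]
    else:
        sid, start, end, _ = candidates[0]
    return SpanAnnotation(
        doc_id=document.doc_id,
        entity_type=ann.entity_type,
        exact_text=ann.exact_text,
        prefix=ann.prefix,
        suffix=ann.suffix,
        sent_id=sid,
        char_start=start,
        char_end=end,
        provenance=ann.provenance,
    )


def anchor_all(
    corpus: Sequence[Document], annotations: Sequence[SpanAnnotation]
) -> tuple[list[SpanAnnotation], list[dict]]:
    """Anchor every annotation; failures are collected in a rejects report."""
    by_id = {d.doc_id: d for d in corpus}
    anchored: list[SpanAnnotation] = []
    rejects: list[dict] = []
    for ann in annotations:
        doc = by_id.get(ann.doc_id)
        if doc is None:
            rejects.append({"doc_id": ann.doc_id, "exact": ann.exact_text,
                            "reason": "unknown document"})
            continue
        try:
            anchored.append(anchor_annotation(doc, ann))
        except AnchorError as exc:
            rejects.append({"doc_id": ann.doc_id, "exact": ann.exact_text,
                            "reason": str(exc)})
    return anchored, rejects


# --- BIO tagging --------------------------------------------------------------


def bio_tag(
    tokenized: TokenizedSentence,
    spans: Sequence[SpanAnnotation],
    entity_type: str | None = None,
) -> TaggedSentence:
    """Tag tokens B/I/O against anchored spans of a single entity type.

    A token is inside a span iff its character range overlaps the span's;
    the first inside token of each span is B, subsequent ones I.  Adjacent
    distinct spans each restart at B.
    """
    types = {s.entity_type for s in spans}
    if len(types) > 1:
        raise ValueError(f"spans of mixed entity types: {sorted(types)}")
    etype = entity_type or (types.pop() if types else "")
    tags = ["O"] * len(tokenized.tokens)
    for span in sorted(spans, key=lambda s: (s.char_start, s.char_end)):
        first = True
        for i, tok in enumerate(tokenized.tokens):
            if tok.char_start < span.char_end and tok.char_end > span.char_start:
                if tags[i] != "O":
                    first = False  # same-type overlap: do not restart
                    continue
                tags[i] = "B" if first else "I"
                first = False
    return TaggedSentence(entity_type=etype, tokenized=tokenized, tags=tags)


def truncate_to_max_len(
    tagged: TaggedSentence, max_len: int = MAX_LEN
) -> tuple[TaggedSentence, bool]:
    """Keep the first max_len tokens/tags; flag set iff tokens were dropped.
    Gold spans lying entirely beyond the limit are logged as unlearnable."""
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if len(tagged.tags) <= max_len:
        return tagged, False
    dropped = tagged.tags[max_len:]
    lost_spans = sum(1 for t in dropped if t == "B")
    if lost_spans:
        logger.info(
            "sentence %s: %d %s span(s) beyond position %d are unlearnable",
            tagged.tokenized.sent_id, lost_spans, tagged.entity_type, max_len,
        )
    out = TaggedSentence(
        entity_type=tagged.entity_type,
        tokenized=TokenizedSentence(
            doc_id=tagged.tokenized.doc_id,
            sent_id=tagged.tokenized.sent_id,
            text=tagged.tokenized.text,
            tokens=tagged.tokenized.tokens[:max_len],
        ),
        tags=tagged.tags[:max_len],
    )
    return out, True


# --- per-entity datasets ------------------------------------------------------


def build_entity_datasets(
    corpus: Sequence[Document],
    annotations: Sequence[SpanAnnotation],
    vocab: SubwordVocabulary,
    seed: int = 9,
    train_frac: float | None = 0.9,
    only_annotated: bool = True,
    max_len: int = MAX_LEN,
) -> dict[str, EntityDataset]:
    """Build the 16 per-entity BIO datasets over one shared sentence set.

    All datasets contain the same sentences and share one train/test split
    (drawn once on sentences), so no sentence leaks across the split in any
    entity model.  ``train_frac=None`` puts everything in train (used for
    distillation training sets built from predicted annotations).
    """
    for ann in annotations:
        validate_entity_type(ann.entity_type)
        if not ann.is_anchored():
            raise ValueError(f"annotation {ann.exact_text!r} is not anchored")

    spans_by_sent: dict[str, list[SpanAnnotation]] = {}
    for ann in annotations:
        spans_by_sent.setdefault(ann.sent_id, []).append(ann)

    sentences: list[tuple[str, Sentence]] = []  # (doc_id, sentence)
    for doc in corpus:
        for section in doc.sections:
            for sent in section.sentences:
                if only_annotated and sent.sent_id not in spans_by_sent:
                    continue
                sentences.append((doc.doc_id, sent))

    tokenized = [
        wordpiece_tokenize(sent, vocab, doc_id=doc_id)
        for doc_id, sent in sentences
    ]

    if train_frac is None:
        train_tok, test_tok = tokenized, []
    else:
        train_tok, test_tok = split_train_test(
            tokenized, train_frac=train_frac, seed=seed
        )

    datasets: dict[str, EntityDataset] = {}
    for etype in ENTITY_TYPES:
        def tag_all(toks: list[TokenizedSentence]) -> list[TaggedSentence]:
            out = []
            for ts in toks:
                spans = [
                    a for a in spans_by_sent.get(ts.sent_id, [])
                    if a.entity_type == etype
                ]
                tagged = bio_tag(ts, spans, entity_type=etype)
                tagged, _ = truncate_to_max_len(tagged, max_len)
                out.append(tagged)
            return out

        datasets[etype] = EntityDataset(
            entity_type=etype,
            train=tag_all(train_tok),
            test=tag_all(test_tok),
            max_len=max_len,
        )
    return datasets


# --- annotation JSONL + dataset TSV ------------------------------------------


def write_annotations_jsonl(
    annotations: Iterable[SpanAnnotation], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a in annotations:
            fh.write(json.dumps({
                "doc_id": a.doc_id,
                "exact": a.exact_text,
                "prefix": a.prefix,
                "suffix": a.suffix,
                "entity_type": a.entity_type,
                "provenance": a.provenance,
                "sent_id": a.sent_id,
                "char_start": a.char_start,
                "char_end": a.char_end,
            }, ensure_ascii=False))
            fh.write("\n")


def read_annotations_jsonl(path: str | Path) -> list[SpanAnnotation]:
    out: list[SpanAnnotation] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                out.append(SpanAnnotation(
                    doc_id=obj["doc_id"],
                    entity_type=obj["entity_type"],
                    exact_text=obj["exact"],
                    prefix=obj.get("prefix", ""),
                    suffix=obj.get("suffix", ""),
                    sent_id=obj.get("sent_id"),
                    char_start=obj.get("char_start"),
                    char_end=obj.get("char_end"),
                    provenance=obj.get("provenance", "curated"),
                ))
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"line {lineno}: malformed annotation: {exc}") from exc
    return out


def write_dataset_tsv(dataset: EntityDataset, outdir: str | Path) -> None:
    outdir = Path(outdir) / dataset.entity_type
    outdir.mkdir(parents=True, exist_ok=True)
    for name, part in (("train.tsv", dataset.train), ("test.tsv", dataset.test)):
        with open(outdir / name, "w", encoding="utf-8") as fh:
            fh.write("sent_id\ttoken\tchar_start\tchar_end\ttag\n")
            for ts in part:
                for tok, tag in zip(ts.tokenized.tokens, ts.tags):
                    fh.write(f"{ts.tokenized.sent_id}\t{tok.text}\t"
                             f"{tok.char_start}\t{tok.char_end}\t{tag}\n")
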