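"""Article corpus I/O: a JATS-like XML subset and a canonical JSONL dialect.

Documents are sectioned, sections are sentence-segmented, and every sentence
carries 0-based half-open character offsets into its parent section's text
(code points, not bytes).  Section headings are normalised to one of six
canonical types via a heading synonym table.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from lxml import etree

CANONICAL_SECTION_TYPES = (
    "abstract",
    "introduction",
    "methods",
    "results",
    "discussion",
    "other",
)

#: Heading → canonical section type.  Case-insensitive lookup after
#: whitespace normalisation.  Editable: pass your own table to read_jats.
DEFAULT_HEADING_SYNONYMS: dict[str, str] = {
    "abstract": "abstract",
    "summary": "abstract",
    "introduction": "introduction",
    "background": "introduction",
    "methods": "methods",
    "method": "methods",
    "materials and methods": "methods",
    "material and methods": "methods",
    "methods and materials": "methods",
    "experimental procedures": "methods",
    "experimental section": "methods",
    "results": "results",
    "findings": "results",
    "discussion": "discussion",
    "results and discussion": "results",
    "conclusions": "discussion",
    "conclusion": "discussion",
}


@dataclass
class Sentence:
    sent_id: str
    text: str
    char_start: int
    char_end: int

    def __post_init__(self) -> None:
        if self.char_start >= self.char_end:
            raise ValueError(
                f"sentence {self.sent_id!r}: char_start must be < char_end"
            )


@dataclass
class Section:
    heading: str
    canonical_type: str
    sentences: list[Sentence] = field(default_factory=list)

    @property
    def text(self) -> str:
        """Section text reconstructed from sentence offsets (gaps → spaces)."""
        if not self.sentences:
            return ""
        end = max(s.char_end for s in self.sentences)
        chars = [" "] * end
        for s in self.sentences:
            chars[s.char_start : s.char_end] = list(s.text)
        return "".join(chars)


@dataclass
class Document:
    doc_id: str
    source_id: str | None
    title: str
    sections: list[Section] = field(default_factory=list)

    def sections_of_type(self, canonical_type: str) -> list[Section]:
        return [s for s in self.sections if s.canonical_type == canonical_type]

    @property
    def full_text(self) -> str:
        return " ".join(sec.text for sec in self.sections)


def canonical_section_type(
    heading: str, synonyms: dict[str, str] | None = None
) -> str:
    """Map a raw heading to a canonical section type (default "other")."""
    table = DEFAULT_HEADING_SYNONYMS if synonyms is None else synonyms
    key = re.sub(r"\s+", " ", heading).strip().lower()
    return table.get(key, "other")


# --- sentence segmentation --------------------------------------------------

#: Tokens that end with a period but do not terminate a sentence.
ABBREVIATIONS = {
    "e.g.", "i.e.", "et al.", "etc.", "fig.", "figs.", "approx.", "ca.",
    "cf.", "vs.", "sp.", "spp.", "subsp.", "no.", "dr.", "st.",
}

_BOUNDARY = re.compile(r"[.!?]+(?=\s+|$)")


def _is_abbreviation(text: str, end: int) -> bool:
    """True if the terminator ending at `end` closes a guarded abbreviation."""
    prefix = text[:end]
    low = prefix.lower()
    for abbr in ABBREVIATIONS:
        if low.endswith(abbr):
            return True
    # single capital letter + period, e.g. genus initials in "E. coli"
    m = re.search(r"(?:^|\s)([A-Z])\.$", prefix)
    return m is not None


def segment_sentences(text: str, id_prefix: str = "s") -> list[Sentence]:
    """Split text into sentences on terminators, guarding abbreviations.

    Returns ordered, non-overlapping Sentence spans; offsets index the input
    string so that ``text[s.char_start:s.char_end] == s.text``.  Empty or
    all-whitespace input yields an empty list.
    """
    sentences: list[Sentence] = []
    start = 0
    n = len(text)

    def emit(lo: int, hi: int) -> None:
        # trim whitespace off both ends, keep offsets consistent
        while lo < hi and text[lo].isspace():
            lo += 1
        while hi > lo and text[hi - 1].isspace():
            hi -= 1
        if lo < hi:
            sentences.append(
                Sentence(
                    sent_id=f"{id_prefix}{len(sentences)}",
                    text=text[lo:hi],
                    char_start=lo,
                    char_end=hi,
                )
            )

    for m in _BOUNDARY.finditer(text):
        end = m.end()
        if _is_abbreviation(text, end):
            continue
        emit(start, end)
        start = end
    if start < n:
        emit(start, n)
    return sentences


# --- JATS-like XML ----------------------------------------------------------


def read_jats(
    xml_bytes: bytes,
    doc_id: str | None = None,
    synonyms: dict[str, str] | None = None,
) -> Document:
    """Parse a JATS-like article (article/front/title, body/sec/title/p).

    One Section per top-level ``sec`` element; nested sub-sections are
    flattened into their top-level parent.  Paragraph text is concatenated
    (whitespace-normalised) and sentence-segmented.  An empty body yields a
    Document with zero sections.
    """
    try:
        root = etree.fromstring(xml_bytes)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed XML: {exc}") from exc

    title_el = root.find("front/title")
    title = _collapse(_all_text(title_el)) if title_el is not None else ""
    source_el = root.get("source-id")
    did = doc_id or root.get("doc-id") or title or "doc"

    sections: list[Section] = []
    body = root.find("body")
    if body is not None:
        for i, sec in enumerate(body.findall("sec")):
            heading_el = sec.find("title")
            heading = (
                _collapse(_all_text(heading_el)) if heading_el is not None else ""
            )
            paras = [
                _collapse(_all_text(p)) for p in sec.iter("p")
            ]
            text = _collapse(" ".join(p for p in paras if p))
            ctype = canonical_section_type(heading, synonyms) if heading else "other"
            sentences = segment_sentences(text, id_prefix=f"{did}.sec{i}.s")
            sections.append(
                Section(heading=heading, canonical_type=ctype, sentences=sentences)
            )
    return Document(doc_id=did, source_id=source_el, title=title, sections=sections)


def write_jats(doc: Document) -> bytes:
    """Serialise a Document in the JATS-like subset read by read_jats."""
    root = etree.Element("article")
    root.set("doc-id", doc.doc_id)
    if doc.source_id:
        root.set("source-id", doc.source_id)
    front = etree.SubElement(root, "front")
    etree.SubElement(front, "title").text = doc.title
    body = etree.SubElement(root, "body")
    for sec in doc.sections:
        sec_el = etree.SubElement(body, "sec")
        if sec.heading:
            etree.SubElement(sec_el, "title").text = sec.heading
        etree.SubElement(sec_el, "p").text = sec.text
    return etree.tostring(root, pretty_print=True, encoding="utf-8")


def _all_text(el: etree._Element | None) -> str:
    return "".join(el.itertext()) if el is not None else ""


def _collapse(text: str) -> str:
    return re.sub(r"\s+", " ", text).strip()


# --- JSONL corpus dialect ---------------------------------------------------


def document_to_dict(doc: Document) -> dict:
    return {
        "doc_id": doc.doc_id,
        "source_id": doc.source_id,
        "title": doc.title,
        "sections": [
            {
                "heading": sec.heading,
                "canonical_type": sec.canonical_type,
                "sentences": [
                    {
                        "sent_id": s.sent_id,
                        "text": s.text,
                        "char_start": s.char_start,
                        "char_end": s.char_end,
                    }
                    for s in sec.sentences
                ],
            }
            for sec in doc.sections
        ],
    }


def document_from_dict(obj: dict) -> Document:
    return Document(
        doc_id=obj["doc_id"],
        source_id=obj.get("source_id"),
        title=obj.get("title", ""),
        sections=[
            Section(
                heading=sec["heading"],
                canonical_type=sec["canonical_type"],
                sentences=[
                    Sentence(
                        sent_id=s["sent_id"],
                        text=s["text"],
                        char_start=s["char_start"],
                        char_end=s["char_end"],
                    )
                    for sec_s in [sec["sentences"]]
                    for s in sec_s
                ],
            )
            for sec in obj["sections"]
        ],
    )


def write_corpus_jsonl(docs: Iterable[Document], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(document_to_dict(doc), ensure_ascii=False))
            fh.write("\n")


def read_corpus_jsonl(path: str | Path) -> list[Document]:
    docs: list[Document] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                doc = document_from_dict(obj)
            except (json.JSONDecodeError, KeyError, TypeError) as exc:
                raise ValueError(f"line {lineno}: malformed document: {exc}") from exc
            if doc.doc_id in seen:
                raise ValueError(f"line {lineno}: duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)
            docs.append(doc)
    return docs
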