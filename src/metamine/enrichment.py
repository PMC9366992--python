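"""Database enrichment: annotation records, study XML, MIxS comparison.

Publication-derived entity mentions are emitted as literature-archive-style
annotation records (exact text + surrounding context + optional ontology
tags from a pluggable mapper).  Archive study XML supplies sample /
experiment / run accessions and author-submitted fields.  Both sources are
pooled onto MIxS terms and compared per study with an exact-match rule after
light canonicalization (trim, collapse whitespace, case-fold) — format
variants deliberately surface as nonidentical rather than being hidden by
fuzzy matching.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from lxml import etree

from .corpus_io import Document
from .mixs import MIxSMapping
from .ner import PredictedSpan

CONTEXT_CHARS = 30
STATUSES = ("identical", "nonidentical", "unique_submitted",
            "unique_annotation", "absent")


# --- ontology normalization ----------------------------------------------------


class OntologyMapper:
    """Dictionary-backed ontology normalizer.

    Maps (surface term, entity type) to an ontology tag {name, uri, source};
    unmapped terms return None, never an error.  A client for a live mapping
    service can subclass and override lookup().
    """

    def __init__(self, table: Mapping[str, dict] | None = None):
        # keys: "term" or "term|entity_type" (more specific wins)
        self._table = {k.lower(): v for k, v in (table or {}).items()}

    def lookup(self, term: str, entity_type: str) -> dict | None:
        key = f"{term.lower()}|{entity_type}"
        return self._table.get(key) or self._table.get(term.lower())


# --- annotation records ---------------------------------------------------------


@dataclass
class AnnotationRecord:
    collection_id: str
    article_id: str
    provider: str
    annotations: list[dict] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "collection_id": self.collection_id,
            "article_id": self.article_id,
            "provider": self.provider,
            "annotations": self.annotations,
        }, sort_keys=True, ensure_ascii=False)

    @classmethod
    def from_json(cls, text: str) -> "AnnotationRecord":
        obj = json.loads(text)
        return cls(
            collection_id=obj["collection_id"],
            article_id=obj["article_id"],
            provider=obj["provider"],
            annotations=obj["annotations"],
        )


def emit_annotations(
    document: Document,
    predicted_spans: Sequence[PredictedSpan],
    mapper: OntologyMapper | None = None,
    provider: str = "metamine",
    collection_id: str = "metagenomics",
) -> AnnotationRecord:
    """One annotation per span: exact text, ≤30 characters of sentence context
    on each side, the section type, and ontology tags when the mapper knows
    the term."""
    mapper = mapper or OntologyMapper()
    sentences: dict[str, tuple[str, str]] = {}
    for sec in document.sections:
        for sent in sec.sentences:
            sentences[sent.sent_id] = (sent.text, sec.canonical_type)

    annotations = []
    for span in predicted_spans:
        if span.sent_id not in sentences:
            raise ValueError(
                f"span {span.exact_text!r} references unknown sentence "
                f"{span.sent_id} in document {document.doc_id}"
            )
        text, section = sentences[span.sent_id]
        if text[span.char_start:span.char_end] != span.exact_text:
            raise ValueError(
                f"integrity error: span slice mismatch for {span.exact_text!r} "
                f"in sentence {span.sent_id}"
            )
        ann = {
            "exact": span.exact_text,
            "prefix": text[max(0, span.char_start - CONTEXT_CHARS):span.char_start],
            "postfix": text[span.char_end:span.char_end + CONTEXT_CHARS],
            "section": section,
            "entity_type": span.entity_type,
            "tags": [],
        }
        tag = mapper.lookup(span.exact_text, span.entity_type)
        if tag is not None:
            ann["tags"] = [{"name": tag["name"], "uri": tag["uri"]}]
        annotations.append(ann)
    return AnnotationRecord(
        collection_id=collection_id,
        article_id=document.source_id or document.doc_id,
        provider=provider,
        annotations=annotations,
    )


# --- study XML -------------------------------------------------------------------


@dataclass
class StudyMetadata:
    study_id: str
    sample_accessions: list[str] = field(default_factory=list)
    experiment_accessions: list[str] = field(default_factory=list)
    run_accessions: list[str] = field(default_factory=list)
    submitted_fields: dict[str, set[str]] = field(default_factory=dict)
    annotation_values: dict[str, set[str]] = field(default_factory=dict)


_TAG_ATTR = {
    "ENA-SAMPLE": "sample_accessions",
    "ENA-EXPERIMENT": "experiment_accessions",
    "ENA-RUN": "run_accessions",
}


def parse_study_xml(xml: bytes | str) -> StudyMetadata:
    """Parse accessions from ENA-SAMPLE / ENA-EXPERIMENT / ENA-RUN tags
    (missing tags → empty lists)."""
    if isinstance(xml, str):
        xml = xml.encode("utf-8")
    try:
        root = etree.fromstring(xml)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed study XML: {exc}") from exc
    meta = StudyMetadata(study_id=root.get("accession") or root.get("alias") or "")
    for tag, attr in _TAG_ATTR.items():
        for el in root.iter(tag):
            accessions = [a for a in re.split(r"[\s,]+", el.text or "") if a]
            getattr(meta, attr).extend(accessions)
    return meta


def write_study_xml(study_id: str, accessions: Mapping[str, list[str]]) -> bytes:
    """Serialise a study in the dialect read by parse_study_xml."""
    root = etree.Element("STUDY", accession=study_id)
    links = etree.SubElement(root, "STUDY_LINKS")
    for kind, tag in (("sample", "ENA-SAMPLE"), ("experiment", "ENA-EXPERIMENT"),
                      ("run", "ENA-RUN")):
        for acc in accessions.get(kind, []):
            etree.SubElement(links, tag).text = acc
    return etree.tostring(root, pretty_print=True, encoding="utf-8")


# --- pooling and comparison ------------------------------------------------------


def canonicalize(value: str) -> str:
    return re.sub(r"\s+", " ", value).strip().casefold()


def pool_metadata(
    study: StudyMetadata, mapping: MIxSMapping | None = None
) -> tuple[dict[str, tuple[set[str], set[str]]], dict[str, int]]:
    """Pool submitted fields and annotation entities onto MIxS terms.

    Returns (term → (submitted value set, annotation value set), coverage log
    of unmapped field/entity value counts).  All values canonicalized.
    Pooling is idempotent under re-application of canonicalization.
    """
    mapping = mapping or MIxSMapping()
    pools: dict[str, tuple[set[str], set[str]]] = {}
    coverage: dict[str, int] = {}

    def pool_for(term: str) -> tuple[set[str], set[str]]:
        return pools.setdefault(term, (set(), set()))

    for field_name, values in study.submitted_fields.items():
        term = mapping.term_for_field(field_name)
        if term is None:
            coverage[f"field:{field_name}"] = len(values)
            continue
        pool_for(term)[0].update(canonicalize(v) for v in values)
    for entity_type, values in study.annotation_values.items():
        term = mapping.term_for_entity(entity_type)
        if term is None:
            coverage[f"entity:{entity_type}"] = len(values)
            continue
        pool_for(term)[1].update(canonicalize(v) for v in values)
    return pools, coverage


@dataclass
class ComparisonCell:
    study_id: str
    mixs_term: str
    status: str

    def __post_init__(self) -> None:
        if self.status not in STATUSES:
            raise ValueError(f"unknown status {self.status!r}")


def compare_study(
    study_id: str,
    pools: Mapping[str, tuple[set[str], set[str]]],
    terms: Iterable[str] | None = None,
) -> list[ComparisonCell]:
    """Exact-match comparison per MIxS term.

    Both pools non-empty and intersecting → identical (one shared value
    suffices); both non-empty, disjoint → nonidentical; one non-empty →
    unique_submitted / unique_annotation; both empty → absent.
    """
    cells = []
    for term in sorted(terms) if terms is not None else sorted(pools):
        submitted, annotated = pools.get(term, (set(), set()))
        if submitted and annotated:
            status = "identical" if submitted & annotated else "nonidentical"
        elif submitted:
            status = "unique_submitted"
        elif annotated:
            status = "unique_annotation"
        else:
            status = "absent"
        cells.append(ComparisonCell(study_id=study_id, mixs_term=term, status=status))
    return cells


def summarize(
    cells: Sequence[ComparisonCell],
    min_studies_per_field: int = 50,
) -> dict[str, dict[str, int]]:
    """Per-term stacked counts of studies by status (absent excluded),
    ranked by total.  Terms whose data comes only from submitted fields in
    ≤ min_studies_per_field studies are filtered out."""
    if not cells:
        raise ValueError("no comparison cells to summarize")
    counts: dict[str, dict[str, int]] = {}
    submitted_studies: dict[str, set[str]] = {}
    for cell in cells:
        if cell.status == "absent":
            continue
        counts.setdefault(cell.mixs_term, {
            s: 0 for s in STATUSES if s != "absent"
        })[cell.status] += 1
        if cell.status in ("identical", "nonidentical", "unique_submitted"):
            submitted_studies.setdefault(cell.mixs_term, set()).add(cell.study_id)

    kept = {
        term: c for term, c in counts.items()
        if c["unique_annotation"] > 0  # any annotation-side data keeps a term
        or len(submitted_studies.get(term, ())) > min_studies_per_field
    }
    return dict(sorted(kept.items(), key=lambda kv: -sum(kv[1].values())))


def write_comparison_tsv(cells: Sequence[ComparisonCell], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("study_id\tmixs_term\tstatus\n")
        for c in cells:
            fh.write(f"{c.study_id}\t{c.mixs_term}\t{c.status}\n")


def write_summary_tsv(summary: Mapping[str, Mapping[str, int]], path: str | Path) -> None:
    statuses = [s for s in STATUSES if s != "absent"]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mixs_term\t" + "\t".join(statuses) + "\n")
        for term, c in summary.items():
            fh.write(term + "\t" + "\t".join(str(c[s]) for s in statuses) + "\n")


def plot_summary(summary: Mapping[str, Mapping[str, int]], path: str | Path) -> None:
    """Stacked bar chart of per-term study counts by comparison status."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    terms = list(summary)
    statuses = [s for s in STATUSES if s != "absent"]
    colors = {"identical": "#2ca02c", "nonidentical": "#ffbf00",
              "unique_submitted": "#d62728", "unique_annotation": "#9467bd"}
    bottom = [0] * len(terms)
    fig, ax = plt.subplots(figsize=(max(6, 0.5 * len(terms)), 4))
    for status in statuses:
        vals = [summary[t][status] for t in terms]
        ax.bar(terms, vals, bottom=bottom, label=status, color=colors[status])
        bottom = [b + v for b, v in zip(bottom, vals)]
    ax.set_ylabel("studies")
    ax.legend(fontsize=8)
    plt.xticks(rotation=60, ha="right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --- end-to-end helpers -----------------------------------------------------------


def study_metadata_from_sources(
    study_id: str,
    submitted_fields: Mapping[str, set[str]],
    annotations: Sequence,
    accessions: Mapping[str, list[str]] | None = None,
) -> StudyMetadata:
    """Assemble StudyMetadata from submitted fields plus annotation objects
    (anything with entity_type and exact_text attributes)."""
    meta = StudyMetadata(
        study_id=study_id,
        submitted_fields={k: set(v) for k, v in submitted_fields.items()},
    )
    if accessions:
        meta.sample_accessions = list(accessions.get("sample", []))
        meta.experiment_accessions = list(accessions.get("experiment", []))
        meta.run_accessions = list(accessions.get("run", []))
    for ann in annotations:
        meta.annotation_values.setdefault(ann.entity_type, set()).add(ann.exact_text)
    return meta


def compare_bundle(bundle, mapping: MIxSMapping | None = None) -> list[ComparisonCell]:
    """Compare a synthetic bundle's planted annotations against its submitted
    metadata, study by study (the generator's end-to-end oracle path)."""
    mapping = mapping or MIxSMapping()
    anns_by_doc: dict[str, list] = {}
    for ann in bundle.annotations:
        anns_by_doc.setdefault(ann.doc_id, []).append(ann)
    cells: list[ComparisonCell] = []
    for study in bundle.studies:
        anns = [a for d in study.publication_ids for a in anns_by_doc.get(d, [])]
        meta = study_metadata_from_sources(
            study.study_id,
            bundle.submitted_metadata.get(study.study_id, {}),
            anns,
            bundle.accessions.get(study.study_id),
        )
        pools, _ = pool_metadata(meta, mapping)
        cells.extend(compare_study(study.study_id, pools))
    return cells
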