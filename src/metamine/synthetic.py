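"""Synthetic corpus generator with known ground truth.

Emulates the inputs of the full mining pipeline: sectioned articles whose
vocabulary carries a biome signal, entity mentions planted in methods
sections with templated context cues (including nested spans and primer
strings with characters outside any subword vocabulary), study records
cross-referencing the articles, and archive-style submitted metadata with
controllable missingness and format inconsistency.

Everything is drawn from one seeded pseudo-random stream in a fixed order,
so a bundle is a deterministic function of its configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .corpus_io import Document, Section, Sentence, write_corpus_jsonl
from .distant import StudyRecord, write_studies_jsonl
from .mixs import MIxSMapping
from .schema import ENTITY_TYPES, SpanAnnotation

BIOME_CLASSES = ("Engineered", "Environmental", "Host-associated")

BIOME_LINEAGES: dict[str, list[str]] = {
    "Environmental": ["Environmental", "Aquatic", "Marine"],
    "Engineered": ["Engineered", "Wastewater", "Activated sludge"],
    "Host-associated": ["Host-associated", "Human", "Digestive system"],
}

DEFAULT_CLASS_VOCABULARIES: dict[str, list[str]] = {
    "Environmental": [
        "soil", "ocean", "river", "sediment", "forest", "lake",
        "marine", "wetland", "groundwater", "tundra",
    ],
    "Engineered": [
        "bioreactor", "wastewater", "fermentation", "sludge", "digester",
        "biofilter", "effluent", "pipeline", "compost", "brewery",
    ],
    "Host-associated": [
        "gut", "microbiota", "saliva", "patient", "rumen",
        "intestinal", "mucosal", "oral", "fecal", "dermal",
    ],
}

DEFAULT_SHARED_VOCABULARY: list[str] = [
    "microbial", "community", "analysis", "diversity", "sample",
    "bacterial", "abundance", "taxa", "dataset", "composition",
    "profile", "relative", "read", "assembly", "cluster",
]

# Nested (outer site, inner place) surface pairs: the site string contains the
# place string, so planting a site also plants an overlapping place span of a
# different type on shared tokens.
NESTED_SITE_PLACE: list[tuple[str, str]] = [
    ("Nevada hot springs", "Nevada"),
    ("Namib Desert dunes", "Namib Desert"),
    ("Yellowstone geyser basin", "Yellowstone"),
    ("Lake Baikal shoreline", "Lake Baikal"),
    ("Atacama salt flats", "Atacama"),
]

DEFAULT_ENTITY_LEXICONS: dict[str, list[str]] = {
    "ecoregion": [
        "tropical rainforest", "desert soil crust", "coral reef",
        "alpine tundra", "mangrove forest",
    ],
    "host": [
        "Homo sapiens", "Mus musculus", "honey bee",
        "zebrafish", "dairy cattle",
    ],
    "engineered": [
        "anaerobic bioreactor", "wastewater treatment plant",
        "microbial fuel cell", "drinking water distribution system",
        "fermentation tank",
    ],
    "date": ["June 2015", "March 2018", "October 2016", "July 2020", "May 2019"],
    "place": [p for _, p in NESTED_SITE_PLACE],
    "site": [s for s, _ in NESTED_SITE_PLACE],
    "body-site": [
        "oral cavity", "gut mucosa", "forearm skin",
        "rumen wall", "posterior vaginal fornix",
    ],
    "sample-material": [
        "surface soil", "seawater", "nasal mucus", "activated sludge granules",
        "fecal matter",
    ],
    "state": [
        "drought stressed", "medically healthy", "diseased",
        "mesotrophic", "antibiotic treated",
    ],
    "treatment": [
        "vancomycin", "nitrogen fertilizer", "probiotic supplementation",
        "benzylpenicillin", "metronidazole",
    ],
    "kit": [
        "PowerSoil DNA isolation kit", "DNeasy PowerWater kit",
        "RNA PowerSoil total RNA isolation kit", "QIAamp DNA stool mini kit",
        "FastDNA spin kit",
    ],
    # primer strings carry the prime character and length > 20 so the
    # tokenizer's preserved-unknown path is always exercised
    "primer": [
        "5′-ACACTCTTTCCCTACACGACGCTCTT-3′",
        "5′-GTGCCAGCMGCCGCGGTAAGGAGT-3′",
        "5′-GGACTACHVGGGTWTCTAATCCTG-3′",
        "5′-AGAGTTTGATCMTGGCTCAGATTG-3′",
        "5′-CCTACGGGNGGCWGCAGTTACCGC-3′",
    ],
    "gene": ["16S rRNA", "18S rRNA", "ITS2 region", "nifH", "mcrA"],
    "LS": ["amplicon", "whole genome shotgun", "metatranscriptome"],
    "LCM": ["paired end", "single end", "mate pair"],
    "sequencing": [
        "Illumina MiSeq", "Illumina HiSeq 2500", "PacBio RS II",
        "Ion Torrent PGM", "Illumina NovaSeq 6000",
    ],
}

SECTION_PLAN = ("abstract", "introduction", "methods", "results", "discussion")

SECTION_CUES: dict[str, list[str]] = {
    "abstract": ["We report", "This study presents", "Here we summarize"],
    "introduction": [
        "Previous studies described", "Background knowledge indicates",
        "It is known that",
    ],
    "methods": [
        "Protocol steps included", "Laboratory processing involved",
        "Extraction workflow used",
    ],
    "results": ["We observed", "Measurements revealed", "Counts showed"],
    "discussion": [
        "These findings suggest", "Interpretation indicates",
        "Limitations include",
    ],
}

# Entity-planting sentence templates.  Literal strings alternate with
# (entity_type,) slots; together the 8 templates cover all 16 types.
_TEMPLATES: list[list] = [
    ["Genomic DNA was extracted with the ", ("kit",),
     " following the manufacturer instructions ."],
    ["The ", ("gene",), " gene was amplified with primer ", ("primer",), " ."],
    ["Samples of ", ("sample-material",), " were collected from the ",
     ("site",), " in ", ("date",), " ."],
    ["Libraries were prepared as ", ("LCM",), " ", ("LS",),
     " libraries and sequenced on the ", ("sequencing",), " platform ."],
    ["Samples were obtained from ", ("host",), " subjects with ", ("state",),
     " status after ", ("treatment",), " treatment ."],
    ["The study area was a ", ("ecoregion",), " located near ", ("place",), " ."],
    ["Swabs were taken from the ", ("body-site",), " of each participant ."],
    ["Biomass was sampled from the ", ("engineered",), " during operation ."],
]

CONTEXT_CHARS = 30


@dataclass
class GeneratorConfig:
    seed: int = 9
    id_prefix: str = "SYN"
    n_docs_per_class: dict[str, int] = dc_field(
        default_factory=lambda: {c: 8 for c in BIOME_CLASSES}
    )
    class_vocabularies: dict[str, list[str]] = dc_field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_CLASS_VOCABULARIES.items()}
    )
    shared_vocabulary: list[str] = dc_field(
        default_factory=lambda: list(DEFAULT_SHARED_VOCABULARY)
    )
    mixture: float = 0.7
    entity_lexicons: dict[str, list[str]] = dc_field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_ENTITY_LEXICONS.items()}
    )
    plant_rate: float = 1.0
    metadata_missingness: float = 0.0
    metadata_inconsistency: float = 0.0

    def __post_init__(self) -> None:
        for name in ("mixture", "plant_rate", "metadata_missingness",
                     "metadata_inconsistency"):
            v = getattr(self, name)
            if name != "plant_rate" and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.plant_rate < 0:
            raise ValueError("plant_rate must be >= 0")
        for etype in ENTITY_TYPES:
            if not self.entity_lexicons.get(etype):
                raise ValueError(f"empty lexicon for entity type {etype!r}")


@dataclass
class GoldBundle:
    documents: list[Document]
    biome_labels: dict[str, list[str]]  # doc_id -> biome lineage
    annotations: list[SpanAnnotation]
    studies: list[StudyRecord]
    submitted_metadata: dict[str, dict[str, set[str]]]  # study -> field -> values
    accessions: dict[str, dict[str, list[str]]]  # study -> kind -> accessions


def _filler_sentence(rng: np.random.Generator, config: GeneratorConfig,
                     biome: str, section: str) -> str:
    cues = SECTION_CUES[section]
    cue = cues[rng.integers(len(cues))]
    words = []
    class_vocab = config.class_vocabularies[biome]
    shared = config.shared_vocabulary
    for _ in range(6):
        if rng.random() < config.mixture:
            words.append(class_vocab[rng.integers(len(class_vocab))])
        else:
            words.append(shared[rng.integers(len(shared))])
    return (f"{cue} {words[0]} {words[1]} and {words[2]} {words[3]} "
            f"in {words[4]} {words[5]} samples .")


def _render_template(template: list, surfaces: dict[str, str]
                     ) -> tuple[str, list[tuple[str, str, int, int]]]:
    """Assemble a template into text + (type, surface, start, end) plants."""
    parts: list[str] = []
    plants: list[tuple[str, str, int, int]] = []
    pos = 0
    for part in template:
        if isinstance(part, tuple):
            etype = part[0]
            surface = surfaces[etype]
            plants.append((etype, surface, pos, pos + len(surface)))
            parts.append(surface)
            pos += len(surface)
        else:
            parts.append(part)
            pos += len(part)
    text = "".join(parts)
    # nested inner place inside a planted site
    for etype, surface, start, _ in list(plants):
        if etype == "site":
            for outer, inner in NESTED_SITE_PLACE:
                if surface == outer:
                    off = surface.find(inner)
                    if off >= 0:
                        plants.append(
                            ("place", inner, start + off, start + off + len(inner))
                        )
    return text, plants


def _sample_surface(rng: np.random.Generator, lexicon: list[str],
                    used: set[str]) -> str:
    """Sample a surface form unused in this document when possible."""
    fresh = [s for s in lexicon if s not in used]
    pool = fresh if fresh else lexicon
    return pool[rng.integers(len(pool))]


def generate(config: GeneratorConfig) -> GoldBundle:
    """Generate a gold bundle: documents, labels, annotations, studies,
    submitted metadata.  Deterministic given config.seed."""
    rng = np.random.default_rng(config.seed)
    mapping = MIxSMapping()

    documents: list[Document] = []
    biome_labels: dict[str, list[str]] = {}
    annotations: list[SpanAnnotation] = []
    studies: list[StudyRecord] = []
    submitted: dict[str, dict[str, set[str]]] = {}
    accessions: dict[str, dict[str, list[str]]] = {}

    doc_counter = 0
    n_templates = len(_TEMPLATES)
    n_planted = int(round(config.plant_rate * n_templates))

    for biome in sorted(config.n_docs_per_class):
        count = config.n_docs_per_class[biome]
        for _ in range(count):
            doc_num = doc_counter
            doc_id = f"{config.id_prefix}DOC{doc_num:04d}"
            doc_counter += 1
            used_surfaces: set[str] = set()
            doc_annotations: list[SpanAnnotation] = []
            sections: list[Section] = []

            template_order = rng.permutation(n_templates)[:n_planted]

            for sec_idx, sec_type in enumerate(SECTION_PLAN):
                n_fillers = int(rng.integers(3, 5))
                sent_texts: list[str] = []
                # (sentence index within section, plants) for methods templates
                planted: list[tuple[int, list[tuple[str, str, int, int]]]] = []
                for _ in range(n_fillers):
                    sent_texts.append(
                        _filler_sentence(rng, config, biome, sec_type)
                    )
                if sec_type == "methods":
                    for t_idx in template_order:
                        template = _TEMPLATES[int(t_idx)]
                        surfaces: dict[str, str] = {}
                        for part in template:
                            if isinstance(part, tuple):
                                etype = part[0]
                                surf = _sample_surface(
                                    rng, config.entity_lexicons[etype], used_surfaces
                                )
                                surfaces[etype] = surf
                                used_surfaces.add(surf)
                        text, plants = _render_template(template, surfaces)
                        planted.append((len(sent_texts), plants))
                        sent_texts.append(text)

                # assemble section text and sentence offsets
                sentences: list[Sentence] = []
                offset = 0
                for j, stext in enumerate(sent_texts):
                    sent_id = f"{doc_id}.sec{sec_idx}.s{j}"
                    sentences.append(Sentence(
                        sent_id=sent_id, text=stext,
                        char_start=offset, char_end=offset + len(stext),
                    ))
                    offset += len(stext) + 1  # single-space joins
                section = Section(
                    heading=sec_type.capitalize(),
                    canonical_type=sec_type,
                    sentences=sentences,
                )
                sections.append(section)

                for j, plants in planted:
                    sent = sentences[j]
                    for etype, surface, start, end in plants:
                        doc_annotations.append(SpanAnnotation(
                            doc_id=doc_id,
                            entity_type=etype,
                            exact_text=surface,
                            prefix=sent.text[max(0, start - CONTEXT_CHARS):start],
                            suffix=sent.text[end:end + CONTEXT_CHARS],
                            sent_id=sent.sent_id,
                            char_start=start,
                            char_end=end,
                            provenance="curated",
                        ))

            title_vocab = config.class_vocabularies[biome]
            title = (f"Synthetic {title_vocab[rng.integers(len(title_vocab))]} "
                     f"microbiome survey {doc_id}")
            documents.append(Document(
                doc_id=doc_id, source_id=f"PMC{900000 + doc_num:d}",
                title=title, sections=sections,
            ))
            biome_labels[doc_id] = list(BIOME_LINEAGES[biome])
            annotations.extend(doc_annotations)

            # one study per document
            study_id = f"{config.id_prefix}STUDY{doc_num:04d}"
            studies.append(StudyRecord(
                study_id=study_id,
                biome_lineage=list(BIOME_LINEAGES[biome]),
                publication_ids=[doc_id],
            ))
            accessions[study_id] = {
                "sample": [f"SAMEA{doc_num:06d}{k}" for k in range(2)],
                "experiment": [f"ERX{doc_num:06d}"],
                "run": [f"ERR{doc_num:06d}"],
            }
            submitted[study_id] = _submitted_fields(
                rng, doc_annotations, mapping, config
            )

    return GoldBundle(
        documents=documents,
        biome_labels=biome_labels,
        annotations=annotations,
        studies=studies,
        submitted_metadata=submitted,
        accessions=accessions,
    )


def _inconsistent_variant(value: str) -> str:
    """Format variant of a value: 'June 2015' → '2015'; multiword → drop the
    first word; single word → append a marker.  Always differs from input."""
    words = value.split()
    if len(words) > 1:
        return " ".join(words[1:])
    return value + " modified"


def _submitted_fields(
    rng: np.random.Generator,
    doc_annotations: list[SpanAnnotation],
    mapping: MIxSMapping,
    config: GeneratorConfig,
) -> dict[str, set[str]]:
    by_term: dict[str, set[str]] = {}
    for ann in doc_annotations:
        term = mapping.term_for_entity(ann.entity_type)
        if term is not None:
            by_term.setdefault(term, set()).add(ann.exact_text)
    fields: dict[str, set[str]] = {}
    for term in sorted(by_term):
        field_name = mapping.field_for_term(term)
        if field_name is None:
            continue
        if rng.random() < config.metadata_missingness:
            continue
        values = set()
        for v in sorted(by_term[term]):
            if rng.random() < config.metadata_inconsistency:
                values.add(_inconsistent_variant(v))
            else:
                values.add(v)
        fields[field_name] = values
    return fields


def truth_report(bundle: GoldBundle) -> dict:
    """Ground-truth counts for a bundle (documents per class, annotations per
    entity type, studies, submitted metadata cells per MIxS term)."""
    mapping = MIxSMapping()
    docs_per_class: dict[str, int] = {}
    for lineage in bundle.biome_labels.values():
        docs_per_class[lineage[0]] = docs_per_class.get(lineage[0], 0) + 1
    ann_per_type: dict[str, int] = {t: 0 for t in ENTITY_TYPES}
    for ann in bundle.annotations:
        ann_per_type[ann.entity_type] += 1
    cells_per_term: dict[str, int] = {}
    for study_fields in bundle.submitted_metadata.values():
        for field_name in study_fields:
            term = mapping.term_for_field(field_name)
            if term is not None:
                cells_per_term[term] = cells_per_term.get(term, 0) + 1
    return {
        "n_documents": len(bundle.documents),
        "documents_per_class": docs_per_class,
        "annotations_per_entity_type": ann_per_type,
        "n_annotations": len(bundle.annotations),
        "n_studies": len(bundle.studies),
        "submitted_cells_per_mixs_term": cells_per_term,
    }


# --- serialization ------------------------------------------------------------


def write_bundle(bundle: GoldBundle, outdir: str | Path) -> None:
    """Write a bundle to a directory: corpus JSONL, annotations JSONL, study
    records JSONL, archive-style study XML, and submitted-metadata JSON."""
    from .bio_datasets import write_annotations_jsonl
    from .enrichment import write_study_xml

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_corpus_jsonl(bundle.documents, outdir / "corpus.jsonl")
    write_annotations_jsonl(bundle.annotations, outdir / "annotations.jsonl")
    write_studies_jsonl(bundle.studies, outdir / "studies.jsonl")
    with open(outdir / "biome_labels.json", "w", encoding="utf-8") as fh:
        json.dump(bundle.biome_labels, fh, indent=1, sort_keys=True)
    with open(outdir / "submitted_metadata.json", "w", encoding="utf-8") as fh:
        json.dump(
            {s: {f: sorted(v) for f, v in fields.items()}
             for s, fields in bundle.submitted_metadata.items()},
            fh, indent=1, sort_keys=True,
        )
    xml_dir = outdir / "study_xml"
    xml_dir.mkdir(exist_ok=True)
    for study in bundle.studies:
        acc = bundle.accessions[study.study_id]
        xml = write_study_xml(study.study_id, acc)
        (xml_dir / f"{study.study_id}.xml").write_bytes(xml)
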