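"""The 16-type metagenomics entity schema and the span-annotation record.

Entity mentions in publications may nest (a sampling site contains a place;
a kit name contains a chemical state), so downstream training data is built
per entity type rather than jointly.
"""

from __future__ import annotations

from dataclasses import dataclass


#: Entity type → one-line definition.  Order is the canonical schema order.
ENTITY_SCHEMA: dict[str, str] = {
    "ecoregion": "microbiome natural environment",
    "host": "microbiome living organism or host",
    "engineered": "microbiome humanmade environment",
    "date": "microbiome sample collection date",
    "place": "the place of microbiome environment or host",
    "site": "the site of microbiome sample within place",
    "body-site": "the organ or tissue of microbiome sample",
    "sample-material": "the material of the microbiome sample (e.g., water, mucus, soil)",
    "state": "the state of the microbiome environment or host (e.g., disease)",
    "treatment": "any treatment performed on the host or the environment",
    "kit": "DNA extraction kit",
    "primer": "PCR primers",
    "gene": "microbiome target genes (e.g., rRNA subunit and amplified regions)",
    "LS": "library source or library strategy (e.g., amplicon, whole genome)",
    "LCM": "library construction method or layout (e.g., paired end, single end)",
    "sequencing": "sequencing platform",
}

ENTITY_TYPES: tuple[str, ...] = tuple(ENTITY_SCHEMA)

assert len(ENTITY_TYPES) == 16
assert len({t.lower() for t in ENTITY_TYPES}) == 16


def validate_entity_type(entity_type: str) -> str:
    if entity_type not in ENTITY_SCHEMA:
        raise ValueError(f"unknown entity type: {entity_type!r}")
    return entity_type


@dataclass
class SpanAnnotation:
    """A character-anchored entity mention.

    Before anchoring (anchor_annotation), sent_id / offsets may be unset and
    the mention is located by exact text plus prefix/suffix context.  After
    anchoring, offsets are sentence-relative and
    ``sentence.text[char_start:char_end] == exact_text``.
    """

    doc_id: str
    entity_type: str
    exact_text: str
    prefix: str = ""
    suffix: str = ""
    sent_id: str | None = None
    char_start: int | None = None
    char_end: int | None = None
    provenance: str = "curated"  # curated | predicted

    def is_anchored(self) -> bool:
        return self.sent_id is not None and self.char_start is not None
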