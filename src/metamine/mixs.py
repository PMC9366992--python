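"""MIxS checklist mapping: entity types and submitted field names → MIxS terms.

MIxS (Minimum Information about any (x) Sequence) defines standard metadata
terms for sequence records (pcr_primers, target_gene, nucl_acid_ext, ...).
Both publication-derived entity mentions and archive-submitted metadata
fields are routed through this mapping so the two sources can be compared
term by term.  The mapping ships as an editable table; a type or field may
map to "unmapped" to be excluded (and counted) rather than compared.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from .schema import ENTITY_TYPES

UNMAPPED = "unmapped"

#: Entity type → MIxS term.  Total over the 16-type schema.
DEFAULT_ENTITY_TO_MIXS: dict[str, str] = {
    "ecoregion": "env_broad_scale",
    "host": "specific_host",
    "engineered": "env_broad_scale",
    "date": "collection_date",
    "place": "geo_loc_name",
    "site": "env_local_scale",
    "body-site": "env_local_scale",
    "sample-material": "env_medium",
    "state": "health_disease_stat",
    "treatment": "env_package",
    "kit": "nucl_acid_ext",
    "primer": "pcr_primers",
    "gene": "target_gene",
    "LS": "lib_strategy",
    "LCM": "lib_layout",
    "sequencing": "seq_meth",
}

#: Archive-submitted field name → MIxS term.
DEFAULT_FIELD_TO_MIXS: dict[str, str] = {
    "collection date": "collection_date",
    "geographic location": "geo_loc_name",
    "environment (biome)": "env_broad_scale",
    "environment (feature)": "env_local_scale",
    "environment (material)": "env_medium",
    "environmental package": "env_package",
    "host scientific name": "specific_host",
    "host disease status": "health_disease_stat",
    "instrument model": "seq_meth",
    "library layout": "lib_layout",
    "library strategy": "lib_strategy",
    "pcr primers": "pcr_primers",
    "target gene": "target_gene",
    "nucleic acid extraction": "nucl_acid_ext",
}


@dataclass
class MIxSMapping:
    """Editable two-sided mapping onto the MIxS term set."""

    entity_to_term: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ENTITY_TO_MIXS)
    )
    field_to_term: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_FIELD_TO_MIXS)
    )

    def __post_init__(self) -> None:
        missing = [t for t in ENTITY_TYPES if t not in self.entity_to_term]
        if missing:
            raise ValueError(f"entity mapping not total; missing {missing}")

    def term_for_entity(self, entity_type: str) -> str | None:
        term = self.entity_to_term.get(entity_type, UNMAPPED)
        return None if term == UNMAPPED else term

    def term_for_field(self, field_name: str) -> str | None:
        term = self.field_to_term.get(field_name.strip().lower(), UNMAPPED)
        return None if term == UNMAPPED else term

    def field_for_term(self, term: str) -> str | None:
        """First submitted field name that maps to `term` (table order)."""
        for name, t in self.field_to_term.items():
            if t == term:
                return name
        return None

    def save_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["kind", "name", "mixs_term"])
            for name, term in self.entity_to_term.items():
                w.writerow(["entity", name, term])
            for name, term in self.field_to_term.items():
                w.writerow(["field", name, term])

    @classmethod
    def load_tsv(cls, path: str | Path) -> "MIxSMapping":
        entity: dict[str, str] = {}
        fields: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                if row["kind"] == "entity":
                    entity[row["name"]] = row["mixs_term"]
                elif row["kind"] == "field":
                    fields[row["name"]] = row["mixs_term"]
                else:
                    raise ValueError(f"unknown mapping kind {row['kind']!r}")
        return cls(entity_to_term=entity, field_to_term=fields)
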