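"""Distant supervision: biome-labeled text datasets from study cross-references.

Curated study records carry a hierarchical biome lineage (up to 5 levels,
level 1 ∈ {Engineered, Environmental, Host-associated}) plus links to the
publications describing the study.  Projecting the lineage label at a chosen
level onto the linked documents yields a labeled text corpus without any
hand-labeling of documents.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus_io import Document

logger = logging.getLogger(__name__)

LEVEL1_CLASSES = ("Engineered", "Environmental", "Host-associated")

SCOPES = ("abstract", "introduction", "methods", "results", "discussion", "fulltext")


@dataclass
class StudyRecord:
    study_id: str
    biome_lineage: list[str]
    publication_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= len(self.biome_lineage) <= 5:
            raise ValueError("biome lineage must have 1-5 levels")
        if self.biome_lineage[0] not in LEVEL1_CLASSES:
            raise ValueError(
                f"level-1 biome must be one of {LEVEL1_CLASSES}, "
                f"got {self.biome_lineage[0]!r}"
            )


@dataclass
class LabeledText:
    doc_id: str
    scope: str
    text: str
    label: str


def _scope_text(doc: Document, scope: str) -> str:
    if scope == "fulltext":
        return doc.full_text
    return " ".join(sec.text for sec in doc.sections_of_type(scope))


def map_labels(
    studies: Sequence[StudyRecord],
    corpus: Sequence[Document],
    level: int = 1,
    scope: str = "fulltext",
) -> list[LabeledText]:
    """Project study biome labels at `level` onto cross-referenced documents.

    A document referenced by studies that disagree on the level-label is
    dropped (and logged): conflict resolution by exclusion avoids label noise.
    """
    if not 1 <= level <= 5:
        raise ValueError("level must be in 1..5")
    if scope not in SCOPES:
        raise ValueError(f"scope must be one of {SCOPES}")

    by_doc: dict[str, set[str]] = {}
    for study in studies:
        if len(study.biome_lineage) < level:
            continue
        label = study.biome_lineage[level - 1]
        for pub in study.publication_ids:
            by_doc.setdefault(pub, set()).add(label)

    if not by_doc:
        logger.warning("no study lineage reaches level %d; empty result", level)
        return []

    out: list[LabeledText] = []
    for doc in corpus:
        labels = by_doc.get(doc.doc_id) or (
            by_doc.get(doc.source_id) if doc.source_id else None
        )
        if not labels:
            continue
        if len(labels) > 1:
            logger.info(
                "document %s dropped: conflicting level-%d labels %s",
                doc.doc_id, level, sorted(labels),
            )
            continue
        text = _scope_text(doc, scope)
        if not text:
            continue
        out.append(
            LabeledText(doc_id=doc.doc_id, scope=scope, text=text, label=labels.pop())
        )
    return out


def balance_dataset(
    labeled: Sequence[LabeledText],
    min_per_class: int = 20,
    max_per_class: int = 100,
    seed: int = 0,
) -> list[LabeledText]:
    """Random balanced selection of min(max_per_class, smallest retained class)
    texts per class; classes below min_per_class are excluded (logged)."""
    if min_per_class > max_per_class:
        raise ValueError("min_per_class must be <= max_per_class")
    by_class: dict[str, list[LabeledText]] = {}
    for item in labeled:
        by_class.setdefault(item.label, []).append(item)
    retained = {c: v for c, v in by_class.items() if len(v) >= min_per_class}
    for c in sorted(set(by_class) - set(retained)):
        logger.info("class %s excluded: %d < %d texts", c, len(by_class[c]), min_per_class)
    if len(retained) < 2:
        raise ValueError(
            f"only {len(retained)} class(es) retained; cannot build a multiclass dataset"
        )
    k = min(max_per_class, min(len(v) for v in retained.values()))
    rng = np.random.default_rng(seed)
    out: list[LabeledText] = []
    for c in sorted(retained):
        items = retained[c]
        idx = rng.choice(len(items), size=k, replace=False)
        out.extend(items[i] for i in sorted(idx))
    return out


def split_train_test(
    items: Sequence,
    train_frac: float = 0.8,
    seed: int = 0,
    stratify_labels: Sequence[str] | None = None,
) -> tuple[list, list]:
    """Seeded stratified partition: per stratum, floor(train_frac * n) items go
    to train and the remainder to test.  A stratum of size 1 goes to train."""
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must be in (0, 1)")
    strata: dict[str, list[int]] = {}
    if stratify_labels is None:
        strata["_all"] = list(range(len(items)))
    else:
        if len(stratify_labels) != len(items):
            raise ValueError("stratify_labels must align with items")
        for i, lab in enumerate(stratify_labels):
            strata.setdefault(lab, []).append(i)

    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for lab in sorted(strata):
        idx = np.array(strata[lab])
        if len(idx) == 1:
            logger.warning("stratum %r has a single item; placed in train", lab)
            train_idx.extend(idx.tolist())
            continue
        perm = rng.permutation(len(idx))
        n_train = math.floor(train_frac * len(idx))
        train_idx.extend(idx[perm[:n_train]].tolist())
        test_idx.extend(idx[perm[n_train:]].tolist())
    train_idx.sort()
    test_idx.sort()
    return [items[i] for i in train_idx], [items[i] for i in test_idx]


# --- study-records JSONL ------------------------------------------------------


def write_studies_jsonl(studies: Iterable[StudyRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in studies:
            fh.write(json.dumps({
                "study_id": s.study_id,
                "biome_lineage": s.biome_lineage,
                "publication_ids": s.publication_ids,
            }, ensure_ascii=False))
            fh.write("\n")


def read_studies_jsonl(path: str | Path) -> list[StudyRecord]:
    out: list[StudyRecord] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
                out.append(StudyRecord(
                    study_id=obj["study_id"],
                    biome_lineage=list(obj["biome_lineage"]),
                    publication_ids=list(obj.get("publication_ids", [])),
                ))
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"line {lineno}: malformed study record: {exc}") from exc
    return out
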