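"""Teacher→student self-distillation validation.

Teachers (labelers trained on the curated corpus) annotate a fresh,
classifier-triaged corpus; students are trained from scratch on those
predicted annotations only and then evaluated token-wise against the curated
gold corpus.  A student passing the macro-F1 ≥ 70% criterion is evidence
that its teacher's accuracy transfers to uncurated text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .bio_datasets import (
    EntityDataset,
    SubwordVocabulary,
    build_entity_datasets,
)
from .classify import TrainedClassifier, predict_proba
from .corpus_io import Document
from .ner import (
    LabelerConfig,
    SequenceLabeler,
    annotate_document,
    grid_search,
    predicted_to_annotation,
)
from .schema import ENTITY_TYPES, SpanAnnotation

logger = logging.getLogger(__name__)


@dataclass
class DistillConfig:
    biome_prob_threshold: float = 0.5
    #: documents per biome class in the distillation corpus (500 at the
    #: original study's scale; 60 at desk scale)
    n_docs_per_class: int = 60
    pass_f1_threshold: float = 0.70
    seed: int = 9

    def __post_init__(self) -> None:
        if not 0 <= self.biome_prob_threshold:
            raise ValueError("biome_prob_threshold must be >= 0")
        if not 0 <= self.pass_f1_threshold <= 1:
            raise ValueError("pass_f1_threshold must be in [0,1]")


def select_distillation_corpus(
    new_corpus: Sequence[Document],
    biome_classifier: TrainedClassifier,
    config: DistillConfig | None = None,
) -> list[Document]:
    """Per biome class, a seeded random sample (without replacement) of up to
    n_docs_per_class documents whose argmax probability meets the threshold."""
    config = config or DistillConfig()
    qualifying: dict[str, list[Document]] = {}
    for doc in new_corpus:
        probs = predict_proba(biome_classifier, doc.full_text)
        best = max(sorted(probs), key=lambda c: probs[c])
        if probs[best] >= config.biome_prob_threshold:
            qualifying.setdefault(best, []).append(doc)

    rng = np.random.default_rng(config.seed)
    selected: list[Document] = []
    for cls in biome_classifier.classes:
        docs = qualifying.get(cls, [])
        if len(docs) < config.n_docs_per_class:
            logger.warning(
                "class %s: only %d qualifying documents (< %d requested)",
                cls, len(docs), config.n_docs_per_class,
            )
        k = min(config.n_docs_per_class, len(docs))
        if k:
            idx = rng.choice(len(docs), size=k, replace=False)
            selected.extend(docs[i] for i in sorted(idx))
    return selected


def distill(
    teachers: dict[str, SequenceLabeler],
    selection: Sequence[Document],
    gold_corpus: Sequence[Document],
    gold_annotations: Sequence[SpanAnnotation],
    vocab: SubwordVocabulary,
    config: DistillConfig | None = None,
    labeler_config: LabelerConfig | None = None,
) -> tuple[dict[str, SequenceLabeler], list[dict]]:
    """Train 16 students on teacher predictions; evaluate on the gold corpus.

    Teachers annotate the selection; the predicted spans (provenance
    "predicted", never a gold label) become the entire student training set.
    Students are grid-searched with the teachers' grids, using the full gold
    corpus as the test set.  Returns the students and one report row per
    entity: {entity, recall, precision, f1, pass}.
    """
    config = config or DistillConfig()
    labeler_config = labeler_config or LabelerConfig(seed=config.seed)
    if not selection:
        raise ValueError("empty distillation selection")
    gold_ids = {d.doc_id for d in gold_corpus}
    overlap = gold_ids & {d.doc_id for d in selection}
    if overlap:
        raise ValueError(f"selection overlaps the gold corpus: {sorted(overlap)[:3]}")

    predicted: list[SpanAnnotation] = []
    for doc in selection:
        for span in annotate_document(doc, teachers, vocab):
            predicted.append(predicted_to_annotation(span))
    if not predicted:
        raise ValueError("teachers produced no annotations on the selection")
    assert all(a.provenance == "predicted" for a in predicted)

    student_train = build_entity_datasets(
        selection, predicted, vocab, seed=config.seed, train_frac=None,
    )
    gold_all = build_entity_datasets(
        gold_corpus, gold_annotations, vocab, seed=config.seed, train_frac=None,
    )

    students: dict[str, SequenceLabeler] = {}
    rows: list[dict] = []
    for etype in ENTITY_TYPES:
        dataset = EntityDataset(
            entity_type=etype,
            train=student_train[etype].train,
            test=gold_all[etype].train,  # entire curated set is the test set
        )
        student, reports = grid_search(dataset, labeler_config)
        students[etype] = student
        best = min(
            (r for r in reports
             if r["learning_rate"] == student.learning_rate
             and r["epoch"] == student.epochs),
            key=lambda r: -r["f1"],
        )
        rows.append({
            "entity": etype,
            "recall": best["recall"],
            "precision": best["precision"],
            "f1": best["f1"],
            "pass": best["f1"] >= config.pass_f1_threshold,
        })
    return students, rows


def write_distill_report(rows: list[dict], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("entity\trecall\tprecision\tf1\tpass\n")
        for r in rows:
            fh.write(f"{r['entity']}\t{r['recall']:.4f}\t{r['precision']:.4f}"
                     f"\t{r['f1']:.4f}\t{str(r['pass']).lower()}\n")


# --- end-to-end distillation study ---------------------------------------------


def run_distillation_study(
    seed: int = 9,
    n_docs_per_class_gold: int = 8,
    n_new_docs_per_class: int = 80,
    distill_config: DistillConfig | None = None,
) -> dict:
    """The full teacher→student study on synthetic corpora.

    Generates a gold bundle, trains teachers (grid search per entity) and a
    biome classifier on it, generates a disjoint fresh bundle, selects the
    distillation corpus at probability ≥ threshold, runs distill(), and
    returns the per-entity student reports plus summary numbers.
    """
    from .classify import train_text_classifier
    from .distant import map_labels
    from .synthetic import BIOME_CLASSES, GeneratorConfig, generate

    config = distill_config or DistillConfig(seed=seed)
    vocab = SubwordVocabulary.default()

    gold = generate(GeneratorConfig(
        seed=seed, id_prefix="GOLD",
        n_docs_per_class={c: n_docs_per_class_gold for c in BIOME_CLASSES},
    ))
    labeler_config = LabelerConfig(seed=seed)
    teacher_datasets = build_entity_datasets(
        gold.documents, gold.annotations, vocab, seed=seed, train_frac=0.9,
    )
    teachers: dict[str, SequenceLabeler] = {}
    teacher_rows: list[dict] = []
    for etype in ENTITY_TYPES:
        teacher, reports = grid_search(teacher_datasets[etype], labeler_config)
        teachers[etype] = teacher
        teacher_rows.append(max(
            (r for r in reports
             if r["learning_rate"] == teacher.learning_rate
             and r["epoch"] == teacher.epochs),
            key=lambda r: r["f1"],
        ))

    labeled = map_labels(gold.studies, gold.documents, level=1, scope="fulltext")
    classifier = train_text_classifier(
        [l.text for l in labeled], [l.label for l in labeled],
        task="biome-level-1",
    )

    fresh = generate(GeneratorConfig(
        seed=seed + 1, id_prefix="NEW",
        n_docs_per_class={c: n_new_docs_per_class for c in BIOME_CLASSES},
    ))
    selection = select_distillation_corpus(fresh.documents, classifier, config)

    students, rows = distill(
        teachers, selection, gold.documents, gold.annotations, vocab,
        config=config, labeler_config=labeler_config,
    )
    mean_f1 = float(np.mean([r["f1"] for r in rows]))
    n_gold_sentences = len({a.sent_id for a in gold.annotations})
    return {
        "teacher_reports": teacher_rows,
        "student_reports": rows,
        "mean_student_macro_f1": mean_f1,
        "mean_teacher_macro_f1": float(np.mean([r["f1"] for r in teacher_rows])),
        "n_students_passing": sum(r["pass"] for r in rows),
        "n_selected_documents": len(selection),
        "n_gold_sentences": n_gold_sentences,
        "students": students,
        "teachers": teachers,
    }
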