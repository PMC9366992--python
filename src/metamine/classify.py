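"""Biome and section document classifiers.

Features are TF-IDF vectors or paragraph-vector embeddings; the classifier
is a random forest whose (n_estimators, max_depth) pair is selected by grid
search under 5-fold stratified shuffle-split cross-validation on the 80%
training split (macro-F1), refit on that split, and reported on the held-out
20%.  Probability-thresholded triage selects documents for their argmax
class; a section classifier recovers methods-like text from documents whose
sections are not tagged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import sparse
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_extraction.text import TfidfVectorizer
from sklearn.metrics import auc, classification_report, roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedShuffleSplit

from .corpus_io import CANONICAL_SECTION_TYPES, Document
from .distant import split_train_test
from .embed import EmbeddingModel, fit_doc_embeddings, transform_corpus

logger = logging.getLogger(__name__)

# lowercase words, punctuation stripped except within-token hyphens
TOKEN_PATTERN = r"(?u)\b\w+(?:-\w+)*\b"


@dataclass
class TfidfModel:
    vectorizer: TfidfVectorizer

    @property
    def vocabulary(self) -> dict[str, int]:
        return self.vectorizer.vocabulary_

    @property
    def idf(self) -> dict[str, float]:
        vocab = self.vectorizer.vocabulary_
        return {term: self.vectorizer.idf_[i] for term, i in vocab.items()}


def fit_tfidf(texts: Sequence[str], min_df: int = 1) -> TfidfModel:
    """Fit a TF-IDF model: smoothed idf, L2-normalised rows, unigrams."""
    if not any(t.strip() for t in texts):
        raise ValueError("all texts are empty")
    vec = TfidfVectorizer(
        lowercase=True,
        token_pattern=TOKEN_PATTERN,
        min_df=min_df,
        norm="l2",
        smooth_idf=True,
    )
    vec.fit(texts)
    return TfidfModel(vectorizer=vec)


def transform(model: TfidfModel, text: str | Sequence[str]) -> sparse.csr_matrix:
    """Transform text(s) into TF-IDF row vector(s); unseen-only text → zeros."""
    if isinstance(text, str):
        text = [text]
    return model.vectorizer.transform(text)


@dataclass
class ForestGrid:
    n_estimators_grid: tuple[int, ...] = (50, 100, 150, 200, 250, 300)
    max_depth_grid: tuple[int | None, ...] = (25, 50, 75, 100, 125, 150, None)
    cv_folds: int = 5
    seed: int = 9

    def __post_init__(self) -> None:
        if not self.n_estimators_grid or not self.max_depth_grid:
            raise ValueError("hyperparameter grids must be non-empty")

    @property
    def n_combinations(self) -> int:
        return len(self.n_estimators_grid) * len(self.max_depth_grid)


@dataclass
class TrainedClassifier:
    task: str
    classes: list[str]
    chosen_params: dict
    report: dict  # per-class + macro precision/recall/f1/support
    roc: dict  # class -> {"fpr": [...], "tpr": [...], "auc": float}
    model: RandomForestClassifier = field(repr=False)
    featurizer: Callable[[Sequence[str]], np.ndarray] = field(repr=False)
    n_grid_combinations: int = 0


def _as_matrix(X) -> np.ndarray | sparse.spmatrix:
    return X


def train_classifier(
    X_train,
    y_train: Sequence[str],
    X_test,
    y_test: Sequence[str],
    grid: ForestGrid,
    featurizer: Callable[[Sequence[str]], np.ndarray],
    task: str = "biome-level-1",
) -> TrainedClassifier:
    """Grid-search a random forest on precomputed features.

    Selects the (n_estimators, max_depth) pair maximising mean CV macro-F1,
    refits on the training split, and reports per-class and macro metrics
    plus one-vs-rest ROC on the held-out test split.
    """
    classes = sorted(set(y_train))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to train a classifier")

    cv = StratifiedShuffleSplit(
        n_splits=grid.cv_folds, test_size=0.2, random_state=grid.seed
    )
    search = GridSearchCV(
        RandomForestClassifier(random_state=grid.seed, n_jobs=1),
        param_grid={
            "n_estimators": list(grid.n_estimators_grid),
            "max_depth": list(grid.max_depth_grid),
        },
        scoring="f1_macro",
        cv=cv,
        n_jobs=1,
        refit=True,
    )
    search.fit(X_train, np.asarray(y_train))
    model = search.best_estimator_

    y_pred = model.predict(X_test)
    report = classification_report(
        y_test, y_pred, labels=sorted(set(y_test) | set(classes)),
        output_dict=True, zero_division=0,
    )

    roc: dict[str, dict] = {}
    proba = model.predict_proba(X_test)
    y_test_arr = np.asarray(y_test)
    for i, cls in enumerate(model.classes_):
        binary = (y_test_arr == cls).astype(int)
        if binary.min() == binary.max():
            continue  # class absent (or universal) in test: ROC undefined
        fpr, tpr, _ = roc_curve(binary, proba[:, i])
        roc[str(cls)] = {"fpr": fpr.tolist(), "tpr": tpr.tolist(),
                         "auc": float(auc(fpr, tpr))}

    return TrainedClassifier(
        task=task,
        classes=[str(c) for c in model.classes_],
        chosen_params=dict(search.best_params_),
        report=report,
        roc=roc,
        model=model,
        featurizer=featurizer,
        n_grid_combinations=len(search.cv_results_["params"]),
    )


def train_text_classifier(
    texts: Sequence[str],
    labels: Sequence[str],
    grid: ForestGrid | None = None,
    features: str = "tfidf",
    task: str = "biome-level-1",
    train_frac: float = 0.8,
    min_df: int = 1,
    embedding_params: EmbeddingModel | None = None,
) -> TrainedClassifier:
    """80/20 split + feature fitting on train + grid-searched forest."""
    grid = grid or ForestGrid()
    pairs = list(zip(texts, labels))
    train, test = split_train_test(
        pairs, train_frac=train_frac, seed=grid.seed,
        stratify_labels=list(labels),
    )
    tr_texts, tr_labels = [t for t, _ in train], [l for _, l in train]
    te_texts, te_labels = [t for t, _ in test], [l for _, l in test]

    if features == "tfidf":
        tfidf = fit_tfidf(tr_texts, min_df=min_df)
        featurizer = lambda ts: transform(tfidf, list(ts))
    elif features == "doc2vec":
        params = embedding_params or EmbeddingModel(seed=grid.seed, workers=1)
        emb = fit_doc_embeddings(list(tr_texts), params)
        featurizer = lambda ts: transform_corpus(emb, list(ts))
    else:
        raise ValueError(f"unknown feature mode {features!r}")

    return train_classifier(
        featurizer(tr_texts), tr_labels,
        featurizer(te_texts), te_labels,
        grid=grid, featurizer=featurizer, task=task,
    )


def predict_proba(classifier: TrainedClassifier, text: str) -> dict[str, float]:
    """Class-probability distribution for one text (sums to 1)."""
    X = classifier.featurizer([text])
    probs = classifier.model.predict_proba(X)[0]
    return {str(cls): float(p) for cls, p in zip(classifier.model.classes_, probs)}


def triage(
    doc_probs: dict[str, dict[str, float]], threshold: float = 0.4
) -> list[tuple[str, str]]:
    """Select each document for its argmax class iff that class's probability
    is >= threshold.  Selection is monotone non-increasing in threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must be in [0,1]")
    selected: list[tuple[str, str]] = []
    for doc_id in sorted(doc_probs):
        probs = doc_probs[doc_id]
        if not probs:
            continue
        best = max(sorted(probs), key=lambda c: probs[c])
        if probs[best] >= threshold:
            selected.append((doc_id, best))
    return selected


SECTION_CLASSES = tuple(t for t in CANONICAL_SECTION_TYPES if t != "other")


def train_section_classifier(
    section_texts: Sequence[str],
    section_labels: Sequence[str],
    grid: ForestGrid | None = None,
) -> TrainedClassifier:
    """Classify section text into the five canonical section types."""
    bad = set(section_labels) - set(SECTION_CLASSES)
    if bad:
        raise ValueError(f"section labels outside canonical types: {sorted(bad)}")
    return train_text_classifier(
        section_texts, section_labels, grid=grid, features="tfidf",
        task="section",
    )


def extract_methods_text(
    document: Document, section_classifier: TrainedClassifier | None = None
) -> str:
    """Methods text of a document.

    Tagged methods sections win; otherwise each section's text is classified
    and predicted-methods sections are concatenated; with nothing predicted,
    returns empty text (warning).
    """
    tagged = document.sections_of_type("methods")
    if tagged:
        return " ".join(sec.text for sec in tagged)
    if section_classifier is not None:
        picked = []
        for sec in document.sections:
            text = sec.text
            if not text:
                continue
            probs = predict_proba(section_classifier, text)
            if max(sorted(probs), key=lambda c: probs[c]) == "methods":
                picked.append(text)
        if picked:
            return " ".join(picked)
    logger.warning("document %s: no methods text found", document.doc_id)
    return ""
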