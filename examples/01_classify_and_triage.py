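"""Distantly supervised biome classification and probability triage.

Generates a synthetic corpus of 60 articles with study cross-references,
projects each study's biome lineage onto its linked publications, trains a
TF-IDF + random-forest classifier (42-combination grid search under 5-fold
stratified shuffle-split CV), and triages documents at probability >= 0.4.
"""

from metamine import GeneratorConfig, generate, map_labels, predict_proba, train_text_classifier, triage
from metamine.synthetic import BIOME_CLASSES

bundle = generate(GeneratorConfig(
    seed=3, mixture=0.9, n_docs_per_class={c: 20 for c in BIOME_CLASSES},
))

# distant supervision: study biome labels -> document labels (level 1)
labeled = map_labels(bundle.studies, bundle.documents, level=1, scope="fulltext")
print(f"{len(labeled)} labeled texts from {len(bundle.studies)} studies")

clf = train_text_classifier(
    [l.text for l in labeled], [l.label for l in labeled], features="tfidf",
)
macro = clf.report["macro avg"]
print(f"chosen forest: {clf.chosen_params}")
print(f"held-out macro P/R/F1 = {macro['precision']:.2f} / "
      f"{macro['recall']:.2f} / {macro['f1-score']:.2f}")
# macro F1 near 1.0: with 90% class-specific vocabulary the three biomes
# (Engineered / Environmental / Host-associated) are almost fully separable

probs = {d.doc_id: predict_proba(clf, d.full_text) for d in bundle.documents[:6]}
selected = triage(probs, threshold=0.4)
print(f"triage at P >= 0.4 selected {len(selected)}/6 documents, e.g. {selected[0]}")
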