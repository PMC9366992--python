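import pytest

from metamine.bio_datasets import SubwordVocabulary, build_entity_datasets
from metamine.classify import train_section_classifier, train_text_classifier
from metamine.distant import map_labels
from metamine.synthetic import BIOME_CLASSES, GeneratorConfig, generate


@pytest.fixture(scope="session")
def vocab():
    return SubwordVocabulary.default()


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic gold bundle."""
    return generate(GeneratorConfig(seed=7))


@pytest.fixture(scope="session")
def separable_bundle():
    """Larger, strongly class-separable bundle for classifier recovery tests."""
    return generate(GeneratorConfig(
        seed=3, mixture=0.9,
        n_docs_per_class={c: 20 for c in BIOME_CLASSES},
    ))


@pytest.fixture(scope="session")
def entity_datasets(bundle, vocab):
    return build_entity_datasets(bundle.documents, bundle.annotations, vocab, seed=9)


@pytest.fixture(scope="session")
def biome_classifier(separable_bundle):
    labeled = map_labels(
        separable_bundle.studies, separable_bundle.documents,
        level=1, scope="fulltext",
    )
    return train_text_classifier(
        [l.text for l in labeled], [l.label for l in labeled],
        task="biome-level-1",
    )


@pytest.fixture(scope="session")
def section_classifier(separable_bundle):
    texts, labels = [], []
    for doc in separable_bundle.documents:
        for sec in doc.sections:
            texts.append(sec.text)
            labels.append(sec.canonical_type)
    return train_section_classifier(texts, labels)
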