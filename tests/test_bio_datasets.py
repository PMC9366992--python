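import numpy as np
import pytest

from metamine.bio_datasets import (
    AnchorError,
    SubwordVocabulary,
    TaggedSentence,
    anchor_all,
    anchor_annotation,
    bio_tag,
    build_entity_datasets,
    read_annotations_jsonl,
    truncate_to_max_len,
    wordpiece_tokenize,
    write_annotations_jsonl,
)
from metamine.corpus_io import Document, Section, Sentence
from metamine.schema import ENTITY_TYPES, SpanAnnotation


def _sentence(text: str, sent_id: str = "s0") -> Sentence:
    return Sentence(sent_id=sent_id, text=text, char_start=0, char_end=len(text))


def _doc_with(text: str, doc_id: str = "d1") -> Document:
    return Document(
        doc_id=doc_id, source_id=None, title="",
        sections=[Section(heading="Methods", canonical_type="methods",
                          sentences=[_sentence(text, f"{doc_id}.s0")])],
    )


class TestWordpiece:
    def test_textbook_segmentation(self):
        vocab = SubwordVocabulary(["un", "##known", "##k"])
        ts = wordpiece_tokenize("unknown", vocab)
        assert [t.text for t in ts.tokens] == ["un", "known"]
        assert [t.is_continuation_piece for t in ts.tokens] == [False, True]

    def test_longest_match_first(self):
        vocab = SubwordVocabulary(["un", "unknow", "##n", "##known"])
        ts = wordpiece_tokenize("unknown", vocab)
        assert [t.text for t in ts.tokens] == ["unknow", "n"]

    def test_primer_with_unknown_characters_preserved(self, vocab):
        primer = "5′-ACACTCTTTCCCTACACGACG-3′"
        ts = wordpiece_tokenize(primer, vocab)
        assert len(ts.tokens) == 1
        tok = ts.tokens[0]
        assert tok.is_preserved_unknown
        assert tok.text == primer  # never the UNK marker

    def test_no_token_is_unk_marker(self, bundle, vocab):
        for doc in bundle.documents[:3]:
            for sec in doc.sections:
                for sent in sec.sentences:
                    ts = wordpiece_tokenize(sent, vocab)
                    assert all(t.text != "[UNK]" for t in ts.tokens)

    def test_offset_round_trip(self, bundle, vocab):
        """Detokenizing via offsets reproduces the sentence text."""
        sents = [
            s for doc in bundle.documents
            for sec in doc.sections for s in sec.sentences
        ]
        for sent in sents[:200]:
            ts = wordpiece_tokenize(sent, vocab)
            rebuilt = [" "] * len(sent.text)
            for t in ts.tokens:
                rebuilt[t.char_start:t.char_end] = list(
                    sent.text[t.char_start:t.char_end]
                )
                assert sent.text[t.char_start:t.char_end] == t.text
            assert "".join(rebuilt) == sent.text
            # spans ordered and non-overlapping
            for a, b in zip(ts.tokens, ts.tokens[1:]):
                assert a.char_end <= b.char_start

    def test_empty_vocabulary_rejected(self):
        with pytest.raises(ValueError):
            SubwordVocabulary([])


class TestAnchoring:
    def test_unique_occurrence(self):
        doc = _doc_with("DNA was extracted with the PowerSoil kit .")
        ann = SpanAnnotation(doc_id="d1", entity_type="kit", exact_text="PowerSoil")
        anchored = anchor_annotation(doc, ann)
        sent = doc.sections[0].sentences[0]
        assert sent.text[anchored.char_start:anchored.char_end] == "PowerSoil"
        assert anchored.sent_id == sent.sent_id

    def test_context_disambiguates_duplicates(self):
        text = "Soil from Nevada was rich . Dust from Nevada was dry ."
        doc = _doc_with(text)
        ann = SpanAnnotation(
            doc_id="d1", entity_type="place", exact_text="Nevada",
            prefix="Dust from ", suffix=" was dry",
        )
        anchored = anchor_annotation(doc, ann)
        assert anchored.char_start == text.index("Dust from Nevada") + len("Dust from ")

    def test_missing_text_is_unanchorable(self):
        doc = _doc_with("Nothing to see here .")
        ann = SpanAnnotation(doc_id="d1", entity_type="kit", exact_text="QIAamp")
        with pytest.raises(AnchorError, match="not found"):
            anchor_annotation(doc, ann)

    def test_ambiguous_without_context_rejected(self):
        doc = _doc_with("Nevada sand and Nevada dust .")
        ann = SpanAnnotation(doc_id="d1", entity_type="place", exact_text="Nevada")
        with pytest.raises(AnchorError, match="ambiguous"):
            anchor_annotation(doc, ann)

    def test_generator_annotations_anchor_perfectly(self, bundle):
        """100% of planted annotations re-anchor to their generated positions."""
        stripped = [
            SpanAnnotation(doc_id=a.doc_id, entity_type=a.entity_type,
                           exact_text=a.exact_text, prefix=a.prefix,
                           suffix=a.suffix)
            for a in bundle.annotations
        ]
        anchored, rejects = anchor_all(bundle.documents, stripped)
        assert rejects == []
        gold = {(a.doc_id, a.entity_type, a.exact_text, a.sent_id,
                 a.char_start, a.char_end) for a in bundle.annotations}
        got = {(a.doc_id, a.entity_type, a.exact_text, a.sent_id,
                a.char_start, a.char_end) for a in anchored}
        assert got == gold


class TestBioTag:
    @pytest.fixture
    def tokenized(self, vocab):
        return wordpiece_tokenize(
            _sentence("Samples were collected from the Namib Desert"), vocab,
        )

    def test_span_tags_b_then_i(self, vocab):
        text = "Samples were collected from the Namib Desert"
        ts = wordpiece_tokenize(_sentence(text), vocab)
        start = text.index("Namib Desert")
        span = SpanAnnotation(
            doc_id="d", entity_type="ecoregion", exact_text="Namib Desert",
            sent_id="s0", char_start=start, char_end=start + len("Namib Desert"),
        )
        tagged = bio_tag(ts, [span])
        word_tags = [
            (tok.text, tag) for tok, tag in zip(ts.tokens, tagged.tags)
            if not tok.is_continuation_piece
        ]
        # first word-initial token of the span is B; later span tokens I
        assert [t for w, t in word_tags if w.lower().startswith("namib")][0] == "B"
        in_span = [tag for tok, tag in zip(ts.tokens, tagged.tags)
                   if tok.char_start >= start]
        assert set(in_span) <= {"B", "I"} and in_span[0] == "B"
        before = [tag for tok, tag in zip(ts.tokens, tagged.tags)
                  if tok.char_end <= start]
        assert set(before) == {"O"}

    def test_no_spans_all_o(self, tokenized):
        tagged = bio_tag(tokenized, [], entity_type="kit")
        assert set(tagged.tags) == {"O"}

    def test_nested_types_tagged_independently(self, vocab):
        text = "Sampling at Nevada hot springs occurred"
        ts = wordpiece_tokenize(_sentence(text), vocab)
        s = text.index("Nevada hot springs")
        site = SpanAnnotation(doc_id="d", entity_type="site",
                              exact_text="Nevada hot springs", sent_id="s0",
                              char_start=s, char_end=s + len("Nevada hot springs"))
        place = SpanAnnotation(doc_id="d", entity_type="place",
                               exact_text="Nevada", sent_id="s0",
                               char_start=s, char_end=s + len("Nevada"))
        site_tags = bio_tag(ts, [site]).tags
        place_tags = bio_tag(ts, [place]).tags
        covered = [i for i, tok in enumerate(ts.tokens)
                   if tok.char_start >= s and tok.char_end <= s + len("Nevada hot springs")]
        assert [site_tags[i] for i in covered] == ["B"] + ["I"] * (len(covered) - 1)
        nevada_idx = [i for i in covered
                      if ts.tokens[i].char_end <= s + len("Nevada")]
        assert [place_tags[i] for i in nevada_idx][0] == "B"
        beyond = [place_tags[i] for i in covered if i not in nevada_idx]
        assert set(beyond) == {"O"}

    def test_mixed_entity_types_rejected(self, tokenized):
        spans = [
            SpanAnnotation(doc_id="d", entity_type="site", exact_text="x",
                           sent_id="s0", char_start=0, char_end=2),
            SpanAnnotation(doc_id="d", entity_type="kit", exact_text="y",
                           sent_id="s0", char_start=4, char_end=6),
        ]
        with pytest.raises(ValueError, match="mixed"):
            bio_tag(tokenized, spans)

    def test_no_i_follows_o(self, bundle, vocab, entity_datasets):
        for ds in entity_datasets.values():
            for tagged in ds.train[:50]:
                for prev, cur in zip(tagged.tags, tagged.tags[1:]):
                    assert not (prev == "O" and cur == "I")


class TestTruncation:
    @staticmethod
    def _long_sentence(vocab, n_words: int):
        text = " ".join(["soil"] * n_words)
        return wordpiece_tokenize(_sentence(text), vocab)

    def test_truncates_beyond_max_len(self, vocab):
        ts = self._long_sentence(vocab, 130)
        tagged = TaggedSentence(entity_type="kit", tokenized=ts,
                                tags=["O"] * len(ts.tokens))
        out, flag = truncate_to_max_len(tagged, 128)
        assert flag and len(out.tags) == 128

    def test_boundary_exact_length_unchanged(self, vocab):
        ts = self._long_sentence(vocab, 128)
        tagged = TaggedSentence(entity_type="kit", tokenized=ts,
                                tags=["O"] * len(ts.tokens))
        out, flag = truncate_to_max_len(tagged, 128)
        assert not flag and len(out.tags) == len(ts.tokens)

    def test_span_beyond_limit_is_dropped_from_tags(self, vocab):
        ts = self._long_sentence(vocab, 130)
        tags = ["O"] * len(ts.tokens)
        tags[-2:] = ["B", "I"]  # gold span entirely beyond the window
        tagged = TaggedSentence(entity_type="kit", tokenized=ts, tags=tags)
        out, flag = truncate_to_max_len(tagged, 128)
        assert flag and "B" not in out.tags


class TestEntityDatasets:
    def test_sixteen_datasets_shared_sentences(self, entity_datasets):
        assert set(entity_datasets) == set(ENTITY_TYPES)
        ref_train = [t.tokenized.sent_id for t in entity_datasets["kit"].train]
        ref_test = [t.tokenized.sent_id for t in entity_datasets["kit"].test]
        for ds in entity_datasets.values():
            assert [t.tokenized.sent_id for t in ds.train] == ref_train
            assert [t.tokenized.sent_id for t in ds.test] == ref_test
        assert not set(ref_train) & set(ref_test)

    def test_reported_split_arithmetic(self, vocab):
        """2,496 tagged sentences split 2,246 / 250 under the 90/10 rule."""
        text = "DNA was extracted with the PowerSoil kit ."
        docs, anns = [], []
        for i in range(2496):
            doc = _doc_with(text, doc_id=f"d{i}")
            docs.append(doc)
            start = text.index("PowerSoil kit")
            anns.append(SpanAnnotation(
                doc_id=f"d{i}", entity_type="kit", exact_text="PowerSoil kit",
                sent_id=f"d{i}.s0", char_start=start,
                char_end=start + len("PowerSoil kit"),
            ))
        datasets = build_entity_datasets(docs, anns, vocab, seed=9)
        for ds in datasets.values():
            assert (len(ds.train), len(ds.test)) == (2246, 250)

    def test_sentence_with_only_kit_is_all_o_elsewhere(self, vocab):
        doc = _doc_with("DNA was extracted with the PowerSoil kit .")
        start = doc.sections[0].sentences[0].text.index("PowerSoil")
        ann = SpanAnnotation(
            doc_id="d1", entity_type="kit", exact_text="PowerSoil kit",
            sent_id="d1.s0", char_start=start, char_end=start + len("PowerSoil kit"),
        )
        datasets = build_entity_datasets([doc], [ann], vocab, train_frac=None)
        assert "B" in datasets["kit"].train[0].tags
        for etype in ENTITY_TYPES:
            if etype != "kit":
                assert set(datasets[etype].train[0].tags) == {"O"}

    def test_bi_union_covers_all_annotations(self, bundle, vocab, entity_datasets):
        """Union of B/I tokens over the 16 datasets equals the token cover of
        all annotations (recount oracle)."""
        from metamine.bio_datasets import wordpiece_tokenize as tok

        spans_by_sent = {}
        for a in bundle.annotations:
            spans_by_sent.setdefault(a.sent_id, []).append(a)
        sent_by_id = {
            s.sent_id: s for d in bundle.documents
            for sec in d.sections for s in sec.sentences
        }
        expected = set()
        for sent_id, spans in spans_by_sent.items():
            ts = tok(sent_by_id[sent_id], vocab)
            for i, t in enumerate(ts.tokens):
                for sp in spans:
                    if t.char_start < sp.char_end and t.char_end > sp.char_start:
                        expected.add((sent_id, i))
        got = set()
        for ds in entity_datasets.values():
            for part in (ds.train, ds.test):
                for tagged in part:
                    for i, tag in enumerate(tagged.tags):
                        if tag in ("B", "I"):
                            got.add((tagged.tokenized.sent_id, i))
        assert got == expected

    def test_unknown_entity_type_rejected(self, bundle, vocab):
        bad = SpanAnnotation(doc_id="x", entity_type="flavor", exact_text="y",
                             sent_id="s", char_start=0, char_end=1)
        with pytest.raises(ValueError, match="flavor"):
            build_entity_datasets(bundle.documents, [bad], vocab)


def test_annotations_jsonl_round_trip(tmp_path, bundle):
    path = tmp_path / "ann.jsonl"
    write_annotations_jsonl(bundle.annotations, path)
    again = read_annotations_jsonl(path)
    key = lambda a: (a.doc_id, a.sent_id, a.entity_type, a.char_start,
                     a.char_end, a.exact_text, a.prefix, a.suffix, a.provenance)
    assert [key(a) for a in again] == [key(a) for a in bundle.annotations]
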