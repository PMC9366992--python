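import numpy as np
import pytest

from metamine.bio_datasets import (
    EntityDataset,
    TaggedSentence,
    Token,
    TokenizedSentence,
    bio_tag,
    wordpiece_tokenize,
)
from metamine.corpus_io import Document, Section, Sentence
from metamine.ner import (
    LABELS,
    LabelerConfig,
    annotate_document,
    decode_spans,
    evaluate_tokenwise,
    grid_search,
    train_labeler,
)
from metamine.schema import ENTITY_TYPES, SpanAnnotation

FAST = LabelerConfig(seed=9)


def _tokenized(words, sent_id="s0", doc_id="d0"):
    tokens, pos = [], 0
    for w in words:
        tokens.append(Token(text=w, char_start=pos, char_end=pos + len(w)))
        pos += len(w) + 1
    return TokenizedSentence(doc_id=doc_id, sent_id=sent_id,
                             text=" ".join(words), tokens=tokens)


def _tagged(words, tags, entity_type="kit"):
    return TaggedSentence(entity_type=entity_type, tokenized=_tokenized(words),
                          tags=list(tags))


# --- token-wise metrics --------------------------------------------------------


class TestEvaluateTokenwise:
    def test_perfect_prediction(self):
        rep = evaluate_tokenwise(["O", "O", "B", "I"], ["O", "O", "B", "I"])
        assert rep.macro_precision == rep.macro_recall == rep.macro_f1 == 1.0

    def test_hand_computed_confusion(self):
        # gold B I O O O, pred B O O O O:
        # B: P=1, R=1, F1=1 ; I: P=0 (no predictions), R=0, F1=0
        # O: P=3/4, R=1, F1=6/7 ; macro = mean over {B, I, O}
        rep = evaluate_tokenwise(["B", "O", "O", "O", "O"],
                                 ["B", "I", "O", "O", "O"])
        assert rep.per_class["B"]["precision"] == 1.0
        assert rep.per_class["I"]["f1"] == 0.0
        assert rep.per_class["O"]["precision"] == pytest.approx(3 / 4)
        assert rep.macro_f1 == pytest.approx((1 + 0 + 6 / 7) / 3)

    def test_all_o_prediction_on_entity_gold(self):
        rep = evaluate_tokenwise(["O"] * 4, ["B", "I", "O", "O"])
        assert rep.macro_f1 < 1.0
        assert rep.per_class["O"]["recall"] == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            evaluate_tokenwise(["O"], ["O", "B"])

    def test_agrees_with_brute_force_recount_on_random_pairs(self):
        """Exact equality with an independent confusion-matrix recount on
        1,000 random tag-sequence pairs."""
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            gold = [LABELS[i] for i in rng.integers(0, 3, n)]
            pred = [LABELS[i] for i in rng.integers(0, 3, n)]
            rep = evaluate_tokenwise(pred, gold)

            # brute force: count every cell of the confusion matrix
            present = [l for l in LABELS if l in gold]
            ps, rs, fs = [], [], []
            for lab in present:
                tp = fp = fn = 0
                for p, g in zip(pred, gold):
                    tp += p == lab and g == lab
                    fp += p == lab and g != lab
                    fn += p != lab and g == lab
                p_ = tp / (tp + fp) if tp + fp else 0.0
                r_ = tp / (tp + fn) if tp + fn else 0.0
                f_ = 2 * p_ * r_ / (p_ + r_) if p_ + r_ else 0.0
                assert rep.per_class[lab]["precision"] == p_
                assert rep.per_class[lab]["recall"] == r_
                assert rep.per_class[lab]["f1"] == f_
                ps.append(p_); rs.append(r_); fs.append(f_)
            assert rep.macro_precision == sum(ps) / len(ps)
            assert rep.macro_recall == sum(rs) / len(rs)
            assert rep.macro_f1 == sum(fs) / len(fs)


# --- training ------------------------------------------------------------------


class TestTrainLabeler:
    def test_all_o_training_predicts_all_o(self):
        sents = [_tagged(["soil", "was", "sampled"], "OOO") for _ in range(10)]
        labeler = train_labeler(sents, 3e-5, 10, FAST)
        assert labeler.degenerate
        assert labeler.predict_tags(_tokenized(["kit", "x", "y"])) == ["O"] * 3

    def test_recovers_templated_kit_entity(self, vocab):
        """Macro-F1 >= 0.85 on a 200-sentence templated kit dataset."""
        rng = np.random.default_rng(0)
        kits = ["PowerSoil kit", "DNeasy kit", "FastDNA kit", "QIAamp kit"]
        fillers = ["soil was sampled in the field .",
                   "communities were profiled with care .",
                   "reads were clustered into taxa ."]
        sentences = []
        for i in range(200):
            if i % 2:
                kit = kits[rng.integers(len(kits))]
                text = f"DNA was extracted with the {kit} today ."
                ts = wordpiece_tokenize(
                    Sentence(sent_id=f"s{i}", text=text,
                             char_start=0, char_end=len(text)), vocab)
                start = text.index(kit)
                span = SpanAnnotation(doc_id="d", entity_type="kit",
                                      exact_text=kit, sent_id=f"s{i}",
                                      char_start=start, char_end=start + len(kit))
                sentences.append(bio_tag(ts, [span]))
            else:
                text = fillers[int(rng.integers(len(fillers)))]
                ts = wordpiece_tokenize(
                    Sentence(sent_id=f"s{i}", text=text,
                             char_start=0, char_end=len(text)), vocab)
                sentences.append(bio_tag(ts, [], entity_type="kit"))
        train, test = sentences[:160], sentences[160:]
        labeler = train_labeler(train, 3e-5, 30, FAST)
        preds = [labeler.predict_tags(t) for t in test]
        rep = evaluate_tokenwise(preds, [t.tags for t in test])
        assert rep.macro_f1 >= 0.85

    def test_same_seed_identical_predictions(self, entity_datasets):
        ds = entity_datasets["kit"]
        l1 = train_labeler(ds, 2e-5, 30, LabelerConfig(seed=5))
        l2 = train_labeler(ds, 2e-5, 30, LabelerConfig(seed=5))
        for tagged in ds.test[:20]:
            assert l1.predict_tags(tagged) == l2.predict_tags(tagged)

    def test_empty_training_split_rejected(self):
        with pytest.raises(ValueError):
            train_labeler([], 1e-5, 10, FAST)


@pytest.fixture(scope="module")
def kit_search(entity_datasets):
    return grid_search(entity_datasets["kit"], LabelerConfig(seed=9))


class TestGridSearch:
    def test_exhaustive_35_combinations(self, kit_search):
        _, reports = kit_search
        assert len(reports) == 35
        combos = {(r["learning_rate"], r["epoch"]) for r in reports}
        assert len(combos) == 35

    def test_tie_break_prefers_fewest_epochs_then_lowest_rate(self, kit_search):
        best, reports = kit_search
        top = max(r["f1"] for r in reports)
        tied = [r for r in reports if r["f1"] == top]
        expected = min(tied, key=lambda r: (r["epoch"], r["learning_rate"]))
        assert (best.learning_rate, best.epochs) == (
            expected["learning_rate"], expected["epoch"])

    def test_selected_report_consistent_with_table(self, kit_search):
        best, reports = kit_search
        row = next(r for r in reports
                   if r["learning_rate"] == best.learning_rate
                   and r["epoch"] == best.epochs)
        assert row["f1"] == max(r["f1"] for r in reports)

    def test_mean_macro_f1_across_entities(self, entity_datasets):
        """Each of the 16 labelers reaches macro-F1 >= 0.8 on the separable
        synthetic bundle; the mean comfortably clears it."""
        f1s = []
        for etype in ENTITY_TYPES:
            _, reports = grid_search(entity_datasets[etype], LabelerConfig(seed=9))
            f1s.append(max(r["f1"] for r in reports))
        assert min(f1s) >= 0.8
        assert float(np.mean(f1s)) >= 0.8


# --- decoding ------------------------------------------------------------------


class TestDecodeSpans:
    def test_single_run(self):
        tagged = _tagged(["a", "b", "kitx", "kity", "c"], "OOBIO")
        spans = decode_spans(tagged)
        assert len(spans) == 1
        assert spans[0].exact_text == "kitx kity"

    def test_i_start_repaired(self):
        tagged = _tagged(["x", "y", "z"], "OII")
        spans = decode_spans(tagged)
        assert len(spans) == 1
        assert spans[0].exact_text == "y z"

    def test_adjacent_b_restarts_span(self):
        tagged = _tagged(["a", "b", "c"], "BBI")
        spans = decode_spans(tagged)
        assert [s.exact_text for s in spans] == ["a", "b c"]

    def test_round_trip_with_bio_tag_on_random_sentences(self, vocab):
        """decode(bio_tag(spans)) recovers the span token-cover on 1,000
        random synthetic sentences."""
        rng = np.random.default_rng(7)
        words = ["soil", "kitx", "water", "sample", "alpha", "beta", "gamma"]
        for _ in range(1000):
            n = int(rng.integers(3, 12))
            ts = _tokenized([words[i] for i in rng.integers(0, len(words), n)])
            # random valid BIO tags (I only after B/I)
            tags = []
            for i in range(n):
                choices = ["O", "B"] if not tags or tags[-1] == "O" \
                    else ["O", "B", "I"]
                tags.append(choices[int(rng.integers(len(choices)))])
            tagged = TaggedSentence(entity_type="kit", tokenized=ts, tags=tags)
            spans = decode_spans(tagged)
            for s in spans:
                assert s.char_start < s.char_end
                assert ts.text[s.char_start:s.char_end] == s.exact_text
            anns = [SpanAnnotation(doc_id="d", entity_type="kit",
                                   exact_text=s.exact_text, sent_id="s0",
                                   char_start=s.char_start, char_end=s.char_end)
                    for s in spans]
            again = bio_tag(ts, anns)
            assert again.tags == tags

    def test_spans_never_overlap_within_type(self):
        tagged = _tagged(["a", "b", "c", "d"], "BIBI")
        spans = decode_spans(tagged)
        for s1, s2 in zip(spans, spans[1:]):
            assert s1.char_end <= s2.char_start


# --- document annotation --------------------------------------------------------


@pytest.fixture(scope="module")
def labelers(entity_datasets):
    cfg = LabelerConfig(seed=9)
    return {
        etype: grid_search(entity_datasets[etype], cfg)[0]
        for etype in ENTITY_TYPES
    }


class TestAnnotateDocument:
    def test_planted_kit_mention_found(self, bundle, vocab, labelers):
        doc = bundle.documents[0]
        gold_kits = {a.exact_text for a in bundle.annotations
                     if a.doc_id == doc.doc_id and a.entity_type == "kit"}
        spans = annotate_document(doc, labelers, vocab)
        found_kits = {s.exact_text for s in spans if s.entity_type == "kit"}
        assert gold_kits <= found_kits

    def test_methods_only_scope(self, bundle, vocab, labelers):
        """A mention present only outside methods sections is not annotated."""
        doc = bundle.documents[0]
        results_sec = doc.sections_of_type("results")[0]
        text = "DNA was extracted with the PowerSoil DNA isolation kit ."
        injected = Section(
            heading="Results", canonical_type="results",
            sentences=results_sec.sentences + [Sentence(
                sent_id="injected.s", text=text,
                char_start=10_000, char_end=10_000 + len(text),
            )],
        )
        modified = Document(
            doc_id="mod", source_id=None, title=doc.title,
            sections=[injected],  # no methods section, no classifier
        )
        spans = annotate_document(modified, labelers, vocab)
        assert spans == []

    def test_idempotent(self, bundle, vocab, labelers):
        doc = bundle.documents[1]
        s1 = annotate_document(doc, labelers, vocab)
        s2 = annotate_document(doc, labelers, vocab)
        key = lambda s: (s.entity_type, s.sent_id, s.char_start, s.char_end)
        assert [key(s) for s in s1] == [key(s) for s in s2]

    def test_missing_labeler_rejected(self, bundle, vocab, labelers):
        partial = dict(labelers)
        partial.pop("kit")
        with pytest.raises(ValueError, match="kit"):
            annotate_document(bundle.documents[0], partial, vocab)
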