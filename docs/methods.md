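# Methods

## Scope and data model

`metamine` treats a publication as an ordered list of sections, each
sentence-segmented with 0-based, half-open, code-point character offsets —
`section_text[char_start:char_end] == sentence.text` is an invariant
maintained everywhere (XML parsing, the JSONL dialect, the synthetic
generator, tokenization, span decoding). Section headings are normalised to
{abstract, introduction, methods, results, discussion, other} through an
editable synonym table; nested sub-sections are flattened into their
top-level parent, and whitespace runs are collapsed before segmentation to
absorb XML pretty-printing noise. Sentence segmentation is terminator-based
with an abbreviation guard list (genus initials, "et al.", "e.g.", …);
tables are not parsed, which is a known recall limitation for entities that
tend to live in tables (primers, dates, places).

## Literature classification

Distant supervision projects a study's biome lineage label at a chosen
level onto its cross-referenced publications. Documents referenced by
studies that disagree at that level are **dropped** (and logged) rather
than majority-voted: at corpus scale the lost documents are cheap and label
noise is not. Class balancing excludes classes below `min_per_class` (20)
and downsamples every retained class to
`min(max_per_class=100, smallest retained class)`, making counts exactly
equal. Splits use a per-stratum floor rule — train size =
`floor(train_frac·n)` — which reproduces the canonical NER corpus
arithmetic exactly: 2,496 sentences at 90/10 give 2,246/250.

Features are either TF-IDF (lowercased unigrams, punctuation stripped
except within-token hyphens, smoothed idf, L2-normalised rows; `min_df`
defaults to 1 so tiny corpora behave correctly, and can be raised for real
corpora) or paragraph vectors. The embedder is a distributed-memory
paragraph-vector model in numpy: each document vector plus the mean of
window-5 context word vectors predicts the centre word by negative sampling
(k=5), 200 dimensions, 15 epochs, linearly decaying step size. With
`workers=1` and a fixed seed training is bit-reproducible; the `workers`
field is an interface-parity hint (training is single-threaded).

The classifier is a scikit-learn random forest grid-searched over
{50,100,150,200,250,300} trees × {25,50,75,100,125,150,None} max depth (42
combinations), scored by mean macro-F1 under 5-fold stratified
shuffle-split CV (test fraction 0.2) on the 80% training split, refit on
that split, and reported (per-class and macro P/R/F1, one-vs-rest ROC/AUC)
on the held-out 20%. One seed value drives the split, the CV shuffling, and
the forest. Triage applies the threshold to the **argmax class only** — a
document is selected *for* a category, not for any category whose
probability happens to clear the bar — which makes selection monotone
non-increasing in the threshold.

## Tokenization and BIO datasets

The WordPiece tokenizer does greedy longest-match-first segmentation of
whitespace-pretokenized, lowercased words against a one-token-per-line
vocabulary with `##` continuation pieces. A word that cannot be fully
segmented is emitted as a single token flagged `is_preserved_unknown` —
never replaced by an unknown-token marker — so primer strings and kit names
with characters outside the vocabulary keep their surface form available to
the labelers. Detection is "cannot fully segment", not a length heuristic.
A small synthetic fixture vocabulary ships in-package
(`data/wordpiece_vocab.txt`); any vocabulary in the same format loads.

Curated annotations arrive as exact text plus prefix/suffix context and are
anchored by exhaustive occurrence search, disambiguated by the longest
agreeing context (suffix-of-prefix + prefix-of-suffix); zero occurrences or
ties go to a rejects report rather than being guessed.

BIO tagging uses **character overlap** (not containment) to decide whether
a token is inside a span, which is robust to subword/annotation boundary
mismatches; the first inside token of each span is B, later ones I, and
adjacent distinct spans restart at B. Because entities nest across types,
16 datasets are built over one shared sentence set — a sentence with only a
kit mention is an all-O example in the other 15 — and one 90/10 split is
drawn once on sentences and reused by all 16, so no sentence crosses the
split in any model. By default only sentences bearing at least one
annotation enter the datasets (`only_annotated=False` includes all).
Sentences are truncated to 128 tokens; gold spans lying entirely beyond the
limit are logged as unlearnable.

## Sequence labelers

The default backend is a first-order conditional sequence model: an
averaged structured perceptron with Viterbi decoding over B/I/O, token
features (lowercased identity, character shape, 3-character prefix/suffix,
neighbour words ±2, neighbour shapes ±1, continuation-piece and
preserved-unknown flags, bias) and learned transition/start scores. The
structural constraint that I may not follow O or open a sentence is a hard
decoder constraint; a predicted I-start is additionally repaired to B at
span-decoding time and logged. Training uses Hamming-cost-augmented
decoding (a unit margin per wrongly labelled token) and stops early once an
epoch makes zero updates — from that point the raw weights are fixed and
only the averaging clock advances. Ties in the decoder resolve to O, which
also makes a model trained on all-O data (flagged `degenerate`) predict
all O.

The hyperparameter grid is the conventional fine-tuning grid — learning
rates {1e-5, 2e-5, 3e-5, 4e-5, 5e-5} × epochs {10, 30, 50, 70, 90, 110,
130} — retained verbatim for a pluggable transformer backend. For the
perceptron the learning rate maps to a step size through a fixed ×2e4
scale, spanning steps 0.2–1.0 against the unit margin, so the grid
genuinely trades step size against passes. Each learning rate is trained
once to the maximum epoch count with snapshots at every grid epoch; because
one seeded shuffle stream drives the pass order, a snapshot at epoch k is
identical to training k epochs from scratch, and the 35 emitted reports are
the exhaustive grid. Selection maximises token-wise macro-F1 on the test
split; ties break to fewer epochs, then lower learning rate (a fixed,
documented rule — performance-equivalent among tied candidates).

Token-wise evaluation builds the 3×3 confusion over B/I/O on subword tokens
as produced by the tokenizer and macro-averages P/R/F1 with equal weight
over the classes **present in the gold** (O included — "token-wise" is
taken literally; per-class F1 is 0 when both P and R are 0). Document
annotation runs all 16 labelers over the methods text only (tagged methods
sections, else sections the section classifier predicts as methods),
keeping overlapping spans across types and dropping exact duplicates within
a type.

## Self-distillation

Teachers annotate a fresh corpus selected per biome class at classifier
probability ≥ 0.5 (sampling without replacement, seeded). The predicted
spans — provenance-tagged `predicted`, never a gold label — form the entire
student training set (no split); students reuse the teachers' backend and
grids, with grid selection and the final report both computed on the full
curated gold corpus (train + test of the teachers), following the reading
that the curated set as a whole is the student test set. The pass criterion
is token-wise macro-F1 ≥ 70%. One distillation round only.

## MIxS comparison

Entity types and submitted field names map onto MIxS terms through an
editable two-sided table (entity side total over the 16 types; either side
may route to `unmapped`, which is excluded and counted in a coverage log).
Values from all of a study's samples are pooled per term as a set union.
Canonicalization before comparison is deliberately minimal — trim, collapse
internal whitespace, case-fold; no stemming, synonym expansion, or unit
conversion — because the comparison is defined as exact match and format
variants should surface as `nonidentical`, not be hidden. Per (study, term)
exactly one status: intersecting non-empty pools → `identical` (one shared
value suffices even if others differ), disjoint non-empty → `nonidentical`,
one side empty → `unique_submitted`/`unique_annotation`, both empty →
`absent`. Summaries count studies per status per term (absent excluded);
the `min_studies_per_field` filter (default 50) drops terms whose data
comes only from rarely used submitted fields. Numeric fields (depth,
lat_lon, elev) are compared as strings, consistent with the exact-match
rule.

## Synthetic corpora: what they emulate and what they do not

The generator draws everything from one seeded pseudo-random stream in a
fixed order, so a bundle is a deterministic function of its configuration.
It emulates: five-section articles whose filler sentences mix
class-specific and shared vocabulary (`mixture`, default 0.7 — separability
rises with it), section-specific cue phrases (so the section classifier has
signal), entity mentions planted in methods sentences through 8 templated
cue contexts covering all 16 types (`plant_rate` scales how many templates
a document uses; each surface form is used at most once per document so
context anchoring is exact), nested site/place span pairs, primer surfaces
with the ′ character and length > 20 (always exercising the
preserved-unknown path), one study per document with a 3-level biome
lineage, archive accessions, and submitted metadata derived from the
planted values with configurable `metadata_missingness` (field dropped) and
`metadata_inconsistency` (format variant, e.g. "June 2015" → "2015").

Default problem sizes are the package's study conditions: 8 documents per
class in the gold bundle, 80 per class in the fresh corpus, 60 per class
selected for distillation (the full-scale study uses 500). What passing
tests show: the pipeline's arithmetic, invariants, and information flow are
correct, and accuracy transfers through the distillation loop when the
underlying signal is learnable. What they do not show: performance on real
prose — the generator has no linguistic variety, no annotation
disagreement, no tables, no out-of-template mentions — so the near-ceiling
synthetic F1 values are not predictions for real corpora, where the
corresponding published models score 71–98% per entity.

## Known limitations

- The feature-based labeler is a deliberate desk-scale default; contextual
  embeddings (a transformer backend) would be needed to approach published
  per-entity accuracy on real text, and the backend field exists for that.
- Exact-match comparison understates true metadata agreement (synonyms,
  units); that bias is intentional and documented above.
- Sentence segmentation and the heading synonym table are small curated
  rule sets; unusual article formatting degrades both gracefully (sections
  default to `other`, segmentation falls back to terminator splitting).
- The paragraph-vector embedder is a minimal implementation tuned for
  determinism and small corpora, not for large-vocabulary throughput.
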