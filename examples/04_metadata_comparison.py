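"""MIxS comparison of publication-derived vs submitted study metadata.

With 30% of submitted fields missing, publication-derived annotations
uniquely supply roughly that fraction of metadata cells; with format
inconsistency, exact-match comparison surfaces nonidentical cells instead
of hiding them.
"""

from collections import Counter

from metamine import GeneratorConfig, generate, summarize
from metamine.enrichment import compare_bundle

bundle = generate(GeneratorConfig(
    seed=13, metadata_missingness=0.3, metadata_inconsistency=0.1,
))
cells = compare_bundle(bundle)
counts = Counter(c.status for c in cells if c.status != "absent")
total = sum(counts.values())
print(f"{total} (study, MIxS term) cells with data:")
for status, n in counts.most_common():
    print(f"  {status:18s} {n:4d} ({n / total:.0%})")
# unique_annotation ≈ the 30% missingness: the literature-mined annotations
# fill exactly the fields the submitter left out

summary = summarize(cells, min_studies_per_field=0)
print("\nper-term stacked counts (top 5 by total):")
for term, c in list(summary.items())[:5]:
    print(f"  {term:20s} identical={c['identical']:2d} nonidentical={c['nonidentical']:2d} "
          f"unique_ann={c['unique_annotation']:2d} unique_sub={c['unique_submitted']:2d}")
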