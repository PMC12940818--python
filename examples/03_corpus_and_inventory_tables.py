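"""Recompute the per-drug corpus rates and pattern-inventory statistics.

Feeds the shipped reference table of absolute study-type counts through
the same rate arithmetic `corpus_summary` applies to any labelled corpus,
and summarizes the structure of the shipped seed pattern inventory.
"""

from acemine import data_path, inventory_stats, load_inventory
from acemine.corpus import load_reference_counts, summary_from_counts

counts, total = load_reference_counts(data_path("reference_corpus_counts.tsv"))
table = summary_from_counts(counts, total)
print(f"corpus of {total} distinct records")
print(table.head(6).to_string(index=False))
# pct_* columns are half-up 2-decimal percentages: shares of each drug's
# texts per study type, and the drug's share of all distinct records.

with open(data_path("pattern_inventory.tsv"), encoding="utf-8") as fh:
    inventory = load_inventory(fh)
print()
print(inventory_stats(inventory).to_string(index=False))
# one row per semantic group: subgroup/phrase counts, mean and median
# phrases per relation subgroup, and strength-tier counts at both the
# subgroup and the phrase level.
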