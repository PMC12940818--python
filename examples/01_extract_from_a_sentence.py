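"""Extract and score candidate associations from a single abstract.

Builds a tiny inventory and lexicon in memory, runs the sentence-level
stages on one hand-written abstract, and prints each candidate with its
token distance d and score Ssent = wp/(1+d).
"""

import io

from acemine import (
    EntityType,
    TypedLexicon,
    clean_text,
    extract_candidates,
    load_inventory,
    match_patterns,
    recognize_gazetteer,
    select_best,
    split_sentences,
    tokenize,
)

inventory = load_inventory(io.StringIO(
    "pattern_id\tgroup\trelation_type\tstrength\tphrase\n"
    "M1\tMECHANISMS\tInhibit\tSTRONG\tinhibits\n"
    "M2\tMECHANISMS\tInhibit\tSTRONG\tinhibit\n"
    "E1\tEFFECTS\tTreatment\tSTRONG\tis effective in the treatment of\n"
    "C1\tCOADMINISTRATION\tCoadministered_with\tSTRONG\tin combination with\n"
))
lexicon = TypedLexicon([
    ("captopril", EntityType.CHEMICAL, True),
    ("enalapril", EntityType.CHEMICAL, True),
    ("hydrochlorothiazide", EntityType.CHEMICAL, False),
    ("MMP2", EntityType.GENE_PROTEIN, False),
    ("hypertension", EntityType.DISEASE, False),
])

title = "Captopril in combination therapy"
abstract = (
    "Captopril inhibits MMP2 in gliosarcoma cells. "
    "Enalapril is effective in the treatment of hypertension. "
    "Captopril did not inhibit MMP2 in control samples. "
    "Enalapril was used in combination with hydrochlorothiazide."
)

document = clean_text(title, abstract)
for sentence in split_sentences(document, pmid="example"):
    tokens = tokenize(sentence)
    hits = match_patterns(tokens, inventory)
    mentions = recognize_gazetteer(sentence, tokens, lexicon)
    for c in select_best(extract_candidates(sentence, mentions, hits, tokens)):
        print(
            f"[{c.group.value:16s}] {c.entity_a.surface} -> {c.entity_b.surface}"
            f"  d={c.d}  Ssent={c.s_sent:.2f}  {c.polarity.value}"
        )

# Each line is one retained candidate: d sums the token gaps between the
# pattern phrase and the two entities, so adjacent triples score wp (3.0
# for a strong pattern); the negated statement is flagged NEGATIVE because
# "not" falls inside the 5-token window around the pattern.
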