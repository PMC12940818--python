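# Methods

## Pipeline and assumptions

The pipeline extracts associations strictly at the sentence level: a
relation is recorded only when a drug mention, a type-compatible second
entity and a curated pattern phrase co-occur in one sentence. This is a
deliberate trade of recall for interpretability — every extracted
association points to a concrete sentence span, and no statement is
inferred across sentence boundaries, through coreference, or from
dependency structure. Relation labels summarize how a claim is phrased,
not the underlying causal biology.

Stages, each behind its own module: corpus ingestion and study-type
labelling (`corpus`), cleaning/segmentation/tokenization (`textproc`),
entity recognition (`ner`), pattern matching (`patterns`), candidate
extraction with negation and distance scoring (`extraction`), offline
identifier normalization (`normalization`), cross-publication aggregation
(`aggregation`) and thresholded network export (`network`). `pipeline`
sequences them; `cli` exposes them as artifact-producing subcommands;
`synthetic` generates fully controlled test corpora.

## Scoring model

Sentence score: `Ssent = wp / (1 + d)` with pattern weight
`wp = 3/2/1` for strong/medium/weak patterns and token distance `d ≥ 0`.
Aggregated confidence: `Sconf = Σ_i Ssent(i)` over the `Npub` supporting
publications. Consequences kept as invariants in the tests:
`0 < Ssent ≤ 3`, `Ssent = wp` iff `d = 0`, strict monotonicity in both
arguments, `Sconf` additivity under new supporting evidence, and
`Npub·min_i Ssent(i) ≤ Sconf ≤ 3·Npub`. `Sconf` is a ranking score, not a
probability, and is never normalized to [0, 1]; affirmative and negated
evidence are aggregated separately and never combined into one number,
since the texts give no objective weighting between supporting and
refuting statements.

## Parameters

| parameter | default | meaning |
|---|---|---|
| negation window | 5 tokens | a cue must begin ≤ 5 positions before the pattern span or end ≤ 5 after it |
| pattern weights | 3 / 2 / 1 | strong / medium / weak indicative strength |
| distance combination | sum | how the two per-entity distances form `d` (see below) |
| per-publication score | max | how several supporting sentences in one publication form `Ssent(i)` (see below) |
| thresholds | 0.1 … 0.7 | inclusive `Sconf ≥ τ` retention grid for networks |
| rounding | half-up, 2 decimals | all reported percentages and means |

## Design choices where the design was open

- **Token definition.** Distances and the negation window are measured in
  tokens, so the tokenizer is part of the model: words are maximal runs of
  unicode letters/digits with internal hyphens (keeping "MMP-2" and
  "α-blocker" atomic); every other non-space character is its own token,
  so punctuation counts toward distance. The choice is centralized in
  `textproc.tokenize` and flagged for sensitivity testing.
- **Combining the two entity distances.** A single scalar `d` is required
  by the scoring formula. The default is the *sum* of the two per-entity
  minimal distances — penalizing total contextual spread around the
  pattern — isolated in `extraction.combine_distances` with `max` and
  `min` available for sensitivity analysis.
- **Several sentences, one publication.** `Ssent(i)` is indexed by
  publication; when one publication supports a key through several
  sentences, the *maximum* sentence score is used (the per-sentence
  selection step already prefers maxima). `aggregation.aggregate` takes a
  `per_pub_score` reducer so the alternative reading (sum) is one argument
  away.
- **Ties in per-sentence selection.** All co-maximal candidates of a
  sentence are retained, in a deterministic order.
- **Key orientation.** Mechanisms and effects keys are ordered
  drug → entity (every relation label is directional); co-administration
  keys are unordered, since co-prescription is symmetric.
- **Overlap resolution.** Overlapping entity mentions reduce by longest
  span, then leftmost, then type priority chemical < gene/protein <
  disease; entity mentions overlapping the pattern span are excluded from
  candidacy because distance is undefined on overlap.
- **Normalization is exact-match only.** Fuzzy matching is excluded on
  purpose: short ambiguous abbreviations (ACE, Ang II) are the dominant
  failure mode of automated normalization, and an exact, table-backed
  lookup keeps every assignment auditable. Unmapped entities are retained
  but flagged and excluded from fully-normalized aggregation. Organism
  comes from the table (human-first on duplicate surfaces), never inferred
  from context.
- **Offline first.** The tested path needs no network: JSON-lines corpus
  fixtures, TSV lexicons/patterns/mappings. Online PubMed retrieval via
  Bio.Entrez is an optional extra behind the same parsing contract; the
  external neural-NER integration is an import/validation contract for a
  TSV dialect, not a model dependency.

## Seed data

The shipped pattern inventory reproduces the documented three-group
structure — mechanisms: 42 subgroups / 248 phrases (mean 5.90, median 6;
9 strong, 23 medium, 10 weak subgroups); effects: 33 / 167 (5.06, 6;
6/14/13); co-administration: 3 / 13 (median 3; 1/1/1) — populated with
representative trigger phrases and their morphological variants stored as
separate rows, keeping matching exact and auditable. Structure, not
phrase content, is the contract; the co-administration mean is reported as
computed (13/3 = 4.33). The drug lexicon ships the 19 ACE inhibitors with
common trade-name synonyms. The per-drug reference count table records
published absolute study-type counts for a 23,294-record corpus and is
the input from which the rate columns are recomputed.

## Synthetic corpus: what it emulates, what it does not

The generator realizes each planted association as a token-calibrated
sentence: filler tokens are inserted to hit the target distance exactly,
the negation cue (when requested) is placed inside the 5-token window,
and every planted surface appears in the emitted lexicons and mapping
tables (closure). Study-type markers (MeSH "Animals", "In Vitro
Techniques", clinical publication types) are written so that
classification recovers the generator's assignment exactly; years are
drawn from the configured range; distractor sentences contain at most two
of the three required elements. All randomness flows through one seeded
generator, and identical spec+seed produce byte-identical corpora.

Passing recovery tests therefore show that the implementation computes
the defined model exactly — they do not show robustness to real
biomedical prose. The generator has no synonymy, no abbreviations, no
nested entities, no cross-sentence discourse, no scope-limited negation
("not only … but"), and a vocabulary chosen to be closed under the
gazetteer. Precision/recall of 1.0 on synthetic data is a correctness
statement, not a performance claim.

Default conditions: 200 publications, 36 planted associations covering
all three groups, all three tiers, both polarities (co-administration
affirmative only), distances 0–6, 1–4 supporting publications each
(~30 % of mechanism/effect triples use a non-ACE chemical so the
ACE filter is exercised), publication years 1976–2025, multi-label
study-type mix ≈ 0.25/0.45/0.35 for in vitro/in vivo/clinical.

## Numerical and reporting conventions

Percentages and means are rounded half-up to 2 decimals via decimal
arithmetic (`round_half_up`), matching the printed-table convention.
Medians of phrase-per-subgroup counts use the middle value, taking the
lower of the two middle values for even counts. Score comparisons in
selection use exact float equality — scores of one sentence derive from
identical integer arithmetic, so ties are exact. TSV round-trips store
scores with `repr` so floats survive bit-exactly; GraphML stores doubles
(round-trip agreement to 1e-9 is asserted). Corpus share denominators use
distinct-PMID counts; per-drug study-type counts are multi-label, so
columns need not sum to the drug's total.

## Known limitations

Sentence-level extraction misses implicit, cross-sentence and
unconventionally phrased relations; pattern matching is exact, so unseen
morphological variants require new inventory rows; abbreviation
disambiguation and synonym merging are out of scope, so aggregated
networks may fragment one concept across nodes; the confidence score is
relative to this scoring scheme and should be used to rank and filter,
not to assert mechanistic certainty.
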