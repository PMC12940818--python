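"""End-to-end orchestration: records -> candidates -> aggregated associations.

Glues the stage modules together in the order the method defines:
preprocessing, entity recognition, pattern matching, candidate extraction
with negation and distance scoring, per-sentence best-candidate selection,
ACE-inhibitor filtering, normalization annotation, aggregation. Each stage
keeps its own module; this module only sequences them and keeps the
bookkeeping counts (candidates extracted, retained after filtering,
normalization outcomes, aggregated records).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .aggregation import AggregatedAssociation, aggregate
from .corpus import DrugLexicon, PublicationRecord, classify_study_types, label_drugs
from .extraction import (
    CandidateAssociation,
    DEFAULT_NEGATION_CUES,
    NegationCues,
    extract_candidates,
    filter_ace,
    select_best,
)
from .ner import TypedLexicon, recognize_gazetteer
from .normalization import AnnotatedCandidate, MappingTable, annotate_candidates
from .patterns import PatternInventory, match_patterns
from .textproc import clean_text, split_sentences, tokenize

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    candidates_all: list[CandidateAssociation] = field(default_factory=list)
    candidates_ace: list[CandidateAssociation] = field(default_factory=list)
    annotated: list[AnnotatedCandidate] = field(default_factory=list)
    aggregated: list[AggregatedAssociation] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        by_norm = {0: 0, 1: 0, 2: 0}
        for a in self.annotated:
            by_norm[a.n_normalized] += 1
        return {
            "candidates_extracted": len(self.candidates_all),
            "candidates_ace_filtered": len(self.candidates_ace),
            "normalized_0": by_norm[0],
            "normalized_1": by_norm[1],
            "normalized_2": by_norm[2],
            "aggregated": len(self.aggregated),
        }


def run_pipeline(
    records: Sequence[PublicationRecord],
    inventory: PatternInventory,
    entity_lexicon: TypedLexicon,
    mapping_table: MappingTable,
    drug_lexicon: DrugLexicon | None = None,
    cues: NegationCues = DEFAULT_NEGATION_CUES,
    window: int = 5,
    distance_mode: str = "sum",
    classify: bool = True,
) -> PipelineResult:
    """Run extraction through aggregation over a record collection.

    When ``classify`` is set, study types and drug labels are (re)assigned
    on the records in place before extraction. Candidates are extracted
    without restricting the chemical to ACE inhibitors, the per-sentence
    maximum-score candidates are retained, and the ACE filter is applied
    afterwards; only fully-normalized candidates enter aggregation.
    """
    result = PipelineResult()
    for rec in records:
        if classify:
            rec.study_types = classify_study_types(rec)
            if drug_lexicon is not None:
                rec.drug_labels = label_drugs(rec, drug_lexicon)
        document = clean_text(rec.title, rec.abstract)
        for sentence in split_sentences(document, pmid=rec.pmid):
            tokens = tokenize(sentence)
            hits = match_patterns(tokens, inventory)
            if not hits:
                continue
            mentions = recognize_gazetteer(sentence, tokens, entity_lexicon)
            if not mentions:
                continue
            cands = extract_candidates(
                sentence, mentions, hits, tokens,
                cues=cues, window=window, distance_mode=distance_mode,
            )
            result.candidates_all.extend(select_best(cands))
    result.candidates_ace = filter_ace(result.candidates_all)
    result.annotated = annotate_candidates(result.candidates_ace, mapping_table)
    result.aggregated = aggregate(
        [a for a in result.annotated if not a.flagged],
        {r.pmid: r for r in records},
    )
    return result
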