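"""acemine: rule-based mining of drug-association networks from abstracts.

Extracts drug-target (mechanisms), drug-disease (effects) and drug-drug
(co-administration) associations from biomedical titles and abstracts using
curated lexical patterns, scores each sentence-level relation by pattern
strength and token distance (Ssent = wp / (1 + d)), normalizes entities to
PubChem / UniProt / Disease Ontology identifiers via offline tables, and
aggregates evidence across publications into confidence-scored
(Sconf = sum of per-publication scores), polarity-separated association
networks. Ships with a synthetic-corpus generator that plants associations
at controlled token distances so the whole pipeline is testable offline.
"""

from importlib import resources

from .corpus import (
    DrugLexicon,
    PublicationRecord,
    StudyType,
    build_pubmed_queries,
    classify_study_types,
    corpus_summary,
    parse_records,
    summary_from_counts,
)
from .textproc import Sentence, Token, clean_text, split_sentences, tokenize
from .ner import EntityMention, EntityType, TypedLexicon, recognize_gazetteer
from .patterns import (
    PatternInventory,
    PatternPhrase,
    SemanticGroup,
    StrengthTier,
    inventory_stats,
    load_inventory,
    match_patterns,
)
from .extraction import (
    CandidateAssociation,
    Polarity,
    detect_negation,
    extract_candidates,
    filter_ace,
    score_sentence,
    select_best,
    token_distance,
)
from .normalization import (
    MappingTable,
    NormalizedEntity,
    annotate_candidates,
    load_mapping_tables,
    normalize_mention,
)
from .aggregation import (
    AggregatedAssociation,
    aggregate,
    polarity_score_summary,
    relation_type_counts,
    strength_distribution,
    temporal_metrics,
)
from .network import build_graph, export_graph, import_graph, retention_table, threshold_filter
from .pipeline import PipelineResult, run_pipeline
from .synthetic import (
    GeneratedCorpus,
    SyntheticSpec,
    default_spec,
    evaluate_recovery,
    generate_corpus,
)

__version__ = "0.1.0"


def data_path(name: str):
    """Path to a shipped data file (seed lexicons, pattern inventory, cues)."""
    return resources.files(__package__) / "data" / name
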