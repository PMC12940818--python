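"""Sentence-level candidate associations: co-occurrence, negation, scoring.

A candidate association is a (drug, second entity, pattern phrase) triple
found in one sentence. Its score is

    Ssent = wp / (1 + d)

where wp in {3, 2, 1} is the indicative strength weight of the pattern and
d >= 0 is the token distance between the pattern phrase and the entity
mentions. The two per-entity minimal distances are combined by SUM; that
choice is isolated in :func:`combine_distances` so its effect can be probed
(max and min are the alternative readings). Negation cues within a 5-token
window of the pattern flip polarity for mechanisms and effects; drug-drug
co-administration statements are always affirmative.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from typing import IO, Iterable, Sequence

from .ner import EntityMention, EntityType
from .patterns import PatternHit, SemanticGroup, StrengthTier
from .textproc import Sentence, Token

__all__ = [
    "Polarity",
    "CandidateAssociation",
    "NegationCues",
    "DEFAULT_NEGATION_CUES",
    "token_distance",
    "combine_distances",
    "detect_negation",
    "score_sentence",
    "extract_candidates",
    "select_best",
    "filter_ace",
    "write_candidates_tsv",
]


class Polarity(str, Enum):
    POSITIVE = "POSITIVE"
    NEGATIVE = "NEGATIVE"


#: Second-entity type required by each semantic group.
GROUP_SECOND_TYPE = {
    SemanticGroup.MECHANISMS: EntityType.GENE_PROTEIN,
    SemanticGroup.EFFECTS: EntityType.DISEASE,
    SemanticGroup.COADMINISTRATION: EntityType.CHEMICAL,
}


@dataclass(frozen=True)
class CandidateAssociation:
    """One sentence-level (drug, entity, pattern) relation."""

    pmid: str
    sentence_index: int
    group: SemanticGroup
    relation_type: str
    entity_a: EntityMention
    entity_b: EntityMention
    pattern_id: str
    strength: StrengthTier
    wp: int
    d: int
    s_sent: float
    polarity: Polarity

    def __post_init__(self) -> None:
        if self.entity_a.entity_type is not EntityType.CHEMICAL:
            raise ValueError("entity_a must be a CHEMICAL mention")
        if self.entity_b.entity_type is not GROUP_SECOND_TYPE[self.group]:
            raise ValueError(
                f"entity_b type {self.entity_b.entity_type} invalid for {self.group}"
            )


def token_distance(span_a: tuple[int, int], span_b: tuple[int, int]) -> int:
    """Number of tokens strictly between two inclusive token spans.

    Adjacent spans have distance 0. Overlapping spans are an error: distance
    is undefined and the caller must exclude such pairs.
    """
    (a0, a1), (b0, b1) = span_a, span_b
    if a0 <= b1 and b0 <= a1:
        raise ValueError(f"overlapping spans {span_a} and {span_b}")
    if a1 < b0:
        return b0 - a1 - 1
    return a0 - b1 - 1


def combine_distances(d_a: int, d_b: int, mode: str = "sum") -> int:
    """Combine the two per-entity distances into the scalar d.

    The default is the sum (total contextual spread around the pattern);
    "max" and "min" are provided for sensitivity analysis.
    """
    if mode == "sum":
        return d_a + d_b
    if mode == "max":
        return max(d_a, d_b)
    if mode == "min":
        return min(d_a, d_b)
    raise ValueError(f"unknown distance combination mode {mode!r}")


def score_sentence(wp: int, d: int) -> float:
    """The sentence-level score Ssent = wp / (1 + d)."""
    if wp not in (1, 2, 3):
        raise ValueError(f"wp must be 1, 2 or 3, got {wp}")
    if d < 0:
        raise ValueError(f"distance must be non-negative, got {d}")
    return wp / (1 + d)


class NegationCues:
    """Negation cue phrases, each stored as a lower-cased token tuple."""

    def __init__(self, cues: Iterable[str]):
        from .textproc import tokenize

        self.cues: list[tuple[str, ...]] = []
        seen = set()
        for cue in cues:
            toks = tuple(t.text.casefold() for t in tokenize(cue))
            if toks and toks not in seen:
                seen.add(toks)
                self.cues.append(toks)

    @classmethod
    def from_file(cls, path) -> "NegationCues":
        with open(path, encoding="utf-8") as fh:
            return cls(
                line.strip() for line in fh
                if line.strip() and not line.startswith("#")
            )

    def __iter__(self):
        return iter(self.cues)

    def __len__(self) -> int:
        return len(self.cues)


DEFAULT_NEGATION_CUES = NegationCues(
    [
        "no", "not", "without", "lack of", "fail to", "fails to", "failed to",
        "does not", "did not", "do not", "cannot", "neither", "nor",
        "absence of", "unable to", "never",
    ]
)


def detect_negation(
    tokens: Sequence[Token],
    pattern_span: tuple[int, int],
    cues: NegationCues = DEFAULT_NEGATION_CUES,
    window: int = 5,
) -> Polarity:
    """Polarity of a pattern occurrence from nearby negation cues.

    NEGATIVE iff some cue occurrence *begins* within ``window`` token
    positions before the pattern span or *ends* within ``window`` positions
    after it; otherwise POSITIVE.
    """
    lowered = [t.text.casefold() for t in tokens]
    p0, p1 = pattern_span
    for cue in cues:
        n = len(cue)
        for i in range(len(lowered) - n + 1):
            if tuple(lowered[i:i + n]) != cue:
                continue
            cue_start, cue_end = i, i + n - 1
            if p0 - window <= cue_start <= p0 - 1:
                return Polarity.NEGATIVE
            if p1 + 1 <= cue_end <= p1 + window:
                return Polarity.NEGATIVE
    return Polarity.POSITIVE


def _spans_disjoint(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[1] < b[0] or b[1] < a[0]


def extract_candidates(
    sentence: Sentence,
    mentions: Sequence[EntityMention],
    hits: Sequence[PatternHit],
    tokens: Sequence[Token],
    cues: NegationCues = DEFAULT_NEGATION_CUES,
    window: int = 5,
    distance_mode: str = "sum",
) -> list[CandidateAssociation]:
    """All candidate associations of one sentence.

    For each pattern hit and each type-compatible (chemical, second entity)
    pair with spans disjoint from the pattern: when an entity surface occurs
    several times in the sentence, the occurrence closest to the pattern is
    used. d is the combination (default: sum) of the two per-entity
    distances, Ssent = wp/(1+d), and polarity comes from negation detection
    (co-administration is always POSITIVE). For co-administration the two
    chemicals must differ after case-folding.
    """
    out: list[CandidateAssociation] = []
    for hit in hits:
        pat = hit.pattern
        span = hit.token_span

        # closest occurrence per distinct (type, case-folded surface) entity
        best_by_entity: dict[tuple[EntityType, str], tuple[int, EntityMention]] = {}
        for m in mentions:
            if not _spans_disjoint(m.token_span, span):
                continue  # distance undefined on overlap with the pattern
            d = token_distance(span, m.token_span)
            key = (m.entity_type, m.surface.casefold())
            prior = best_by_entity.get(key)
            if prior is None or d < prior[0] or (d == prior[0] and m.start < prior[1].start):
                best_by_entity[key] = (d, m)

        chemicals = [
            (d, m) for (etype, _), (d, m) in best_by_entity.items()
            if etype is EntityType.CHEMICAL
        ]
        second_type = GROUP_SECOND_TYPE[pat.group]
        seconds = [
            (d, m) for (etype, _), (d, m) in best_by_entity.items()
            if etype is second_type
        ]

        if pat.group is SemanticGroup.COADMINISTRATION:
            polarity = Polarity.POSITIVE
        else:
            polarity = detect_negation(tokens, span, cues=cues, window=window)

        if pat.group is SemanticGroup.COADMINISTRATION:
            ordered = sorted(chemicals, key=lambda dm: dm[1].start)
            pairs = [
                (a, b)
                for i, a in enumerate(ordered)
                for b in ordered[i + 1:]
                if a[1].surface.casefold() != b[1].surface.casefold()
            ]
        else:
            pairs = [(a, b) for a in chemicals for b in seconds]

        for (d_a, ma), (d_b, mb) in pairs:
            if not _spans_disjoint(ma.token_span, mb.token_span):
                continue
            d = combine_distances(d_a, d_b, distance_mode)
            out.append(
                CandidateAssociation(
                    pmid=sentence.pmid,
                    sentence_index=sentence.index,
                    group=pat.group,
                    relation_type=pat.relation_type,
                    entity_a=ma,
                    entity_b=mb,
                    pattern_id=pat.pattern_id,
                    strength=pat.strength,
                    wp=pat.weight,
                    d=d,
                    s_sent=score_sentence(pat.weight, d),
                    polarity=polarity,
                )
            )
    return out


def select_best(candidates: Sequence[CandidateAssociation]) -> list[CandidateAssociation]:
    """Retain the candidates with the maximal Ssent in one sentence.

    Co-maximal candidates (ties) are all kept. Output is ordered by
    (group, relation_type, entity_a.start, entity_b.start).
    """
    if not candidates:
        return []
    pmids = {(c.pmid, c.sentence_index) for c in candidates}
    if len(pmids) > 1:
        raise ValueError("select_best expects candidates of a single sentence")
    top = max(c.s_sent for c in candidates)
    kept = [c for c in candidates if c.s_sent == top]
    return sorted(
        kept,
        key=lambda c: (c.group.value, c.relation_type, c.entity_a.start, c.entity_b.start),
    )


def filter_ace(candidates: Iterable[CandidateAssociation]) -> list[CandidateAssociation]:
    """Keep only candidates involving at least one ACE inhibitor mention."""
    return [
        c for c in candidates
        if c.entity_a.is_ace_inhibitor or c.entity_b.is_ace_inhibitor
    ]


_TSV_COLUMNS = (
    "pmid", "sentence_index", "group", "relation_type", "pattern_id",
    "strength", "entity_a", "entity_b", "d", "s_sent", "polarity",
)


def write_candidates_tsv(candidates: Iterable[CandidateAssociation], stream: IO[str]) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(_TSV_COLUMNS)
    for c in candidates:
        writer.writerow(
            [c.pmid, c.sentence_index, c.group.value, c.relation_type,
             c.pattern_id, c.strength.value, c.entity_a.surface,
             c.entity_b.surface, c.d, repr(c.s_sent), c.polarity.value]
        )
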