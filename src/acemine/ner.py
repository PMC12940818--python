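"""Typed entity mentions: gazetteer recognition and external-NER import.

The offline (tested) recognizer is a longest-match gazetteer over per-type
term lists; output of an external neural recognizer can be imported from a
simple TSV dialect and is validated against the sentences it refers to.
Overlapping mentions are resolved by a fixed rule so downstream distance
computations see pairwise non-overlapping spans.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass
from enum import Enum
from typing import IO, Iterable, Mapping, Sequence

from .textproc import Sentence, Token, tokenize

logger = logging.getLogger(__name__)

__all__ = [
    "EntityType",
    "EntityMention",
    "TypedLexicon",
    "recognize_gazetteer",
    "import_external_mentions",
    "export_mentions",
    "resolve_overlaps",
]


class EntityType(str, Enum):
    CHEMICAL = "CHEMICAL"
    GENE_PROTEIN = "GENE_PROTEIN"
    DISEASE = "DISEASE"


#: Priority used to break overlap ties: chemicals outrank proteins outrank
#: diseases when spans of equal length start at the same position.
_TYPE_ORDER = {
    EntityType.CHEMICAL: 0,
    EntityType.GENE_PROTEIN: 1,
    EntityType.DISEASE: 2,
}


@dataclass(frozen=True)
class EntityMention:
    """A typed mention located in one sentence.

    ``start``/``end`` are character offsets within the sentence;
    ``token_span`` is the inclusive [first, last] token-index pair covering
    the mention.
    """

    pmid: str
    sentence_index: int
    surface: str
    entity_type: EntityType
    start: int
    end: int
    token_span: tuple[int, int]
    is_ace_inhibitor: bool = False
    source: str = "GAZETTEER"

    @property
    def length(self) -> int:
        return self.end - self.start


class TypedLexicon:
    """Per-type term lists for the gazetteer recognizer.

    Loaded from TSV rows ``term<TAB>type<TAB>ace_flag`` (ace_flag in
    {0, 1}); lookups are case-folded.
    """

    def __init__(self, terms: Iterable[tuple[str, EntityType, bool]]):
        self._terms: dict[str, tuple[str, EntityType, bool]] = {}
        for term, etype, ace in terms:
            key = term.casefold()
            if key in self._terms and self._terms[key][1] != EntityType(etype):
                raise ValueError(f"term {term!r} declared with two types")
            self._terms[key] = (term, EntityType(etype), bool(ace))

    def __len__(self) -> int:
        return len(self._terms)

    def items(self):
        return self._terms.items()

    @classmethod
    def from_tsv(cls, source: IO[str]) -> "TypedLexicon":
        rows = []
        for row in csv.reader(source, delimiter="\t"):
            if not row or row[0].startswith("#"):
                continue
            term, etype = row[0], row[1]
            ace = len(row) > 2 and row[2].strip() in ("1", "true", "True")
            rows.append((term, EntityType(etype), ace))
        return cls(rows)

    def to_tsv(self, stream: IO[str]) -> None:
        for key in sorted(self._terms):
            term, etype, ace = self._terms[key]
            stream.write(f"{term}\t{etype.value}\t{int(ace)}\n")


def _token_span_for(tokens: Sequence[Token], start: int, end: int) -> tuple[int, int] | None:
    covered = [t.index for t in tokens if t.start < end and t.end > start]
    if not covered:
        return None
    return (covered[0], covered[-1])


def recognize_gazetteer(
    sentence: Sentence,
    tokens: Sequence[Token],
    lexicon: TypedLexicon,
) -> list[EntityMention]:
    """Case-insensitive longest match of lexicon terms at word boundaries.

    All candidate matches are generated, then reduced with
    :func:`resolve_overlaps`, so "enalapril maleate" beats its substring
    "enalapril" when both are in the lexicon.
    """
    text = sentence.text
    candidates: list[EntityMention] = []
    for key, (term, etype, ace) in lexicon.items():
        pattern = rf"(?<![^\W_]){re.escape(term)}(?![^\W_])"
        for m in re.finditer(pattern, text, re.IGNORECASE):
            span = _token_span_for(tokens, m.start(), m.end())
            if span is None:
                continue
            candidates.append(
                EntityMention(
                    pmid=sentence.pmid,
                    sentence_index=sentence.index,
                    surface=text[m.start():m.end()],
                    entity_type=etype,
                    start=m.start(),
                    end=m.end(),
                    token_span=span,
                    is_ace_inhibitor=ace,
                    source="GAZETTEER",
                )
            )
    return resolve_overlaps(candidates)


def resolve_overlaps(mentions: Iterable[EntityMention]) -> list[EntityMention]:
    """Reduce overlapping mentions of one sentence to a non-overlapping set.

    Longer span wins; ties go to the leftmost start, then to the type order
    CHEMICAL < GENE_PROTEIN < DISEASE. The result is sorted by start and is
    invariant to input order.
    """
    ranked = sorted(
        mentions,
        key=lambda m: (-m.length, m.start, _TYPE_ORDER[m.entity_type],
                       m.surface.casefold()),
    )
    kept: list[EntityMention] = []
    for m in ranked:
        if all(m.end <= k.start or m.start >= k.end for k in kept):
            kept.append(m)
    return sorted(kept, key=lambda m: m.start)


_EXTERNAL_COLUMNS = ("pmid", "sentence_index", "start", "end", "entity_type", "surface")


def import_external_mentions(
    source: IO[str],
    sentences: Mapping[tuple[str, int], Sentence],
    ace_surfaces: Iterable[str] = (),
) -> list[EntityMention]:
    """Import external (e.g. neural) NER output from TSV.

    Columns: pmid, sentence_index, start, end, entity_type, surface.
    Rows whose surface does not equal the referenced sentence slice, whose
    offsets fall outside the sentence, or whose type is unknown are dropped
    with a logged diagnostic; valid rows become mentions with token spans
    recomputed from the sentence.
    """
    ace = {s.casefold() for s in ace_surfaces}
    reader = csv.DictReader(source, delimiter="\t")
    mentions: list[EntityMention] = []
    for i, row in enumerate(reader):
        try:
            etype = EntityType(row["entity_type"])
            start, end = int(row["start"]), int(row["end"])
            key = (row["pmid"], int(row["sentence_index"]))
        except (ValueError, KeyError):
            logger.warning("external NER row %d rejected: bad fields %r", i, row)
            continue
        sent = sentences.get(key)
        if sent is None:
            logger.warning("external NER row %d rejected: unknown sentence %s", i, key)
            continue
        if not (0 <= start < end <= len(sent.text)) or sent.text[start:end] != row["surface"]:
            logger.warning(
                "external NER row %d rejected: surface mismatch at %s[%d:%d]",
                i, key, start, end,
            )
            continue
        tokens = tokenize(sent)
        span = _token_span_for(tokens, start, end)
        if span is None:
            logger.warning("external NER row %d rejected: no covered tokens", i)
            continue
        mentions.append(
            EntityMention(
                pmid=sent.pmid, sentence_index=sent.index,
                surface=row["surface"], entity_type=etype,
                start=start, end=end, token_span=span,
                is_ace_inhibitor=row["surface"].casefold() in ace,
                source="EXTERNAL",
            )
        )
    return mentions


def export_mentions(mentions: Iterable[EntityMention], stream: IO[str]) -> None:
    """Write mentions in the external-NER TSV dialect (round-trips with import)."""
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(_EXTERNAL_COLUMNS)
    for m in mentions:
        writer.writerow(
            [m.pmid, m.sentence_index, m.start, m.end, m.entity_type.value, m.surface]
        )
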