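"""Entity normalization against offline mapping tables.

Chemical mentions map to PubChem compound identifiers, gene/protein
mentions to UniProt accessions, disease mentions to Human Disease Ontology
terms. The tested path is a pure, case-folded exact lookup in TSV-backed
tables — fuzzy matching is deliberately excluded to keep normalization
auditable (short ambiguous abbreviations are the dominant error source in
this kind of pipeline). Where several organisms share a protein surface,
the human entry wins.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from enum import Enum
from typing import IO, Iterable, Sequence

from .extraction import CandidateAssociation
from .ner import EntityMention, EntityType

logger = logging.getLogger(__name__)

__all__ = [
    "Namespace",
    "NormalizedEntity",
    "MappingTable",
    "AnnotatedCandidate",
    "load_mapping_tables",
    "normalize_mention",
    "annotate_candidates",
]


class Namespace(str, Enum):
    PUBCHEM_CID = "PUBCHEM_CID"
    UNIPROT_AC = "UNIPROT_AC"
    DOID = "DOID"


TYPE_TO_NAMESPACE = {
    EntityType.CHEMICAL: Namespace.PUBCHEM_CID,
    EntityType.GENE_PROTEIN: Namespace.UNIPROT_AC,
    EntityType.DISEASE: Namespace.DOID,
}

_HUMAN = ("human", "homo sapiens", "9606")


@dataclass(frozen=True)
class NormalizedEntity:
    surface: str
    namespace: Namespace
    identifier: str  # empty iff UNMAPPED
    organism: str | None = None

    @property
    def status(self) -> str:
        return "NORMALIZED" if self.identifier else "UNMAPPED"


class MappingTable:
    """Per-namespace case-folded surface → (identifier, organism) maps."""

    def __init__(self):
        self._maps: dict[Namespace, dict[str, tuple[str, str | None]]] = {
            ns: {} for ns in Namespace
        }

    def add(
        self, surface: str, namespace: Namespace, identifier: str,
        organism: str | None = None,
    ) -> None:
        ns_map = self._maps[Namespace(namespace)]
        key = surface.casefold()
        if key in ns_map:
            prior_id, prior_org = ns_map[key]
            new_human = (organism or "").casefold() in _HUMAN
            old_human = (prior_org or "").casefold() in _HUMAN
            if new_human and not old_human:
                ns_map[key] = (identifier, organism)
            else:
                logger.warning(
                    "duplicate surface %r in %s: keeping %s, ignoring %s",
                    surface, namespace, prior_id, identifier,
                )
            return
        ns_map[key] = (identifier, organism)

    def lookup(self, surface: str, namespace: Namespace) -> tuple[str, str | None] | None:
        return self._maps[Namespace(namespace)].get(surface.casefold())

    def __len__(self) -> int:
        return sum(len(m) for m in self._maps.values())

    def __eq__(self, other) -> bool:
        return isinstance(other, MappingTable) and self._maps == other._maps

    def to_tsv(self, stream: IO[str]) -> None:
        writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
        writer.writerow(["surface", "namespace", "identifier", "organism"])
        for ns in Namespace:
            for key in sorted(self._maps[ns]):
                ident, org = self._maps[ns][key]
                writer.writerow([key, ns.value, ident, org or ""])


def load_mapping_tables(sources: Iterable[IO[str]] | IO[str]) -> MappingTable:
    """Load one or more mapping TSVs (surface, namespace, identifier, organism).

    Duplicate surfaces within a namespace resolve human-first, then
    first-row-wins with a logged warning; an unknown namespace fails the load.
    """
    if hasattr(sources, "read"):
        sources = [sources]
    table = MappingTable()
    for src in sources:
        reader = csv.DictReader(src, delimiter="\t")
        for i, row in enumerate(reader):
            try:
                ns = Namespace(row["namespace"])
            except (ValueError, KeyError):
                raise ValueError(
                    f"row {i}: unknown namespace {row.get('namespace')!r}"
                ) from None
            table.add(row["surface"], ns, row["identifier"], row.get("organism") or None)
    return table


def normalize_mention(mention: EntityMention, tables: MappingTable) -> NormalizedEntity:
    """Exact case-folded lookup in the namespace matching the mention type."""
    ns = TYPE_TO_NAMESPACE[mention.entity_type]
    found = tables.lookup(mention.surface, ns)
    if found is None:
        return NormalizedEntity(surface=mention.surface, namespace=ns, identifier="")
    identifier, organism = found
    return NormalizedEntity(
        surface=mention.surface, namespace=ns, identifier=identifier, organism=organism
    )


@dataclass(frozen=True)
class AnnotatedCandidate:
    """A candidate association with the normalization outcome of both entities.

    Associations with fewer than two normalized entities are retained but
    flagged; fully-normalized aggregation excludes flagged ones.
    """

    candidate: CandidateAssociation
    norm_a: NormalizedEntity
    norm_b: NormalizedEntity

    @property
    def n_normalized(self) -> int:
        return int(bool(self.norm_a.identifier)) + int(bool(self.norm_b.identifier))

    @property
    def flagged(self) -> bool:
        return self.n_normalized < 2


def annotate_candidates(
    candidates: Sequence[CandidateAssociation], tables: MappingTable
) -> list[AnnotatedCandidate]:
    """Look up both entities of every candidate and attach the outcome."""
    return [
        AnnotatedCandidate(
            candidate=c,
            norm_a=normalize_mention(c.entity_a, tables),
            norm_b=normalize_mention(c.entity_b, tables),
        )
        for c in candidates
    ]
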