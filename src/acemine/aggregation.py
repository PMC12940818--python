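"""Corpus-level aggregation of sentence-level associations.

Sentence-level evidence is collapsed into unique associations keyed by the
normalized entity pair, semantic group, relation type and polarity (negated
and affirmative statements are never merged). Each supporting publication i
contributes one sentence score Ssent(i) — the maximum over its supporting
sentences, a swappable choice — and the confidence score is their sum:

    Sconf = sum_{i=1..Npub} Ssent(i)

Sconf grows with recurrence across independent sources and is deliberately
not normalized to [0, 1]: it ranks evidence, it is not a probability.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import IO, Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import PublicationRecord, StudyType, round_half_up
from .extraction import Polarity
from .normalization import AnnotatedCandidate
from .patterns import SemanticGroup, StrengthTier

__all__ = [
    "AggregatedAssociation",
    "aggregate",
    "strength_distribution",
    "relation_type_counts",
    "temporal_metrics",
    "polarity_score_summary",
    "write_aggregated_tsv",
    "read_aggregated_tsv",
]

_TIER_RANK = {StrengthTier.STRONG: 0, StrengthTier.MEDIUM: 1, StrengthTier.WEAK: 2}


@dataclass
class AggregatedAssociation:
    """A unique normalized association with its pooled evidence."""

    identifier_a: str
    identifier_b: str
    group: SemanticGroup
    relation_type: str
    polarity: Polarity
    pmids: set[str] = field(default_factory=set)
    per_pub_scores: dict[str, float] = field(default_factory=dict)
    best_strength: StrengthTier = StrengthTier.WEAK
    study_types: set[StudyType] = field(default_factory=set)
    years: set[int] = field(default_factory=set)
    n_mentions: int = 0

    @property
    def key(self) -> tuple:
        return (
            self.identifier_a, self.identifier_b, self.group.value,
            self.relation_type, self.polarity.value,
        )

    @property
    def n_pub(self) -> int:
        return len(self.pmids)

    @property
    def s_conf(self) -> float:
        return sum(self.per_pub_scores.values())

    @property
    def temporal_span(self) -> int:
        return max(self.years) - min(self.years) if self.years else 0


def _canonical_pair(
    id_a: str, id_b: str, group: SemanticGroup
) -> tuple[str, str]:
    # co-administration is symmetric: unordered key; mechanisms/effects are
    # directional drug -> entity
    if group is SemanticGroup.COADMINISTRATION and id_b < id_a:
        return id_b, id_a
    return id_a, id_b


def aggregate(
    annotated: Sequence[AnnotatedCandidate],
    records: Mapping[str, PublicationRecord] | Iterable[PublicationRecord] = (),
    per_pub_score: Callable[[Sequence[float]], float] = max,
) -> list[AggregatedAssociation]:
    """Collapse fully-normalized candidates into unique associations.

    Flagged candidates (fewer than two normalized entities) are excluded.
    ``per_pub_score`` reduces the scores a single publication contributes to
    one key into Ssent(i); the default takes the maximum (``sum`` is the
    alternative reading). Years and study types are unioned from the
    supporting publication records when given.
    """
    if not isinstance(records, Mapping):
        records = {r.pmid: r for r in records}

    per_key_pub_scores: dict[tuple, dict[str, list[float]]] = {}
    out: dict[tuple, AggregatedAssociation] = {}
    for ann in annotated:
        if ann.flagged:
            continue
        c = ann.candidate
        id_a, id_b = _canonical_pair(ann.norm_a.identifier, ann.norm_b.identifier, c.group)
        key = (id_a, id_b, c.group.value, c.relation_type, c.polarity.value)
        agg = out.get(key)
        if agg is None:
            agg = AggregatedAssociation(
                identifier_a=id_a, identifier_b=id_b, group=c.group,
                relation_type=c.relation_type, polarity=c.polarity,
                best_strength=c.strength,
            )
            out[key] = agg
            per_key_pub_scores[key] = {}
        agg.pmids.add(c.pmid)
        agg.n_mentions += 1
        per_key_pub_scores[key].setdefault(c.pmid, []).append(c.s_sent)
        if _TIER_RANK[c.strength] < _TIER_RANK[agg.best_strength]:
            agg.best_strength = c.strength
        rec = records.get(c.pmid)
        if rec is not None:
            agg.years.add(rec.year)
            agg.study_types |= rec.study_types

    for key, agg in out.items():
        agg.per_pub_scores = {
            pmid: per_pub_score(scores)
            for pmid, scores in sorted(per_key_pub_scores[key].items())
        }
    return sorted(out.values(), key=lambda a: a.key)


def strength_distribution(aggregated: Sequence[AggregatedAssociation]) -> pd.DataFrame:
    """Counts of aggregated associations per (group, strongest supporting tier)."""
    rows = []
    for group in SemanticGroup:
        for tier in StrengthTier:
            n = sum(
                1 for a in aggregated
                if a.group is group and a.best_strength is tier
            )
            if n:
                rows.append(
                    {"group": group.value, "best_strength": tier.value, "n": n}
                )
    return pd.DataFrame(rows, columns=["group", "best_strength", "n"])


def relation_type_counts(
    aggregated: Sequence[AggregatedAssociation], top_n: int | None = 20
) -> pd.DataFrame:
    """Ranked (group, relation_type, count) table, descending, ties by name."""
    counts: dict[tuple[str, str], int] = {}
    for a in aggregated:
        counts[(a.group.value, a.relation_type)] = (
            counts.get((a.group.value, a.relation_type), 0) + 1
        )
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
    if top_n is not None:
        rows = rows[:top_n]
    return pd.DataFrame(
        [{"group": g, "relation_type": r, "n": n} for (g, r), n in rows],
        columns=["group", "relation_type", "n"],
    )


def temporal_metrics(
    aggregated: Sequence[AggregatedAssociation],
) -> pd.DataFrame:
    """Cohort comparison: in vitro-only vs in vivo-or-clinical associations.

    An association is in the in vitro-only cohort when every supporting
    study type is IN_VITRO; otherwise it is in the in vivo-or-clinical
    cohort. Per cohort: number of associations, mean temporal span
    (max year - min year over supporting publications), association
    mentions per supporting publication, unique associations per supporting
    publication, and mean number of supporting publications. Associations
    with no recorded year are excluded from the span mean (their count is
    reported).
    """
    cohorts = {
        "in_vitro_only": [
            a for a in aggregated
            if a.study_types and a.study_types <= {StudyType.IN_VITRO}
        ],
        "in_vivo_or_clinical": [
            a for a in aggregated
            if a.study_types - {StudyType.IN_VITRO}
        ],
    }
    rows = []
    for name, members in cohorts.items():
        with_years = [a for a in members if a.years]
        pubs = set().union(*(a.pmids for a in members)) if members else set()
        rows.append(
            {
                "cohort": name,
                "n_associations": len(members),
                "n_missing_year": len(members) - len(with_years),
                "mean_span_years": (
                    round_half_up(
                        float(np.mean([a.temporal_span for a in with_years]))
                    ) if with_years else float("nan")
                ),
                "mentions_per_publication": (
                    round_half_up(sum(a.n_mentions for a in members) / len(pubs))
                    if pubs else float("nan")
                ),
                "unique_associations_per_publication": (
                    round_half_up(len(members) / len(pubs)) if pubs else float("nan")
                ),
                "mean_n_pub": (
                    round_half_up(float(np.mean([a.n_pub for a in members])))
                    if members else float("nan")
                ),
            }
        )
    return pd.DataFrame(rows)


def polarity_score_summary(
    aggregated: Sequence[AggregatedAssociation],
) -> pd.DataFrame:
    """Five-number summary (min, q1, median, q3, max) of Sconf per polarity."""
    rows = []
    for pol in Polarity:
        scores = np.array([a.s_conf for a in aggregated if a.polarity is pol])
        if scores.size == 0:
            continue
        q1, med, q3 = np.percentile(scores, [25, 50, 75])
        rows.append(
            {
                "polarity": pol.value,
                "n": int(scores.size),
                "min": float(scores.min()),
                "q1": float(q1),
                "median": float(med),
                "q3": float(q3),
                "max": float(scores.max()),
            }
        )
    return pd.DataFrame(rows)


_TSV_COLUMNS = (
    "identifier_a", "identifier_b", "group", "relation_type", "polarity",
    "n_pub", "s_conf", "best_strength", "pmids", "study_types", "years",
    "n_mentions",
)


def write_aggregated_tsv(
    aggregated: Iterable[AggregatedAssociation], stream: IO[str]
) -> None:
    writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
    writer.writerow(_TSV_COLUMNS)
    for a in aggregated:
        writer.writerow(
            [
                a.identifier_a, a.identifier_b, a.group.value, a.relation_type,
                a.polarity.value, a.n_pub, repr(a.s_conf), a.best_strength.value,
                ";".join(sorted(a.pmids)),
                ";".join(sorted(s.value for s in a.study_types)),
                ";".join(str(y) for y in sorted(a.years)),
                a.n_mentions,
            ]
        )


def read_aggregated_tsv(stream: IO[str]) -> list[AggregatedAssociation]:
    """Re-load an aggregated TSV; per-publication scores collapse to Sconf/Npub
    placeholders preserving the exact Sconf total."""
    out = []
    for row in csv.DictReader(stream, delimiter="\t"):
        pmids = set(filter(None, row["pmids"].split(";")))
        s_conf = float(row["s_conf"])
        n = max(len(pmids), 1)
        out.append(
            AggregatedAssociation(
                identifier_a=row["identifier_a"],
                identifier_b=row["identifier_b"],
                group=SemanticGroup(row["group"]),
                relation_type=row["relation_type"],
                polarity=Polarity(row["polarity"]),
                pmids=pmids,
                per_pub_scores={p: s_conf / n for p in (pmids or {"?"})},
                best_strength=StrengthTier(row["best_strength"]),
                study_types={
                    StudyType(s) for s in filter(None, row["study_types"].split(";"))
                },
                years={int(y) for y in filter(None, row["years"].split(";"))},
                n_mentions=int(row["n_mentions"]),
            )
        )
    return out
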