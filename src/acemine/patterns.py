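"""The curated pattern inventory: loading, matching, structure statistics.

Patterns are lexical trigger phrases organized in three semantic groups —
mechanisms of action (drug–protein), pharmacological effects (drug–disease)
and co-administration (drug–drug) — each split into relation subgroups and
annotated with an indicative strength tier that maps to an integer weight:
strong = 3, medium = 2, weak = 1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from enum import Enum
from typing import IO, Iterable, Sequence

import pandas as pd

from .corpus import round_half_up
from .textproc import Token, tokenize

__all__ = [
    "SemanticGroup",
    "StrengthTier",
    "STRENGTH_WEIGHTS",
    "PatternPhrase",
    "PatternInventory",
    "PatternHit",
    "InventoryError",
    "load_inventory",
    "match_patterns",
    "inventory_stats",
]


class SemanticGroup(str, Enum):
    MECHANISMS = "MECHANISMS"
    EFFECTS = "EFFECTS"
    COADMINISTRATION = "COADMINISTRATION"


class StrengthTier(str, Enum):
    STRONG = "STRONG"
    MEDIUM = "MEDIUM"
    WEAK = "WEAK"


STRENGTH_WEIGHTS = {
    StrengthTier.STRONG: 3,
    StrengthTier.MEDIUM: 2,
    StrengthTier.WEAK: 1,
}


class InventoryError(ValueError):
    """Raised when the pattern inventory fails validation; names the row."""


@dataclass(frozen=True)
class PatternPhrase:
    """One lexical trigger with its group, relation subgroup and strength."""

    pattern_id: str
    group: SemanticGroup
    relation_type: str
    strength: StrengthTier
    phrase: str
    tokens: tuple[str, ...]

    @property
    def weight(self) -> int:
        return STRENGTH_WEIGHTS[self.strength]


@dataclass(frozen=True)
class PatternHit:
    """A pattern matched over a contiguous token span of one sentence."""

    pattern: PatternPhrase
    token_span: tuple[int, int]  # inclusive [first, last]

    @property
    def pattern_id(self) -> str:
        return self.pattern.pattern_id


class PatternInventory:
    def __init__(self, phrases: Iterable[PatternPhrase]):
        self.phrases: list[PatternPhrase] = list(phrases)
        seen: set[tuple[SemanticGroup, str]] = set()
        for p in self.phrases:
            key = (p.group, p.phrase.casefold())
            if key in seen:
                raise InventoryError(f"duplicate (group, phrase): {key}")
            seen.add(key)
        self.by_group: dict[SemanticGroup, list[PatternPhrase]] = {}
        for p in self.phrases:
            self.by_group.setdefault(p.group, []).append(p)

    def __len__(self) -> int:
        return len(self.phrases)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PatternInventory)
            and sorted(self.phrases, key=lambda p: p.pattern_id)
            == sorted(other.phrases, key=lambda p: p.pattern_id)
        )

    def to_tsv(self, stream: IO[str]) -> None:
        writer = csv.writer(stream, delimiter="\t", lineterminator="\n")
        writer.writerow(["pattern_id", "group", "relation_type", "strength", "phrase"])
        for p in self.phrases:
            writer.writerow(
                [p.pattern_id, p.group.value, p.relation_type,
                 p.strength.value, p.phrase]
            )


def load_inventory(source: IO[str]) -> PatternInventory:
    """Load and validate the inventory TSV.

    Columns: pattern_id, group, relation_type, strength, phrase. Phrases are
    lower-cased and tokenized with the pipeline tokenizer. Unknown groups or
    strengths and duplicate (group, phrase) pairs fail the load with the
    offending row named.
    """
    reader = csv.DictReader(source, delimiter="\t")
    phrases = []
    for i, row in enumerate(reader):
        try:
            group = SemanticGroup(row["group"].strip().upper())
        except (ValueError, AttributeError, KeyError):
            raise InventoryError(f"row {i}: unknown group {row.get('group')!r}") from None
        try:
            strength = StrengthTier(row["strength"].strip().upper())
        except (ValueError, AttributeError, KeyError):
            raise InventoryError(
                f"row {i}: unknown strength {row.get('strength')!r}"
            ) from None
        phrase = row["phrase"].strip().lower()
        if not phrase:
            raise InventoryError(f"row {i}: empty phrase")
        phrases.append(
            PatternPhrase(
                pattern_id=row["pattern_id"].strip(),
                group=group,
                relation_type=row["relation_type"].strip(),
                strength=strength,
                phrase=phrase,
                tokens=tuple(t.text for t in tokenize(phrase)),
            )
        )
    return PatternInventory(phrases)


def match_patterns(
    tokens: Sequence[Token], inventory: PatternInventory
) -> list[PatternHit]:
    """Find every pattern whose token sequence occurs contiguously.

    Matching is case-insensitive over token texts. Overlapping hits of
    different patterns are all reported; when two patterns of one group
    match the identical span, the longer phrase (more characters) wins.
    Output order is (span start, span end, pattern_id), independent of
    inventory row order.
    """
    lowered = [t.text.casefold() for t in tokens]
    # index patterns by first token for a linear scan
    by_first: dict[str, list[PatternPhrase]] = {}
    for p in inventory.phrases:
        if p.tokens:
            by_first.setdefault(p.tokens[0].casefold(), []).append(p)

    hits: dict[tuple[SemanticGroup, int, int], PatternHit] = {}
    for i, tok in enumerate(lowered):
        for p in by_first.get(tok, ()):
            n = len(p.tokens)
            if i + n > len(lowered):
                continue
            if all(lowered[i + j] == p.tokens[j].casefold() for j in range(n)):
                key = (p.group, i, i + n - 1)
                prior = hits.get(key)
                if prior is None or len(p.phrase) > len(prior.pattern.phrase) or (
                    len(p.phrase) == len(prior.pattern.phrase)
                    and p.pattern_id < prior.pattern.pattern_id
                ):
                    hits[key] = PatternHit(pattern=p, token_span=(i, i + n - 1))
    return sorted(
        hits.values(),
        key=lambda h: (h.token_span[0], h.token_span[1], h.pattern.pattern_id),
    )


def inventory_stats(inventory: PatternInventory) -> pd.DataFrame:
    """Per-group structural statistics of the inventory.

    For each semantic group: number of relation subgroups, number of
    phrases, mean phrases per subgroup (half-up, 2 decimals), median phrases
    per subgroup (middle value; the lower of the two middle values for an
    even number of subgroups), subgroup-level strength-tier counts (a
    subgroup is counted under the strongest tier among its phrases) and
    phrase-level tier counts.
    """
    rows = []
    for group in SemanticGroup:
        phrases = inventory.by_group.get(group, [])
        if not phrases:
            continue
        per_sub: dict[str, list[PatternPhrase]] = {}
        for p in phrases:
            per_sub.setdefault(p.relation_type, []).append(p)
        counts = sorted(len(v) for v in per_sub.values())
        n_sg, n_pt = len(per_sub), len(phrases)
        median = counts[(n_sg - 1) // 2]  # lower-of-two convention
        tier_order = [StrengthTier.STRONG, StrengthTier.MEDIUM, StrengthTier.WEAK]
        sub_tiers = {t: 0 for t in tier_order}
        for members in per_sub.values():
            best = min(members, key=lambda p: tier_order.index(p.strength))
            sub_tiers[best.strength] += 1
        phrase_tiers = {t: sum(1 for p in phrases if p.strength is t) for t in tier_order}
        rows.append(
            {
                "group": group.value,
                "n_subgroups": n_sg,
                "n_phrases": n_pt,
                "mean_phrases_per_subgroup": round_half_up(n_pt / n_sg),
                "median_phrases_per_subgroup": median,
                "n_strong_subgroups": sub_tiers[StrengthTier.STRONG],
                "n_medium_subgroups": sub_tiers[StrengthTier.MEDIUM],
                "n_weak_subgroups": sub_tiers[StrengthTier.WEAK],
                "n_strong_phrases": phrase_tiers[StrengthTier.STRONG],
                "n_medium_phrases": phrase_tiers[StrengthTier.MEDIUM],
                "n_weak_phrases": phrase_tiers[StrengthTier.WEAK],
            }
        )
    return pd.DataFrame(rows)
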