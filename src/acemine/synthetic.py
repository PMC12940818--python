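"""Synthetic abstract corpus with planted, analytically scored associations.

The generator emulates the statistical structure the pipeline is built
for — abstracts whose sentences place a drug, a second entity and a pattern
phrase at controlled token distances, with negation cues planted inside or
outside the 5-token window, study-type markers, publication years and
distractor sentences — while emitting the matching lexicons, mapping
tables and pattern rows so that every planted surface is recognizable and
normalizable by construction (generator closure).

Templates are token-calibrated: filler tokens are inserted to hit each
target distance d exactly, so the expected sentence score wp/(1+d) and the
expected confidence score (its sum over supporting publications) are
analytic, not empirical. Linguistic realism is a non-goal.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .corpus import DrugLexicon, PublicationRecord, StudyType
from .extraction import Polarity, score_sentence
from .ner import EntityType, TypedLexicon
from .normalization import MappingTable, Namespace
from .patterns import (
    PatternInventory,
    PatternPhrase,
    SemanticGroup,
    StrengthTier,
    STRENGTH_WEIGHTS,
)
from .textproc import tokenize

__all__ = [
    "PlantedAssociation",
    "SyntheticSpec",
    "GroundTruthEntry",
    "GeneratedCorpus",
    "GenerationError",
    "default_spec",
    "generate_corpus",
    "evaluate_recovery",
    "RecoveryReport",
]


class GenerationError(ValueError):
    """Raised when a planted association cannot be realized; names it."""


# --- generator vocabularies -------------------------------------------------

ACE_DRUGS = ("captopril", "enalapril", "lisinopril", "ramipril", "perindopril")
OTHER_CHEMICALS = ("hydrochlorothiazide", "temozolomide", "empagliflozin", "amlodipine")
PROTEINS = ("ACE2", "MMP-2", "renin", "BDNF", "neprilysin")
DISEASES = ("hypertension", "nephropathy", "fibrosis", "depression", "proteinuria")

#: Filler vocabulary: disjoint from every pattern token, cue token and
#: entity surface, so fillers can never complete a pattern or a cue.
FILLERS = (
    "samples", "baseline", "cohort", "values", "observed", "levels",
    "assay", "profiles", "subjects", "during", "analysis", "protocol",
)

_GEN_PATTERNS = (
    ("GM1", SemanticGroup.MECHANISMS, "Inhibit", StrengthTier.STRONG, "inhibits"),
    ("GM2", SemanticGroup.MECHANISMS, "Modulate", StrengthTier.MEDIUM, "modulates activity of"),
    ("GM3", SemanticGroup.MECHANISMS, "Linked_to", StrengthTier.WEAK, "is linked to"),
    ("GE1", SemanticGroup.EFFECTS, "Treatment", StrengthTier.STRONG, "is effective in the treatment of"),
    ("GE2", SemanticGroup.EFFECTS, "Improve", StrengthTier.MEDIUM, "improves"),
    ("GE3", SemanticGroup.EFFECTS, "Associated_with", StrengthTier.WEAK, "is associated with"),
    ("GC1", SemanticGroup.COADMINISTRATION, "Coadministered_with", StrengthTier.STRONG, "in combination with"),
    ("GC2", SemanticGroup.COADMINISTRATION, "Cooccurrence", StrengthTier.MEDIUM, "was given together with"),
    ("GC3", SemanticGroup.COADMINISTRATION, "Added_to", StrengthTier.WEAK, "alongside"),
)


@dataclass(frozen=True)
class PlantedAssociation:
    """One association to be planted, with its analytic score ingredients."""

    group: SemanticGroup
    relation_type: str
    strength: StrengthTier
    drug: str            # chemical surface (entity_a)
    entity: str          # second-entity surface (type implied by group)
    d: int               # target total token distance (d_a + d_b)
    negated: bool = False
    n_pubs: int = 1

    @property
    def wp(self) -> int:
        return STRENGTH_WEIGHTS[self.strength]

    @property
    def expected_s_sent(self) -> float:
        return score_sentence(self.wp, self.d)

    @property
    def polarity(self) -> Polarity:
        return Polarity.NEGATIVE if self.negated else Polarity.POSITIVE


@dataclass
class SyntheticSpec:
    """Study conditions for one generated corpus."""

    n_publications: int = 200
    year_range: tuple[int, int] = (1976, 2025)
    study_type_mix: dict[StudyType, float] = field(
        default_factory=lambda: {
            StudyType.IN_VITRO: 0.25,
            StudyType.IN_VIVO: 0.45,
            StudyType.CLINICAL: 0.35,
        }
    )
    planted: list[PlantedAssociation] = field(default_factory=list)
    distractor_rate: float = 1.0  # expected distractor sentences per abstract
    seed: int = 0


@dataclass(frozen=True)
class GroundTruthEntry:
    """Expected aggregation outcome of one planted association."""

    key: tuple  # (identifier_a, identifier_b, group, relation_type, polarity)
    group: SemanticGroup
    polarity: Polarity
    expected_s_sent: float
    expected_s_conf: float
    involves_ace: bool
    pmids: tuple[str, ...]
    years: tuple[int, ...]
    study_types: frozenset[StudyType]


@dataclass
class GeneratedCorpus:
    """Everything the pipeline needs, plus the planted truth."""

    records: list[PublicationRecord]
    drug_lexicon: DrugLexicon
    entity_lexicon: TypedLexicon
    mapping_table: MappingTable
    inventory: PatternInventory
    truth: list[GroundTruthEntry]
    identifiers: dict[str, str]  # case-folded surface -> identifier


def default_spec(n_publications: int = 200, seed: int = 0) -> SyntheticSpec:
    """A corpus spanning all groups, tiers, polarities and distances 0-6.

    Planted associations cycle through the generator pattern inventory
    (3 groups x 3 tiers), alternate polarity for mechanisms/effects, and
    sweep target distances 0..6 with 1-4 supporting publications each.
    Roughly 30% of mechanism/effect triples use a non-ACE chemical so the
    ACE filter has something to remove.
    """
    rng = random.Random(seed)
    planted: list[PlantedAssociation] = []
    pairs_seen: set[tuple] = set()
    budget = n_publications  # supporting publications available for planting
    i = 0
    while len(planted) < 36 and budget >= 4 and i < 400:
        pid, group, rtype, tier, _ = _GEN_PATTERNS[i % len(_GEN_PATTERNS)]
        d = i % 7
        negated = group is not SemanticGroup.COADMINISTRATION and i % 3 == 0
        use_ace = not (group is not SemanticGroup.COADMINISTRATION and i % 10 in (3, 6, 9))
        drug = (ACE_DRUGS if use_ace else OTHER_CHEMICALS)[i % (5 if use_ace else 4)]
        if group is SemanticGroup.MECHANISMS:
            entity = PROTEINS[(i // 2) % len(PROTEINS)]
        elif group is SemanticGroup.EFFECTS:
            entity = DISEASES[(i // 2) % len(DISEASES)]
        else:
            entity = OTHER_CHEMICALS[(i // 2) % len(OTHER_CHEMICALS)]
            if entity.casefold() == drug.casefold():
                i += 1
                continue
        key = (group, rtype, drug.casefold(), entity.casefold(), negated)
        i += 1
        if key in pairs_seen:
            continue
        pairs_seen.add(key)
        n_pubs = rng.randint(1, 4)
        budget -= n_pubs
        planted.append(
            PlantedAssociation(
                group=group, relation_type=rtype, strength=tier,
                drug=drug, entity=entity, d=d, negated=negated,
                n_pubs=n_pubs,
            )
        )
    return SyntheticSpec(n_publications=n_publications, planted=planted, seed=seed)


def _assign_identifiers() -> dict[str, str]:
    ids: dict[str, str] = {}
    for i, name in enumerate(ACE_DRUGS + OTHER_CHEMICALS):
        ids[name.casefold()] = f"CID:{44093 + i}"
    for i, name in enumerate(PROTEINS):
        ids[name.casefold()] = f"P{12821 + i}"
    for i, name in enumerate(DISEASES):
        ids[name.casefold()] = f"DOID:{10763 + i}"
    return ids


def _realize_sentence(
    assoc: PlantedAssociation,
    pattern_tokens: Sequence[str],
    rng: random.Random,
) -> str:
    """Build one sentence realizing the association at exactly distance d."""
    d_a = assoc.d // 2
    d_b = assoc.d - d_a
    fill = lambda n: [rng.choice(FILLERS) for _ in range(n)]
    before = fill(d_a)
    if assoc.negated:
        if d_a >= 1:
            before[-1] = "not"  # cue starts 1 token before the pattern
        else:
            pass  # cue goes in front of the drug instead (still in window)
    drug_tokens = [t.text for t in tokenize(assoc.drug)]
    if assoc.negated and d_a == 0 and len(drug_tokens) + 1 > 5:
        raise GenerationError(
            f"cannot place negation cue in window for {assoc}: "
            f"drug name {assoc.drug!r} too long at distance 0"
        )
    toks: list[str] = []
    if assoc.negated and d_a == 0:
        toks.append("not")
    toks.extend(drug_tokens)
    toks.extend(before)
    toks.extend(pattern_tokens)
    toks.extend(fill(d_b))
    toks.append(assoc.entity)
    text = " ".join(toks) + "."
    return text[0].upper() + text[1:]


def _distractor_sentence(rng: random.Random) -> str:
    kind = rng.randrange(3)
    fill = [rng.choice(FILLERS) for _ in range(rng.randint(2, 5))]
    if kind == 0:  # drug only
        toks = [rng.choice(ACE_DRUGS)] + fill
    elif kind == 1:  # drug + disease, no pattern
        toks = [rng.choice(ACE_DRUGS)] + fill + [rng.choice(DISEASES)]
    else:  # fillers only
        toks = fill
    text = " ".join(toks) + "."
    return text[0].upper() + text[1:]


def _draw_study_types(
    rng: random.Random, mix: dict[StudyType, float]
) -> set[StudyType]:
    out = {st for st in StudyType if rng.random() < mix.get(st, 0.0)}
    return out or {StudyType.IN_VIVO}


def _markers_for(study_types: set[StudyType]) -> tuple[set[str], set[str]]:
    mesh, pubtypes = set(), {"Journal Article"}
    if StudyType.IN_VITRO in study_types:
        mesh.add("In Vitro Techniques")
    if StudyType.IN_VIVO in study_types:
        mesh.add("Animals")
    if StudyType.CLINICAL in study_types:
        pubtypes.add("Randomized Controlled Trial")
    return mesh, pubtypes


def generate_corpus(spec: SyntheticSpec) -> GeneratedCorpus:
    """Generate a corpus and its side tables from a spec, deterministically.

    Each planted association receives ``n_pubs`` dedicated publications,
    each holding one calibrated sentence plus a random number of distractor
    sentences; remaining publications (up to ``n_publications``) are pure
    distractors. The same spec and seed always produce identical output.
    """
    rng = random.Random(spec.seed)
    inventory = PatternInventory(
        [
            PatternPhrase(
                pattern_id=pid, group=group, relation_type=rtype,
                strength=tier, phrase=phrase,
                tokens=tuple(t.text for t in tokenize(phrase)),
            )
            for pid, group, rtype, tier, phrase in _GEN_PATTERNS
        ]
    )
    by_key = {(p.group, p.relation_type): p for p in inventory.phrases}
    ids = _assign_identifiers()

    n_planted_pubs = sum(a.n_pubs for a in spec.planted)
    if n_planted_pubs > spec.n_publications:
        raise GenerationError(
            f"{n_planted_pubs} supporting publications exceed "
            f"n_publications={spec.n_publications}"
        )

    records: list[PublicationRecord] = []
    truth: list[GroundTruthEntry] = []
    counter = 0

    def new_pub(sentences: list[str]) -> PublicationRecord:
        nonlocal counter
        counter += 1
        pmid = f"{90000000 + counter}"
        study_types = _draw_study_types(rng, spec.study_type_mix)
        mesh, pubtypes = _markers_for(study_types)
        n_distract = min(2, max(0, int(rng.random() < spec.distractor_rate)
                                + int(rng.random() < spec.distractor_rate / 2)))
        body = list(sentences) + [_distractor_sentence(rng) for _ in range(n_distract)]
        rec = PublicationRecord(
            pmid=pmid,
            title=f"Report {counter} on cardiovascular pharmacology.",
            abstract=" ".join(body),
            year=rng.randint(*spec.year_range),
            journal="J Synth Pharmacol",
            publication_types=pubtypes,
            mesh_terms=mesh,
            study_types=study_types,
        )
        rec.drug_labels = set()  # labelled later by the pipeline
        records.append(rec)
        return rec

    for assoc in spec.planted:
        pattern = by_key.get((assoc.group, assoc.relation_type))
        if pattern is None:
            raise GenerationError(
                f"no generator pattern for ({assoc.group}, {assoc.relation_type})"
            )
        if pattern.strength is not assoc.strength:
            raise GenerationError(
                f"strength mismatch for {assoc}: pattern is {pattern.strength}"
            )
        pubs = [
            new_pub([_realize_sentence(assoc, pattern.tokens, rng)])
            for _ in range(assoc.n_pubs)
        ]
        id_a = ids[assoc.drug.casefold()]
        id_b = ids[assoc.entity.casefold()]
        if assoc.group is SemanticGroup.COADMINISTRATION and id_b < id_a:
            id_a, id_b = id_b, id_a
        truth.append(
            GroundTruthEntry(
                key=(id_a, id_b, assoc.group.value, assoc.relation_type,
                     assoc.polarity.value),
                group=assoc.group,
                polarity=assoc.polarity,
                expected_s_sent=assoc.expected_s_sent,
                expected_s_conf=assoc.n_pubs * assoc.expected_s_sent,
                involves_ace=(
                    assoc.drug in ACE_DRUGS or assoc.entity in ACE_DRUGS
                ),
                pmids=tuple(p.pmid for p in pubs),
                years=tuple(p.year for p in pubs),
                study_types=frozenset().union(*(p.study_types for p in pubs)),
            )
        )

    while counter < spec.n_publications:
        new_pub([])

    drug_lexicon = DrugLexicon({name: set() for name in ACE_DRUGS})
    entity_lexicon = TypedLexicon(
        [(n, EntityType.CHEMICAL, True) for n in ACE_DRUGS]
        + [(n, EntityType.CHEMICAL, False) for n in OTHER_CHEMICALS]
        + [(n, EntityType.GENE_PROTEIN, False) for n in PROTEINS]
        + [(n, EntityType.DISEASE, False) for n in DISEASES]
    )
    table = MappingTable()
    for name in ACE_DRUGS + OTHER_CHEMICALS:
        table.add(name, Namespace.PUBCHEM_CID, ids[name.casefold()])
    for name in PROTEINS:
        table.add(name, Namespace.UNIPROT_AC, ids[name.casefold()], organism="human")
    for name in DISEASES:
        table.add(name, Namespace.DOID, ids[name.casefold()])

    return GeneratedCorpus(
        records=records,
        drug_lexicon=drug_lexicon,
        entity_lexicon=entity_lexicon,
        mapping_table=table,
        inventory=inventory,
        truth=truth,
        identifiers=ids,
    )


@dataclass
class RecoveryReport:
    precision: float | None  # None when nothing was recovered
    recall: float | None     # None when nothing was planted
    max_abs_score_error: float
    n_planted: int
    n_recovered: int
    by_group: pd.DataFrame = field(default_factory=pd.DataFrame)


def evaluate_recovery(
    aggregated,
    truth: Sequence[GroundTruthEntry],
    ace_only: bool = True,
) -> RecoveryReport:
    """Compare pipeline output with the planted ground truth.

    recall = planted keys recovered / planted keys; precision = recovered
    keys that were planted / recovered keys; the score error is the largest
    |Sconf - expected Sconf| over recovered planted keys. With ``ace_only``
    the expectation is restricted to planted associations involving an ACE
    inhibitor (matching the pipeline's ACE filter).
    """
    expected = {
        t.key: t for t in truth if (t.involves_ace or not ace_only)
    }
    recovered = {a.key: a for a in aggregated}
    tp = set(expected) & set(recovered)
    max_err = max(
        (abs(recovered[k].s_conf - expected[k].expected_s_conf) for k in tp),
        default=0.0,
    )
    rows = []
    for group in SemanticGroup:
        for pol in Polarity:
            exp_gp = {k for k, t in expected.items()
                      if t.group is group and t.polarity is pol}
            rec_gp = {k for k, a in recovered.items()
                      if a.group is group and a.polarity is pol}
            if not exp_gp and not rec_gp:
                continue
            rows.append(
                {
                    "group": group.value,
                    "polarity": pol.value,
                    "n_planted": len(exp_gp),
                    "n_recovered": len(rec_gp),
                    "recall": (len(exp_gp & rec_gp) / len(exp_gp)) if exp_gp else None,
                    "precision": (len(exp_gp & rec_gp) / len(rec_gp)) if rec_gp else None,
                }
            )
    return RecoveryReport(
        precision=(len(tp) / len(recovered)) if recovered else None,
        recall=(len(tp) / len(expected)) if expected else None,
        max_abs_score_error=max_err,
        n_planted=len(expected),
        n_recovered=len(recovered),
        by_group=pd.DataFrame(rows),
    )


def write_ground_truth_tsv(truth: Sequence[GroundTruthEntry], stream) -> None:
    stream.write(
        "identifier_a\tidentifier_b\tgroup\trelation_type\tpolarity\t"
        "expected_s_sent\texpected_s_conf\tinvolves_ace\tpmids\tyears\tstudy_types\n"
    )
    for t in truth:
        stream.write(
            "\t".join(
                [
                    *map(str, t.key),
                    repr(t.expected_s_sent),
                    repr(t.expected_s_conf),
                    str(int(t.involves_ace)),
                    ";".join(t.pmids),
                    ";".join(map(str, t.years)),
                    ";".join(sorted(s.value for s in t.study_types)),
                ]
            )
            + "\n"
        )
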