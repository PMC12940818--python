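"""Corpus construction: queries, record ingestion, study-type labelling.

Publication records carry a PMID, title/abstract text, year, journal,
publication types and MeSH terms. Study types (in vitro / in vivo /
clinical) are assigned from MeSH markers and publication types; a record
may belong to several categories. The tested ingestion path is a JSON-lines
fixture dialect; MEDLINE/PubMed XML is parsed with lxml; live E-utilities
retrieval is an optional extra that is never needed offline.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from enum import Enum
from typing import IO, Iterable, Mapping

import pandas as pd
from lxml import etree

logger = logging.getLogger(__name__)

__all__ = [
    "StudyType",
    "PublicationRecord",
    "DrugLexicon",
    "UnknownStudyTypeError",
    "CorpusParseError",
    "build_pubmed_queries",
    "parse_records",
    "write_jsonl",
    "classify_study_types",
    "label_drugs",
    "corpus_summary",
    "summary_from_counts",
    "round_half_up",
    "IN_VITRO_MESH",
    "IN_VIVO_MESH",
    "CLINICAL_PUBTYPES",
    "EXCLUDED_PUBTYPES",
]


class StudyType(str, Enum):
    IN_VITRO = "IN_VITRO"
    IN_VIVO = "IN_VIVO"
    CLINICAL = "CLINICAL"


IN_VITRO_MESH = ("Cells", "Cell Line", "In Vitro Techniques")
IN_VIVO_MESH = ("Animals",)
CLINICAL_PUBTYPES = (
    "Clinical Trial",
    "Controlled Clinical Trial",
    "Randomized Controlled Trial",
    "Multicenter Study",
)
EXCLUDED_PUBTYPES = (
    "Review", "Meta-Analysis", "Editorial", "Letter", "Comment", "News",
)


class UnknownStudyTypeError(ValueError):
    """Raised for a study-type tag outside {IN_VITRO, IN_VIVO, CLINICAL}."""


class CorpusParseError(ValueError):
    """Raised for a malformed record stream; names the offending record."""


@dataclass
class PublicationRecord:
    """One PubMed item with metadata and derived labels."""

    pmid: str
    title: str = ""
    abstract: str = ""
    year: int = 1900
    journal: str = ""
    publication_types: set[str] = field(default_factory=set)
    mesh_terms: set[str] = field(default_factory=set)
    drug_labels: set[str] = field(default_factory=set)
    study_types: set[StudyType] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.pmid:
            raise ValueError("pmid must be non-empty")
        if not 1900 <= int(self.year) <= 2100:
            raise ValueError(f"implausible year {self.year} for PMID {self.pmid}")
        self.study_types = {StudyType(s) for s in self.study_types}

    def to_dict(self) -> dict:
        return {
            "pmid": self.pmid,
            "title": self.title,
            "abstract": self.abstract,
            "year": self.year,
            "journal": self.journal,
            "publication_types": sorted(self.publication_types),
            "mesh_terms": sorted(self.mesh_terms),
            "drug_labels": sorted(self.drug_labels),
            "study_types": sorted(s.value for s in self.study_types),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "PublicationRecord":
        return cls(
            pmid=str(d["pmid"]),
            title=d.get("title", "") or "",
            abstract=d.get("abstract", "") or "",
            year=int(d.get("year", 1900)),
            journal=d.get("journal", "") or "",
            publication_types=set(d.get("publication_types", ())),
            mesh_terms=set(d.get("mesh_terms", ())),
            drug_labels=set(d.get("drug_labels", ())),
            study_types={StudyType(s) for s in d.get("study_types", ())},
        )


class DrugLexicon:
    """Canonical drug names with case-insensitive synonyms.

    No synonym may map to two canonical names; lookups are case-folded.
    """

    def __init__(self, entries: Mapping[str, Iterable[str]]):
        self.entries: dict[str, set[str]] = {
            canon: {s for s in syns} for canon, syns in entries.items()
        }
        self._surface_to_canonical: dict[str, str] = {}
        for canon, syns in self.entries.items():
            for surface in {canon, *syns}:
                key = surface.casefold()
                prior = self._surface_to_canonical.get(key)
                if prior is not None and prior != canon:
                    raise ValueError(
                        f"synonym {surface!r} maps to both {prior!r} and {canon!r}"
                    )
                self._surface_to_canonical[key] = canon

    @property
    def canonical_names(self) -> list[str]:
        return sorted(self.entries)

    def surfaces(self) -> list[str]:
        """All names and synonyms, unsorted case preserved."""
        out = []
        for canon, syns in self.entries.items():
            out.append(canon)
            out.extend(syns)
        return out

    def canonical_for(self, surface: str) -> str | None:
        return self._surface_to_canonical.get(surface.casefold())

    def __contains__(self, surface: str) -> bool:
        return surface.casefold() in self._surface_to_canonical

    def __len__(self) -> int:
        return len(self.entries)

    def __eq__(self, other) -> bool:
        return isinstance(other, DrugLexicon) and self.entries == other.entries

    @classmethod
    def from_tsv(cls, source: IO[str] | str) -> "DrugLexicon":
        """Load ``canonical<TAB>synonym`` rows (synonym may be empty)."""
        close = False
        if isinstance(source, str):
            source, close = open(source, encoding="utf-8"), True
        entries: dict[str, set[str]] = {}
        try:
            for line in source:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                canon = parts[0].strip()
                entries.setdefault(canon, set())
                if len(parts) > 1 and parts[1].strip() and parts[1].strip() != canon:
                    entries[canon].add(parts[1].strip())
        finally:
            if close:
                source.close()
        return cls(entries)

    def to_tsv(self, stream: IO[str]) -> None:
        for canon in sorted(self.entries):
            syns = sorted(self.entries[canon])
            if not syns:
                stream.write(f"{canon}\t\n")
            for syn in syns:
                stream.write(f"{canon}\t{syn}\n")


def _or_block(terms: list[str]) -> str:
    quoted = [f'"{t}"[Title/Abstract]' for t in terms]
    return "(" + " OR ".join(quoted) + ")"


def build_pubmed_queries(lexicon: DrugLexicon, study_type: StudyType | str) -> list[str]:
    """One PubMed query per drug for the given study-type category.

    Each query ORs the canonical name with its synonyms, ANDs the
    study-type block (cell-system MeSH for in vitro, "Animals" for in vivo,
    clinical publication types for clinical) and NOTs the exclusion block
    (reviews, meta-analyses, editorials, letters, comments, news).
    """
    try:
        study_type = StudyType(study_type)
    except ValueError:
        raise UnknownStudyTypeError(f"unknown study type {study_type!r}") from None

    if study_type is StudyType.IN_VITRO:
        block = "(" + " OR ".join(f'"{m}"[MeSH Terms]' for m in IN_VITRO_MESH) + ")"
    elif study_type is StudyType.IN_VIVO:
        block = "(" + " OR ".join(f'"{m}"[MeSH Terms]' for m in IN_VIVO_MESH) + ")"
    else:
        block = "(" + " OR ".join(
            f'"{p}"[Publication Type]' for p in CLINICAL_PUBTYPES
        ) + ")"
    exclusion = "(" + " OR ".join(
        f'"{p}"[Publication Type]' for p in EXCLUDED_PUBTYPES
    ) + ")"

    queries = []
    for canon in lexicon.canonical_names:
        terms = [canon, *sorted(lexicon.entries[canon])]
        queries.append(f"{_or_block(terms)} AND {block} NOT {exclusion}")
    return queries


# ---------------------------------------------------------------------------
# ingestion

def parse_records(source: IO, dialect: str = "JSONL_FIXTURE") -> list[PublicationRecord]:
    """Parse publication records from a stream.

    dialect ``JSONL_FIXTURE``: one JSON object per line, fields matching
    :class:`PublicationRecord`. dialect ``PUBMED_XML``: a
    ``PubmedArticleSet`` document. Records lacking an abstract are retained
    with empty text; duplicate PMIDs collapse to the first occurrence with a
    logged warning.
    """
    if dialect == "JSONL_FIXTURE":
        records = _parse_jsonl(source)
    elif dialect == "PUBMED_XML":
        records = _parse_pubmed_xml(source)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    seen: dict[str, PublicationRecord] = {}
    for rec in records:
        if rec.pmid in seen:
            logger.warning("duplicate PMID %s collapsed to first occurrence", rec.pmid)
            continue
        seen[rec.pmid] = rec
    return list(seen.values())


def _parse_jsonl(source: IO) -> list[PublicationRecord]:
    records = []
    for i, line in enumerate(source):
        if isinstance(line, bytes):
            line = line.decode("utf-8")
        if not line.strip():
            continue
        try:
            records.append(PublicationRecord.from_dict(json.loads(line)))
        except (json.JSONDecodeError, KeyError, ValueError, TypeError) as exc:
            raise CorpusParseError(f"malformed record at line {i}: {exc}") from exc
    return records


def _parse_pubmed_xml(source: IO) -> list[PublicationRecord]:
    try:
        tree = etree.parse(source)
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(f"malformed XML: {exc}") from exc
    records = []
    for i, art in enumerate(tree.iter("PubmedArticle")):
        try:
            pmid = art.findtext(".//PMID")
            title = art.findtext(".//ArticleTitle") or ""
            abstract = " ".join(
                (t.text or "") for t in art.findall(".//Abstract/AbstractText")
            ).strip()
            year_text = (
                art.findtext(".//JournalIssue/PubDate/Year")
                or art.findtext(".//PubMedPubDate[@PubStatus='pubmed']/Year")
                or "1900"
            )
            journal = art.findtext(".//Journal/Title") or ""
            pubtypes = {t.text for t in art.findall(".//PublicationType") if t.text}
            mesh = {
                t.text for t in art.findall(".//MeshHeading/DescriptorName") if t.text
            }
            records.append(
                PublicationRecord(
                    pmid=pmid, title=title, abstract=abstract,
                    year=int(year_text), journal=journal,
                    publication_types=pubtypes, mesh_terms=mesh,
                )
            )
        except (TypeError, ValueError) as exc:
            raise CorpusParseError(f"malformed article at index {i}: {exc}") from exc
    return records


def write_jsonl(records: Iterable[PublicationRecord], stream: IO[str]) -> None:
    for rec in records:
        stream.write(json.dumps(rec.to_dict(), ensure_ascii=False, sort_keys=True))
        stream.write("\n")


# ---------------------------------------------------------------------------
# labelling

def classify_study_types(
    record: PublicationRecord,
    in_vivo_text_markers: Iterable[str] = (),
) -> set[StudyType]:
    """Assign study-type categories from MeSH markers and publication types.

    Multi-label: a record reporting both an animal experiment and a trial
    gets both IN_VIVO and CLINICAL. A record matching nothing gets the empty
    set (the caller may flag it).
    """
    out: set[StudyType] = set()
    if record.mesh_terms & set(IN_VITRO_MESH):
        out.add(StudyType.IN_VITRO)
    if record.mesh_terms & set(IN_VIVO_MESH):
        out.add(StudyType.IN_VIVO)
    elif in_vivo_text_markers:
        text = f"{record.title} {record.abstract}".casefold()
        if any(m.casefold() in text for m in in_vivo_text_markers):
            out.add(StudyType.IN_VIVO)
    if record.publication_types & set(CLINICAL_PUBTYPES):
        out.add(StudyType.CLINICAL)
    return out


def label_drugs(record: PublicationRecord, lexicon: DrugLexicon) -> set[str]:
    """Case-insensitive whole-word matching of lexicon surfaces in title+abstract."""
    import re as _re

    text = f"{record.title} {record.abstract}"
    labels: set[str] = set()
    for surface in lexicon.surfaces():
        if _re.search(rf"(?<![^\W_]){_re.escape(surface)}(?![^\W_])", text, _re.IGNORECASE):
            labels.add(lexicon.canonical_for(surface))
    return labels


# ---------------------------------------------------------------------------
# summary

def round_half_up(x: float, ndigits: int = 2) -> float:
    """Round half away from zero at ndigits (the printed-table convention)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summary_from_counts(counts: pd.DataFrame, corpus_total: int) -> pd.DataFrame:
    """Derive the per-drug rate columns from absolute study-type counts.

    ``counts`` must have columns drug, in_vitro, in_vivo, clinical, total.
    Adds pct_in_vitro / pct_in_vivo / pct_clinical (share within that drug's
    texts) and pct_of_corpus (share of distinct corpus records), all rounded
    half-up to 2 decimals. Drugs with zero texts report 0.00 everywhere.
    """
    df = counts.copy()
    for col, base in (
        ("pct_in_vitro", "in_vitro"),
        ("pct_in_vivo", "in_vivo"),
        ("pct_clinical", "clinical"),
    ):
        df[col] = [
            round_half_up(100.0 * n / t) if t else 0.0
            for n, t in zip(df[base], df["total"])
        ]
    df["pct_of_corpus"] = [
        round_half_up(100.0 * t / corpus_total) if corpus_total else 0.0
        for t in df["total"]
    ]
    return df


def load_reference_counts(path) -> tuple[pd.DataFrame, int]:
    """Load a shipped per-drug count table and its distinct-record total.

    The TSV carries a ``# distinct_records: N`` comment giving the number
    of unique PMIDs in the underlying corpus (less than the column sum when
    texts mention several drugs).
    """
    total = None
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    for line in lines:
        if line.startswith("# distinct_records:"):
            total = int(line.split(":", 1)[1].strip())
    df = pd.read_csv(path, sep="\t", comment="#")
    if total is None:
        total = int(df["total"].sum())
    return df, total


def corpus_summary(records: Iterable[PublicationRecord]) -> pd.DataFrame:
    """Per-drug table of study-type counts and rates.

    One row per drug label found in the corpus: absolute in vitro / in vivo
    / clinical counts (a multi-labelled record counts in every matching
    column), total texts mentioning the drug, within-drug percentages and
    share of the corpus total (distinct PMIDs).
    """
    records = list(records)
    corpus_total = len({r.pmid for r in records})
    rows: dict[str, dict[str, int]] = {}
    for rec in records:
        for drug in rec.drug_labels:
            row = rows.setdefault(
                drug, {"in_vitro": 0, "in_vivo": 0, "clinical": 0, "total": 0}
            )
            row["total"] += 1
            if StudyType.IN_VITRO in rec.study_types:
                row["in_vitro"] += 1
            if StudyType.IN_VIVO in rec.study_types:
                row["in_vivo"] += 1
            if StudyType.CLINICAL in rec.study_types:
                row["clinical"] += 1
    if not rows:
        return pd.DataFrame(
            columns=["drug", "in_vitro", "in_vivo", "clinical", "total",
                     "pct_in_vitro", "pct_in_vivo", "pct_clinical", "pct_of_corpus"]
        )
    counts = pd.DataFrame(
        [{"drug": d, **row} for d, row in sorted(rows.items())]
    ).sort_values("total", ascending=False, kind="stable").reset_index(drop=True)
    return summary_from_counts(counts, corpus_total)
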