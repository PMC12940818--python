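import io
import random

import numpy as np
import pytest

from acemine.aggregation import (
    aggregate,
    polarity_score_summary,
    read_aggregated_tsv,
    relation_type_counts,
    strength_distribution,
    temporal_metrics,
    write_aggregated_tsv,
)
from acemine.corpus import PublicationRecord, StudyType
from acemine.extraction import CandidateAssociation, Polarity, score_sentence
from acemine.ner import EntityMention, EntityType
from acemine.normalization import AnnotatedCandidate, Namespace, NormalizedEntity
from acemine.patterns import SemanticGroup, StrengthTier, STRENGTH_WEIGHTS


def _annotated(
    pmid="1", group=SemanticGroup.MECHANISMS, relation="Inhibit",
    surf_a="captopril", surf_b="ACE2", id_a="CID:44093", id_b="P12821",
    wp=3, d=0, polarity=Polarity.POSITIVE, strength=StrengthTier.STRONG,
    sentence_index=0,
):
    etype_b = {
        SemanticGroup.MECHANISMS: EntityType.GENE_PROTEIN,
        SemanticGroup.EFFECTS: EntityType.DISEASE,
        SemanticGroup.COADMINISTRATION: EntityType.CHEMICAL,
    }[group]
    ns_b = {
        EntityType.GENE_PROTEIN: Namespace.UNIPROT_AC,
        EntityType.DISEASE: Namespace.DOID,
        EntityType.CHEMICAL: Namespace.PUBCHEM_CID,
    }[etype_b]
    ma = EntityMention(pmid=pmid, sentence_index=sentence_index, surface=surf_a,
                       entity_type=EntityType.CHEMICAL, start=0, end=len(surf_a),
                       token_span=(0, 0), is_ace_inhibitor=True)
    mb = EntityMention(pmid=pmid, sentence_index=sentence_index, surface=surf_b,
                       entity_type=etype_b, start=20, end=20 + len(surf_b),
                       token_span=(5, 5))
    cand = CandidateAssociation(
        pmid=pmid, sentence_index=sentence_index, group=group,
        relation_type=relation, entity_a=ma, entity_b=mb, pattern_id="P1",
        strength=strength, wp=wp, d=d, s_sent=score_sentence(wp, d),
        polarity=polarity,
    )
    return AnnotatedCandidate(
        candidate=cand,
        norm_a=NormalizedEntity(surf_a, Namespace.PUBCHEM_CID, id_a),
        norm_b=NormalizedEntity(surf_b, ns_b, id_b),
    )


class TestAggregate:
    def test_three_publications_sum(self):
        anns = [_annotated(pmid=p) for p in ("1", "2", "3")]
        (agg,) = aggregate(anns)
        assert agg.n_pub == 3
        assert agg.s_conf == 9.0
        assert agg.n_mentions == 3

    def test_single_candidate_identity(self):
        (agg,) = aggregate([_annotated(wp=2, d=3)])
        assert agg.n_pub == 1
        assert agg.s_conf == 0.5

    def test_polarity_separated(self):
        anns = [
            _annotated(pmid="1"),
            _annotated(pmid="2", polarity=Polarity.NEGATIVE),
        ]
        aggs = aggregate(anns)
        assert len(aggs) == 2
        assert {a.polarity for a in aggs} == {Polarity.POSITIVE, Polarity.NEGATIVE}

    def test_per_publication_max_within_one_pmid(self):
        # two sentences of one publication support the same key
        anns = [
            _annotated(pmid="1", sentence_index=0, d=0),   # 3.0
            _annotated(pmid="1", sentence_index=1, d=2),   # 1.0
        ]
        (agg,) = aggregate(anns)
        assert agg.n_pub == 1
        assert agg.s_conf == 3.0
        assert agg.n_mentions == 2

    def test_per_pub_score_swappable(self):
        anns = [
            _annotated(pmid="1", sentence_index=0, d=0),
            _annotated(pmid="1", sentence_index=1, d=2),
        ]
        (agg,) = aggregate(anns, per_pub_score=sum)
        assert agg.s_conf == 4.0

    def test_flagged_excluded(self):
        ann = _annotated()
        flagged = AnnotatedCandidate(
            candidate=ann.candidate,
            norm_a=ann.norm_a,
            norm_b=NormalizedEntity("ACE2", Namespace.UNIPROT_AC, ""),
        )
        assert aggregate([flagged]) == []

    def test_coadministration_key_unordered(self):
        a1 = _annotated(group=SemanticGroup.COADMINISTRATION,
                        relation="Coadministered_with", surf_b="hctz",
                        id_a="CID:2", id_b="CID:1")
        a2 = _annotated(pmid="2", group=SemanticGroup.COADMINISTRATION,
                        relation="Coadministered_with", surf_b="hctz",
                        id_a="CID:1", id_b="CID:2")
        (agg,) = aggregate([a1, a2])
        assert (agg.identifier_a, agg.identifier_b) == ("CID:1", "CID:2")
        assert agg.n_pub == 2

    def test_sconf_additivity_property(self):
        rng = random.Random(17)
        for _ in range(50):
            n = rng.randint(1, 6)
            anns = [
                _annotated(pmid=str(p), wp=rng.choice([1, 2, 3]), d=rng.randint(0, 6))
                for p in range(n)
            ]
            (base,) = aggregate(anns)
            extra = _annotated(pmid="new", wp=2, d=rng.randint(0, 4))
            (grown,) = aggregate(anns + [extra])
            assert grown.n_pub == base.n_pub + 1
            assert grown.s_conf == pytest.approx(
                base.s_conf + extra.candidate.s_sent, abs=1e-12
            )

    def test_sconf_bounds(self):
        rng = random.Random(3)
        for _ in range(50):
            anns = [
                _annotated(pmid=str(p), wp=rng.choice([1, 2, 3]), d=rng.randint(0, 8))
                for p in range(rng.randint(1, 8))
            ]
            (agg,) = aggregate(anns)
            scores = list(agg.per_pub_scores.values())
            assert agg.n_pub * min(scores) <= agg.s_conf <= agg.n_pub * 3

    def test_sconf_sum_exactness_random_instances(self):
        rng = random.Random(99)
        for _ in range(1000):
            n = rng.randint(1, 10)
            anns = [
                _annotated(pmid=str(p), wp=rng.choice([1, 2, 3]),
                           d=rng.randint(0, 20))
                for p in range(n)
            ]
            (agg,) = aggregate(anns)
            expected = sum(agg.per_pub_scores.values())
            assert abs(agg.s_conf - expected) < 1e-12
            assert agg.per_pub_scores == {
                str(p): anns[p].candidate.s_sent for p in range(n)
            }


class TestSummaries:
    def test_strength_distribution(self):
        anns = [
            _annotated(pmid="1", strength=StrengthTier.STRONG),
            _annotated(pmid="1", surf_b="renin", id_b="P00797",
                       strength=StrengthTier.STRONG),
            _annotated(pmid="1", surf_b="BDNF", id_b="P23560",
                       strength=StrengthTier.WEAK, wp=1),
        ]
        table = strength_distribution(aggregate(anns))
        by_tier = dict(zip(table.best_strength, table.n))
        assert by_tier == {"STRONG": 2, "WEAK": 1}

    def test_strength_empty(self):
        assert strength_distribution([]).empty

    def test_relation_type_ranking(self):
        anns = [
            _annotated(pmid="1", relation="Inhibit"),
            _annotated(pmid="1", relation="Inhibit", surf_b="renin", id_b="P00797"),
            _annotated(pmid="1", group=SemanticGroup.EFFECTS,
                       relation="Treatment", surf_b="htn", id_b="DOID:1"),
        ]
        table = relation_type_counts(aggregate(anns))
        assert table.iloc[0].relation_type == "Inhibit"
        assert table.iloc[0].n == 2
        assert relation_type_counts(aggregate(anns), top_n=0).empty


def _record(pmid, year, study_types):
    return PublicationRecord(pmid=pmid, year=year, study_types=study_types)


class TestTemporalMetrics:
    def test_span_examples(self):
        recs = {
            "1": _record("1", 1990, {StudyType.IN_VIVO}),
            "2": _record("2", 1993, {StudyType.CLINICAL}),
            "3": _record("3", 2000, {StudyType.IN_VITRO}),
        }
        anns = [
            _annotated(pmid="1"), _annotated(pmid="2"),
            _annotated(pmid="3", surf_b="renin", id_b="P00797"),
        ]
        aggs = aggregate(anns, recs)
        spans = {a.identifier_b: a.temporal_span for a in aggs}
        assert spans == {"P12821": 3, "P00797": 0}

    def test_cohort_partition_and_means(self, gen_bundle, pipeline_result):
        """Cohort means recomputed directly from the aggregated set."""
        aggs = pipeline_result.aggregated
        table = temporal_metrics(aggs).set_index("cohort")
        ivt_only = [a for a in aggs if a.study_types
                    and a.study_types <= {StudyType.IN_VITRO}]
        other = [a for a in aggs if a.study_types - {StudyType.IN_VITRO}]
        assert len(ivt_only) + len(other) == len(aggs)
        assert table.loc["in_vitro_only", "n_associations"] == len(ivt_only)
        assert table.loc["in_vivo_or_clinical", "n_associations"] == len(other)
        if other:
            expected = round(float(np.mean([a.temporal_span for a in other])), 2)
            assert table.loc["in_vivo_or_clinical", "mean_span_years"] == pytest.approx(
                expected, abs=0.01
            )


class TestPolaritySummary:
    def test_median_of_three(self):
        anns = [
            _annotated(pmid="1", wp=1, d=0),
            _annotated(pmid="1", surf_b="renin", id_b="P00797", wp=2, d=0),
            _annotated(pmid="1", surf_b="BDNF", id_b="P23560", wp=3, d=0),
        ]
        table = polarity_score_summary(aggregate(anns)).set_index("polarity")
        assert table.loc["POSITIVE", "median"] == 2.0

    def test_single_record_degenerate(self):
        (agg,) = aggregate([_annotated(wp=2, d=1)])
        row = polarity_score_summary([agg]).iloc[0]
        assert row["min"] == row.q1 == row["median"] == row.q3 == row["max"] == 1.0

    def test_positive_median_exceeds_negated_by_construction(self):
        # positives get systematically more supporting publications
        anns = []
        for k in range(4):
            for p in range(3):
                anns.append(
                    _annotated(pmid=f"p{k}-{p}", surf_b=f"prot{k}", id_b=f"P{k}")
                )
            anns.append(
                _annotated(pmid=f"n{k}", surf_b=f"prot{k}", id_b=f"P{k}",
                           polarity=Polarity.NEGATIVE)
            )
        table = polarity_score_summary(aggregate(anns)).set_index("polarity")
        assert table.loc["POSITIVE", "median"] > table.loc["NEGATIVE", "median"]


class TestRoundTrip:
    def test_tsv_round_trip_preserves_sconf(self, pipeline_result):
        aggs = pipeline_result.aggregated
        buf = io.StringIO()
        write_aggregated_tsv(aggs, buf)
        buf.seek(0)
        reread = read_aggregated_tsv(buf)
        assert len(reread) == len(aggs)
        for a, b in zip(aggs, sorted(reread, key=lambda x: x.key)):
            assert a.key == b.key
            assert b.s_conf == pytest.approx(a.s_conf, abs=1e-9)
            assert a.pmids == b.pmids
            assert a.years == b.years
            assert a.n_mentions == b.n_mentions
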