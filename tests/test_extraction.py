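import io
import random

import pytest

from acemine.extraction import (
    DEFAULT_NEGATION_CUES,
    NegationCues,
    Polarity,
    combine_distances,
    detect_negation,
    extract_candidates,
    filter_ace,
    score_sentence,
    select_best,
    token_distance,
    write_candidates_tsv,
)
from acemine.ner import EntityType, TypedLexicon, recognize_gazetteer
from acemine.patterns import SemanticGroup, load_inventory, match_patterns

from conftest import make_sentence

HEADER = "pattern_id\tgroup\trelation_type\tstrength\tphrase\n"
MINI_INVENTORY = load_inventory(
    io.StringIO(
        HEADER
        + "M1\tMECHANISMS\tInhibit\tSTRONG\tinhibits\n"
        + "M2\tMECHANISMS\tInhibit\tSTRONG\tinhibit\n"
        + "M3\tMECHANISMS\tModulate\tMEDIUM\tmodulates activity of\n"
        + "E1\tEFFECTS\tTreatment\tSTRONG\tis effective in the treatment of\n"
        + "C1\tCOADMINISTRATION\tCoadministered_with\tSTRONG\tin combination with\n"
    )
)

LEXICON = TypedLexicon(
    [
        ("captopril", EntityType.CHEMICAL, True),
        ("enalapril", EntityType.CHEMICAL, True),
        ("hydrochlorothiazide", EntityType.CHEMICAL, False),
        ("temozolomide", EntityType.CHEMICAL, False),
        ("ACE2", EntityType.GENE_PROTEIN, False),
        ("renin", EntityType.GENE_PROTEIN, False),
        ("MMP2", EntityType.GENE_PROTEIN, False),
        ("hypertension", EntityType.DISEASE, False),
        ("glioma", EntityType.DISEASE, False),
    ]
)


def _candidates(text, inventory=MINI_INVENTORY, **kw):
    sent, toks = make_sentence(text)
    mentions = recognize_gazetteer(sent, toks, LEXICON)
    hits = match_patterns(toks, inventory)
    return extract_candidates(sent, mentions, hits, toks, **kw)


class TestTokenDistance:
    @pytest.mark.parametrize(
        "a, b, expected",
        [((0, 0), (1, 1), 0), ((0, 1), (5, 6), 3), ((5, 6), (0, 1), 3), ((0, 0), (9, 9), 8)],
    )
    def test_examples(self, a, b, expected):
        assert token_distance(a, b) == expected

    def test_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            token_distance((0, 3), (2, 5))

    def test_against_direct_count(self):
        rng = random.Random(11)
        for _ in range(1000):
            a0 = rng.randint(0, 30); a1 = a0 + rng.randint(0, 4)
            b0 = a1 + 1 + rng.randint(0, 10); b1 = b0 + rng.randint(0, 4)
            spans = [(a0, a1), (b0, b1)]
            rng.shuffle(spans)
            expected = sum(
                1 for i in range(0, 60)
                if max(spans[0][1], spans[1][1]) > i > min(spans[0][0], spans[1][0])
                and not any(s0 <= i <= s1 for s0, s1 in spans)
            )
            assert token_distance(*spans) == expected


class TestScoreSentence:
    @pytest.mark.parametrize("wp,d,expected", [(3, 0, 3.0), (2, 3, 0.5), (1, 0, 1.0)])
    def test_examples(self, wp, d, expected):
        assert score_sentence(wp, d) == expected

    def test_cross_tier_comparison(self):
        assert score_sentence(1, 0) > score_sentence(3, 8)

    def test_formula_grid(self):
        for wp in (1, 2, 3):
            for d in range(51):
                assert score_sentence(wp, d) == wp / (1 + d)

    def test_bounds_and_monotonicity(self):
        for wp in (1, 2, 3):
            prev = float("inf")
            for d in range(20):
                s = score_sentence(wp, d)
                assert 0 < s <= 3
                assert s < prev
                prev = s
                if d == 0:
                    assert s == wp

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            score_sentence(3, -1)
        with pytest.raises(ValueError):
            score_sentence(4, 0)


class TestDetectNegation:
    def test_cue_before_pattern(self):
        _, toks = make_sentence("captopril did not inhibit renin release")
        # pattern "inhibit" is token 3
        assert detect_negation(toks, (3, 3)) is Polarity.NEGATIVE

    def test_cue_outside_window(self):
        _, toks = make_sentence("not a b c d e f inhibits renin")
        # cue at 0 begins 7 tokens before the pattern at 7
        assert detect_negation(toks, (7, 7)) is Polarity.POSITIVE

    def test_cue_at_window_boundary(self):
        _, toks = make_sentence("not a b c d inhibits renin")
        assert detect_negation(toks, (5, 5)) is Polarity.NEGATIVE

    def test_multi_token_cue_after_pattern(self):
        _, toks = make_sentence("renin was inhibited in the absence of captopril")
        # "absence of" ends 4 tokens after pattern token 2
        assert detect_negation(toks, (2, 2)) is Polarity.NEGATIVE

    def test_positional_oracle_fuzz(self):
        """Plant a cue at every offset 0-8 on both sides; polarity must equal
        direct window membership of the cue position."""
        rng = random.Random(23)
        filler = ["alpha", "beta", "gamma", "delta", "epsilon", "zeta",
                  "eta", "theta", "iota", "kappa"]
        for trial in range(500):
            offset = rng.randint(1, 8)
            side = rng.choice(["before", "after"])
            pre = [rng.choice(filler) for _ in range(10)]
            post = [rng.choice(filler) for _ in range(10)]
            if side == "before":
                pre[len(pre) - offset] = "not"
            else:
                post[offset - 1] = "not"
            toks_text = pre + ["inhibits"] + post
            _, toks = make_sentence(" ".join(toks_text))
            span = (10, 10)
            expected = Polarity.NEGATIVE if offset <= 5 else Polarity.POSITIVE
            assert detect_negation(toks, span) is expected, (side, offset)


class TestExtractCandidates:
    def test_adjacent_mechanism(self):
        (c,) = _candidates("captopril inhibits ACE2")
        assert c.group is SemanticGroup.MECHANISMS
        assert (c.d, c.s_sent, c.polarity) == (0, 3.0, Polarity.POSITIVE)
        assert c.entity_a.surface == "captopril"
        assert c.entity_b.surface == "ACE2"

    def test_missing_third_element(self):
        assert _candidates("captopril and hypertension were studied") == []

    def test_coadministration_always_positive(self):
        (c,) = _candidates("enalapril not in combination with hydrochlorothiazide")
        assert c.group is SemanticGroup.COADMINISTRATION
        assert c.polarity is Polarity.POSITIVE

    def test_coadministration_requires_distinct_drugs(self):
        assert _candidates("enalapril in combination with enalapril") == []

    def test_closest_mention_used(self):
        # two captopril occurrences; the one nearer the pattern defines d
        cands = _candidates("captopril something captopril inhibits ACE2")
        (c,) = cands
        assert c.d == 0
        assert c.entity_a.token_span == (2, 2)

    def test_distance_sums_both_sides(self):
        (c,) = _candidates("captopril strongly and rapidly inhibits renal ACE2")
        # 3 tokens between drug and pattern, 1 between pattern and protein
        assert c.d == 4
        assert c.s_sent == 3 / 5

    def test_negated_mechanism(self):
        (c,) = _candidates("captopril did not inhibit renin")
        assert c.polarity is Polarity.NEGATIVE
        assert c.relation_type == "Inhibit"

    def test_distance_mode_isolated(self):
        (c_sum,) = _candidates("captopril strongly and rapidly inhibits renal ACE2")
        (c_max,) = _candidates(
            "captopril strongly and rapidly inhibits renal ACE2", distance_mode="max"
        )
        assert c_sum.d == 4 and c_max.d == 3
        assert combine_distances(3, 1, "min") == 1


class TestSelectBest:
    def test_strict_maximum(self):
        cands = _candidates(
            "captopril inhibits ACE2 while enalapril modulates activity of distant renin"
        )
        assert len(cands) > 1
        best = select_best(cands)
        top = max(c.s_sent for c in cands)
        assert all(c.s_sent == top for c in best)

    def test_ties_all_kept(self):
        # two adjacent drug-protein-pattern triples, both at d = 0
        cands = _candidates("captopril inhibits ACE2 and enalapril inhibits renin")
        best = select_best(cands)
        assert len(best) == 2
        assert len({c.s_sent for c in best}) == 1

    def test_empty(self):
        assert select_best([]) == []

    def test_brute_force_argmax(self):
        rng = random.Random(5)
        texts = [
            "captopril inhibits ACE2 and renin near hypertension",
            "enalapril modulates activity of MMP2 while captopril inhibits renin",
            "temozolomide in combination with captopril inhibits MMP2",
        ]
        for text in texts:
            cands = _candidates(text)
            if not cands:
                continue
            top = max(c.s_sent for c in cands)
            expected = sorted(
                [c for c in cands if c.s_sent == top],
                key=lambda c: (c.group.value, c.relation_type,
                               c.entity_a.start, c.entity_b.start),
            )
            assert select_best(cands) == expected


class TestFilterAce:
    def test_ace_retained_non_ace_dropped(self):
        kept = _candidates("captopril inhibits MMP2")
        dropped = _candidates("temozolomide inhibits MMP2")
        assert filter_ace(kept) == kept
        assert filter_ace(dropped) == []

    def test_subset_property(self):
        cands = _candidates(
            "temozolomide in combination with captopril inhibits MMP2"
        )
        assert set(map(id, filter_ace(cands))) <= set(map(id, cands))

    def test_planted_ace_fraction_recovered(self, gen_bundle, pipeline_result):
        planted_ace = {t.key for t in gen_bundle.truth if t.involves_ace}
        planted_all = {t.key for t in gen_bundle.truth}
        assert planted_ace < planted_all  # generator plants non-ACE triples too
        recovered = {a.key for a in pipeline_result.aggregated}
        assert recovered == planted_ace


def test_candidates_tsv_columns():
    cands = _candidates("captopril inhibits ACE2")
    buf = io.StringIO()
    write_candidates_tsv(cands, buf)
    header, row = buf.getvalue().strip().split("\n")
    assert header.split("\t")[:4] == ["pmid", "sentence_index", "group", "relation_type"]
    assert "3.0" in row and "POSITIVE" in row
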