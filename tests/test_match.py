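"""Exact matcher, phonetic matcher (against a brute-force oracle), variant
rewrites and the full cascade."""

import pytest

import anatomap as am
from anatomap.match import (
    CurationError,
    adjectival_to_noun,
    expand_shorthand,
    plural_variants,
    read_curation_tsv,
)
from anatomap.phonetic import encode_phrase

from conftest import clean_term


class TestExactMatch:
    def test_label_hit(self, small_index):
        cands = am.exact_match(clean_term("liver"), small_index)
        assert [(c.class_id, c.match_kind) for c in cands] == [
            ("T:0001", "exact_label")
        ]

    def test_synonym_hit(self, small_index):
        cands = am.exact_match(clean_term("hepar"), small_index)
        assert [(c.class_id, c.match_kind) for c in cands] == [
            ("T:0001", "exact_synonym")
        ]

    def test_composite_string_misses(self, small_index):
        assert am.exact_match(clean_term("liver/kidney"), small_index) == []

    def test_duplicate_label_ranked_by_id(self):
        idx = am.build_index(
            [am.OntologyClass("T:002", "Ureter"), am.OntologyClass("T:001", "ureter")]
        )
        cands = am.exact_match(clean_term("ureter"), idx)
        assert [(c.class_id, c.rank) for c in cands] == [("T:001", 1), ("T:002", 2)]


class TestPhoneticMatch:
    def test_singleton_bucket(self, small_index):
        cands = am.phonetic_match(clean_term("kiddney"), small_index)
        assert [c.class_id for c in cands] == ["T:0002"]
        assert all(c.match_kind == "phonetic" for c in cands)

    def test_exact_string_suppressed(self, small_index):
        # a query equal to an index string is an exact match, not a proposal
        cands = am.phonetic_match(clean_term("liver"), small_index)
        assert all("liver" != c.evidence.split("|")[0] for c in cands)

    def test_equals_bruteforce_oracle(self, corpus_1000):
        """Bucketed phonetic lookup returns exactly the pairs found by
        exhaustively encoding and comparing every (query, index string)."""
        idx = am.build_index(corpus_1000.ontology)
        queries = [
            "levar", "kidny", "hart", "femer", "asofagus", "both ventrickles",
            "doarsal hert", "left kidnee", "renel cortex", "bone marow",
        ]
        for q in queries:
            term = clean_term(q)
            got = {(c.evidence.split("|")[0], c.class_id) for c in am.phonetic_match(term, idx)}
            qcodes = {c for c in encode_phrase(q) if c}
            expected = set()
            for key, hits in idx.lexical_map.items():
                if key == q:
                    continue
                kcodes = {c for c in encode_phrase(key) if c}
                if qcodes & kcodes:
                    expected |= {(key, cid) for cid, _ in hits}
            assert got == expected, q

    def test_deterministic_order(self, corpus_1000):
        idx = am.build_index(corpus_1000.ontology)
        a = am.phonetic_match(clean_term("levar"), idx)
        b = am.phonetic_match(clean_term("levar"), idx)
        assert a == b
        assert [c.rank for c in a] == list(range(1, len(a) + 1))


class TestVariants:
    @pytest.mark.parametrize(
        ("plural", "expected"),
        [
            ("kidneys", ["kidney"]),
            ("arteries", ["artery"]),
            ("pancreas", []),  # exception word, not a plural
            ("arches", ["arch"]),
            ("vertebrae", ["vertebra"]),
            ("left kidneys", ["left kidney"]),
        ],
    )
    def test_plural_variants(self, plural, expected):
        got = plural_variants(plural)
        for want in expected:
            assert want in got
        if not expected:
            assert got == []

    @pytest.mark.parametrize(
        ("adjective", "noun"),
        [("abdominal", "abdomen"), ("arterial", "artery")],
    )
    def test_adjectival(self, adjective, noun):
        assert adjectival_to_noun(adjective) == noun

    def test_adjectival_unknown_key_unchanged(self):
        assert (
            adjectival_to_noun("hepatic portal vein", {"renal": "kidney"})
            == "hepatic portal vein"
        )

    def test_shorthand_multi_expansion(self):
        assert expand_shorthand("both ventricles") == [
            "left ventricle of heart",
            "right ventricle of heart",
        ]
        assert expand_shorthand("antrum") == ["pyloric antrum"]
        assert expand_shorthand("liver") == ["liver"]


class TestRunMatcher:
    def test_empty_terms(self, small_index):
        assert am.run_matcher([], small_index) == []

    def test_exact_counts_fixed_fixture(self, small_index):
        present = ["liver", "kidney", "femur", "abdomen", "artery", "colon"]
        absent = ["cloaca", "gizzard lining", "wattle", "syrinx"]
        terms = [clean_term(t) for t in present + absent]
        config = am.MatchConfig(phonetic=False)
        outcomes = am.run_matcher(terms, small_index, config)
        assert sum(o.status == "matched" for o in outcomes) == 6

    def test_phonetic_never_removes_matches(self, small_index):
        terms = [clean_term(t) for t in ["liver", "kidney", "kiddney", "wattle"]]
        off = am.run_matcher(terms, small_index, am.MatchConfig(phonetic=False))
        on = am.run_matcher(terms, small_index, am.MatchConfig(phonetic=True))
        matched_off = {o.query.normalized for o in off if o.status == "matched"}
        matched_on = {o.query.normalized for o in on if o.status == "matched"}
        assert matched_off <= matched_on
        proposed = {o.query.normalized for o in on if o.status == "proposed_only"}
        assert "kiddney" in proposed

    def test_variant_cascade_kinds(self, small_index):
        terms = [clean_term(t) for t in ["kidneys", "abdominal", "both ventricles"]]
        outcomes = am.run_matcher(terms, small_index, am.MatchConfig())
        kinds = {
            o.query.normalized: {c.match_kind for c in o.proposed}
            for o in outcomes
        }
        assert kinds["kidneys"] == {"plural_variant"}
        assert kinds["abdominal"] == {"adjectival"}
        assert kinds["both ventricles"] == {"shorthand"}
        both = next(o for o in outcomes if o.query.normalized == "both ventricles")
        assert both.accepted == {"T:0009", "T:0010"}

    def test_reflexivity_every_label_matches_itself(self, corpus_1000):
        """Every indexed label submitted as a query exact-matches its class."""
        idx = am.build_index(corpus_1000.ontology)
        for cls in corpus_1000.ontology[:200]:
            term = clean_term(am.normalize_text(cls.label).normalized)
            cands = am.exact_match(term, idx)
            assert cls.id in {c.class_id for c in cands}

    def test_exact_ranks_precede_phonetic(self, small_index):
        # duplicate-ish query that has both exact and phonetic candidates
        idx = small_index
        outcomes = am.run_matcher(
            [clean_term("liver")], idx, am.MatchConfig(phonetic=True)
        )
        kinds_in_rank_order = [
            c.match_kind for c in sorted(outcomes[0].proposed, key=lambda c: c.rank)
        ]
        first_phonetic = (
            kinds_in_rank_order.index("phonetic")
            if "phonetic" in kinds_in_rank_order
            else len(kinds_in_rank_order)
        )
        assert all(k != "phonetic" for k in kinds_in_rank_order[:first_phonetic])

    def test_curation_promotes_proposals(self, small_index, tmp_path):
        terms = [clean_term("kiddney")]
        config = am.MatchConfig(phonetic=True)
        bare = am.run_matcher(terms, small_index, config)
        assert bare[0].status == "proposed_only"

        cur = tmp_path / "curation.tsv"
        cur.write_text("kiddney\tT:0002\n", encoding="utf-8")
        curated = am.run_matcher(
            terms, small_index, config, curation=read_curation_tsv(cur)
        )
        assert curated[0].status == "matched"
        assert curated[0].accepted == {"T:0002"}

    def test_curation_unknown_term_rejected(self, small_index):
        with pytest.raises(CurationError, match="ghost"):
            am.run_matcher(
                [clean_term("liver")],
                small_index,
                am.MatchConfig(phonetic=True),
                curation={"ghost": ["T:0001"]},
            )

    def test_proposals_never_auto_accepted(self, small_index):
        """Without curation, phonetic proposals stay out of accepted sets."""
        terms = [clean_term(t) for t in ["kiddney", "levar"]]
        outcomes = am.run_matcher(terms, small_index, am.MatchConfig(phonetic=True))
        for o in outcomes:
            assert not o.accepted
            assert o.status in ("proposed_only", "unmatched")
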