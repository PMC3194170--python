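"""Synthetic ontology and corpus generation."""

import pytest

import anatomap as am
from anatomap.normalize import normalize_text, strip_species
from anatomap.synth import (
    CORRUPTION_CLASSES,
    DEFAULT_PROPORTIONS,
    generate_dense_ontology,
    write_corpus,
)


class TestGenerateOntology:
    def test_deterministic(self):
        a = am.generate_ontology(10, 0.0, 0, seed=1)
        b = am.generate_ontology(10, 0.0, 0, seed=1)
        assert a == b

    def test_exact_synonym_count(self):
        classes = am.generate_ontology(10, 0.5, 0, seed=42)
        assert sum(1 for c in classes if c.synonyms) == 5
        assert all(s[1] == "EXACT" for c in classes for s in c.synonyms)

    def test_injected_duplicates_detected(self):
        classes = am.generate_ontology(20, 0.2, 2, seed=7)
        assert len(am.find_duplicate_labels(classes)) == 2

    def test_unique_ids_and_labels(self):
        classes = am.generate_ontology(50, 0.3, 0, seed=3)
        assert len({c.id for c in classes}) == 50
        assert len({c.label for c in classes}) == 50

    def test_excessive_duplicates_rejected(self):
        with pytest.raises(ValueError):
            am.generate_ontology(4, 0.0, 3, seed=1)


class TestCorruptionSpec:
    def test_proportions_must_sum_to_one(self):
        bad = dict(DEFAULT_PROPORTIONS)
        bad["identity"] += 0.01
        with pytest.raises(ValueError, match="sum"):
            am.CorruptionSpec(n_terms=10, proportions=bad)

    def test_unknown_class_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            am.CorruptionSpec(n_terms=10, proportions={"typo_class": 1.0})

    def test_defaults_are_valid(self):
        spec = am.CorruptionSpec()
        assert abs(sum(spec.proportions.values()) - 1.0) < 1e-9
        assert set(spec.proportions) == set(CORRUPTION_CLASSES)


@pytest.fixture(scope="module")
def ontology():
    return am.generate_ontology(n_classes=200, seed=5)


class TestCorrupt:
    def test_all_identity(self, ontology):
        """Identity-only corpus: every annotation is a verbatim label and the
        exact-only pipeline recovers everything with no false positives."""
        spec = am.CorruptionSpec(n_terms=50, seed=5, proportions={"identity": 1.0})
        corpus = am.corrupt(ontology, spec)
        labels = {c.label for c in ontology}
        assert all(a.text in labels for a in corpus.annotations)

        idx = am.build_index(corpus.ontology)
        terms, _ = am.clean_annotations(corpus.annotations)
        outcomes = am.run_matcher(terms, idx, am.MatchConfig(phonetic=False))
        cm = am.compare_to_gold(outcomes, corpus.gold)
        assert (cm.tp, cm.fp, cm.fn) == (50, 0, 0)

    def test_all_uninterpretable(self, ontology):
        spec = am.CorruptionSpec(
            n_terms=30, seed=5, proportions={"uninterpretable": 1.0}
        )
        corpus = am.corrupt(ontology, spec)
        assert all(not ids for ids in corpus.gold.map.values())

        idx = am.build_index(corpus.ontology)
        terms, _ = am.clean_annotations(corpus.annotations)
        outcomes = am.run_matcher(terms, idx, am.MatchConfig(phonetic=False))
        cm = am.compare_to_gold(outcomes, corpus.gold)
        assert cm.tn == 30

    def test_bit_identical_regeneration(self, corpus_1000):
        again = am.corrupt(
            am.generate_ontology(n_classes=600, seed=1),
            am.CorruptionSpec(n_terms=1000, seed=1),
        )
        assert again.annotations == corpus_1000.annotations
        assert again.gold.map == corpus_1000.gold.map
        assert again.labels == corpus_1000.labels
        assert again.shorthand_table == corpus_1000.shorthand_table

    def test_gold_ids_exist_in_ontology(self, corpus_1000):
        known = {c.id for c in corpus_1000.ontology}
        for ids in corpus_1000.gold.map.values():
            assert ids <= known

    def test_labels_match_applied_rules(self, corpus_1000):
        """Spot-check that corruption labels describe the rule applied."""
        by_label = {c.label for c in corpus_1000.ontology}
        for ann, label in zip(corpus_1000.annotations, corpus_1000.labels):
            if label == "identity":
                assert ann.text in by_label
            elif label == "composite_delimiter":
                assert "/" in ann.text or "," in ann.text
            elif label == "uninterpretable":
                key = normalize_text(strip_species(ann.text, ann.species)).normalized
                assert corpus_1000.gold[key] == frozenset()
            elif label == "species_suffix":
                assert ann.species.lower() in ann.text.lower()

    def test_quota_apportionment(self, corpus_1000):
        from collections import Counter

        counts = Counter(corpus_1000.labels)
        assert sum(counts.values()) == 1000
        for kind, share in DEFAULT_PROPORTIONS.items():
            assert abs(counts[kind] - share * 1000) <= 1

    def test_empty_ontology_rejected(self):
        with pytest.raises(ValueError):
            am.corrupt([], am.CorruptionSpec(n_terms=5))


class TestDenseOntology:
    def test_queries_share_codes_with_groups(self):
        classes, queries = generate_dense_ontology(n_groups=5, group_size=6, seed=2)
        assert len(classes) == 30
        assert len(queries) == 5
        labels = {c.label for c in classes}
        from anatomap.phonetic import double_metaphone

        for q in queries:
            assert q not in labels
            bucket = [c for c in classes if double_metaphone(c.label)[0] == double_metaphone(q)[0]]
            assert len(bucket) >= 6  # its whole group sounds identical

    def test_deterministic(self):
        assert generate_dense_ontology(seed=9) == generate_dense_ontology(seed=9)


def test_write_corpus_fixtures_roundtrip(tmp_path, corpus_1000):
    """Corpus fixture files parse back into the same world."""
    small = am.corrupt(
        am.generate_ontology(n_classes=100, seed=3),
        am.CorruptionSpec(n_terms=40, seed=3),
    )
    paths = write_corpus(small, tmp_path)
    classes = am.parse_obo(paths["obo"])
    assert classes == small.ontology
    from anatomap.normalize import read_term_tsv
    from anatomap.evaluate import read_gold_tsv

    anns = read_term_tsv(paths["terms"])
    assert [a.text for a in anns] == [a.text for a in small.annotations]
    assert read_gold_tsv(paths["gold"]).map == small.gold.map
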