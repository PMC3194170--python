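"""OBO parsing, index construction and lexical QC."""

import pytest

import anatomap as am
from anatomap.ontology_io import (
    OboParseError,
    parse_lexicon_tsv,
    write_duplicate_report,
)


class TestParseObo:
    def test_fixture_counts(self, obo_path):
        classes = am.parse_obo(obo_path)
        assert len(classes) == 5  # Typedef stanza ignored
        assert sum(c.obsolete for c in classes) == 1

    def test_minimal_stanza(self, tmp_path):
        p = tmp_path / "m.obo"
        p.write_text("[Term]\nid: T:001\nname: liver\n", encoding="utf-8")
        (cls,) = am.parse_obo(p)
        assert (cls.id, cls.label, cls.synonyms, cls.obsolete) == (
            "T:001",
            "liver",
            (),
            False,
        )

    def test_synonym_scopes(self, obo_path):
        liver = next(c for c in am.parse_obo(obo_path) if c.id == "T:0001")
        assert ("hepar", "EXACT") in liver.synonyms
        assert ("hepatic tissue", "RELATED") in liver.synonyms

    def test_scope_defaults_to_related(self, tmp_path):
        p = tmp_path / "s.obo"
        p.write_text(
            '[Term]\nid: T:001\nname: liver\nsynonym: "hepar" []\n',
            encoding="utf-8",
        )
        (cls,) = am.parse_obo(p)
        assert cls.synonyms == (("hepar", "RELATED"),)

    def test_stanza_without_id_names_line(self, tmp_path):
        p = tmp_path / "bad.obo"
        p.write_text("[Term]\nname: orphan\n", encoding="utf-8")
        with pytest.raises(OboParseError, match="line 1"):
            am.parse_obo(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(OSError):
            am.parse_obo(tmp_path / "absent.obo")

    def test_lexicon_tsv(self, tmp_path):
        p = tmp_path / "lex.tsv"
        p.write_text("T:001\tliver\nT:002\tkidney\n", encoding="utf-8")
        classes = parse_lexicon_tsv(p)
        assert [c.label for c in classes] == ["liver", "kidney"]


class TestBuildIndex:
    def test_single_label_casefolded(self):
        idx = am.build_index([am.OntologyClass("T:001", "Liver")])
        assert idx.lexical_map["liver"] == {("T:001", "label")}

    def test_duplicate_label_two_members(self):
        idx = am.build_index(
            [am.OntologyClass("T:001", "ureter"), am.OntologyClass("T:002", "Ureter")]
        )
        assert len(idx.lexical_map["ureter"]) == 2

    def test_key_count_matches_enumeration(self, corpus_1000):
        """Index key count equals a brute-force enumeration of the unique
        normalized labels + EXACT synonyms of non-obsolete classes."""
        classes = corpus_1000.ontology
        idx = am.build_index(classes)
        expected = {
            am.normalize_text(c.label).normalized
            for c in classes
            if not c.obsolete and c.label
        } | {
            am.normalize_text(s).normalized
            for c in classes
            if not c.obsolete
            for s, scope in c.synonyms
            if scope == "EXACT"
        }
        assert idx.keys() == expected

    def test_obsolete_excluded_by_default(self, obo_path):
        classes = am.parse_obo(obo_path)
        idx = am.build_index(classes)
        assert "gizzard" not in idx.lexical_map
        idx_all = am.build_index(classes, include_obsolete=True)
        assert "gizzard" in idx_all.lexical_map

    def test_synonym_scope_admission(self, obo_path):
        classes = am.parse_obo(obo_path)
        default = am.build_index(classes)
        assert "hepar" in default.lexical_map
        assert "hepatic tissue" not in default.lexical_map
        widened = am.build_index(classes, synonym_scopes=("EXACT", "RELATED"))
        assert "hepatic tissue" in widened.lexical_map

    def test_empty_classes_error(self):
        with pytest.raises(ValueError):
            am.build_index([])

    def test_rebuild_identical(self, obo_path):
        classes = am.parse_obo(obo_path)
        a, b = am.build_index(classes), am.build_index(classes)
        assert a.lexical_map == b.lexical_map
        assert a.phonetic_map == b.phonetic_map

    def test_phonetic_map_closed_over_lexical_keys(self, corpus_1000):
        idx = am.build_index(corpus_1000.ontology)
        for strings in idx.phonetic_map.values():
            assert strings <= idx.keys()


class TestDuplicateLabels:
    def test_case_insensitive_duplicate(self, obo_path):
        classes = am.parse_obo(obo_path)
        dupes = am.find_duplicate_labels(classes)
        assert dupes == [("ureter", ["T:0003", "T:0004"])]
        for _label, ids in dupes:
            known = {c.id for c in classes}
            assert set(ids) <= known

    def test_all_distinct(self, small_classes):
        assert am.find_duplicate_labels(small_classes) == []

    def test_three_way_collision(self):
        classes = [am.OntologyClass(f"T:{i}", "Ureter") for i in range(3)]
        assert am.find_duplicate_labels(classes) == [
            ("ureter", ["T:0", "T:1", "T:2"])
        ]

    def test_report_tsv(self, tmp_path):
        out = tmp_path / "dupes.tsv"
        write_duplicate_report([("ureter", ["T:1", "T:2"])], out)
        assert out.read_text(encoding="utf-8") == "ureter\tT:1,T:2\n"


class TestLexicalOverlap:
    def _index_for(self, labels, start=0):
        classes = [
            am.OntologyClass(f"X:{start + i}", lab) for i, lab in enumerate(labels)
        ]
        return am.build_index(classes)

    def test_identical_is_100(self):
        idx = self._index_for(["a", "b", "c"])
        assert am.lexical_overlap(idx, idx) == 100.0

    def test_disjoint_is_0(self):
        a = self._index_for(["a", "b"])
        b = self._index_for(["c", "d"], start=10)
        assert am.lexical_overlap(a, b) == 0.0

    def test_jaccard_half(self):
        a = self._index_for(["a", "b", "c"])
        b = self._index_for(["b", "c", "d"], start=10)
        assert am.lexical_overlap(a, b) == 50.0  # 2 shared / 4 total
        assert am.lexical_overlap(b, a) == 50.0

    def test_config_mismatch_rejected(self):
        a = self._index_for(["a"])
        classes = [am.OntologyClass("Y:1", "a")]
        b = am.build_index(classes, am.NormalizerConfig(americanize=False))
        with pytest.raises(ValueError):
            am.lexical_overlap(a, b)
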