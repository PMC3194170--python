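import pytest

import anatomap as am


OBO_FIXTURE = """\
format-version: 1.2
date: 01:01:2011 00:00

[Term]
id: T:0001
name: liver
synonym: "hepar" EXACT []
synonym: "hepatic tissue" RELATED []

[Term]
id: T:0002
name: kidney

[Term]
id: T:0003
name: Ureter

[Term]
id: T:0004
name: ureter

[Term]
id: T:0005
name: gizzard
is_obsolete: true

[Typedef]
id: part_of
name: part of
"""


@pytest.fixture()
def obo_path(tmp_path):
    """A 5-term OBO file: synonyms, a duplicated label, one obsolete class."""
    path = tmp_path / "toy.obo"
    path.write_text(OBO_FIXTURE, encoding="utf-8")
    return path


@pytest.fixture()
def small_classes():
    """A small in-memory lexicon used across matcher tests."""
    return [
        am.OntologyClass("T:0001", "liver", (("hepar", "EXACT"),)),
        am.OntologyClass("T:0002", "kidney"),
        am.OntologyClass("T:0003", "bone marrow"),
        am.OntologyClass("T:0004", "femur"),
        am.OntologyClass("T:0005", "acetabulum"),
        am.OntologyClass("T:0006", "abdomen"),
        am.OntologyClass("T:0007", "artery"),
        am.OntologyClass("T:0008", "pyloric antrum"),
        am.OntologyClass("T:0009", "left ventricle of heart"),
        am.OntologyClass("T:0010", "right ventricle of heart"),
        am.OntologyClass("T:0011", "adrenal cortex"),
        am.OntologyClass("T:0012", "adrenal gland"),
        am.OntologyClass("T:0013", "esophagus"),
        am.OntologyClass("T:0014", "colon"),
    ]


@pytest.fixture()
def small_index(small_classes):
    return am.build_index(small_classes)


@pytest.fixture(scope="session")
def corpus_1000():
    """The standard synthetic world: 600-class ontology, 1000 corrupted terms."""
    ontology = am.generate_ontology(n_classes=600, seed=1)
    spec = am.CorruptionSpec(n_terms=1000, seed=1)
    return am.corrupt(ontology, spec)


@pytest.fixture(scope="session")
def corpus_1000_run(corpus_1000):
    """Cleaned terms, index, and a full-stages matcher run over corpus_1000."""
    index = am.build_index(corpus_1000.ontology)
    terms, dropped = am.clean_annotations(corpus_1000.annotations)
    config = am.MatchConfig(spellfix=True, shorthand_table=corpus_1000.shorthand_table)
    outcomes = am.run_matcher(terms, index, config)
    return {
        "index": index,
        "terms": terms,
        "dropped": dropped,
        "config": config,
        "outcomes": outcomes,
    }


def clean_term(text: str) -> am.CleanTerm:
    """Shortcut: an already-normalized query term."""
    return am.CleanTerm(original=text, normalized=text)
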