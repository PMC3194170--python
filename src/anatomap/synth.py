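"""Synthetic ontologies and annotation corpora with known ground truth.

The original annotation corpus behind this kind of study is rarely
deposited, so every stage of the pipeline is exercised against generated
data instead: a toy anatomy ontology built from a label grammar
(modifier + organ nouns), and an annotation list produced by sampling
classes and corrupting their labels according to a stated taxonomy of
real-world annotation defects — plural forms, adjectival forms, British
spellings, attached species names, whitespace/punctuation noise, single-edit
misspellings, composite terms, shorthand, procedure phrases, and
uninterpretable noise.

Because every annotation remembers the class (or classes) it was derived
from, the generator emits a perfect gold standard and a per-annotation
corruption label, so per-defect-class recovery rates are measurable exactly.
Generation is deterministic: identical spec + seed reproduces the corpus
bit for bit.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import tables
from .evaluate import GoldStandard, write_gold_tsv
from .normalize import NormalizerConfig, RawAnnotation, normalize_text, strip_species
from .ontology_io import OntologyClass
from .phonetic import double_metaphone

__all__ = [
    "CORRUPTION_CLASSES",
    "DEFAULT_PROPORTIONS",
    "CorruptionSpec",
    "SyntheticCorpus",
    "generate_ontology",
    "generate_dense_ontology",
    "corrupt",
    "write_corpus",
]

CORRUPTION_CLASSES = (
    "identity",
    "synonym_use",
    "plural",
    "adjectival",
    "anglicism",
    "species_suffix",
    "whitespace_punct",
    "misspelling_ed1",
    "composite_delimiter",
    "composite_locative",
    "shorthand",
    "process_phrase",
    "uninterpretable",
)

# Per-class sampling proportions. The source taxonomy gives no frequencies
# beyond "most mismatches were composites", so composites carry the largest
# combined share (0.20) and clean/exact terms a comparable one; the rest is
# spread to keep every class populated at n = 1000.
DEFAULT_PROPORTIONS: dict[str, float] = {
    "identity": 0.20,
    "synonym_use": 0.06,
    "plural": 0.08,
    "adjectival": 0.06,
    "anglicism": 0.05,
    "species_suffix": 0.07,
    "whitespace_punct": 0.08,
    "misspelling_ed1": 0.05,
    "composite_delimiter": 0.12,
    "composite_locative": 0.08,
    "shorthand": 0.05,
    "process_phrase": 0.04,
    "uninterpretable": 0.06,
}

# label grammar ------------------------------------------------------------

# organ nouns; most are nouns of the adjective table so adjectival
# corruption has targets, plus American-spelled words (esophagus, cecum,
# fiber) so Anglicism corruption has targets
_ORGANS = (
    "abdomen", "artery", "liver", "kidney", "heart", "stomach", "lung",
    "spleen", "cerebrum", "cerebellum", "pancreas", "trachea", "esophagus",
    "duodenum", "colon", "rectum", "bladder", "uterus", "ovary", "testis",
    "dermis", "cranium", "femur", "tibia", "sternum", "vertebra", "retina",
    "cornea", "tongue", "larynx", "pharynx", "aorta", "vein", "nerve",
    "muscle", "bone", "thymus", "cecum", "gland", "duct", "lobe", "cortex",
    "medulla", "septum", "valve", "ganglion", "follicle", "tendon",
    "ligament", "cartilage", "marrow", "membrane", "node", "fiber",
)

# positional/descriptive modifiers; "fetal" and "gray" have British
# spellings in the Anglicism table, widening Anglicism eligibility.
# None of these is a key of the adjective table.
_MODIFIERS = (
    "left", "right", "dorsal", "ventral", "anterior", "posterior", "medial",
    "lateral", "proximal", "distal", "superior", "inferior", "deep",
    "superficial", "accessory", "primitive", "embryonic", "fetal", "compact",
    "spongy", "ascending", "descending", "transverse", "circular",
    "longitudinal", "internal", "external", "central", "peripheral",
    "upper", "lower", "celiac", "hematopoietic", "gray",
)

# invented alternative nouns for synonym construction (latin-ish); organs
# without an entry get a "<label> structure" synonym instead
_SYNONYM_ALT = {
    "liver": "hepar",
    "kidney": "ren",
    "heart": "cor",
    "stomach": "gaster",
    "lung": "pulmo",
    "spleen": "lien",
    "artery": "arteria",
    "vein": "vena",
    "nerve": "nervus",
    "muscle": "musculus",
    "tongue": "lingua",
    "bladder": "vesica",
    "bone": "os",
    "esophagus": "gullet",
}

_AMERICAN_TO_BRITISH = {v: k for k, v in tables.ANGLICISMS.items()}
_NOUN_TO_ADJECTIVE = {
    noun: adj for adj, noun in tables.ADJECTIVE_TO_NOUN.items() if " " not in noun
}


@dataclass(frozen=True)
class CorruptionSpec:
    """The stated world: how many terms, corrupted how, under which seed."""

    n_terms: int = 1000
    seed: int = 0
    proportions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS)
    )
    duplicate_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_terms <= 0:
            raise ValueError("n_terms must be positive")
        unknown = set(self.proportions) - set(CORRUPTION_CLASSES)
        if unknown:
            raise ValueError(f"unknown corruption classes: {sorted(unknown)}")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, expected 1")
        if self.duplicate_fraction < 0:
            raise ValueError("duplicate_fraction must be >= 0")


@dataclass
class SyntheticCorpus:
    """A generated world: ontology, raw annotations, truth, and provenance."""

    ontology: list[OntologyClass]
    annotations: list[RawAnnotation]
    gold: GoldStandard
    labels: list[str]  # per-annotation corruption class
    shorthand_table: dict[str, tuple[str, ...]] = field(default_factory=dict)
    spec: CorruptionSpec | None = None


def generate_ontology(
    n_classes: int = 600,
    synonym_rate: float = 0.3,
    duplicate_label_count: int = 0,
    seed: int = 0,
) -> list[OntologyClass]:
    """Generate a toy anatomy ontology from the label grammar.

    Labels are unique "organ" / "modifier organ" / "modifier modifier organ"
    strings; an exact fraction of classes (``round(n * synonym_rate)``)
    carries one EXACT synonym; ``duplicate_label_count`` label collisions are
    injected by copying an early label onto a late class — the classic
    one-term-two-ids ontology defect.
    """
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    if duplicate_label_count * 2 > n_classes:
        raise ValueError("duplicate_label_count too large for n_classes")
    rng = random.Random(seed)

    labels: list[str] = []
    seen: set[str] = set()
    while len(labels) < n_classes:
        pattern = rng.choice((0, 1, 1, 2))  # favour one-modifier labels
        words = rng.sample(_MODIFIERS, pattern) + [rng.choice(_ORGANS)]
        label = " ".join(words)
        if label not in seen:
            seen.add(label)
            labels.append(label)

    n_syn = round(n_classes * synonym_rate)
    syn_slots = set(rng.sample(range(n_classes), n_syn))
    classes: list[OntologyClass] = []
    for i, label in enumerate(labels):
        synonyms: tuple[tuple[str, str], ...] = ()
        if i in syn_slots:
            organ = label.split()[-1]
            alt = _SYNONYM_ALT.get(organ)
            if alt is not None:
                syn_text = " ".join(label.split()[:-1] + [alt])
            else:
                syn_text = f"{label} structure"
            synonyms = ((syn_text, "EXACT"),)
        classes.append(
            OntologyClass(id=f"TOY:{i + 1:05d}", label=label, synonyms=synonyms)
        )

    # inject duplicate labels: last k classes re-use the first k labels
    for k in range(duplicate_label_count):
        src = classes[k]
        dup_idx = n_classes - 1 - k
        classes[dup_idx] = OntologyClass(
            id=classes[dup_idx].id,
            label=src.label,
            synonyms=(),
        )
    return classes


def generate_dense_ontology(
    n_groups: int = 20,
    group_size: int = 12,
    seed: int = 0,
) -> tuple[list[OntologyClass], list[str]]:
    """Generate a phonetically *dense* ontology plus query strings.

    Double Metaphone discards vowels after the first letter, so spelling
    variants of one consonant skeleton all share a code. Each group takes an
    organ word and emits ``group_size`` distinct vowel-substituted labels
    (one bucket of same-sounding classes), plus one further variant held out
    as a query. A proposal-generating phonetic matcher then proposes the
    whole bucket for every query — the regime where false-positive counts
    dwarf the term count.

    Returns ``(classes, queries)``; every query is absent from the ontology
    but phonetically identical to its group.
    """
    if n_groups < 1 or group_size < 1:
        raise ValueError("n_groups and group_size must be >= 1")
    rng = random.Random(seed)
    vowels = "aeiou"
    # avoid C/G: their sound depends on the following vowel, which defeats
    # code-preserving vowel substitution
    bases = [
        o
        for o in _ORGANS
        if len(o) >= 5
        and sum(c in vowels for c in o[1:]) >= 2
        and "c" not in o
        and "g" not in o
    ]
    if n_groups > len(bases):
        raise ValueError(f"at most {len(bases)} groups available")
    classes: list[OntologyClass] = []
    queries: list[str] = []
    picked = rng.sample(bases, n_groups)
    for g, base in enumerate(picked):
        code = double_metaphone(base)[0]
        slots = [i for i, c in enumerate(base) if i > 0 and c in vowels]
        variants: list[str] = []
        seen = {base}
        attempts = 0
        while len(variants) < group_size + 1 and attempts < 2000:
            attempts += 1
            chars = list(base)
            for i in rng.sample(slots, rng.randint(1, len(slots))):
                chars[i] = rng.choice(vowels)
            v = "".join(chars)
            if v not in seen:
                seen.add(v)
                # context-sensitive letters (c/g before e/i …) can shift the
                # code under a vowel swap; keep only code-preserving variants
                if double_metaphone(v)[0] == code:
                    variants.append(v)
        if len(variants) < group_size + 1:
            raise ValueError(f"cannot derive enough variants of {base!r}")
        for j, label in enumerate(variants[:group_size]):
            classes.append(OntologyClass(id=f"DNS:{g + 1:03d}{j + 1:03d}", label=label))
        queries.append(variants[group_size])
    return classes, queries


# --------------------------------------------------------------------------
# corruption rules

def _pluralize(word: str) -> str | None:
    if word in tables.PLURAL_EXCEPTIONS or word in tables.IRREGULAR_PLURALS.values():
        return None
    if word.endswith("y") and len(word) > 2 and word[-2] not in "aeiou":
        return word[:-1] + "ies"
    if word.endswith(("ch", "sh", "ss", "x", "z", "s")):
        return word + "es"
    return word + "s"


def _one_deletion(word: str, rng: random.Random) -> str:
    pos = rng.randrange(1, len(word))  # keep the first letter
    return word[:pos] + word[pos + 1 :]


class CorruptionError(RuntimeError):
    """A corruption rule could not be applied within the retry budget."""


def corrupt(
    ontology: Sequence[OntologyClass],
    spec: CorruptionSpec,
    config: NormalizerConfig | None = None,
) -> SyntheticCorpus:
    """Sample an annotation corpus from an ontology under a corruption spec.

    Each base annotation derives from one class (or two, for composites) by
    applying its assigned corruption rule; the gold standard maps the
    annotation's *pipeline-normalized* form to the deriving class ids
    (empty for uninterpretable noise). Base annotations are constructed with
    pairwise-distinct normalized forms, so after species stripping and
    deduplication exactly ``n_terms`` unique terms remain;
    ``duplicate_fraction`` then appends cross-species duplicate rows on top.

    Shorthand corruption synthesizes initialisms ("left kidney" -> "lk") and
    returns the shorthand table it used on the corpus, to be injected into
    the matcher for closed-world recovery runs.
    """
    if not ontology:
        raise ValueError("ontology must be non-empty")
    config = config or NormalizerConfig()
    rng = random.Random(spec.seed)

    live = [c for c in ontology if not c.obsolete]
    ids_by_label: dict[str, list[str]] = {}
    for c in live:
        ids_by_label.setdefault(c.label, []).append(c.id)
    vocab = {c.label for c in live} | {
        s for c in live for s, scope in c.synonyms if scope == "EXACT"
    }
    with_synonym = [c for c in live if c.synonyms]

    # largest-remainder apportionment of n_terms over the classes
    quotas: dict[str, int] = {}
    remainders: list[tuple[float, str]] = []
    for name in CORRUPTION_CLASSES:
        share = spec.proportions.get(name, 0.0) * spec.n_terms
        quotas[name] = int(share)
        remainders.append((share - int(share), name))
    shortfall = spec.n_terms - sum(quotas.values())
    for _, name in sorted(remainders, key=lambda t: (-t[0], t[1]))[:shortfall]:
        quotas[name] += 1

    species_pool = sorted(tables.SPECIES_MIXTURE)
    species_weights = [tables.SPECIES_MIXTURE[s] for s in species_pool]

    def pick_species() -> str:
        return rng.choices(species_pool, weights=species_weights, k=1)[0]

    def normalized_key(text: str, species: str) -> str:
        return normalize_text(strip_species(text, species), config).normalized

    used_keys: set[str] = set()
    annotations: list[RawAnnotation] = []
    labels: list[str] = []
    gold_map: dict[str, frozenset[str]] = {}
    shorthand_table: dict[str, tuple[str, ...]] = {}

    def survives_without_spellfix(text: str) -> bool:
        """A misspelling must not be rescued by a non-spellfix stage."""
        from .match import adjectival_to_noun, plural_variants

        if text in vocab or adjectival_to_noun(text) in vocab:
            return False
        return not any(v in vocab for v in plural_variants(text))

    def make_one(kind: str) -> tuple[str, str, frozenset[str]]:
        """Return (text, species, gold ids) for one base annotation."""
        species = pick_species()
        if kind == "identity":
            c = rng.choice(live)
            return c.label, species, frozenset(ids_by_label[c.label])
        if kind == "synonym_use":
            if not with_synonym:
                raise CorruptionError("no classes carry synonyms")
            c = rng.choice(with_synonym)
            return c.synonyms[0][0], species, frozenset([c.id])
        if kind == "plural":
            c = rng.choice(live)
            words = c.label.split()
            plural = _pluralize(words[-1])
            if plural is None:
                raise CorruptionError("head noun not pluralizable")
            text = " ".join(words[:-1] + [plural])
            if text in vocab:
                raise CorruptionError("plural collides with vocabulary")
            return text, species, frozenset(ids_by_label[c.label])
        if kind == "adjectival":
            c = rng.choice(live)
            words = c.label.split()
            adjective = _NOUN_TO_ADJECTIVE.get(words[-1])
            if adjective is None:
                raise CorruptionError("head noun has no adjective form")
            text = " ".join(words[:-1] + [adjective])
            if text in vocab:
                raise CorruptionError("adjectival form collides with vocabulary")
            return text, species, frozenset(ids_by_label[c.label])
        if kind == "anglicism":
            c = rng.choice(live)
            words = c.label.split()
            targets = [i for i, w in enumerate(words) if w in _AMERICAN_TO_BRITISH]
            if not targets:
                raise CorruptionError("label has no British-spellable word")
            i = rng.choice(targets)
            words[i] = _AMERICAN_TO_BRITISH[words[i]]
            return " ".join(words), species, frozenset(ids_by_label[c.label])
        if kind == "species_suffix":
            c = rng.choice(live)
            return f"{c.label} {species}", species, frozenset(ids_by_label[c.label])
        if kind == "whitespace_punct":
            c = rng.choice(live)
            words = c.label.split()
            style = rng.randrange(3)
            if style == 0:
                text = "  ".join(w.capitalize() for w in words) + " "
            elif style == 1 and len(words) > 1:
                text = "-".join(words).upper()
            else:
                text = f'"{c.label.title()}"'
            return text, species, frozenset(ids_by_label[c.label])
        if kind == "misspelling_ed1":
            c = rng.choice(live)
            words = c.label.split()
            long_idx = [i for i, w in enumerate(words) if len(w) > 4]
            if not long_idx:
                raise CorruptionError("no word long enough to misspell")
            i = rng.choice(long_idx)
            words[i] = _one_deletion(words[i], rng)
            text = " ".join(words)
            from .normalize import _within_distance_one

            neighbours = [v for v in vocab if _within_distance_one(text, v)]
            if neighbours != [c.label] or not survives_without_spellfix(text):
                raise CorruptionError("misspelling not uniquely recoverable")
            return text, species, frozenset(ids_by_label[c.label])
        if kind in ("composite_delimiter", "composite_locative"):
            a, b = rng.sample(live, 2)
            if a.label == b.label:
                raise CorruptionError("composite components share a label")
            if kind == "composite_delimiter":
                joiner = rng.choice(("/", ", "))
                text = f"{a.label}{joiner}{b.label}"
            else:
                connector = rng.choice(("flushed from", "derived from", "from"))
                text = f"{a.label}, {connector} {b.label}" if connector == "flushed from" else f"{a.label} {connector} {b.label}"
            ids = frozenset(ids_by_label[a.label]) | frozenset(ids_by_label[b.label])
            return text, species, ids
        if kind == "shorthand":
            c = rng.choice(live)
            words = c.label.split()
            if len(words) >= 2:
                key = "".join(w[0] for w in words)
            else:
                key = words[0][:3]
            if (
                len(key) < 2
                or key in vocab
                or key in shorthand_table
                or key in tables.ADJECTIVE_TO_NOUN
            ):
                raise CorruptionError("initialism unusable")
            shorthand_table[key] = (c.label,)
            return key, species, frozenset(ids_by_label[c.label])
        if kind == "process_phrase":
            c = rng.choice(live)
            phrase = rng.choice(("pinch biopsy", "lavage", "biopsy", "homogenate"))
            return f"{c.label} {phrase}", species, frozenset(ids_by_label[c.label])
        if kind == "uninterpretable":
            template = rng.choice(
                (
                    "{n} different tissues",
                    "mixed sample {n}",
                    "pool {n}",
                    "unknown tissue {n}",
                    "fraction {n}",
                )
            )
            return template.format(n=rng.randint(2, 999)), species, frozenset()
        raise ValueError(f"unknown corruption class {kind!r}")

    for kind in CORRUPTION_CLASSES:
        for _ in range(quotas[kind]):
            for _attempt in range(200):
                try:
                    text, species, ids = make_one(kind)
                except CorruptionError:
                    continue
                key = normalized_key(text, species)
                if key in used_keys:
                    if kind == "shorthand":  # undo speculative table entry
                        shorthand_table.pop(text, None)
                    continue
                used_keys.add(key)
                gold_map[key] = ids
                annotations.append(
                    RawAnnotation(text=text, species=species, source="synthetic")
                )
                labels.append(kind)
                break
            else:
                raise CorruptionError(
                    f"could not generate a fresh {kind} annotation after 200 tries"
                )

    # cross-species duplicate rows: same text, different species tag
    n_dups = round(spec.duplicate_fraction * spec.n_terms)
    base = len(annotations)
    for _ in range(n_dups):
        i = rng.randrange(base)
        original = annotations[i]
        other = pick_species()
        annotations.append(
            RawAnnotation(text=original.text, species=other, source="synthetic")
        )
        labels.append(labels[i])

    return SyntheticCorpus(
        ontology=list(ontology),
        annotations=annotations,
        gold=GoldStandard(map=gold_map),
        labels=labels,
        shorthand_table=shorthand_table,
        spec=spec,
    )


# --------------------------------------------------------------------------
# fixture output

def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> dict[str, Path]:
    """Write the corpus as text fixtures: OBO, term TSV, gold TSV, labels TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "obo": out_dir / "ontology.obo",
        "terms": out_dir / "terms.tsv",
        "gold": out_dir / "gold.tsv",
        "labels": out_dir / "labels.tsv",
    }
    with open(paths["obo"], "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\n")
        for c in corpus.ontology:
            fh.write("\n[Term]\n")
            fh.write(f"id: {c.id}\n")
            fh.write(f"name: {c.label}\n")
            for text, scope in c.synonyms:
                fh.write(f'synonym: "{text}" {scope} []\n')
            if c.obsolete:
                fh.write("is_obsolete: true\n")
    with open(paths["terms"], "w", encoding="utf-8") as fh:
        for ann in corpus.annotations:
            fh.write(f"{ann.text}\t{ann.species}\n")
    write_gold_tsv(corpus.gold, paths["gold"])
    with open(paths["labels"], "w", encoding="utf-8") as fh:
        for ann, label in zip(corpus.annotations, corpus.labels):
            fh.write(f"{ann.text}\t{label}\n")
    return paths
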