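"""Ontology lexical surface: OBO parsing, term indexing and lexical QC.

Only the lexical layer of an ontology matters for string matching — class
ids, primary labels, synonyms with their scopes, and obsolescence flags. The
graph structure (is_a/part_of) is deliberately ignored.

The :class:`TermIndex` is the searchable artifact: every admitted label and
synonym is normalized with the same configuration used for queries and keyed
both by its normalized string (exact lookup) and by its Double Metaphone
codes (phonetic lookup). QC helpers surface duplicate labels — the kind of
defect where one ontology carries the same term twice under two ids — and
quantify lexical overlap between two ontologies.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .normalize import NormalizerConfig, normalize_text, UnusableAnnotationError
from .phonetic import encode_phrase

__all__ = [
    "SYNONYM_SCOPES",
    "OntologyClass",
    "TermIndex",
    "OboParseError",
    "parse_obo",
    "parse_lexicon_tsv",
    "build_index",
    "find_duplicate_labels",
    "lexical_overlap",
    "write_duplicate_report",
]

SYNONYM_SCOPES = ("EXACT", "BROAD", "NARROW", "RELATED")


class OboParseError(ValueError):
    """Malformed OBO stanza (e.g. a [Term] without an id)."""


@dataclass(frozen=True)
class OntologyClass:
    """One ontology class reduced to its lexical surface."""

    id: str
    label: str
    synonyms: tuple[tuple[str, str], ...] = ()  # (text, scope)
    obsolete: bool = False

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ontology class id must be non-empty")
        if not self.obsolete and not self.label:
            raise ValueError(f"non-obsolete class {self.id} has empty label")
        for _, scope in self.synonyms:
            if scope not in SYNONYM_SCOPES:
                raise ValueError(f"unknown synonym scope {scope!r} on {self.id}")


@dataclass
class TermIndex:
    """Normalized-string and phonetic-code lookup over an ontology.

    ``lexical_map`` maps a normalized string to the set of
    ``(class_id, origin)`` pairs carrying it, where origin is ``"label"`` or
    ``"synonym:<SCOPE>"``. ``phonetic_map`` maps a primary-or-alternate
    phrase code to the normalized strings producing it; every such string is
    a key of ``lexical_map``.
    """

    lexical_map: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    phonetic_map: dict[str, set[str]] = field(default_factory=dict)
    normalizer_config: NormalizerConfig = field(default_factory=NormalizerConfig)

    def keys(self) -> set[str]:
        return set(self.lexical_map)

    def __len__(self) -> int:
        return len(self.lexical_map)


# ---------------------------------------------------------------------------
# parsing

def _unquote_obo(value: str) -> tuple[str, str]:
    """Split an OBO quoted-string tag value into (text, trailer)."""
    if not value.startswith('"'):
        return value, ""
    end = 1
    while end < len(value):
        if value[end] == '"' and value[end - 1] != "\\":
            break
        end += 1
    text = value[1:end].replace('\\"', '"')
    return text, value[end + 1 :].strip()


def parse_obo(path: str | Path) -> list[OntologyClass]:
    """Parse an OBO 1.2/1.4 flat file into ontology classes.

    Reads the tags the lexical layer needs (``id``, ``name``, ``synonym``,
    ``is_obsolete``) from each ``[Term]`` stanza and ignores everything else.
    Synonym scope defaults to RELATED when the scope keyword is absent, per
    the OBO specification.
    """
    classes: list[OntologyClass] = []
    in_term = False
    cur: dict | None = None
    stanza_line = 0

    def flush() -> None:
        nonlocal cur
        if cur is None:
            return
        if "id" not in cur:
            raise OboParseError(f"[Term] stanza starting at line {stanza_line} has no id")
        classes.append(
            OntologyClass(
                id=cur["id"],
                label=cur.get("name", ""),
                synonyms=tuple(cur.get("synonyms", [])),
                obsolete=cur.get("obsolete", False),
            )
        )
        cur = None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("!", 1)[0].strip() if not raw.lstrip().startswith("!") else ""
            if not line:
                continue
            if line.startswith("["):
                flush()
                in_term = line == "[Term]"
                if in_term:
                    cur = {}
                    stanza_line = lineno
                continue
            if not in_term or cur is None:
                continue
            if ":" not in line:
                raise OboParseError(f"line {lineno}: tag without value: {line!r}")
            tag, _, value = line.partition(":")
            tag = tag.strip()
            value = value.strip()
            if tag == "id":
                cur["id"] = value
            elif tag == "name":
                cur["name"] = value
            elif tag == "is_obsolete":
                cur["obsolete"] = value.lower() == "true"
            elif tag == "synonym":
                text, trailer = _unquote_obo(value)
                scope = "RELATED"
                first = trailer.split(" ", 1)[0].split("[", 1)[0].strip()
                if first in SYNONYM_SCOPES:
                    scope = first
                cur.setdefault("synonyms", []).append((text, scope))
    flush()

    ids = [c.id for c in classes]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise OboParseError(f"duplicate class ids in {path}: {dupes}")
    return classes


def parse_lexicon_tsv(path: str | Path) -> list[OntologyClass]:
    """Read a minimal 2-column lexicon (``id<TAB>label``) as ontology classes."""
    classes: list[OntologyClass] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE):
            if not row or not row[0].strip():
                continue
            classes.append(OntologyClass(id=row[0].strip(), label=row[1].strip()))
    return classes


# ---------------------------------------------------------------------------
# indexing

def build_index(
    classes: Sequence[OntologyClass],
    config: NormalizerConfig | None = None,
    synonym_scopes: Sequence[str] = ("EXACT",),
    include_obsolete: bool = False,
) -> TermIndex:
    """Build the exact + phonetic lookup index over an ontology.

    Non-obsolete labels are always indexed; synonyms are admitted per scope
    (EXACT only by default — a conservative choice, since BROAD/RELATED
    synonyms invite false positives). Rebuilding from the same classes and
    config yields an identical index.
    """
    if not classes:
        raise ValueError("cannot index an empty class list")
    config = config or NormalizerConfig()
    index = TermIndex(normalizer_config=config)

    def insert(text: str, class_id: str, origin: str) -> None:
        try:
            clean = normalize_text(text, config)
        except UnusableAnnotationError:
            return
        key = clean.normalized
        index.lexical_map.setdefault(key, set()).add((class_id, origin))
        primary, alternate = encode_phrase(key)
        for code in {primary, alternate} - {""}:
            index.phonetic_map.setdefault(code, set()).add(key)

    for cls in classes:
        if cls.obsolete and not include_obsolete:
            continue
        if cls.label:
            insert(cls.label, cls.id, "label")
        for text, scope in cls.synonyms:
            if scope in synonym_scopes:
                insert(text, cls.id, f"synonym:{scope}")
    return index


# ---------------------------------------------------------------------------
# QC

def find_duplicate_labels(
    classes: Sequence[OntologyClass],
    config: NormalizerConfig | None = None,
) -> list[tuple[str, list[str]]]:
    """Find labels carried by two or more distinct non-obsolete classes.

    The comparison is on normalized labels, so "Ureter" and "ureter" under
    two ids count as one duplicated label. Output is ordered by label then
    id for deterministic QC reports.
    """
    config = config or NormalizerConfig()
    by_label: dict[str, set[str]] = {}
    for cls in classes:
        if cls.obsolete or not cls.label:
            continue
        try:
            key = normalize_text(cls.label, config).normalized
        except UnusableAnnotationError:
            continue
        by_label.setdefault(key, set()).add(cls.id)
    return [
        (label, sorted(ids))
        for label, ids in sorted(by_label.items())
        if len(ids) >= 2
    ]


def lexical_overlap(a: TermIndex, b: TermIndex) -> float:
    """Jaccard overlap (percentage) between two indexes' normalized strings.

    Symmetric by construction: 100 × |A ∩ B| / |A ∪ B|. Both indexes must
    have been built with the same normalizer configuration, otherwise equal
    surface strings may normalize apart and the overlap is meaningless.
    """
    if a.normalizer_config != b.normalizer_config:
        raise ValueError("indexes built with different normalizer configs")
    keys_a, keys_b = a.keys(), b.keys()
    union = keys_a | keys_b
    if not union:
        return 100.0
    return 100.0 * len(keys_a & keys_b) / len(union)


def write_duplicate_report(
    duplicates: Iterable[tuple[str, list[str]]], path: str | Path
) -> None:
    """Write the duplicate-label QC report: ``label<TAB>comma-joined ids``."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n", quoting=csv.QUOTE_NONE)
        for label, ids in duplicates:
            writer.writerow([label, ",".join(ids)])
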