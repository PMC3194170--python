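"""Annotation preprocessing: the cleanup that turns verbatim, user-submitted
anatomy annotations into matchable terms.

The transformations mirror what a curator does before lexical matching:
species names are stripped from the structure term, whitespace and sentence
casing are regularized, punctuation/hyphenation unified, non-printing
characters removed (these are invisible to a human but defeat exact string
matching), and British spellings converted to the American forms that anatomy
ontologies use as primary labels. Terms that were distinct only because of an
attached species collapse to one.

Every applied transformation is recorded on the resulting :class:`CleanTerm`
as an ordered provenance trail, and normalization is idempotent: cleaning a
clean term is a no-op.
"""

from __future__ import annotations

import csv
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import tables

__all__ = [
    "NormalizerConfig",
    "RawAnnotation",
    "CleanTerm",
    "UnusableAnnotationError",
    "strip_species",
    "normalize_text",
    "deduplicate",
    "duplicate_groups",
    "spellfix",
    "read_term_tsv",
    "write_clean_tsv",
]

STEP_TAGS = (
    "species_strip",
    "whitespace",
    "casefold",
    "punctuation",
    "americanize",
    "control_char_strip",
    "spellfix",
)


class UnusableAnnotationError(ValueError):
    """Raised when an annotation is empty after cleaning (nothing to match)."""


@dataclass(frozen=True)
class NormalizerConfig:
    """Settings shared by index construction and query normalization.

    Both sides of a match *must* be normalized identically, otherwise the
    exact matcher compares apples to oranges; indexes therefore remember the
    config they were built with.
    """

    hyphen_to_space: bool = True
    americanize: bool = True
    strip_control_chars: bool = True
    anglicisms: Mapping[str, str] = field(default_factory=lambda: dict(tables.ANGLICISMS))

    def fingerprint(self) -> str:
        items = ";".join(f"{k}>{v}" for k, v in sorted(self.anglicisms.items()))
        return f"h2s={self.hyphen_to_space}|am={self.americanize}|cc={self.strip_control_chars}|tbl={hash(items) & 0xFFFFFFFF:08x}"


@dataclass(frozen=True)
class RawAnnotation:
    """A verbatim annotation row: free-text term plus its species tag."""

    text: str
    species: str = ""
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.text.strip():
            raise ValueError("annotation text empty after whitespace trim")


@dataclass(frozen=True)
class CleanTerm:
    """A normalized term with the transformations that produced it."""

    original: str
    normalized: str
    steps: tuple[str, ...] = ()


# C0/C1 controls plus zero-width and bidi marks: invisible to a curator's eye
# but fatal to exact string matching
_CONTROL_RE = re.compile(
    "[\\x00-\\x1f\\x7f\\u00ad\\u200b-\\u200f\\ufeff]"
)
_WS_RE = re.compile(r"\s+")
_PUNCT_STRIP_RE = re.compile(r"[\"'`´’‘“”.!?*_]")


def _collapse_ws(text: str) -> str:
    return _WS_RE.sub(" ", text).strip()


def strip_species(
    text: str,
    species: str = "",
    lexicon: Sequence[str] = tables.SPECIES_LEXICON,
) -> str:
    """Remove species names from an anatomical term.

    Whole-word occurrences of the paired binomial (and each of its words when
    the full binomial is absent) and of any lexicon entry are deleted;
    surrounding whitespace collapses. A term that mentions no species passes
    through unchanged.
    """
    result = text
    phrases: list[str] = []
    if species and species.strip():
        phrases.append(species.strip())
    phrases.extend(e for e in lexicon if e.strip())
    # longest first so "xenopus laevis" wins over "xenopus"
    for phrase in sorted(set(phrases), key=len, reverse=True):
        pattern = re.compile(
            r"(?<![a-z0-9])" + re.escape(phrase) + r"(?![a-z0-9])", re.IGNORECASE
        )
        result = pattern.sub(" ", result)
    return _collapse_ws(result)


def normalize_text(text: str, config: NormalizerConfig | None = None) -> CleanTerm:
    """Normalize one annotation string, recording which rules fired.

    Order is fixed — control characters, whitespace, case, punctuation,
    Americanization — so the provenance trail is deterministic. Raises
    :class:`UnusableAnnotationError` when nothing survives cleaning.
    """
    if config is None:
        config = NormalizerConfig()
    if not text:
        raise UnusableAnnotationError("empty annotation")

    steps: list[str] = []
    current = unicodedata.normalize("NFC", text)

    if config.strip_control_chars:
        stripped = _CONTROL_RE.sub("", current)
        if stripped != current:
            steps.append("control_char_strip")
        current = stripped

    collapsed = _collapse_ws(current)
    if collapsed != current:
        steps.append("whitespace")
    current = collapsed

    folded = current.casefold()
    if folded != current:
        steps.append("casefold")
    current = folded

    # punctuation unification: hyphens/slashes kept (slashes are composite
    # separators), quotes and terminal punctuation dropped, hyphens optionally
    # opened to spaces so "fore-limb" and "fore limb" coincide
    depunct = _PUNCT_STRIP_RE.sub("", current)
    if config.hyphen_to_space:
        depunct = re.sub(r"[-‐‑–—]+", " ", depunct)
    depunct = _collapse_ws(depunct)
    if depunct != current:
        steps.append("punctuation")
    current = depunct

    if config.americanize and current:
        words = current.split(" ")
        replaced = [config.anglicisms.get(w, w) for w in words]
        if replaced != words:
            steps.append("americanize")
        current = " ".join(replaced)

    if not current:
        raise UnusableAnnotationError(f"annotation unusable after cleaning: {text!r}")
    return CleanTerm(original=text, normalized=current, steps=tuple(steps))


def deduplicate(terms: Iterable[CleanTerm]) -> list[CleanTerm]:
    """Collapse terms with equal normalized forms, keeping first occurrences.

    Terms unique only because they carried different species names become a
    single term once species are stripped; this removes those duplicates
    while preserving input order.
    """
    seen: set[str] = set()
    kept: list[CleanTerm] = []
    for term in terms:
        if term.normalized not in seen:
            seen.add(term.normalized)
            kept.append(term)
    return kept


def duplicate_groups(terms: Iterable[CleanTerm]) -> dict[str, list[str]]:
    """Report of collapsed groups: normalized form -> original strings (only
    for forms seen more than once). Useful for audit logging."""
    groups: dict[str, list[str]] = {}
    for term in terms:
        groups.setdefault(term.normalized, []).append(term.original)
    return {k: v for k, v in groups.items() if len(v) > 1}


def _within_distance_one(a: str, b: str) -> bool:
    """True iff Levenshtein distance(a, b) <= 1 (direct check, no DP table)."""
    if a == b:
        return True
    la, lb = len(a), len(b)
    if abs(la - lb) > 1:
        return False
    if la == lb:  # exactly one substitution allowed
        return sum(x != y for x, y in zip(a, b)) == 1
    if la > lb:
        a, b, la, lb = b, a, lb, la
    # b is longer by one: one deletion from b must yield a
    i = 0
    while i < la and a[i] == b[i]:
        i += 1
    return a[i:] == b[i + 1 :]


def spellfix(text: str, vocabulary: Iterable[str]) -> str:
    """Repair an obvious misspelling against an indexed vocabulary.

    Off by default in the pipeline: the original cleanup was manual, and
    automated repair is conservative here — the input is replaced only when
    exactly one vocabulary entry lies at edit distance 1. Exact members and
    ambiguous inputs pass through unchanged.
    """
    vocab = set(vocabulary)
    if text in vocab:
        return text
    neighbours = [v for v in vocab if _within_distance_one(text, v)]
    if len(neighbours) == 1:
        return neighbours[0]
    return text


def read_term_tsv(path: str | Path, header: bool = False) -> list[RawAnnotation]:
    """Read an annotation list: ``term<TAB>species`` (species optional), UTF-8."""
    annotations: list[RawAnnotation] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
        for i, row in enumerate(reader):
            if header and i == 0:
                continue
            if not row or not row[0].strip():
                continue
            species = row[1].strip() if len(row) > 1 else ""
            annotations.append(RawAnnotation(text=row[0], species=species))
    return annotations


def write_clean_tsv(terms: Sequence[CleanTerm], path: str | Path) -> None:
    """Write cleaned terms with a semicolon-joined provenance column."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n", quoting=csv.QUOTE_NONE)
        writer.writerow(["original", "normalized", "steps"])
        for t in terms:
            writer.writerow([t.original, t.normalized, ";".join(t.steps)])
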