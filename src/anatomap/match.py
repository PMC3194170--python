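"""Exact and phonetic term matchers plus morphological variant handling.

Two matching philosophies are implemented side by side:

* **exact** — a term matches a class only when its normalized string equals
  an indexed label or synonym. No false positives by construction, many
  false negatives (the strict-matcher regime).
* **phonetic** — terms and index strings are reduced to Double Metaphone
  codes and compared by sound. Highly sensitive, prone to false positives,
  so phonetic hits are *proposals* for a curator, never auto-accepted.

Between the two sit cheap query rewrites that recover the classic annotation
gaps: plural forms ("kidneys" vs the singular ontology label), adjectival
forms ("abdominal" for "abdomen"), and shorthand ("antrum" for "pyloric
antrum", "both ventricles" for the two ventricle classes). Each rewrite
re-enters the exact matcher, so every accepted hit is auditable as an exact
match on a stated rewrite.

The cascade per term: exact → variant rewrites → composite decomposition →
phonetic proposals. Accepted sets contain exact-tier matches only unless a
curation file supplies decisions on proposals.
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import tables
from .composite import CompositeConfig, cross_product_match, split_composite, strip_process_phrases
from .normalize import CleanTerm, _within_distance_one, spellfix
from .ontology_io import TermIndex
from .phonetic import encode_phrase

__all__ = [
    "MatchConfig",
    "Candidate",
    "MappingOutcome",
    "CurationError",
    "exact_match",
    "phonetic_match",
    "plural_variants",
    "adjectival_to_noun",
    "expand_shorthand",
    "run_matcher",
    "write_match_files",
    "read_curation_tsv",
]

EXACT_KINDS = (
    "exact_label",
    "exact_synonym",
    "plural_variant",
    "adjectival",
    "shorthand",
    "spellfix",
    "composite",
)


@dataclass(frozen=True)
class MatchConfig:
    """Stage toggles and tables for one matcher run."""

    plural: bool = True
    adjectival: bool = True
    shorthand: bool = True
    composite: bool = True
    phonetic: bool = False
    spellfix: bool = False
    levenshtein: bool = False  # future-work hook: distance-1 accept, off by default
    composite_policy: str = "any"
    adjective_table: Mapping[str, str] = field(default_factory=lambda: dict(tables.ADJECTIVE_TO_NOUN))
    shorthand_table: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: {k: tuple(v) for k, v in tables.SHORTHAND.items()}
    )
    composite_config: CompositeConfig = field(default_factory=CompositeConfig)


@dataclass(frozen=True)
class Candidate:
    """One proposed (query -> class) pair with its evidence and rank."""

    query: CleanTerm
    class_id: str
    match_kind: str
    evidence: str
    rank: int


@dataclass(frozen=True)
class MappingOutcome:
    """Per-query result: accepted ids, ranked proposals, and a status."""

    query: CleanTerm
    accepted: frozenset[str]
    proposed: tuple[Candidate, ...]
    status: str  # matched | proposed_only | unmatched

    def __post_init__(self) -> None:
        expected = (
            "matched"
            if self.accepted
            else ("proposed_only" if self.proposed else "unmatched")
        )
        if self.status != expected:
            raise ValueError(f"status {self.status!r} inconsistent with contents")


class CurationError(ValueError):
    """Curation file references terms absent from the run."""


# ---------------------------------------------------------------------------
# single-stage matchers

def exact_match(term: CleanTerm, index: TermIndex) -> list[Candidate]:
    """All classes whose indexed string equals the term's normalized form.

    Label hits rank above synonym hits; ties break on class id so duplicate
    labels (one string under two ids) come back in a stable order.
    """
    hits = index.lexical_map.get(term.normalized, set())
    ordered = sorted(hits, key=lambda h: (0 if h[1] == "label" else 1, h[0]))
    return [
        Candidate(
            query=term,
            class_id=cid,
            match_kind="exact_label" if origin == "label" else "exact_synonym",
            evidence=term.normalized,
            rank=i + 1,
        )
        for i, (cid, origin) in enumerate(ordered)
    ]


def phonetic_match(term: CleanTerm, index: TermIndex) -> list[Candidate]:
    """Classes whose indexed strings *sound* like the term.

    Primary-code agreement outranks alternate-code agreement; within a tier,
    candidates order by token-count difference from the query, then by the
    matched string, then by class id. Strings identical to the query are
    suppressed — they are already exact matches, and repeating them as
    phonetic proposals is noise.
    """
    primary, alternate = encode_phrase(term.normalized)
    if not primary and not alternate:
        return []
    n_tokens = len(term.normalized.split())

    tiers: list[tuple[int, str]] = []
    seen_strings: set[str] = set()
    for tier, code in enumerate(dict.fromkeys([primary, alternate])):
        if not code:
            continue
        for matched in sorted(index.phonetic_map.get(code, ())):
            if matched == term.normalized or matched in seen_strings:
                continue
            seen_strings.add(matched)
            tiers.append((tier, matched))

    keyed = sorted(
        (
            (tier, abs(len(matched.split()) - n_tokens), matched, cid)
            for tier, matched in tiers
            for cid, _origin in sorted(index.lexical_map.get(matched, ()))
        ),
    )
    out: list[Candidate] = []
    seen_pairs: set[tuple[str, str]] = set()
    for tier, _tokdiff, matched, cid in keyed:
        if (matched, cid) in seen_pairs:
            continue
        seen_pairs.add((matched, cid))
        code = primary if tier == 0 else alternate
        out.append(
            Candidate(
                query=term,
                class_id=cid,
                match_kind="phonetic",
                evidence=f"{matched}|code={code}",
                rank=len(out) + 1,
            )
        )
    return out


# ---------------------------------------------------------------------------
# variant rewrites

def _singularize_word(word: str) -> list[str]:
    if word in tables.PLURAL_EXCEPTIONS:
        return []
    if word in tables.IRREGULAR_PLURALS:
        return [tables.IRREGULAR_PLURALS[word]]
    out: list[str] = []
    if word.endswith("ies") and len(word) > 4:
        out.append(word[:-3] + "y")
    elif word.endswith("es") and len(word) > 3:
        # "lobes" -> "lobe"; "arches" -> "arch" (sibilant stems take -es)
        if word.endswith(("ches", "shes", "sses", "xes", "zes")):
            out.append(word[:-2])
        else:
            out.append(word[:-1])
            out.append(word[:-2])
    elif word.endswith("s") and not word.endswith("ss") and len(word) > 3:
        out.append(word[:-1])
    return out


def plural_variants(text: str) -> list[str]:
    """Candidate singular forms of a possibly-plural annotation.

    Ontology classes are written in the singular while annotators use both;
    this proposes singularizations of the *last* word (anatomy terms are
    head-final: "mammary glands"). Exception words ("pancreas") and known
    Latin plurals are handled before the English -ies/-es/-s rules.
    """
    words = text.split()
    if not words:
        return []
    head = words[-1]
    variants = [" ".join(words[:-1] + [s]) for s in _singularize_word(head)]
    return [v for v in dict.fromkeys(variants) if v != text]


def adjectival_to_noun(text: str, table: Mapping[str, str] | None = None) -> str:
    """Rewrite anatomical adjectives to their nouns, one pass, whole words.

    "abdominal" -> "abdomen"; words absent from the table pass through, so
    an unknown adjective leaves the string unchanged.
    """
    table = table if table is not None else tables.ADJECTIVE_TO_NOUN
    words = text.split()
    rewritten = [table.get(w, w) for w in words]
    return " ".join(rewritten)


def expand_shorthand(
    text: str, table: Mapping[str, Sequence[str]] | None = None
) -> list[str]:
    """Expand curator shorthand to the full class labels it denotes.

    One shorthand may expand to several labels ("both ventricles" names two
    classes). Unknown input expands to itself.
    """
    table = table if table is not None else tables.SHORTHAND
    expansion = table.get(text)
    if expansion is None:
        return [text]
    return list(expansion)


# ---------------------------------------------------------------------------
# cascade

def _rewrite_candidates(
    term: CleanTerm, index: TermIndex, config: MatchConfig
) -> list[Candidate]:
    """Variant rewrites re-entering the exact matcher, in cascade order."""
    out: list[Candidate] = []

    def try_exact(rewritten: str, kind: str) -> list[Candidate]:
        probe = replace(term, normalized=rewritten)
        return [
            Candidate(
                query=term,
                class_id=c.class_id,
                match_kind=kind,
                evidence=f"rewrite={rewritten}",
                rank=0,
            )
            for c in exact_match(probe, index)
        ]

    if config.plural:
        for variant in plural_variants(term.normalized):
            out.extend(try_exact(variant, "plural_variant"))
            if out:
                return out
    if config.adjectival:
        rewritten = adjectival_to_noun(term.normalized, config.adjective_table)
        if rewritten != term.normalized:
            out.extend(try_exact(rewritten, "adjectival"))
            if out:
                return out
    if config.shorthand:
        expansions = expand_shorthand(term.normalized, config.shorthand_table)
        if expansions != [term.normalized]:
            hits: list[Candidate] = []
            for exp in expansions:
                hits.extend(try_exact(exp, "shorthand"))
            if hits:
                return hits
    if config.spellfix:
        fixed = spellfix(term.normalized, index.lexical_map.keys())
        if fixed != term.normalized:
            out.extend(try_exact(fixed, "spellfix"))
            if out:
                return out
    if config.levenshtein:
        # optional fuzzy stage (off by default): unique distance-1 index key
        neighbours = [
            k for k in index.lexical_map if _within_distance_one(term.normalized, k)
        ]
        if len(neighbours) == 1:
            out.extend(try_exact(neighbours[0], "spellfix"))
    return out


def _match_one(term: CleanTerm, index: TermIndex, config: MatchConfig) -> tuple[list[Candidate], list[Candidate]]:
    """Return (accepted-tier candidates, proposal-tier candidates) for a term."""
    accepted = exact_match(term, index)
    if not accepted:
        accepted = _rewrite_candidates(term, index, config)
    if not accepted and config.composite:
        stripped = strip_process_phrases(
            term.normalized, config.composite_config.stop_phrases
        )
        if stripped and stripped != term.normalized:
            probe = replace(term, normalized=stripped)
            accepted = [
                replace(c, query=term, match_kind="composite", evidence=f"process_strip={stripped}")
                for c in exact_match(probe, index)
            ]
            if not accepted:
                accepted = [
                    replace(c, query=term)
                    for c in _rewrite_candidates(probe, index, config)
                ]
        if not accepted:
            target = stripped or term.normalized
            decomp = split_composite(target, config.composite_config)
            if decomp.kind != "none":
                accepted = [
                    replace(c, query=term)
                    for c in cross_product_match(decomp, index, config.composite_policy)
                ]

    proposals: list[Candidate] = []
    if config.phonetic:
        accepted_ids = {c.class_id for c in accepted}
        for cand in phonetic_match(term, index):
            if cand.class_id in accepted_ids:
                continue
            proposals.append(cand)

    # global re-ranking: exact tier first, in stage order, then proposals
    ranked: list[Candidate] = []
    for cand in accepted + proposals:
        ranked.append(replace(cand, rank=len(ranked) + 1))
    n_accept = len(accepted)
    return ranked[:n_accept], ranked[n_accept:]


def run_matcher(
    terms: Sequence[CleanTerm],
    index: TermIndex,
    config: MatchConfig | None = None,
    curation: Mapping[str, Sequence[str]] | None = None,
) -> list[MappingOutcome]:
    """Run the full matching cascade over a term list.

    Accepted sets contain exact-tier matches (including variant and composite
    rewrites); phonetic candidates are proposals unless *curation* maps a
    term's normalized form to class ids, in which case those proposals are
    promoted. A curation entry naming an unknown term is an error — silent
    typos in curation files corrupt evaluations.
    """
    config = config or MatchConfig()
    if curation:
        known = {t.normalized for t in terms}
        unknown = sorted(set(curation) - known)
        if unknown:
            raise CurationError(f"curation references unknown terms: {unknown}")

    outcomes: list[MappingOutcome] = []
    for term in terms:
        accepted_cands, proposals = _match_one(term, index, config)
        accepted = {c.class_id for c in accepted_cands}
        if curation and term.normalized in curation:
            promoted = set(curation[term.normalized])
            proposal_ids = {c.class_id for c in proposals}
            accepted |= promoted & proposal_ids
            proposals = [c for c in proposals if c.class_id not in accepted]
        status = (
            "matched" if accepted else ("proposed_only" if proposals else "unmatched")
        )
        outcomes.append(
            MappingOutcome(
                query=term,
                accepted=frozenset(accepted),
                proposed=tuple(accepted_cands + proposals),
                status=status,
            )
        )
    return outcomes


# ---------------------------------------------------------------------------
# I/O

def read_curation_tsv(path: str | Path) -> dict[str, list[str]]:
    """Read curation decisions: ``term<TAB>class_id`` (repeatable per term)."""
    decisions: dict[str, list[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE):
            if not row or not row[0].strip():
                continue
            decisions.setdefault(row[0].strip(), []).append(row[1].strip())
    return decisions


def write_match_files(
    outcomes: Iterable[MappingOutcome],
    out_dir: str | Path,
    timestamp: str,
) -> tuple[Path, Path]:
    """Write the two per-run report files: matches and failures.

    ``matches_<timestamp>.tsv`` holds one row per candidate of each matched
    or proposed term; ``failures_<timestamp>.tsv`` one row per unmatched
    term. Timestamps live only in the filenames so contents stay diffable.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    matches_path = out_dir / f"matches_{timestamp}.tsv"
    failures_path = out_dir / f"failures_{timestamp}.tsv"
    with open(matches_path, "w", newline="", encoding="utf-8") as mfh, open(
        failures_path, "w", newline="", encoding="utf-8"
    ) as ffh:
        mw = csv.writer(mfh, delimiter="\t", lineterminator="\n", quoting=csv.QUOTE_NONE)
        fw = csv.writer(ffh, delimiter="\t", lineterminator="\n", quoting=csv.QUOTE_NONE)
        mw.writerow(["term", "class_id", "match_kind", "evidence", "rank", "accepted"])
        fw.writerow(["term", "reason"])
        for outcome in outcomes:
            if outcome.status == "unmatched":
                reason = (
                    "uninterpretable"
                    if re.search(r"\d", outcome.query.normalized)
                    else "no_lexical_match"
                )
                fw.writerow([outcome.query.normalized, reason])
                continue
            for cand in outcome.proposed:
                mw.writerow(
                    [
                        outcome.query.normalized,
                        cand.class_id,
                        cand.match_kind,
                        cand.evidence,
                        cand.rank,
                        "1" if cand.class_id in outcome.accepted else "0",
                    ]
                )
    return matches_path, failures_path
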