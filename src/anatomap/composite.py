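"""Composite-annotation decomposition and component-wise matching.

Annotators pack several anatomical entities into one string — "liver/kidney",
"acetabulum and pelvic soft tissues", "bone marrow, flushed from femur" — and
such strings match nothing as a whole even when every component is in the
ontology. This module splits a normalized annotation into components along
explicit delimiters, conjunctions and locative connector phrases, then
exact-matches each component independently (a poor man's searchable
cross-product).

"of" is *not* a separator: "left ventricle of heart" is one entity. Only
configured connector phrases ("flushed from", "derived from", bare "from")
mark a boundary. Procedure phrases that imply a location without naming one
("pinch biopsy", "lavage") are stripped before matching.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

from . import tables

if TYPE_CHECKING:  # pragma: no cover
    from .ontology_io import TermIndex

__all__ = [
    "CompositeConfig",
    "Decomposition",
    "split_composite",
    "cross_product_match",
    "strip_process_phrases",
]


@dataclass(frozen=True)
class CompositeConfig:
    delimiters: tuple[str, ...] = tables.DELIMITERS
    conjunctions: tuple[str, ...] = tables.CONJUNCTIONS
    locative_connectors: tuple[str, ...] = tables.LOCATIVE_CONNECTORS
    stop_phrases: tuple[str, ...] = tables.PROCESS_STOP_PHRASES


@dataclass(frozen=True)
class Decomposition:
    """Result of splitting one annotation into candidate entities."""

    original: str
    components: tuple[str, ...]
    separators_used: tuple[str, ...] = ()
    kind: str = "none"  # delimiter | conjunction | locative | none


def strip_process_phrases(
    text: str, stop_phrases: Sequence[str] = tables.PROCESS_STOP_PHRASES
) -> str:
    """Remove procedure words ("colon pinch biopsy" -> "colon").

    Longest phrases are removed first so "pinch biopsy" wins over "biopsy".
    """
    result = text
    for phrase in sorted(stop_phrases, key=len, reverse=True):
        pattern = re.compile(r"(?<!\w)" + re.escape(phrase) + r"(?!\w)", re.IGNORECASE)
        result = pattern.sub(" ", result)
    return re.sub(r"\s+", " ", result).strip()


def split_composite(text: str, config: CompositeConfig | None = None) -> Decomposition:
    """Split a normalized annotation into component entity strings.

    Splitting is staged: explicit delimiters first, then conjunction words,
    then locative connector phrases inside each piece. ``kind`` records the
    strongest evidence seen, with locative > conjunction > delimiter (a
    locative split needs phrase knowledge, so when one fires it defines the
    decomposition's character). A string with no separators comes back whole
    with ``kind="none"``.
    """
    config = config or CompositeConfig()
    seps_used: list[str] = []
    kinds: set[str] = set()

    # parenthetical asides become their own components
    pieces = [text]
    if "(" in text:
        opened = re.split(r"[()]", text)
        if len(opened) > 1:
            pieces = [p for p in opened if p.strip()]
            seps_used.append("()")
            kinds.add("delimiter")

    def split_on(parts: list[str], token: str, kind: str, pattern: str) -> list[str]:
        out: list[str] = []
        for part in parts:
            chunks = re.split(pattern, part)
            if len(chunks) > 1:
                seps_used.append(token)
                kinds.add(kind)
            out.extend(chunks)
        return out

    for d in config.delimiters:
        pieces = split_on(pieces, d, "delimiter", re.escape(d))
    for c in config.conjunctions:
        pieces = split_on(pieces, c, "conjunction", re.escape(c))
    # longest connectors first so "flushed from" is consumed before "from"
    for conn in sorted(config.locative_connectors, key=len, reverse=True):
        pieces = split_on(
            pieces, conn, "locative", r"(?:(?<=\s)|^)" + re.escape(conn) + r"(?=\s|$)"
        )

    components = tuple(p.strip() for p in pieces if p.strip())
    if len(components) <= 1 and not kinds:
        return Decomposition(original=text, components=(text,), kind="none")
    if not components:
        return Decomposition(original=text, components=(text,), kind="none")

    for kind in ("locative", "conjunction", "delimiter"):
        if kind in kinds:
            return Decomposition(
                original=text,
                components=components,
                separators_used=tuple(seps_used),
                kind=kind,
            )
    return Decomposition(original=text, components=(text,), kind="none")


def _tokens_related(a: str, b: str) -> bool:
    """Components sharing a token ("adrenal cortex" / "adrenal gland") may be
    one entity plus a redundant qualifier rather than two entities."""
    return bool(set(a.split()) & set(b.split()))


def cross_product_match(
    decomp: Decomposition,
    index: "TermIndex",
    policy: str = "any",
) -> list:
    """Exact-match each component of a decomposition independently.

    Under ``policy="any"`` every component hit becomes a candidate; under
    ``policy="all"`` candidates are emitted only when *every* component hits
    (the strict cross-product reading). When two components stand in a token
    subset relation — "adrenal cortex, adrenal gland" — the candidates carry
    a redundancy flag in their evidence: a curator must decide whether the
    annotator meant two entities or one.

    Returns :class:`anatomap.match.Candidate` objects with
    ``match_kind="composite"``; ranks are assigned by the caller's cascade.
    """
    from .match import Candidate  # local import to avoid a cycle
    from .normalize import CleanTerm

    if policy not in ("any", "all"):
        raise ValueError(f"unknown policy {policy!r}")
    if decomp.kind == "none":
        return []

    redundant = any(
        _tokens_related(a, b)
        for i, a in enumerate(decomp.components)
        for b in decomp.components[i + 1 :]
    )

    per_component: list[list[tuple[str, str]]] = []
    for comp in decomp.components:
        hits = sorted(index.lexical_map.get(comp, ()))
        per_component.append([(comp, cid) for cid, _origin in hits])

    if policy == "all" and any(not hits for hits in per_component):
        return []

    query = CleanTerm(original=decomp.original, normalized=decomp.original)
    candidates = []
    rank = 1
    for hits in per_component:
        seen: set[str] = set()
        for comp, cid in hits:
            if cid in seen:
                continue
            seen.add(cid)
            evidence = f"component={comp}"
            if redundant:
                evidence += ";redundant_components"
            candidates.append(
                Candidate(
                    query=query,
                    class_id=cid,
                    match_kind="composite",
                    evidence=evidence,
                    rank=rank,
                )
            )
            rank += 1
    return candidates
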