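"""Scoring mapping outcomes against a curated gold standard.

The gold standard maps each query term to the set of class ids a curator
judged correct; an empty set means the term is correctly unmappable. From a
run's outcomes we derive a confusion matrix and the usual metrics:

* **tp** — gold-mapped terms whose accepted set intersects the gold set
* **fn** — gold-mapped terms with no such intersection
* **tn** — gold-unmappable terms the matcher left unmatched
* **fp** — accepted (query, class) *pairs* not in gold; optionally also
  every proposed-but-unaccepted pair not in gold

The counting units are deliberately asymmetric: tp/tn/fn count terms, fp
counts candidate pairs. A sensitive proposal-generating matcher can emit
tens of proposals per term, so its false-positive count can exceed the term
count by an order of magnitude while every other cell stays term-scaled —
that is exactly the regime a curator of proposal-driven matching sees, and
the only arithmetic under which precision can collapse to below 0.01 while
recall holds at 1.0.

Precision and recall are undefined (``None``), not zero, on empty
denominators, so degenerate runs are not silently flattered. Rounding is
half-up and applied only at report time.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

from .match import MappingOutcome

__all__ = [
    "GoldStandard",
    "ConfusionMatrix",
    "MetricsReport",
    "GoldMismatchError",
    "compare_to_gold",
    "precision",
    "recall",
    "coverage",
    "build_report",
    "read_gold_tsv",
    "write_gold_tsv",
    "write_report",
]


class GoldMismatchError(ValueError):
    """Outcomes contain query terms the gold standard does not cover."""


@dataclass(frozen=True)
class GoldStandard:
    """Curated truth: normalized query term -> set of correct class ids.

    An empty id set records that the term is *correctly unmappable* (noise,
    uninterpretable shorthand); distinguishing "unmappable" from "absent
    from the gold file" is what makes true negatives countable.
    """

    map: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __contains__(self, term: str) -> bool:
        return term in self.map

    def __getitem__(self, term: str) -> frozenset[str]:
        return self.map[term]

    def mapped_terms(self) -> set[str]:
        return {t for t, ids in self.map.items() if ids}

    def unmappable_terms(self) -> set[str]:
        return {t for t, ids in self.map.items() if not ids}


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion matrix cells must be non-negative")


@dataclass(frozen=True)
class MetricsReport:
    precision: float | None
    recall: float | None
    coverage_percent: float
    matched_count: int
    total_terms: int
    confusion: ConfusionMatrix


def _round_half_up(value: float, decimals: int) -> float:
    quantum = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


def compare_to_gold(
    outcomes: Sequence[MappingOutcome],
    gold: GoldStandard,
    count_proposals: bool = False,
) -> ConfusionMatrix:
    """Score a run's outcomes against the gold standard.

    With ``count_proposals=False`` only accepted pairs can be false
    positives (the exact-matcher regime); with ``True`` every unaccepted
    proposal absent from gold also counts, which is how a proposal-heavy
    phonetic matcher accrues false positives far beyond the term count.
    Every outcome's query must be present in gold.
    """
    missing = sorted({o.query.normalized for o in outcomes} - set(gold.map))
    if missing:
        raise GoldMismatchError(f"gold standard missing terms: {missing}")

    tp = fp = tn = fn = 0
    for outcome in outcomes:
        gold_ids = gold[outcome.query.normalized]
        accepted = outcome.accepted
        if gold_ids:
            if accepted & gold_ids:
                tp += 1
            else:
                fn += 1
        else:
            if not accepted:
                tn += 1
        fp += len(accepted - gold_ids)
        if count_proposals:
            proposal_ids = {c.class_id for c in outcome.proposed} - accepted
            fp += len(proposal_ids - gold_ids)
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def precision(cm: ConfusionMatrix) -> float | None:
    """tp/(tp+fp) rounded half-up to 3 decimals; None when tp+fp = 0."""
    if cm.tp + cm.fp == 0:
        return None
    return _round_half_up(cm.tp / (cm.tp + cm.fp), 3)


def recall(cm: ConfusionMatrix) -> float | None:
    """tp/(tp+fn) rounded half-up to 3 decimals; None when tp+fn = 0."""
    if cm.tp + cm.fn == 0:
        return None
    return _round_half_up(cm.tp / (cm.tp + cm.fn), 3)


def coverage(matched: int, total: int) -> float:
    """Percentage of corpus terms with at least one match, to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= matched <= total:
        raise ValueError("matched must lie in [0, total]")
    return _round_half_up(100.0 * matched / total, 2)


def build_report(
    outcomes: Sequence[MappingOutcome],
    gold: GoldStandard,
    count_proposals: bool = False,
) -> MetricsReport:
    """Confusion matrix plus derived metrics for one run."""
    cm = compare_to_gold(outcomes, gold, count_proposals=count_proposals)
    matched = sum(1 for o in outcomes if o.status == "matched")
    total = len(outcomes)
    return MetricsReport(
        precision=precision(cm),
        recall=recall(cm),
        coverage_percent=coverage(matched, total) if total else 0.0,
        matched_count=matched,
        total_terms=total,
        confusion=cm,
    )


# ---------------------------------------------------------------------------
# I/O

def read_gold_tsv(path: str | Path) -> GoldStandard:
    """Read a gold standard: ``term<TAB>id[;id...]``; empty second column
    (or none) marks a correctly-unmappable term."""
    mapping: dict[str, frozenset[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t", quoting=csv.QUOTE_NONE):
            if not row or not row[0].strip():
                continue
            ids = row[1].strip() if len(row) > 1 else ""
            mapping[row[0].strip()] = frozenset(
                i.strip() for i in ids.split(";") if i.strip()
            )
    return GoldStandard(map=mapping)


def write_gold_tsv(gold: GoldStandard, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n", quoting=csv.QUOTE_NONE)
        for term in sorted(gold.map):
            writer.writerow([term, ";".join(sorted(gold.map[term]))])


def write_report(
    report: MetricsReport, path_tsv: str | Path, path_json: str | Path, fingerprint: str = ""
) -> None:
    """Write a metrics TSV and a JSON summary (with config fingerprint)."""
    cm = report.confusion
    rows = [
        ("tp", cm.tp),
        ("fp", cm.fp),
        ("tn", cm.tn),
        ("fn", cm.fn),
        ("precision", "NA" if report.precision is None else f"{report.precision:.3f}"),
        ("recall", "NA" if report.recall is None else f"{report.recall:.3f}"),
        ("coverage_percent", f"{report.coverage_percent:.2f}"),
        ("matched_count", report.matched_count),
        ("total_terms", report.total_terms),
    ]
    with open(path_tsv, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n", quoting=csv.QUOTE_NONE)
        for key, value in rows:
            writer.writerow([key, value])
    payload = {
        "tp": cm.tp,
        "fp": cm.fp,
        "tn": cm.tn,
        "fn": cm.fn,
        "precision": report.precision,
        "recall": report.recall,
        "coverage_percent": report.coverage_percent,
        "matched_count": report.matched_count,
        "total_terms": report.total_terms,
        "config_fingerprint": fingerprint,
    }
    with open(path_json, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")
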