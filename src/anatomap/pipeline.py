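"""End-to-end orchestration: preprocess -> index -> match -> evaluate.

A *study* is a grid of runs — matcher mode × ontology — over one annotation
list, mirroring the two-tools-by-two-ontologies design this package
re-implements: an exact matcher run and a phonetic (proposal-generating)
matcher run against each ontology, each scored against the same gold
standard. Per-run artifacts are the two time-stamped match/failure TSVs, a
confusion matrix and metrics JSON; the study summary is one row per run.

Timestamps appear only in file *names*; file contents are deterministic for
a fixed config and seed, so runs diff cleanly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from pathlib import Path
from typing import Sequence

import pandas as pd

from .evaluate import GoldStandard, MetricsReport, build_report, write_report
from .match import MatchConfig, MappingOutcome, run_matcher, write_match_files
from .normalize import (
    CleanTerm,
    NormalizerConfig,
    RawAnnotation,
    deduplicate,
    normalize_text,
    read_term_tsv,
    strip_species,
    UnusableAnnotationError,
)
from .ontology_io import OntologyClass, TermIndex, build_index, parse_obo

__all__ = ["RunConfig", "RunResult", "clean_annotations", "run_one", "run_study"]


@dataclass(frozen=True)
class RunConfig:
    """One cell of the study grid."""

    name: str
    ontology_path: str | Path | None = None
    mode: str = "exact"  # exact | phonetic
    match_config: MatchConfig = field(default_factory=MatchConfig)
    normalizer_config: NormalizerConfig = field(default_factory=NormalizerConfig)
    synonym_scopes: tuple[str, ...] = ("EXACT",)
    count_proposals: bool | None = None  # default: True iff mode == phonetic

    def effective_match_config(self) -> MatchConfig:
        return replace(self.match_config, phonetic=(self.mode == "phonetic"))

    def effective_count_proposals(self) -> bool:
        if self.count_proposals is not None:
            return self.count_proposals
        return self.mode == "phonetic"


@dataclass
class RunResult:
    config: RunConfig
    outcomes: list[MappingOutcome]
    report: MetricsReport | None


def clean_annotations(
    annotations: Sequence[RawAnnotation],
    config: NormalizerConfig | None = None,
    strip_species_names: bool = True,
) -> tuple[list[CleanTerm], list[RawAnnotation]]:
    """Species-strip, normalize and deduplicate raw annotations.

    Returns the unique clean terms (input order preserved) and the
    annotations dropped as unusable (empty after cleaning).
    """
    config = config or NormalizerConfig()
    cleaned: list[CleanTerm] = []
    dropped: list[RawAnnotation] = []
    for ann in annotations:
        text = ann.text
        stripped_any = False
        if strip_species_names:
            stripped = strip_species(text, ann.species)
            stripped_any = stripped != " ".join(text.split())
            text = stripped
        try:
            term = normalize_text(text, config)
        except UnusableAnnotationError:
            dropped.append(ann)
            continue
        if stripped_any:
            term = CleanTerm(
                original=ann.text,
                normalized=term.normalized,
                steps=("species_strip",) + term.steps,
            )
        else:
            term = replace(term, original=ann.text)
        cleaned.append(term)
    return deduplicate(cleaned), dropped


def run_one(
    terms: Sequence[CleanTerm],
    index: TermIndex,
    config: RunConfig,
    gold: GoldStandard | None = None,
    out_dir: str | Path | None = None,
    timestamp: str | None = None,
) -> RunResult:
    """Execute one matcher run and, when gold is given, score it."""
    outcomes = run_matcher(terms, index, config.effective_match_config())
    report = None
    if gold is not None:
        report = build_report(
            outcomes, gold, count_proposals=config.effective_count_proposals()
        )
    if out_dir is not None:
        out_dir = Path(out_dir) / config.name
        out_dir.mkdir(parents=True, exist_ok=True)
        ts = timestamp or datetime.now(timezone.utc).strftime("%Y%m%dT%H%M%SZ")
        write_match_files(outcomes, out_dir, ts)
        if report is not None:
            write_report(
                report,
                out_dir / "metrics.tsv",
                out_dir / "metrics.json",
                fingerprint=f"{config.mode}|{config.normalizer_config.fingerprint()}",
            )
    return RunResult(config=config, outcomes=outcomes, report=report)


def run_study(
    terms_path: str | Path | None,
    gold: GoldStandard | None,
    configs: Sequence[RunConfig],
    out_dir: str | Path | None = None,
    annotations: Sequence[RawAnnotation] | None = None,
    indexes: dict[str, TermIndex] | None = None,
    ontologies: dict[str, list[OntologyClass]] | None = None,
) -> pd.DataFrame:
    """Run the full study grid and return the summary table.

    Inputs may come from files (``terms_path`` + per-config
    ``ontology_path``) or be passed in memory (``annotations`` plus
    ``indexes``/``ontologies`` keyed by config name). One summary row per
    config, ordered by (mode, name) for deterministic output.
    """
    if not configs:
        raise ValueError("at least one run config required")
    if annotations is None:
        if terms_path is None:
            raise ValueError("terms_path or annotations required")
        annotations = read_term_tsv(terms_path)
    if not annotations:
        raise ValueError("empty annotation list")

    rows = []
    for config in sorted(configs, key=lambda c: (c.mode, c.name)):
        terms, _dropped = clean_annotations(annotations, config.normalizer_config)
        index: TermIndex
        if indexes and config.name in indexes:
            index = indexes[config.name]
        else:
            if ontologies and config.name in ontologies:
                classes = ontologies[config.name]
            elif config.ontology_path is not None:
                classes = parse_obo(config.ontology_path)
            else:
                raise ValueError(f"run {config.name!r} has no ontology source")
            index = build_index(
                classes, config.normalizer_config, synonym_scopes=config.synonym_scopes
            )
        result = run_one(terms, index, config, gold=gold, out_dir=out_dir)
        matched = sum(1 for o in result.outcomes if o.status == "matched")
        proposed = sum(1 for o in result.outcomes if o.status == "proposed_only")
        unmatched = sum(1 for o in result.outcomes if o.status == "unmatched")
        row = {
            "run": config.name,
            "mode": config.mode,
            "terms": len(result.outcomes),
            "matched": matched,
            "proposed_only": proposed,
            "unmatched": unmatched,
        }
        if result.report is not None:
            row.update(
                {
                    "tp": result.report.confusion.tp,
                    "fp": result.report.confusion.fp,
                    "tn": result.report.confusion.tn,
                    "fn": result.report.confusion.fn,
                    "precision": result.report.precision,
                    "recall": result.report.recall,
                    "coverage_percent": result.report.coverage_percent,
                }
            )
        rows.append(row)

    summary = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    return summary
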