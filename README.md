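# anatomap

Lexical mapping of free-text anatomical annotations onto anatomy ontologies.

## The problem

Biologists annotate samples with free-text anatomy terms — `animal cap`,
`Liver/Kidney`, `Abdominal`, `bone marrow, flushed from femur` — while
ontologies such as the FMA (human anatomy) and Uberon (multi-species
anatomy) carry curated class labels and synonyms, usually singular,
American-spelled nouns. Measuring how well an ontology covers what
annotators actually write, and *why* terms fail to map, requires a
reproducible pipeline: normalize the annotations, index the ontology's
lexical surface, match by several strategies of increasing looseness, and
score against a curated gold standard.

`anatomap` implements that pipeline for curators and ontology engineers:

- **ontology_io** — OBO flat-file parsing, exact + phonetic term indexing,
  duplicate-label QC (the one-term-two-ids defect), lexical overlap between
  ontologies (Jaccard, as a percentage).
- **normalize** — species-name stripping, whitespace/case/punctuation
  unification, non-printing-character removal, British→American spelling,
  cross-species deduplication; every transformation recorded as provenance.
- **match** — an exact matcher (no false positives by construction) and a
  Double Metaphone phonetic matcher (high sensitivity, proposals only, for
  curator-driven matching), plus variant rewrites: plural→singular,
  adjective→noun (`abdominal`→`abdomen`), shorthand expansion
  (`both ventricles`→ the two ventricle classes).
- **composite** — decomposition of composite annotations (`liver/kidney`,
  `acetabulum and pelvic soft tissues`, `bone marrow, flushed from femur`)
  and component-wise cross-product matching.
- **evaluate** — confusion matrices and precision/recall/coverage, with the
  term/pair counting convention under which proposal-generating matchers
  accrue false positives far beyond the corpus size.
- **synth** — a generator of toy ontologies and corrupted annotation
  corpora with exact gold standards and per-term corruption labels, so
  every stage is testable with no external data.
- **pipeline / cli** — the study grid (matcher mode × ontology) and a thin
  `anatomap` command-line tool (`clean`, `index`, `match`, `evaluate`,
  `generate`, `study`).

## The statistics at the core

For a run scored against a gold standard `G` (term → set of correct class
ids; empty set = correctly unmappable):

- `TP` / `FN` count gold-mapped **terms** recovered / missed,
- `TN` counts gold-unmappable **terms** left unmatched,
- `FP` counts accepted (term, class) **pairs** outside `G` — and, when
  proposals are counted, every unaccepted proposal outside `G` as well,

with precision = TP/(TP+FP), recall = TP/(TP+FN) (3 decimals, half-up;
undefined — not 0 — on empty denominators) and coverage = 100·matched/total
(2 decimals). The asymmetric units are deliberate: they describe what a
curator of proposal-driven matching actually reviews, and they are the only
arithmetic under which a sensitive phonetic matcher's precision can collapse
below 0.01 while its recall stays 1.0.

## Worked example

```python
import anatomap as am

ontology = am.generate_ontology(n_classes=150, seed=4)
corpus = am.corrupt(ontology, am.CorruptionSpec(n_terms=120, seed=4))
index = am.build_index(corpus.ontology)
terms, _ = am.clean_annotations(corpus.annotations)

cfg = am.MatchConfig(spellfix=True, shorthand_table=corpus.shorthand_table)
configs = [
    am.RunConfig(name="exact", mode="exact", match_config=cfg),
    am.RunConfig(name="phonetic", mode="phonetic", match_config=cfg),
]
summary = am.run_study(None, corpus.gold, configs,
                       annotations=corpus.annotations,
                       indexes={c.name: index for c in configs})
print(summary.to_string(index=False))
```

prints

```
     run     mode  terms  matched  proposed_only  unmatched  tp  fp  tn  fn  precision  recall  coverage_percent
   exact    exact    120      113              0          7 113   0   7   0        1.0     1.0             94.17
phonetic phonetic    120      113              0          7 113   0   7   0        1.0     1.0             94.17
```

All 113 recoverable terms (identity, synonyms, plurals, adjectives, British
spellings, species suffixes, misspellings, composites, shorthand, procedure
phrases) map back to their source classes with zero false positives; the 7
unmatched terms are the generator's uninterpretable noise, correctly counted
as true negatives. This grammar is phonetically sparse, so the phonetic run
adds no proposals here; on a phonetically *dense* ontology the proposal
regime appears:

```python
from anatomap.synth import generate_dense_ontology
classes, queries = generate_dense_ontology(n_groups=20, group_size=12, seed=3)
index = am.build_index(classes)
outcomes = am.run_matcher([am.CleanTerm(q, q) for q in queries], index,
                          am.MatchConfig(phonetic=True, composite=False))
gold = am.GoldStandard(map={q: frozenset() for q in queries})
cm = am.compare_to_gold(outcomes, gold, count_proposals=True)
print(len(queries), cm.fp)   # -> 20 240
```

20 query terms generate 240 false-positive proposals — twelve same-sounding
classes each — which is why phonetic hits are never auto-accepted.

## Acceptance script

`scripts/acceptance.py` recomputes, from scratch at run time, the package's
reference quantities: the precision and recall values derived from the four
published confusion matrices of the exact and phonetic matchers against two
anatomy ontologies, and the two coverage percentages, after first running
the full generate→clean→index→match→score pipeline on a 1000-term synthetic
corpus as a self-check (any recovery failure aborts the run).

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

See `docs/methods.md` for the model, parameter defaults, and the limits of
what the synthetic corpus can establish.
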