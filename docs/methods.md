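# Methods

This note documents the models and procedures implemented in `anatomap`,
the defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical conventions.

## Normalization

Annotations pass through a fixed transformation order — control/zero-width
character removal → whitespace collapse → case folding → punctuation
unification → British→American respelling — so that the provenance trail
(`CleanTerm.steps`) is deterministic. Normalization is idempotent; an
annotation empty after cleaning raises an "unusable" signal rather than
silently vanishing.

Choices that were genuinely open:

- **Hyphen policy.** Hyphens open to single spaces by default
  (`fore-limb` ≡ `fore limb`); slashes and commas are *kept* because they
  are composite-term separators consumed later by decomposition.
- **Anglicism table.** ~40 anatomy-relevant British→American pairs ship as
  an editable mapping (`tables.ANGLICISMS`); the policy (American primary
  labels) is fixed, the table is configuration.
- **Species stripping** removes whole-word occurrences of the row's paired
  binomial and of a vernacular lexicon (`mouse`, `bovine`, …), longest
  phrase first. Whole-word matching prevents `rat` firing inside
  `stratum`.
- **Misspelling repair is OFF by default.** Automated repair risks false
  positives (full lemmatisation/stemming is excluded for the same reason);
  when enabled, a term is replaced only by a *unique* vocabulary entry at
  edit distance 1.
- Cross-species **deduplication** keeps the first occurrence and preserves
  order; collapsed groups are reportable for audit.

## Matching cascade

Per term: **exact → variant rewrites → composite decomposition → phonetic
proposals**. The tiers are strictly ordered and every accepted hit is
auditable as an exact match on a stated rewrite:

1. **Exact**: the normalized term equals an indexed label or synonym
   (labels rank above synonyms, ties break on class id). Synonym scopes
   admitted to the index default to EXACT only — BROAD/RELATED synonyms
   invite false positives; the config can widen them.
2. **Variant rewrites** (each individually switchable): plural→singular on
   the head noun (Latin irregulars and an exception list first, then
   -ies/-es/-s rules), adjective→noun whole-word substitution from a table
   (`arterial`→`artery`), shorthand expansion from a table (one shorthand
   may denote several classes). Rewritten strings re-enter the exact
   matcher.
3. **Composite stage**: procedure stop-phrases are stripped
   (`colon pinch biopsy`→`colon`), then the string is split on delimiters
   (`/ ; , + &`), conjunctions (`and`, `with`, `plus`) and locative
   connector phrases (`flushed from`, `derived from`, `from`). **`of` is
   not a separator** — `left ventricle of heart` is atomic. Components are
   exact-matched independently; under the default `any` policy every
   component hit is a candidate, under `all` only full cross-products.
   Components sharing a token (`adrenal cortex, adrenal gland`) are flagged
   as possibly redundant and left to a curator, never auto-resolved.
4. **Phonetic proposals**: Double Metaphone codes, computed word by word
   and joined in order (whole-phrase encoding destroys word boundaries and
   explodes false positives). Primary-code agreement outranks
   alternate-code agreement; within a tier candidates order by token-count
   difference, matched string, class id. **Proposals are never
   auto-accepted**: acceptance of a proposal requires an explicit curation
   file, mirroring curator-driven matching. A curation entry naming an
   unknown term is an error.

An optional Levenshtein distance-1 stage exists behind a flag (default
off), as the natural next loosening after phonetics.

The Double Metaphone encoder is implemented in-package (no maintained
reference implementation is available in this environment) following the
published algorithm: initial silent clusters (KN-, GN-, PS-, WR-),
context-dependent C/G/H, the Slavo-Germanic heuristic, vowels encoded only
word-initially, voiced/unvoiced mergers (V→F, Z→S, D→T), `0` for the TH
sound. Codes are **not truncated to four characters**: anatomical
vocabulary is long, and truncation merges far too many distinct organ
names. It reproduces the canonical primary/alternate vectors (Smith →
SM0/XMT, Schmidt → XMT/SMT) and, notably, encodes `periosteum` and the
misspelling `perisoteum` identically — the classic phonetic-matcher false
positive.

## Evaluation conventions

- `TP`/`FN`/`TN` count **terms**; `FP` counts **(term, class) pairs** —
  accepted pairs outside gold and, when `count_proposals=True`, every
  unaccepted proposal outside gold. This asymmetry is the only arithmetic
  under which a proposal-generating matcher can show five-digit
  false-positive counts against a ~1100-term corpus while recall stays
  1.0; it reflects what a curator actually reviews. The exact matcher under
  `count_proposals=False` has zero false positives whenever the gold
  standard is derived from index membership.
- Precision and recall are **undefined (`None`), not 0**, on empty
  denominators, so degenerate runs are not flattered.
- Rounding is **half-up**, applied only at report time (precision/recall to
  3 decimals, coverage to 2); internal values stay full precision.
- Coverage = 100 · matched / total terms.
- Lexical overlap between two indexes is Jaccard (100·|A∩B|/|A∪B|); the
  measure is symmetric by construction. Published overlap figures of this
  kind rarely state their denominator, so the Jaccard choice is this
  package's own and is not claimed to reproduce any particular figure.

## The synthetic world

The real annotation corpus this kind of study uses is not deposited, so the
generator *states* a world instead:

- **Ontology**: unique labels from a grammar of positional modifiers and
  organ nouns (`"left kidney"`, `"fetal esophagus"`); default 600 classes,
  30% carrying one EXACT synonym (a Latin-ish alternative noun or a
  `"<label> structure"` form); optional injected duplicate labels (the
  one-term-two-ids QC case).
- **Corpus**: default 1000 terms drawn by sampling a class and applying one
  of 13 corruption rules — identity, synonym use, plural, adjectival,
  Anglicism, species suffix, whitespace/punctuation noise, single-edit
  misspelling (guaranteed uniquely repairable and not rescuable by any
  non-spellfix stage), composite with delimiter, composite with locative
  connector, shorthand (synthesized initialisms whose table is returned for
  injection into the matcher), procedure phrase, and uninterpretable noise
  (gold = empty set). Base annotations are constructed with pairwise
  distinct normalized forms, so `n_terms` is exact after deduplication;
  `duplicate_fraction` then appends cross-species duplicate rows (e.g.
  1097 unique terms + 440 duplicates = 1537 raw rows).
- **Proportions**: the default mixture weights composites highest (0.20
  combined) — consistent with composites being the dominant reported
  mismatch class — and keeps every class populated at n = 1000; no
  published per-class frequencies exist, so these proportions are this
  package's own statement. The species mixture (50.88% human, 27.91%
  mouse, 10.61% rat, remainder spread) is cosmetic realism.
- Generation is bit-identical under a fixed (spec, seed).

A separate **phonetically dense** generator emits groups of
vowel-substituted, code-preserving spelling variants plus held-out query
variants; it exists to demonstrate the proposal-counting false-positive
regime, which the sparse grammar cannot.

**What a green test establishes — and does not.** The generator and matcher
share their adjective/shorthand/Anglicism tables, so recovery tests are
closed-world: they verify that each pipeline stage exactly inverts its own
corruption class (100% per-class recovery, stage isolation under toggling,
0% for noise). They do *not* establish real-world recall: real annotations
contain vocabulary outside any shared table, ambiguous shorthand, and
cell-vs-tissue or granularity mismatches that no lexical method resolves. A
deliberate "table mismatch" is possible by passing the matcher tables
differing from the generator's, which reproduces the open-world gap
qualitatively.

Stage-isolation caveat: the isolation property is tested with spellfix off
as the baseline, because edit-distance-1 repair can legitimately rescue
plural and adjectival forms (`kidneys`/`kidney` are distance 1) — an
interaction inherent to fuzzy repair, not a defect.

## Numerical / procedural details

- Largest-remainder apportionment converts corruption proportions into
  exact per-class counts.
- Corruption rules that are inapplicable to a sampled class (pluralizing
  `pancreas`, Anglicizing a label with no British variant) resample with a
  bounded retry budget (200) and fail loudly when exhausted.
- Matcher output ranks are globally unique per query; exact-tier kinds
  always precede phonetic kinds.
- Run outputs are two tab-delimited files per run (matches and failures)
  with UTC timestamps **only in filenames**, so contents are byte-stable
  across reruns; the study summary is one TSV row per (mode, ontology)
  cell, deterministically ordered.
- OBO parsing reads only the lexical layer (`id`, `name`, `synonym` with
  scope defaulting to RELATED, `is_obsolete`); obsolete classes are
  excluded from indexing by default. Graph structure and OWL are out of
  scope.

## Known limitations

- Lexical only: no semantic similarity, no cross-ontology bridging, no
  quantitative annotations (`75% kidney`); these are explicit non-goals.
- The Double Metaphone implementation targets the published algorithm but
  has no independent oracle in this environment; it is validated against
  canonical vectors and hand-derived codes plus property tests.
- English-centric morphology: the plural/adjective rules cover
  English/Latin anatomy vocabulary, not hybrid multilingual terms.
- The evaluation assumes the gold standard covers every query term;
  partially-covered corpora must be filtered first.
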