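# Methods

This note documents the verification model the package implements, the
conventions it fixes where the underlying procedure is underspecified, what
the synthetic-data generator does and does not emulate, and the numerical
and design choices a maintainer would want spelled out.

## The verification model

The object of study is a *generated biomedical association*: a typed pair
of ontology terms proposed by a language model, serialized as a two-key
JSON record mapping each CURIE to its label. Four types are supported,
each tied to a (source, target) ontology prefix pair:

| type | source → target | prefixes |
|---|---|---|
| disease_drug | disease → drug | DOID → CHEBI |
| disease_symptom | disease → symptom | DOID → SYMP |
| disease_gene | disease → genetic process/gene | DOID → GO |
| process_gene | genetic process → gene product | GO → GO |

Verification is decomposed into two independent questions:

**Is each term real?** A term label is compared against the names and
synonyms of its ontology. The comparison is exact whole-label equality
under a shared normalization policy (below); matching any primary name
yields `VERIFIED_NAME`, matching only synonyms yields `VERIFIED_SYNONYM`,
otherwise `UNVERIFIED`. All four OBO synonym scopes count as matches: the
canonical hypertension entry itself carries a RELATED synonym among those
a curator would accept. Obsolete terms are loaded (so they can be
inspected) but never indexed, so retired vocabulary cannot verify a term.
No fuzzy or embedding-based matching is attempted: the "semantic" reach of
the method is exactly the synonym metadata curated into the ontology.

**Is the association attested?** A pair is checked against a corpus of
abstracts. An abstract supports a pair when it contains both labels; the
number of supporting abstracts is the pair's counter, each abstract
counting at most once per pair regardless of repeated mentions. A pair
with counter > 0 is *covered* ("verified" in the operational sense —
coverage is evidence of attestation, not a truth label, and zero coverage
means *not yet verified*, not *false*). Reports aggregate per association
type and optionally per publication period:

- `verified_pct = 100·|{counter > 0}|/n`, `unverified_pct = 100 − verified_pct`
  (the identity holds exactly before rounding);
- `avg_frequency` = mean counter over **verified pairs only**. Averaging
  over all pairs would conflate support strength with coverage; the
  quantity reported is "how many abstracts support a supported
  association". This convention is a deliberate choice — the procedure's
  description does not state whether zero-counter pairs enter the mean.

A per-pair "hit ratio" dividing one pair's abstract count by the number of
pairs appears in one formulation of the counting procedure; it is
dimensionally inconsistent (it mixes a per-pair quantity with the pair-set
size) and is not reproduced. The package stores raw counters and derives
all rates at report level.

**Cross-model consistency.** The same pair sets can be scored against
several corpora, one per generator model; each (model, type) row reports
the verified count and percentage. Agreement across independently
generated corpora indicates the associations are stable knowledge rather
than sampling noise.

## Normalization policy

All label comparison and containment goes through one normalizer, applied
in a fixed order: Unicode NFKC compatibility normalization → case-folding
→ every punctuation character (hyphens and apostrophes included) replaced
by a single space → whitespace collapse → trim. It is deterministic and
idempotent. The policy is deliberately aggressive: observed match failures
are dominated by casing, punctuation, and spacing variants ("Bull's-Eye
Rash" vs "bulls eye rash"), and normalization recovers those without
introducing approximate matching. What it does *not* do: stemming
("rashes" never matches "rash"), token reordering, or sub-label matching —
"itchy blisters" does not verify against "blister", by design.

Corpus containment is the same policy applied to both sides: the label's
normalized token sequence must occur contiguously at word boundaries in
the normalized abstract. Synonym expansion during corpus search (counting
an abstract that mentions `HTN` for a pair labeled `hypertension`) is
available but **off by default**: association verification checks the
generated strings themselves; ontology synonyms belong to term
verification unless explicitly requested.

## Accuracy-report convention

Published per-feature accuracy tables list separate "name", "synonym", and
"name/synonym" rates whose relationship is not defined by the procedure
(a synonym rate can sit below the name rate while the combined rate
exceeds both). The package fixes the one convention consistent with that
ordering in every observed row: over a single denominator (all terms),

- `name_pct` counts terms matching any primary name;
- `synonym_pct` counts terms matching any synonym, whether or not they
  also match a name;
- `combined_pct` counts terms matching either, hence
  `combined ≥ max(name, synonym)` always.

Percentages are kept unrounded internally; display rounding is half-up to
two decimals (93.365 → 93.37).

## Association file handling

Records are two-key JSON objects, disease (source) first; files are a JSON
array or JSONL, both accepted, array written. Parsing is defensive and
total: per-record failures (wrong arity, malformed CURIE, empty label,
broken JSONL line) are collected as rejects with machine-readable reasons;
only an unparseable top-level array document is fatal (with byte offset).
The parse outcome partitions its input exactly:
`records = accepted + rejected + duplicates_removed`, where duplicates are
identical (ids, normalized labels) 4-tuples — generated output repeats
itself, and redundancy is an observed failure mode worth counting.
CURIE syntax is `<PREFIX>:<digits>` with case-sensitive prefixes; GO
requires exactly 7 digits. A prefix-alias table (default `SYMPTOM → SYMP`)
reconciles the two spellings that occur in generated records, rewriting at
parse time so downstream code sees canonical prefixes only.

Term verification and identifier validation are deliberately separate:
labels verify against the ontology regardless of whether the generated
CURIE is correct, because generated ids are frequently invalid even when
labels are accurate. CURIE repair by ontology search is out of scope —
invalid ids are reported, not fixed.

## Prompt generation and the generator contract

One-shot prompts embed the requested record count, the association-type
name, and exactly one example record. The generation backend is a
synchronous `generate(prompt) -> response` contract so any API client,
file replay, or mock satisfies it; live API clients are out of the test
surface (hermetic, cost-free tests). The seeded `MockGenerator` emits
byte-identical responses for a fixed seed, logs its ground-truth
emissions, and can inject configurable fractions of invalid JSON,
malformed CURIEs and duplicate records to exercise every rejection path.
The same prompt template is used for all four association types with the
type name substituted; a response that fails JSON parsing becomes a data
outcome ("Invalid JSON format in response."), never an exception.

## The synthetic-data generator

The fixture module emulates the shape of the study inputs — ontologies
with scoped synonyms, association sets of controlled validity, corpora of
dated abstracts — at desk scale, with exact ground truth. Defaults (50
terms, 0.5 synonym rate, 200 pairs, 0.8 valid fraction, ~100 abstracts,
0.6 plant fraction, years 2009–2024) are modest analogues of the study
conditions: generated term sets verify against their ontologies at high
rates, corpora span the three 5-year reporting periods, and a majority of
pairs find at least one supporting abstract.

Exactness is by construction, not luck. All text is drawn from synthesized
pronounceable words over three mutually disjoint vocabularies (label
words, sliced disjointly per CURIE prefix; perturbation words; filler
words), and generated labels within an ontology are mutually non-contained
token sequences. Consequences:

- an *invalid* endpoint — a label with one token replaced by one or two
  out-of-vocabulary words, optionally hyphen-joined (emulating lay
  paraphrase, verbosity, and punctuation-variant failure modes) — can
  never equal or contain an ontology label, so term-verification ground
  truth is exact; replacement words are additionally never reused within a
  run, so two independently perturbed labels can never coincide and create
  an unplanned co-occurrence;
- a corpus abstract contains both labels of a pair **iff** it was planted
  for that pair, so every counter equals the plant-log count exactly.
  Planted pairs receive a geometric number of supporting abstracts
  (continuation probability 0.3), giving a skewed support distribution;
  filler abstracts carry at most one label of any pair.

What the generator does **not** emulate: natural-language abstracts (filler
is a fixed word list, not a language model), MeSH indexing, realistic
abstract-length or term-frequency distributions, morphological variation,
or cross-ontology ambiguity of real vocabularies. Passing tests therefore
demonstrate that the pipeline measures exactly what it claims on inputs
with known truth — not that any particular real-world accuracy level will
be attained, which depends on the generator model and ontology coverage.

`gen_planted_setup` additionally builds pair sets at arbitrary sizes with
an exact number of corpus-attested pairs (each planted pair in exactly one
chunked abstract), used for consistency experiments at the real dataset
sizes (thousands of pairs) in well under a second.

## Numerical and implementation choices

- **Determinism.** Every stream derives from one integer seed through
  stream-labelled `random.Random` instances (`f"{seed}|ontology|DOID"` …),
  so artifacts are byte-identical across runs and platforms; report JSON
  uses sorted keys.
- **Counting speed.** `verify_associations` builds an inverted token index
  over the normalized corpus; candidate abstracts (those containing every
  token of a label variant) are then confirmed by contiguous substring
  match. This is exactly equivalent to the naive scan — tests assert the
  equivalence against an independent normalize-and-scan oracle — and keeps
  5,000-pair runs fast.
- **Degenerate inputs.** Empty labels never match; an empty verdict list
  or empty report group is an error (percentages undefined); an empty
  `[Term]` list is a valid ontology; a corpus record without a year is
  excluded from period-stratified runs (counted and logged) but included
  in unstratified runs; duplicate labels across ontology terms are legal —
  lookup returns a set and a verdict carries all matched ids.
- **Ties and precedence.** A term matching one entry by name and another
  by synonym reports both; a single entry matched both ways reports NAME
  once (synonyms duplicating their own term's name are dropped at load).
- **Problem sizes.** The test suite and the acceptance script run fixture
  suites of 30–500 pairs and ≤ 200 abstracts, plus consistency setups at
  the full pair-set sizes (2625 / 5008 / 5466) against chunked planted
  corpora; these sizes exercise every code path while keeping the whole
  suite to a few seconds.

## Known limitations

- Whole-token matching cannot credit morphological or word-order variants;
  real-corpus coverage is thus a lower bound on attestation.
- Synonym expansion resolves through the pair's CURIE; if the generated id
  is wrong, expansion falls back to the literal label.
- Coverage is co-occurrence, not relation extraction: a pair can co-occur
  in an abstract that refutes the association.
- The absolute accuracy and coverage values published for full-scale
  ontologies and PubMed extracts are not reproducible at desk scale; the
  package instead verifies the method's internal identities (accounting,
  oracle equivalence, plant-log recovery, percentage arithmetic) exactly.
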