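# assocverify

Two-stage verification of biomedical associations produced by large
language models.

Generative models will happily emit disease-centric "knowledge" — pairs
like *(breast cancer, Carbamazepine)* or *(epistaxis, nosebleed)* encoded
as ontology-term records — but that output mixes well-grounded facts with
invented terms and unsupported links. `assocverify` checks such
associations against two independent sources of ground truth:

1. **Term verification** — each term label is checked against a domain
   ontology (Human Disease Ontology for diseases, ChEBI for drugs, the
   Symptom Ontology for symptoms, the Gene Ontology for genetic processes).
   A term is `VERIFIED_NAME` when its normalized label equals a term's
   primary name, `VERIFIED_SYNONYM` when it equals any scoped synonym
   (`EXACT`/`RELATED`/`NARROW`/`BROAD`), and `UNVERIFIED` otherwise.
2. **Association verification** — a pair *(p_i, p_j)* is checked against a
   corpus of literature abstracts: every abstract containing both labels
   (whole-token contiguous match after normalization) increments the pair's
   co-occurrence counter; a pair with counter > 0 is *covered* by the
   literature. Coverage is reported per association type and per 5-year
   publication period (2009–2014, 2015–2019, 2020–2024), and the same pairs
   can be scored against per-model corpora for cross-model consistency.

For a set of pairs `L` and corpus `D`, the reported statistics are

    verified_pct  = 100 · |{P ∈ L : counter(P, D) > 0}| / |L|
    avg_frequency = mean counter over verified pairs only

together with name / synonym / combined accuracy rates for term
verification, where the combined rate counts terms matching either way and
therefore always dominates both components.

Everything is testable without network access or real ontology downloads:
the `fixtures` module generates miniature OBO ontologies, association sets
with a controlled valid fraction, and corpora with planted co-occurrences,
recording exact ground truth (the *plant log*) so that every reported
statistic can be recomputed independently.

## Worked example

```python
import io
from assocverify import load_obo, verify_term

doid = load_obo(io.StringIO('''\
[Term]
id: DOID:10763
name: hypertension
synonym: "HTN" EXACT []
synonym: "hyperpiesia" EXACT []
synonym: "hypertensive disease" RELATED []
synonym: "vascular hypertensive disorder" EXACT []
'''), "DOID")

for label in ("hypertension", "HTN", "Hypertensive-Disease", "itchy blisters"):
    v = verify_term(label, doid)
    print(f"{label!r:35} -> {v.status.value:17} {sorted(v.matched_ids)}")
```

prints

```
'hypertension'                      -> VERIFIED_NAME     ['DOID:10763']
'HTN'                               -> VERIFIED_SYNONYM  ['DOID:10763']
'Hypertensive-Disease'              -> VERIFIED_SYNONYM  ['DOID:10763']
'itchy blisters'                    -> UNVERIFIED        []
```

The first label equals the primary name; the next two resolve through the
term's synonym metadata despite casing and punctuation differences; the lay
paraphrase fails because matching is exact whole-label comparison after
normalization, never substring or fuzzy search.

Coverage works the same way end to end (see `examples/`): generate or load
pairs and a corpus, then

```python
from assocverify import FixtureConfig, gen_suite, verify_associations, coverage_report

suite = gen_suite(FixtureConfig(seed=7))                 # 200 pairs, planted corpus
covs = verify_associations(suite.pairs, suite.corpus)
(row,) = coverage_report({("disease_symptom", "all"): covs})
print(row.verified_pct)   # 69.0 — exactly the planted fraction in the log
```

## Command line

A thin CLI wraps the library for file-based runs:

```sh
assoc-verify fixtures --seed 7 --out-dir fx/                # synthetic suite + plant log
assoc-verify validate --type disease_symptom --in fx/pairs.json --report rejects.tsv
assoc-verify verify-terms --type disease_symptom --pairs fx/pairs.json \
    --source-obo fx/source.obo --target-obo fx/target.obo --out-dir report/
assoc-verify cover --type disease_symptom --pairs fx/pairs.json \
    --corpus fx/corpus.jsonl --by-period --out-dir report/
assoc-verify consistency --pairs-dir pairs/ --corpora-dir corpora/ --out-dir report/
```

Reports are written as TSV and JSON plus a run manifest (inputs, seed,
version, counts); identical invocations produce identical bytes.

## Layout

- `src/assocverify/ontology.py` — OBO loading, normalization, label lookup
- `src/assocverify/terms.py` — term verification and accuracy reports
- `src/assocverify/associations.py` — association file I/O and CURIE checks
- `src/assocverify/coverage.py` — co-occurrence counting, coverage and
  consistency reports, corpus readers
- `src/assocverify/prompts.py` — one-shot prompt building, generator
  contract, seeded mock generator
- `src/assocverify/fixtures.py` — synthetic ontologies / pairs / corpora
  with exact plant logs
- `src/assocverify/cli.py`, `reports.py` — CLI and report rendering
- `docs/methods.md` — models, conventions, and design choices in detail
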