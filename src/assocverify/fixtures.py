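"""Seeded synthetic fixtures: mini ontologies, association sets, corpora.

Every other module in the package is tested against data generated here,
because the generator records exact ground truth (the plant log): which
pair endpoints carry real ontology labels, and which abstracts were
constructed to contain which pairs. Downstream statistics — verification
accuracy, coverage percentages, average co-occurrence frequency — are then
recomputable from the log alone and must match the pipeline's output
exactly.

Exactness is guaranteed by construction rather than by hoping collisions
are rare. All text is drawn from synthesized pronounceable words over three
mutually disjoint vocabularies:

* **label words** — per-CURIE-prefix disjoint slices, so a drug label can
  never appear inside a disease label;
* **perturbation words** — used to corrupt invalid endpoints by *replacing*
  a label token, so a perturbed label never equals (or contains) any
  ontology label;
* **filler words** — abstract padding that can never complete a label.

Within one ontology, generated labels (names and synonyms) are mutually
non-contained token sequences. Together these rules mean an abstract
contains both labels of a pair if and only if it was planted for that pair.

Perturbations emulate the characteristic failure modes of generated
biomedical terms — lay paraphrase (token replaced by an out-of-vocabulary
word), verbosity (token replaced by two words), stray punctuation (the two
words hyphen-joined) — while remaining provably non-matching.

All randomness flows from ``FixtureConfig.seed`` through stream-specific
``random.Random`` instances, so identical configs yield byte-identical
artifacts on every platform.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from itertools import count
from typing import Iterator, Sequence

from .associations import (
    ASSOC_PREFIXES,
    AssociationPair,
    serialize_associations,
)
from .coverage import AbstractRecord, Corpus
from .ontology import Ontology, OntologyTerm, SynonymEntry, SynonymScope, normalize_label

__all__ = [
    "FixtureConfig",
    "PairPlant",
    "PlantLog",
    "gen_ontology",
    "gen_association_set",
    "gen_corpus",
    "gen_planted_setup",
    "FixtureSuite",
    "gen_suite",
]

# --- word machinery --------------------------------------------------------

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"
_SYLLABLES = [c + v for c in _CONSONANTS for v in _VOWELS]  # 70 syllables
_N_SYL = len(_SYLLABLES)


def _word(i: int) -> str:
    """Deterministic pronounceable word #i (2 syllables, then 3, then 4...).

    Words of different syllable counts have different lengths, so the
    sequence is collision-free for all i.
    """
    length = 2
    block = _N_SYL**2
    while i >= block:
        i -= block
        length += 1
        block = _N_SYL**length
    out = []
    for _ in range(length):
        i, r = divmod(i, _N_SYL)
        out.append(_SYLLABLES[r])
    return "".join(out)


def _words(start: int, count: int) -> list[str]:
    return [_word(i) for i in range(start, start + count)]


_FILLER_WORDS = _words(0, 200)
#: start of the word range consumed (one word per use, never reused) by
#: label perturbation; disjoint from filler and every label slice.
_PERTURB_BASE = 30_000
_LABEL_BASE = 300
_LABEL_SLICE = 600
_PREFIX_SLOTS = {"DOID": 0, "CHEBI": 1, "SYMP": 2, "GO": 3}


def _label_pool(prefix: str) -> list[str]:
    slot = _PREFIX_SLOTS.get(prefix)
    if slot is None:
        slot = 4 + sum(ord(c) for c in prefix) % 16
    start = _LABEL_BASE + slot * _LABEL_SLICE
    return _words(start, _LABEL_SLICE)


# --- config and logs -------------------------------------------------------


@dataclass(frozen=True)
class FixtureConfig:
    """Knobs for one fixture suite; identical configs give identical bytes.

    Defaults are deliberately modest desk-scale analogues of the study
    conditions: a few dozen terms with roughly half carrying a synonym, a
    few hundred pairs with a high planted-valid fraction (generated
    biomedical terms verify at high rates against their ontologies), and a
    corpus spanning the three 2009–2024 publication periods with a majority
    of pairs attested at least once.
    """

    seed: int = 0
    n_terms: int = 50
    synonym_rate: float = 0.5
    n_pairs: int = 200
    valid_fraction: float = 0.8
    n_abstracts: int = 100
    plant_fraction: float = 0.6
    year_range: tuple[int, int] = (2009, 2024)
    #: geometric continuation probability for extra planted abstracts per
    #: planted pair (mean plants per planted pair = 1/(1-rate)).
    extra_plant_rate: float = 0.3
    #: fraction of corpus records emitted without a year field.
    missing_year_rate: float = 0.0

    def __post_init__(self) -> None:
        for name in ("synonym_rate", "valid_fraction", "plant_fraction",
                     "extra_plant_rate", "missing_year_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_terms", "n_pairs", "n_abstracts"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class PairPlant:
    """Ground truth for one generated pair."""

    index: int
    source_id: str
    source_label: str
    target_id: str
    target_label: str
    source_valid: bool
    target_valid: bool
    planted_abstract_ids: list[str] = field(default_factory=list)

    @property
    def both_valid(self) -> bool:
        return self.source_valid and self.target_valid


@dataclass
class PlantLog:
    """Per-pair ground truth covering validity and corpus plants."""

    pairs: list[PairPlant] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps([asdict(p) for p in self.pairs], indent=2) + "\n"

    @property
    def n_planted(self) -> int:
        return sum(1 for p in self.pairs if p.planted_abstract_ids)


# --- ontology generation ---------------------------------------------------

_SCOPES = (
    SynonymScope.EXACT,
    SynonymScope.RELATED,
    SynonymScope.NARROW,
    SynonymScope.BROAD,
)


class _LabelFactory:
    """Draws unique, mutually non-contained multi-word labels from a pool."""

    def __init__(self, pool: Sequence[str], rng: random.Random) -> None:
        self.pool = list(pool)
        self.rng = rng
        self.accepted: set[tuple[str, ...]] = set()
        self.subruns: set[tuple[str, ...]] = set()

    def _runs(self, tokens: tuple[str, ...]):
        for i in range(len(tokens)):
            for j in range(i + 1, len(tokens) + 1):
                yield tokens[i:j]

    def draw(self) -> str:
        for _ in range(10_000):
            k = self.rng.choice((1, 2, 2, 3))
            tokens = tuple(self.rng.choice(self.pool) for _ in range(k))
            if tokens in self.subruns:
                continue  # contained in (or equal to) an accepted label
            if any(run in self.accepted for run in self._runs(tokens)):
                continue  # would contain an accepted label
            self.accepted.add(tokens)
            self.subruns.update(self._runs(tokens))
            return " ".join(tokens)
        raise RuntimeError("label pool exhausted")


def gen_ontology(
    config: FixtureConfig, prefix: str
) -> tuple[str, list[OntologyTerm]]:
    """Generate a miniature OBO ontology for one CURIE prefix.

    Emits ``config.n_terms`` terms with pronounceable multi-word labels;
    each term gains one synonym with probability ``config.synonym_rate``,
    its scope drawn uniformly from the four OBO scopes. GO identifiers are
    7 digits, other prefixes use shorter local ids. Returns the OBO text
    and the term manifest.
    """
    if config.n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    rng = random.Random(f"{config.seed}|ontology|{prefix}")
    factory = _LabelFactory(_label_pool(prefix), rng)
    if prefix == "GO":
        start = rng.randrange(1_000_000, 9_000_000)
        fmt = "{:07d}"
    else:
        start = rng.randrange(1_000, 90_000)
        fmt = "{}"
    terms = []
    for i in range(config.n_terms):
        synonyms = []
        if rng.random() < config.synonym_rate:
            synonyms.append(
                SynonymEntry(text=factory.draw(), scope=rng.choice(_SCOPES))
            )
        terms.append(
            OntologyTerm(
                id=f"{prefix}:{fmt.format(start + i)}",
                name=factory.draw(),
                synonyms=synonyms,
            )
        )
    lines = ["format-version: 1.2", f"ontology: {prefix.lower()}", ""]
    for term in terms:
        lines.append("[Term]")
        lines.append(f"id: {term.id}")
        lines.append(f"name: {term.name}")
        for syn in term.synonyms:
            lines.append(f'synonym: "{syn.text}" {syn.scope.value} []')
        lines.append("")
    return "\n".join(lines), terms


# --- association generation ------------------------------------------------


def _perturb(label: str, rng: random.Random, fresh: "Iterator[str]") -> str:
    """Corrupt a label so it cannot match any ontology label.

    One token is replaced by one or two out-of-vocabulary words (the pair
    optionally hyphen-joined). Replacement words come from ``fresh`` — a
    stream that never repeats a word within a generation run and is
    disjoint from every label vocabulary — so a perturbed label can
    neither equal nor contain a full ontology label, and two perturbed
    labels can never accidentally coincide.
    """
    tokens = label.split()
    pos = rng.randrange(len(tokens))
    w1 = next(fresh)
    style = rng.random()
    if style < 0.4:
        repl = w1  # lay paraphrase: single foreign token
    elif style < 0.7:
        repl = f"{w1} {next(fresh)}"  # verbose rewording
    else:
        repl = f"{w1}-{next(fresh)}"  # punctuation variant
    tokens[pos] = repl
    return " ".join(tokens)


def _assoc_type_for(src_prefix: str, tgt_prefix: str) -> str:
    for assoc_type, prefixes in ASSOC_PREFIXES.items():
        if prefixes == (src_prefix, tgt_prefix):
            return assoc_type
    raise ValueError(f"no association type for prefixes {src_prefix}->{tgt_prefix}")


def _endpoint(
    term: OntologyTerm,
    valid: bool,
    rng: random.Random,
    ontology: Ontology,
    fresh: "Iterator[str]",
) -> str:
    if valid:
        if term.synonyms and rng.random() < 0.3:
            return rng.choice(term.synonyms).text
        return term.name
    label = _perturb(term.name, rng, fresh)
    assert normalize_label(label) not in ontology.label_index
    return label


def gen_association_set(
    ontology_src: Ontology,
    ontology_tgt: Ontology,
    config: FixtureConfig,
) -> tuple[str, PlantLog]:
    """Generate an association file with a controlled valid-label fraction.

    Each endpoint independently carries a real ontology label (name or,
    sometimes, a synonym) with probability ``config.valid_fraction``;
    otherwise the label is perturbed so that it provably fails term
    verification. CURIE ids always refer to the real drawn terms. Returns
    the serialized JSON array and the plant log recording per-endpoint
    validity.
    """
    if not ontology_src.terms_by_id or not ontology_tgt.terms_by_id:
        raise ValueError("both ontologies must be non-empty")
    assoc_type = _assoc_type_for(ontology_src.prefix, ontology_tgt.prefix)
    rng = random.Random(
        f"{config.seed}|pairs|{ontology_src.prefix}|{ontology_tgt.prefix}"
    )
    src_terms = sorted(ontology_src.terms_by_id.values(), key=lambda t: t.id)
    tgt_terms = sorted(ontology_tgt.terms_by_id.values(), key=lambda t: t.id)
    fresh = (_word(i) for i in count(_PERTURB_BASE))
    log = PlantLog()
    pairs: list[AssociationPair] = []
    seen: set[tuple] = set()
    attempts = 0
    while len(pairs) < config.n_pairs:
        attempts += 1
        if attempts > 100 * max(config.n_pairs, 1):
            raise RuntimeError("could not generate enough distinct pairs")
        src = rng.choice(src_terms)
        tgt = rng.choice(tgt_terms)
        src_valid = rng.random() < config.valid_fraction
        tgt_valid = rng.random() < config.valid_fraction
        pair = AssociationPair(
            source_id=src.id,
            source_label=_endpoint(src, src_valid, rng, ontology_src, fresh),
            target_id=tgt.id,
            target_label=_endpoint(tgt, tgt_valid, rng, ontology_tgt, fresh),
            assoc_type=assoc_type,
        )
        if pair.key() in seen:
            continue
        seen.add(pair.key())
        log.pairs.append(
            PairPlant(
                index=len(pairs),
                source_id=pair.source_id,
                source_label=pair.source_label,
                target_id=pair.target_id,
                target_label=pair.target_label,
                source_valid=src_valid,
                target_valid=tgt_valid,
            )
        )
        pairs.append(pair)
    return serialize_associations(pairs), log


# --- corpus generation -----------------------------------------------------


def _sentence(rng: random.Random, n_lo: int, n_hi: int) -> list[str]:
    return [rng.choice(_FILLER_WORDS) for _ in range(rng.randint(n_lo, n_hi))]


def gen_corpus(
    pairs: Sequence[AssociationPair],
    config: FixtureConfig,
    plant_log: PlantLog | None = None,
) -> tuple[str, PlantLog]:
    """Generate a JSONL corpus with planted co-occurrences.

    A ``config.plant_fraction`` share of pairs receives one or more
    abstracts containing both labels verbatim inside filler sentences (the
    count per planted pair is geometric with continuation probability
    ``config.extra_plant_rate``); the remaining abstracts are filler that
    contains at most one label of any pair. Years are uniform over
    ``config.year_range``. When ``plant_log`` (from
    :func:`gen_association_set`) is supplied, planted abstract ids are
    recorded into it; otherwise a fresh log is created.
    """
    if not pairs:
        raise ValueError("pairs must be non-empty")
    rng = random.Random(f"{config.seed}|corpus")
    if plant_log is None:
        plant_log = PlantLog(
            pairs=[
                PairPlant(
                    index=i,
                    source_id=p.source_id,
                    source_label=p.source_label,
                    target_id=p.target_id,
                    target_label=p.target_label,
                    source_valid=True,
                    target_valid=True,
                )
                for i, p in enumerate(pairs)
            ]
        )
    if len(plant_log.pairs) != len(pairs):
        raise ValueError("plant_log does not cover the pair list")

    drafts: list[tuple[int | None, list[str]]] = []  # (pair index or None, words)
    for i, pair in enumerate(pairs):
        if rng.random() >= config.plant_fraction:
            continue
        n_plants = 1
        while rng.random() < config.extra_plant_rate:
            n_plants += 1
        for _ in range(n_plants):
            words = (
                _sentence(rng, 4, 9)
                + [pair.source_label]
                + _sentence(rng, 2, 5)
                + [pair.target_label]
                + _sentence(rng, 4, 9)
            )
            drafts.append((i, words))
    n_filler = max(config.n_abstracts - len(drafts), 0)
    for _ in range(n_filler):
        words = _sentence(rng, 12, 25)
        if rng.random() < 0.3:
            pair = rng.choice(list(pairs))
            label = pair.source_label if rng.random() < 0.5 else pair.target_label
            pos = rng.randrange(len(words) + 1)
            words = words[:pos] + [label] + words[pos:]
        drafts.append((None, words))
    rng.shuffle(drafts)

    lines = []
    for n, (pair_idx, words) in enumerate(drafts):
        record_id = f"A{n:06d}"
        year: int | None = rng.randint(*config.year_range)
        if rng.random() < config.missing_year_rate:
            year = None
        title = " ".join(_sentence(rng, 3, 6))
        record = {
            "id": record_id,
            "year": year,
            "title": title,
            "abstract": " ".join(words) + ".",
        }
        lines.append(json.dumps(record, ensure_ascii=False))
        if pair_idx is not None:
            plant_log.pairs[pair_idx].planted_abstract_ids.append(record_id)
    return "\n".join(lines) + "\n", plant_log


# --- exact consistency setups ----------------------------------------------


def gen_planted_setup(
    n_pairs: int,
    n_verified: int,
    assoc_type: str,
    seed: int = 0,
    pairs_per_abstract: int = 50,
    corpus_label: str = "planted",
) -> tuple[list[AssociationPair], Corpus]:
    """Pairs and a corpus in which exactly ``n_verified`` pairs co-occur.

    Every pair gets globally unique single-word labels; the first
    ``n_verified`` pairs (after a seeded shuffle) are written into chunked
    abstracts, the rest appear nowhere, so the verified count is exact by
    construction. Used for cross-model consistency experiments at realistic
    pair-set sizes.
    """
    if not 0 <= n_verified <= n_pairs:
        raise ValueError("need 0 <= n_verified <= n_pairs")
    src_prefix, tgt_prefix = ASSOC_PREFIXES[assoc_type]
    rng = random.Random(f"{seed}|planted|{assoc_type}")
    base = 50_000 + 4 * _N_SYL**2  # far past every fixture vocabulary slice
    pairs = []
    for i in range(n_pairs):
        local_src = 1_000_000 + i if src_prefix == "GO" else 10_000 + i
        local_tgt = 2_000_000 + i if tgt_prefix == "GO" else 500_000 + i
        pairs.append(
            AssociationPair(
                source_id=f"{src_prefix}:{local_src:07d}" if src_prefix == "GO" else f"{src_prefix}:{local_src}",
                source_label=_word(base + 2 * i),
                target_id=f"{tgt_prefix}:{local_tgt:07d}" if tgt_prefix == "GO" else f"{tgt_prefix}:{local_tgt}",
                target_label=_word(base + 2 * i + 1),
                assoc_type=assoc_type,
            )
        )
    order = list(range(n_pairs))
    rng.shuffle(order)
    planted = [pairs[i] for i in order[:n_verified]]
    records = []
    for chunk_start in range(0, len(planted), pairs_per_abstract):
        chunk = planted[chunk_start : chunk_start + pairs_per_abstract]
        words: list[str] = []
        for pair in chunk:
            words.extend(_sentence(rng, 1, 3))
            words.append(pair.source_label)
            words.append(pair.target_label)
        records.append(
            AbstractRecord(
                record_id=f"S{chunk_start:06d}",
                year=rng.randint(2009, 2024),
                text=" ".join(words),
            )
        )
    if not records:
        records.append(
            AbstractRecord(
                record_id="S000000",
                year=rng.randint(2009, 2024),
                text=" ".join(_sentence(rng, 10, 20)),
            )
        )
    return pairs, Corpus(label=corpus_label, records=records)


# --- full suite ------------------------------------------------------------


@dataclass
class FixtureSuite:
    """Everything one end-to-end run needs, generated from one config."""

    config: FixtureConfig
    source_obo: str
    target_obo: str
    source_ontology: Ontology
    target_ontology: Ontology
    pairs_json: str
    pairs: list[AssociationPair]
    corpus_jsonl: str
    corpus: Corpus
    plant_log: PlantLog


def gen_suite(
    config: FixtureConfig,
    assoc_type: str = "disease_symptom",
) -> FixtureSuite:
    """Generate a coherent ontology-pair / associations / corpus suite."""
    from io import StringIO

    from .associations import parse_associations
    from .coverage import read_corpus_jsonl
    from .ontology import parse_obo

    src_prefix, tgt_prefix = ASSOC_PREFIXES[assoc_type]
    src_obo, _ = gen_ontology(config, src_prefix)
    tgt_obo, _ = gen_ontology(config, tgt_prefix)
    src_ont = parse_obo(StringIO(src_obo), src_prefix)
    tgt_ont = parse_obo(StringIO(tgt_obo), tgt_prefix)
    pairs_json, log = gen_association_set(src_ont, tgt_ont, config)
    pairs = parse_associations(pairs_json, assoc_type).pairs
    corpus_jsonl, log = gen_corpus(pairs, config, plant_log=log)
    import tempfile, os

    # materialize through the real reader so the loader path is exercised
    with tempfile.NamedTemporaryFile(
        "w", suffix=".jsonl", delete=False, encoding="utf-8"
    ) as handle:
        handle.write(corpus_jsonl)
        tmp = handle.name
    try:
        corpus = read_corpus_jsonl(tmp, label=f"fixture:{assoc_type}")
    finally:
        os.unlink(tmp)
    return FixtureSuite(
        config=config,
        source_obo=src_obo,
        target_obo=tgt_obo,
        source_ontology=src_ont,
        target_ontology=tgt_ont,
        pairs_json=pairs_json,
        pairs=pairs,
        corpus_jsonl=corpus_jsonl,
        corpus=corpus,
        plant_log=log,
    )
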