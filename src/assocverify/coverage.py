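"""Association verification by literature co-occurrence.

An association is "verified" by a corpus when at least one abstract contains
both of its term labels; the number of such abstracts is the pair's
co-occurrence counter, and the fraction of pairs with a positive counter is
the coverage of that association type. Containment is strict: the label's
normalized token sequence must occur contiguously at word boundaries in the
normalized abstract text ("rash" does not match "rashes"). Each abstract
contributes at most one count per pair regardless of repeat mentions.

Corpora are read from JSONL (``id``/``year``/``title``/``abstract``) or
MEDLINE flat files, and can be stratified into the three five-year
publication periods 2009–2014, 2015–2019 and 2020–2024 to measure how
coverage shifts with publication recency. Cross-model consistency reports
run the same pairs against one corpus per generator model.

Matching is exact-by-construction but accelerated: an inverted token index
over the corpus narrows each pair to candidate abstracts containing all
tokens of both labels, and contiguity is then confirmed by substring search.
Synonym expansion (counting an abstract when it contains any ontology
synonym of the term rather than the generated label itself) is off by
default and available via ``synonym_expansion``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .associations import AssociationPair, ConfigurationError
from .ontology import Ontology, normalize_label

__all__ = [
    "AbstractRecord",
    "Corpus",
    "PairCoverage",
    "CoverageReport",
    "ConsistencyRow",
    "PERIODS",
    "assign_period",
    "split_by_period",
    "contains_label",
    "count_cooccurrence",
    "verify_associations",
    "coverage_report",
    "consistency_report",
    "read_corpus_jsonl",
    "read_corpus_medline",
]

logger = logging.getLogger(__name__)

#: Five-year publication periods used for stratified coverage.
PERIODS: tuple[tuple[str, int, int], ...] = (
    ("P1", 2009, 2014),
    ("P2", 2015, 2019),
    ("P3", 2020, 2024),
)

PERIOD_SPANS: dict[str, tuple[int, int]] = {p: (lo, hi) for p, lo, hi in PERIODS}


def assign_period(year: int | None) -> str | None:
    """Map a publication year to its period label (P1/P2/P3), or None."""
    if year is None:
        return None
    for label, lo, hi in PERIODS:
        if lo <= year <= hi:
            return label
    return None


@dataclass(frozen=True)
class AbstractRecord:
    """One literature record: opaque id, optional year, title+abstract text."""

    record_id: str
    year: int | None
    text: str


@dataclass
class Corpus:
    """A named collection of abstracts with unique record ids."""

    label: str
    records: list[AbstractRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [r.record_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError(f"corpus {self.label!r} has duplicate record ids")

    def __len__(self) -> int:
        return len(self.records)


def split_by_period(corpus: Corpus) -> tuple[dict[str, Corpus], int]:
    """Partition a corpus into period sub-corpora.

    Returns (period label -> sub-corpus, number of records excluded for
    missing or out-of-span years); exclusions are logged.
    """
    buckets: dict[str, list[AbstractRecord]] = {p: [] for p, _, _ in PERIODS}
    excluded = 0
    for record in corpus.records:
        period = assign_period(record.year)
        if period is None:
            excluded += 1
        else:
            buckets[period].append(record)
    if excluded:
        logger.info(
            "corpus %s: %d records excluded from period stratification "
            "(missing or out-of-span year)",
            corpus.label,
            excluded,
        )
    return (
        {p: Corpus(label=f"{corpus.label}:{p}", records=recs) for p, recs in buckets.items()},
        excluded,
    )


# --- containment and counting ---------------------------------------------


def contains_label(text: str, label: str) -> bool:
    """Whole-token contiguous containment under the normalization policy."""
    norm_label = normalize_label(label)
    if not norm_label:
        return False
    return f" {norm_label} " in f" {normalize_label(text)} "


def _expand(label: str, term_id: str, ontology: Ontology | None) -> list[str]:
    """The label plus, with synonym expansion, the id's name and synonyms."""
    variants = [label]
    if ontology is not None:
        term = ontology.terms_by_id.get(term_id)
        if term is not None and not term.obsolete:
            variants.append(term.name)
            variants.extend(s.text for s in term.synonyms)
    # normalized, deduplicated, original label first
    seen: set[str] = set()
    out = []
    for v in variants:
        key = normalize_label(v)
        if key and key not in seen:
            seen.add(key)
            out.append(key)
    return out


class _CorpusIndex:
    """Normalized texts plus an inverted token index for candidate pruning."""

    def __init__(self, corpus: Corpus) -> None:
        self.texts: list[str] = []
        self.token_index: dict[str, set[int]] = {}
        for i, record in enumerate(corpus.records):
            norm = normalize_label(record.text)
            self.texts.append(f" {norm} ")
            for token in set(norm.split()):
                self.token_index.setdefault(token, set()).add(i)

    def candidates(self, norm_labels: Sequence[str]) -> set[int]:
        """Abstracts containing every token of at least one label variant."""
        hits: set[int] = set()
        for norm in norm_labels:
            tokens = norm.split()
            sets = [self.token_index.get(t) for t in tokens]
            if any(s is None for s in sets):
                continue
            cand = set.intersection(*sets)  # type: ignore[arg-type]
            hits.update(cand)
        return hits

    def matches(self, norm_labels: Sequence[str]) -> set[int]:
        """Abstract indexes containing any variant as a contiguous token run."""
        out: set[int] = set()
        for i in self.candidates(norm_labels):
            text = self.texts[i]
            for norm in norm_labels:
                if f" {norm} " in text:
                    out.add(i)
                    break
        return out


def count_cooccurrence(
    pair: AssociationPair,
    corpus: Corpus,
    synonym_expansion: tuple[Ontology, Ontology] | None = None,
) -> int:
    """Number of abstracts containing both terms of the pair.

    With ``synonym_expansion`` = (source ontology, target ontology), a term
    counts as present when its generated label *or* any name/synonym of its
    CURIE's ontology entry is contained. Symmetric in source and target.
    """
    coverages = verify_associations([pair], corpus, synonym_expansion)
    return coverages[0].counter


@dataclass(frozen=True)
class PairCoverage:
    """Co-occurrence outcome for one pair against one corpus."""

    pair: AssociationPair
    counter: int

    @property
    def verified(self) -> bool:
        return self.counter > 0


def verify_associations(
    pairs: Sequence[AssociationPair],
    corpus: Corpus,
    synonym_expansion: tuple[Ontology, Ontology] | None = None,
) -> list[PairCoverage]:
    """Count co-occurring abstracts for every pair; order-preserving.

    Every input pair appears in the result, zero-counter (unverified) pairs
    included.
    """
    index = _CorpusIndex(corpus)
    src_ont = synonym_expansion[0] if synonym_expansion else None
    tgt_ont = synonym_expansion[1] if synonym_expansion else None
    out = []
    for pair in pairs:
        src_hits = index.matches(_expand(pair.source_label, pair.source_id, src_ont))
        tgt_hits = index.matches(_expand(pair.target_label, pair.target_id, tgt_ont))
        out.append(PairCoverage(pair=pair, counter=len(src_hits & tgt_hits)))
    return out


# --- reports ---------------------------------------------------------------


@dataclass(frozen=True)
class CoverageReport:
    """Verified/unverified split and mean support for one type × period group.

    ``avg_frequency`` is the mean counter over *verified* pairs only (the
    average number of supporting abstracts per supported association);
    it is None when no pair in the group is verified. ``verified_pct`` and
    ``unverified_pct`` sum to exactly 100 before any rounding.
    """

    assoc_type: str
    period: str
    n_pairs: int
    verified_pct: float
    unverified_pct: float
    avg_frequency: float | None


def coverage_report(
    groups: Mapping[tuple[str, str], Sequence[PairCoverage]],
) -> list[CoverageReport]:
    """Aggregate grouped pair coverages into report rows.

    ``groups`` maps (association type, period label) to that group's pair
    coverages; an empty group is an error (its percentages are undefined).
    """
    rows = []
    for (assoc_type, period), coverages in groups.items():
        n = len(coverages)
        if n == 0:
            raise ValueError(f"empty coverage group: {assoc_type}/{period}")
        verified = [c for c in coverages if c.verified]
        verified_pct = 100.0 * len(verified) / n
        avg = (
            sum(c.counter for c in verified) / len(verified) if verified else None
        )
        rows.append(
            CoverageReport(
                assoc_type=assoc_type,
                period=period,
                n_pairs=n,
                verified_pct=verified_pct,
                unverified_pct=100.0 - verified_pct,
                avg_frequency=avg,
            )
        )
    return rows


@dataclass(frozen=True)
class ConsistencyRow:
    """One model × association-type row of a cross-model consistency report."""

    model: str
    assoc_type: str
    count: int
    total: int
    percentage: float


def consistency_report(
    pairs_by_type: Mapping[str, Sequence[AssociationPair]],
    corpora_by_model: Mapping[str, Corpus],
    models: Sequence[str] | None = None,
) -> list[ConsistencyRow]:
    """Verified-pair counts and percentages per model corpus and type.

    For each model's corpus and each association type: ``count`` pairs have
    a positive co-occurrence counter out of ``total`` pairs of that type,
    giving ``percentage`` = 100·count/total (unrounded; renderers round
    half-up to two decimals). Listing a model without a corpus raises
    :class:`ConfigurationError`.
    """
    model_list = list(models) if models is not None else list(corpora_by_model)
    missing = [m for m in model_list if m not in corpora_by_model]
    if missing:
        raise ConfigurationError(f"no corpus for model(s): {', '.join(missing)}")
    rows = []
    for model in model_list:
        corpus = corpora_by_model[model]
        for assoc_type, pairs in pairs_by_type.items():
            if not pairs:
                raise ValueError(f"no pairs of type {assoc_type}")
            coverages = verify_associations(list(pairs), corpus)
            count = sum(1 for c in coverages if c.verified)
            rows.append(
                ConsistencyRow(
                    model=model,
                    assoc_type=assoc_type,
                    count=count,
                    total=len(pairs),
                    percentage=100.0 * count / len(pairs),
                )
            )
    return rows


# --- corpus readers --------------------------------------------------------


def _build_corpus(
    label: str, raw: Iterable[tuple[str, int | None, str]]
) -> Corpus:
    records = []
    skipped = 0
    for record_id, year, text in raw:
        if not text.strip():
            skipped += 1
            continue
        records.append(AbstractRecord(record_id=record_id, year=year, text=text))
    if skipped:
        logger.info("corpus %s: %d empty records skipped", label, skipped)
    return Corpus(label=label, records=records)


def read_corpus_jsonl(path: str | Path, label: str | None = None) -> Corpus:
    """Read a JSONL corpus with fields ``id``, ``year``, ``title``, ``abstract``.

    ``text`` is the title and abstract concatenated; ``year`` may be null.
    """
    path = Path(path)

    def rows():
        for line in path.read_text(encoding="utf-8").splitlines():
            if not line.strip():
                continue
            obj = json.loads(line)
            year = obj.get("year")
            yield (
                str(obj["id"]),
                int(year) if year is not None else None,
                " ".join(filter(None, (obj.get("title"), obj.get("abstract")))),
            )

    return _build_corpus(label or path.stem, rows())


def read_corpus_medline(path: str | Path, label: str | None = None) -> Corpus:
    """Read a MEDLINE flat file (PMID / DP / TI / AB fields)."""
    from Bio import Medline

    path = Path(path)

    def rows():
        with open(path, encoding="utf-8") as handle:
            for rec in Medline.parse(handle):
                pmid = rec.get("PMID")
                if pmid is None:
                    continue
                dp = rec.get("DP", "")
                year = None
                head = dp.strip()[:4]
                if head.isdigit():
                    year = int(head)
                yield (
                    str(pmid),
                    year,
                    " ".join(filter(None, (rec.get("TI"), rec.get("AB")))),
                )

    return _build_corpus(label or path.stem, rows())
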