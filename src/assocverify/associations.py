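"""Reading, validating and writing association files.

An association is a typed pair of ontology terms — disease–drug,
disease–symptom, disease–gene, or genetic-process–gene — serialized as a
two-key JSON object mapping each CURIE to its label, disease (source) first::

    {"DOID:11734": "Epistaxis", "SYMP:1080": "Nosebleed"}

Files are either a JSON array of such objects or one object per line
(JSONL); both dialects are read, the array form is written. Generators are
sloppy about identifiers, so parsing is defensive: every record is checked
for arity, CURIE syntax and non-empty labels, rejects are collected with
machine-readable reasons, and exact duplicates (after label normalization)
are collapsed and counted. Generated output also mixes prefix spellings
(``SYMPTOM:`` for the SYMP ontology), handled by a configurable prefix-alias
table applied at parse time.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

from .ontology import normalize_label

__all__ = [
    "AssociationPair",
    "ParseOutcome",
    "RejectedRecord",
    "AssociationParseError",
    "ConfigurationError",
    "ASSOC_TYPES",
    "ASSOC_PREFIXES",
    "DEFAULT_ALIASES",
    "validate_curie",
    "parse_associations",
    "read_associations",
    "write_associations",
    "serialize_associations",
]

#: Expected (source, target) CURIE prefixes for each association type.
ASSOC_PREFIXES: dict[str, tuple[str, str]] = {
    "disease_drug": ("DOID", "CHEBI"),
    "disease_symptom": ("DOID", "SYMP"),
    "disease_gene": ("DOID", "GO"),
    "process_gene": ("GO", "GO"),
}

ASSOC_TYPES = tuple(ASSOC_PREFIXES)

#: Prefix spellings accepted and rewritten at parse time.
DEFAULT_ALIASES: dict[str, str] = {"SYMPTOM": "SYMP"}


class AssociationParseError(ValueError):
    """Top-level association document could not be parsed at all."""


class ConfigurationError(ValueError):
    """Inputs are inconsistent with each other (wrong ontology, missing corpus)."""


_CURIE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9_]*):(\d+)$")


def validate_curie(
    curie: str,
    expected_prefix: str,
    aliases: Mapping[str, str] | None = None,
) -> bool:
    """True iff ``curie`` is ``<PREFIX>:<digits>`` for the expected prefix.

    GO identifiers must carry exactly 7 digits; the other supported
    prefixes accept any non-empty digit run. Prefix comparison is
    case-sensitive; ``aliases`` maps accepted alternative spellings onto
    canonical prefixes (e.g. ``SYMPTOM`` -> ``SYMP``) before comparison.
    """
    if not isinstance(curie, str):
        return False
    m = _CURIE_RE.match(curie.strip())
    if m is None:
        return False
    prefix, digits = m.groups()
    if aliases:
        prefix = aliases.get(prefix, prefix)
    if prefix != expected_prefix:
        return False
    if expected_prefix == "GO":
        return len(digits) == 7
    return True


def _canonical_curie(curie: str, aliases: Mapping[str, str] | None) -> str:
    prefix, _, local = curie.strip().partition(":")
    if aliases and prefix in aliases:
        return f"{aliases[prefix]}:{local}"
    return curie.strip()


@dataclass(frozen=True)
class AssociationPair:
    """A typed source→target term pair with CURIE ids and labels."""

    source_id: str
    source_label: str
    target_id: str
    target_label: str
    assoc_type: str

    def key(self) -> tuple[str, str, str, str]:
        """Identity used for duplicate collapse: ids plus normalized labels."""
        return (
            self.source_id,
            normalize_label(self.source_label),
            self.target_id,
            normalize_label(self.target_label),
        )


@dataclass(frozen=True)
class RejectedRecord:
    raw: str
    reason: str


@dataclass
class ParseOutcome:
    """Partition of input records into accepted pairs, rejects and duplicates.

    Invariant (checked by tests): ``n_records == len(pairs) + len(rejected)
    + duplicates_removed``.
    """

    pairs: list[AssociationPair] = field(default_factory=list)
    rejected: list[RejectedRecord] = field(default_factory=list)
    duplicates_removed: int = 0

    @property
    def n_records(self) -> int:
        return len(self.pairs) + len(self.rejected) + self.duplicates_removed


def _record_to_pair(
    record: object,
    assoc_type: str,
    aliases: Mapping[str, str] | None,
) -> AssociationPair | str:
    """Convert one decoded JSON value to a pair, or return a rejection reason."""
    if not isinstance(record, dict):
        return "record is not a JSON object"
    if len(record) != 2:
        return "ambiguous pair arity"
    src_prefix, tgt_prefix = ASSOC_PREFIXES[assoc_type]
    (src_id, src_label), (tgt_id, tgt_label) = record.items()
    if not validate_curie(src_id, src_prefix, aliases):
        return f"invalid source CURIE for {src_prefix}: {src_id!r}"
    if not validate_curie(tgt_id, tgt_prefix, aliases):
        return f"invalid target CURIE for {tgt_prefix}: {tgt_id!r}"
    if not isinstance(src_label, str) or not normalize_label(src_label):
        return "empty source label"
    if not isinstance(tgt_label, str) or not normalize_label(tgt_label):
        return "empty target label"
    return AssociationPair(
        source_id=_canonical_curie(src_id, aliases),
        source_label=src_label,
        target_id=_canonical_curie(tgt_id, aliases),
        target_label=tgt_label,
        assoc_type=assoc_type,
    )


def parse_associations(
    text: str,
    assoc_type: str,
    aliases: Mapping[str, str] | None = DEFAULT_ALIASES,
) -> ParseOutcome:
    """Parse association records from an in-memory document.

    Accepts a JSON array of two-key objects or JSONL (one object per line).
    In JSONL form a line failing JSON syntax becomes a rejected record; in
    array form an unparseable document raises :class:`AssociationParseError`
    naming the byte offset, because nothing can be salvaged.
    """
    if assoc_type not in ASSOC_PREFIXES:
        raise ConfigurationError(f"unknown association type: {assoc_type!r}")
    outcome = ParseOutcome()
    stripped = text.lstrip()
    records: list[tuple[str, object | None, str | None]] = []
    if stripped.startswith("["):
        try:
            decoded = json.loads(text)
        except json.JSONDecodeError as exc:
            raise AssociationParseError(
                f"invalid JSON document at byte offset {exc.pos}: {exc.msg}"
            ) from exc
        for item in decoded:
            records.append((json.dumps(item, ensure_ascii=False), item, None))
    else:
        for line in text.splitlines():
            if not line.strip():
                continue
            try:
                records.append((line, json.loads(line), None))
            except json.JSONDecodeError as exc:
                records.append((line, None, f"invalid JSON line: {exc.msg}"))

    seen: set[tuple[str, str, str, str]] = set()
    for raw, item, error in records:
        if error is not None:
            outcome.rejected.append(RejectedRecord(raw=raw, reason=error))
            continue
        result = _record_to_pair(item, assoc_type, aliases)
        if isinstance(result, str):
            outcome.rejected.append(RejectedRecord(raw=raw, reason=result))
            continue
        if result.key() in seen:
            outcome.duplicates_removed += 1
            continue
        seen.add(result.key())
        outcome.pairs.append(result)
    return outcome


def read_associations(
    path: str | Path,
    assoc_type: str,
    aliases: Mapping[str, str] | None = DEFAULT_ALIASES,
) -> ParseOutcome:
    """Read and validate an association file (JSON array or JSONL)."""
    text = Path(path).read_text(encoding="utf-8")
    return parse_associations(text, assoc_type, aliases=aliases)


def serialize_associations(pairs: list[AssociationPair]) -> str:
    """Deterministic JSON-array serialization (source key first)."""
    records = [
        {pair.source_id: pair.source_label, pair.target_id: pair.target_label}
        for pair in pairs
    ]
    return json.dumps(records, indent=2, ensure_ascii=False) + "\n"


def write_associations(pairs: list[AssociationPair], path: str | Path) -> None:
    """Write pairs as a JSON array; round-trips exactly through reading."""
    Path(path).write_text(serialize_associations(pairs), encoding="utf-8")
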