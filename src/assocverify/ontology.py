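"""OBO ontology loading and normalized label lookup.

Term verification needs two things from an ontology: the primary name of
every term and every synonym attached to it, both reachable through a single
deterministic normalization policy. Real-world mismatches are dominated by
casing, punctuation, and whitespace variants, so normalization is aggressive:
Unicode NFKC, case-folding, punctuation replaced by spaces, whitespace
collapsed. Matching beyond that (fuzzy, embedding) is deliberately out of
scope — a label either equals a name/synonym under the policy or it does not.

The loader is a line-oriented OBO 1.2/1.4 flat-file reader that keeps
synonym scopes (EXACT/RELATED/NARROW/BROAD) and collects record-level parse
problems instead of aborting: a malformed stanza costs one term, not the run.
"""

from __future__ import annotations

import enum
import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, TextIO

__all__ = [
    "SynonymScope",
    "SynonymEntry",
    "OntologyTerm",
    "Ontology",
    "MatchKind",
    "normalize_label",
    "lookup",
    "load_obo",
    "parse_obo",
]


class SynonymScope(str, enum.Enum):
    EXACT = "EXACT"
    RELATED = "RELATED"
    NARROW = "NARROW"
    BROAD = "BROAD"
    UNSPECIFIED = "UNSPECIFIED"


class MatchKind(str, enum.Enum):
    NAME = "NAME"
    SYNONYM = "SYNONYM"


_PUNCT_RE = re.compile(r"[^\w\s]|_")
_WS_RE = re.compile(r"\s+")


def normalize_label(text: str) -> str:
    """Canonical form used for every label comparison in the package.

    Applies, in order: Unicode NFKC compatibility normalization,
    case-folding, replacement of every punctuation character (hyphens and
    apostrophes included) by a space, whitespace collapse, and trimming.
    Deterministic and idempotent; empty input yields the empty string.

    >>> normalize_label("Bull's-Eye  Rash")
    'bull s eye rash'
    """
    text = unicodedata.normalize("NFKC", text).casefold()
    text = _PUNCT_RE.sub(" ", text)
    return _WS_RE.sub(" ", text).strip()


@dataclass(frozen=True)
class SynonymEntry:
    """One scoped synonym of an ontology term."""

    text: str
    scope: SynonymScope = SynonymScope.UNSPECIFIED


@dataclass
class OntologyTerm:
    """A single ontology entry: CURIE id, primary name, scoped synonyms."""

    id: str
    name: str
    synonyms: list[SynonymEntry] = field(default_factory=list)
    obsolete: bool = False


@dataclass
class Ontology:
    """An indexed ontology supporting exact name and synonym lookup.

    ``name_index`` and ``synonym_index`` map normalized labels to term ids;
    obsolete terms are stored in ``terms_by_id`` but never indexed, so they
    can be inspected yet never verify a generated term. ``parse_errors``
    carries record-level problems collected while loading.
    """

    prefix: str
    terms_by_id: dict[str, OntologyTerm] = field(default_factory=dict)
    name_index: dict[str, set[str]] = field(default_factory=dict)
    synonym_index: dict[str, set[str]] = field(default_factory=dict)
    parse_errors: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.terms_by_id)

    @property
    def label_index(self) -> dict[str, set[str]]:
        """Merged view: normalized label -> ids carrying it as name or synonym."""
        merged: dict[str, set[str]] = {}
        for index in (self.name_index, self.synonym_index):
            for label, ids in index.items():
                merged.setdefault(label, set()).update(ids)
        return merged

    def add_term(self, term: OntologyTerm) -> None:
        # Dedupe synonyms: keep the first entry per normalized text, and drop
        # synonyms that merely repeat the primary name.
        name_key = normalize_label(term.name)
        seen: set[str] = {name_key}
        unique: list[SynonymEntry] = []
        for syn in term.synonyms:
            key = normalize_label(syn.text)
            if not key or key in seen:
                continue
            seen.add(key)
            unique.append(syn)
        term.synonyms = unique
        self.terms_by_id[term.id] = term
        if term.obsolete:
            return
        if name_key:
            self.name_index.setdefault(name_key, set()).add(term.id)
        for syn in term.synonyms:
            self.synonym_index.setdefault(normalize_label(syn.text), set()).add(term.id)


def lookup(ontology: Ontology, label: str) -> set[tuple[str, MatchKind]]:
    """All non-obsolete terms matching ``label`` under the normalization policy.

    A term whose primary name matches is tagged ``NAME``; a term matching
    only through a synonym is tagged ``SYNONYM``. A term matching both ways
    is reported once, as ``NAME``. Empty labels match nothing.
    """
    key = normalize_label(label)
    if not key:
        return set()
    name_ids = ontology.name_index.get(key, set())
    hits = {(tid, MatchKind.NAME) for tid in name_ids}
    for tid in ontology.synonym_index.get(key, set()):
        if tid not in name_ids:
            hits.add((tid, MatchKind.SYNONYM))
    return hits


# --- OBO flat-file parsing -------------------------------------------------

_SYNONYM_RE = re.compile(
    r'"((?:[^"\\]|\\.)*)"\s*(EXACT|RELATED|NARROW|BROAD)?'
)


def _parse_synonym(value: str) -> SynonymEntry | None:
    m = _SYNONYM_RE.search(value)
    if m is None:
        return None
    text = m.group(1).replace('\\"', '"').replace("\\\\", "\\")
    scope = SynonymScope(m.group(2)) if m.group(2) else SynonymScope.UNSPECIFIED
    return SynonymEntry(text=text, scope=scope)


def _strip_comment(value: str) -> str:
    # OBO trailing comments start with an unescaped "!".
    out = []
    prev = ""
    for ch in value:
        if ch == "!" and prev != "\\":
            break
        out.append(ch)
        prev = ch
    return "".join(out).strip()


def parse_obo(lines: Iterable[str], prefix: str) -> Ontology:
    """Parse OBO flat-file lines into an :class:`Ontology`.

    Only ``[Term]`` stanzas are read; ``id``, ``name``, ``synonym`` and
    ``is_obsolete`` tags are interpreted, everything else is ignored. A
    stanza without an id (or without a name) is recorded in
    ``Ontology.parse_errors`` and skipped rather than aborting the load.
    """
    ontology = Ontology(prefix=prefix)
    in_term = False
    started = False
    current: dict | None = None

    def flush() -> None:
        nonlocal current
        if current is None:
            return
        if not current.get("id"):
            ontology.parse_errors.append(
                f"[Term] stanza starting at line {current['line']} has no id"
            )
        elif not current.get("name"):
            ontology.parse_errors.append(
                f"term {current['id']} has no name tag"
            )
        else:
            ontology.add_term(
                OntologyTerm(
                    id=current["id"],
                    name=current["name"],
                    synonyms=current["synonyms"],
                    obsolete=current["obsolete"],
                )
            )
        current = None

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line or line.startswith("!"):
            continue
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            started = True
            if in_term:
                current = {
                    "line": lineno,
                    "id": None,
                    "name": None,
                    "synonyms": [],
                    "obsolete": False,
                }
            continue
        if not in_term or not started or current is None:
            continue
        tag, sep, value = line.partition(":")
        if not sep:
            continue
        tag = tag.strip()
        value = value.strip()
        if tag == "id":
            current["id"] = _strip_comment(value)
        elif tag == "name":
            current["name"] = _strip_comment(value)
        elif tag == "synonym":
            entry = _parse_synonym(value)
            if entry is None or not normalize_label(entry.text):
                ontology.parse_errors.append(
                    f"unparseable synonym at line {lineno}: {value!r}"
                )
            else:
                current["synonyms"].append(entry)
        elif tag == "is_obsolete":
            current["obsolete"] = _strip_comment(value).lower() == "true"
    flush()
    return ontology


def load_obo(path: str | Path | TextIO, prefix: str) -> Ontology:
    """Load an OBO 1.2/1.4 flat file into an indexed :class:`Ontology`.

    ``prefix`` is the CURIE prefix the ontology is expected to carry
    (e.g. ``DOID``, ``CHEBI``, ``SYMP``, ``GO``); it is stored on the result
    and used downstream for association/ontology consistency checks.
    """
    if hasattr(path, "read"):
        return parse_obo(path, prefix)  # type: ignore[arg-type]
    with open(path, "r", encoding="utf-8") as handle:
        return parse_obo(handle, prefix)
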