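"""Semantic term verification against a domain ontology.

A generated term is VERIFIED when its label equals, under the shared
normalization policy, the primary name of some non-obsolete ontology term
(VERIFIED_NAME) or any of its scoped synonyms (VERIFIED_SYNONYM); otherwise
it is UNVERIFIED. All synonym scopes count — an ontology's RELATED synonyms
are part of how its curators expect the term to be referred to.

Aggregation mirrors the standard accuracy-report layout: the name rate
counts terms matching any primary name, the synonym rate counts terms
matching any synonym (whether or not they also match a name), and the
combined rate counts terms matching either, so combined >= max(name,
synonym) always holds. Percentages are kept unrounded internally and
rounded half-up to two decimals only for display.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .associations import AssociationPair, ConfigurationError
from .ontology import MatchKind, Ontology, lookup

__all__ = [
    "VerificationStatus",
    "TermVerdict",
    "VerificationReport",
    "verify_term",
    "verify_association_terms",
    "accuracy_report",
    "round_half_up",
]


class VerificationStatus(str, enum.Enum):
    VERIFIED_NAME = "VERIFIED_NAME"
    VERIFIED_SYNONYM = "VERIFIED_SYNONYM"
    UNVERIFIED = "UNVERIFIED"


def round_half_up(value: float, digits: int = 2) -> float:
    """Display rounding: half-up, as in printed accuracy tables (93.365 -> 93.37)."""
    quantum = Decimal(1).scaleb(-digits)
    return float(Decimal(repr(value)).quantize(quantum, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class TermVerdict:
    """Outcome of verifying one generated term against one ontology."""

    term_text: str
    status: VerificationStatus
    name_ids: frozenset[str] = frozenset()
    synonym_ids: frozenset[str] = frozenset()
    term_type: str | None = None

    @property
    def matched_ids(self) -> frozenset[str]:
        return self.name_ids | self.synonym_ids

    @property
    def verified(self) -> bool:
        return self.status is not VerificationStatus.UNVERIFIED


def verify_term(
    term_text: str, ontology: Ontology, term_type: str | None = None
) -> TermVerdict:
    """Verify one term label against an ontology's names and synonyms.

    Returns VERIFIED_NAME if any primary-name match exists, else
    VERIFIED_SYNONYM if any synonym match exists, else UNVERIFIED.
    ``matched_ids`` carries every matching term id (matching is set-valued:
    duplicate labels across terms are legal and never an error).
    """
    hits = lookup(ontology, term_text)
    name_ids = frozenset(tid for tid, kind in hits if kind is MatchKind.NAME)
    synonym_ids = frozenset(tid for tid, kind in hits if kind is MatchKind.SYNONYM)
    # A name-matched term may additionally match through a synonym of a
    # *different* term; record synonym evidence independently so component
    # rates can be computed over the same denominator.
    if name_ids:
        status = VerificationStatus.VERIFIED_NAME
    elif synonym_ids:
        status = VerificationStatus.VERIFIED_SYNONYM
    else:
        status = VerificationStatus.UNVERIFIED
    return TermVerdict(
        term_text=term_text,
        status=status,
        name_ids=name_ids,
        synonym_ids=synonym_ids,
        term_type=term_type,
    )


def verify_association_terms(
    pairs: Sequence[AssociationPair],
    source_ontology: Ontology,
    target_ontology: Ontology,
) -> list[tuple[AssociationPair, TermVerdict, TermVerdict]]:
    """Verify both endpoints of each association, order-preserving.

    Raises :class:`ConfigurationError` when a pair's CURIE prefixes do not
    match the supplied ontologies (e.g. disease pairs against a drug
    ontology).
    """
    results = []
    for pair in pairs:
        src_prefix = pair.source_id.split(":", 1)[0]
        tgt_prefix = pair.target_id.split(":", 1)[0]
        if src_prefix != source_ontology.prefix:
            raise ConfigurationError(
                f"pair source prefix {src_prefix} does not match "
                f"ontology prefix {source_ontology.prefix}"
            )
        if tgt_prefix != target_ontology.prefix:
            raise ConfigurationError(
                f"pair target prefix {tgt_prefix} does not match "
                f"ontology prefix {target_ontology.prefix}"
            )
        results.append(
            (
                pair,
                verify_term(pair.source_label, source_ontology),
                verify_term(pair.target_label, target_ontology),
            )
        )
    return results


@dataclass(frozen=True)
class VerificationReport:
    """Aggregated verification rates over a set of term verdicts.

    Percentages are unrounded; use :func:`round_half_up` (or the report
    renderers) for display. ``combined_pct`` counts terms with any match,
    so it is never below either component rate.
    """

    n_terms: int
    name_pct: float
    synonym_pct: float
    combined_pct: float

    def rounded(self) -> tuple[float, float, float]:
        return (
            round_half_up(self.name_pct),
            round_half_up(self.synonym_pct),
            round_half_up(self.combined_pct),
        )


def accuracy_report(verdicts: Sequence[TermVerdict]) -> VerificationReport:
    """Name / synonym / combined verification rates over one verdict list.

    All three rates share the denominator ``len(verdicts)``; the synonym
    rate counts every term with synonym evidence, including terms that also
    matched a primary name.
    """
    n = len(verdicts)
    if n == 0:
        raise ValueError("accuracy_report requires at least one verdict")
    n_name = sum(1 for v in verdicts if v.name_ids)
    n_syn = sum(1 for v in verdicts if v.synonym_ids)
    n_combined = sum(1 for v in verdicts if v.verified)
    return VerificationReport(
        n_terms=n,
        name_pct=100.0 * n_name / n,
        synonym_pct=100.0 * n_syn / n,
        combined_pct=100.0 * n_combined / n,
    )
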