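"""Rendering of the four report shapes as TSV (human) and JSON (machine).

All percentages are computed unrounded upstream and rounded half-up to two
decimals here, at the display boundary only. The JSON form is the stable
machine surface; the TSV form mirrors it column for column.
"""

from __future__ import annotations

import json
from typing import Sequence

from .associations import ParseOutcome
from .coverage import ConsistencyRow, CoverageReport
from .terms import VerificationReport, round_half_up

__all__ = [
    "verification_rows",
    "coverage_rows",
    "consistency_rows",
    "validation_rows",
    "to_tsv",
    "to_json",
]


def verification_rows(
    reports: Sequence[tuple[str, VerificationReport]],
) -> list[dict]:
    """Category / feature / accuracy rows for labelled verification reports.

    ``reports`` pairs a feature label (e.g. ``"disease"``/``"drug"``) with
    its report; each report expands to name, synonym and name/synonym rows.
    """
    rows = []
    for feature, report in reports:
        name_pct, syn_pct, combined_pct = report.rounded()
        rows.extend(
            [
                {"feature": f"{feature} name", "n": report.n_terms, "accuracy_pct": name_pct},
                {"feature": f"{feature} synonym", "n": report.n_terms, "accuracy_pct": syn_pct},
                {
                    "feature": f"{feature} name/synonym",
                    "n": report.n_terms,
                    "accuracy_pct": combined_pct,
                },
            ]
        )
    return rows


def coverage_rows(reports: Sequence[CoverageReport]) -> list[dict]:
    """Association type × period coverage rows (verified split and support)."""
    return [
        {
            "assoc_type": r.assoc_type,
            "period": r.period,
            "n_pairs": r.n_pairs,
            "unverified_pct": round_half_up(r.unverified_pct),
            "verified_pct": round_half_up(r.verified_pct),
            "avg_frequency": (
                round_half_up(r.avg_frequency) if r.avg_frequency is not None else None
            ),
        }
        for r in reports
    ]


def consistency_rows(rows: Sequence[ConsistencyRow]) -> list[dict]:
    """Model × association type consistency rows (count and percentage)."""
    return [
        {
            "model": r.model,
            "assoc_type": r.assoc_type,
            "count": r.count,
            "total": r.total,
            "percentage": round_half_up(r.percentage),
        }
        for r in rows
    ]


def validation_rows(outcome: ParseOutcome) -> list[dict]:
    """One row per rejected record of a parse outcome."""
    return [{"raw": r.raw, "reason": r.reason} for r in outcome.rejected]


def to_tsv(rows: Sequence[dict]) -> str:
    """Serialize rows as TSV with a header; deterministic column order."""
    if not rows:
        return "\n"
    columns = list(rows[0])
    lines = ["\t".join(columns)]
    for row in rows:
        lines.append("\t".join("" if row[c] is None else str(row[c]) for c in columns))
    return "\n".join(lines) + "\n"


def to_json(rows: Sequence[dict]) -> str:
    """Serialize rows as a JSON array; byte-deterministic."""
    return json.dumps(list(rows), indent=2, ensure_ascii=False, sort_keys=True) + "\n"
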