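"""One-shot prompt construction and generator-response parsing.

Association generation is driven by a one-shot prompt: an instruction
sentence naming the association type and the requested record count,
followed by exactly one worked example (the "shot") in the two-key JSON
record format. The text generator behind the prompt is a pluggable,
synchronous text-in/text-out contract — any API client, fixture file or
mock satisfies it — and responses are parsed with the same defensive
machinery as association files, so invalid JSON is reported as data, never
raised.

:class:`MockGenerator` is the hermetic stand-in for a live model: seeded,
byte-deterministic, with configurable fractions of invalid-JSON responses,
bad CURIEs and duplicate records to exercise every rejection path, and a
ground-truth log of everything it emitted.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from typing import Protocol

from .associations import (
    ASSOC_PREFIXES,
    AssociationPair,
    AssociationParseError,
    DEFAULT_ALIASES,
    ParseOutcome,
    RejectedRecord,
    parse_associations,
    validate_curie,
)
from .ontology import Ontology

__all__ = [
    "PromptSpec",
    "TextGenerator",
    "MockGenerator",
    "build_prompt",
    "parse_response",
    "INVALID_JSON_MESSAGE",
    "extract_shot",
]

INVALID_JSON_MESSAGE = "Invalid JSON format in response."

#: Human-readable pair names used in the instruction sentence.
_PAIR_NAMES = {
    "disease_symptom": "DOID-SYMPTOM",
    "disease_drug": "DOID-CHEBI",
    "disease_gene": "DOID-GO",
    "process_gene": "GO-GO",
}

_TEMPLATE = (
    "You are an assistant that generates {n} {pair_name} term associations "
    "in a structured JSON format. Ensure the JSON is valid and correctly "
    "formatted for parsing. Provide one example in the following format:\n"
    "{shot}"
)


@dataclass(frozen=True)
class PromptSpec:
    """One-shot prompt parameters: type, requested count, example record."""

    assoc_type: str
    n_associations: int
    shot: AssociationPair
    model_name: str = "mock"

    def __post_init__(self) -> None:
        if self.assoc_type not in ASSOC_PREFIXES:
            raise ValueError(f"unknown association type: {self.assoc_type!r}")
        if self.n_associations < 1:
            raise ValueError("n_associations must be >= 1")
        src_prefix, tgt_prefix = ASSOC_PREFIXES[self.assoc_type]
        if not validate_curie(self.shot.source_id, src_prefix, DEFAULT_ALIASES):
            raise ValueError(f"shot source id invalid: {self.shot.source_id!r}")
        if not validate_curie(self.shot.target_id, tgt_prefix, DEFAULT_ALIASES):
            raise ValueError(f"shot target id invalid: {self.shot.target_id!r}")


def _shot_json(shot: AssociationPair) -> str:
    # single line so the shot is itself a valid JSONL association record
    return json.dumps(
        {shot.source_id: shot.source_label, shot.target_id: shot.target_label},
        ensure_ascii=False,
    )


def build_prompt(spec: PromptSpec) -> str:
    """Render the one-shot prompt text; deterministic for a fixed spec."""
    return _TEMPLATE.format(
        n=spec.n_associations,
        pair_name=_PAIR_NAMES[spec.assoc_type],
        shot=_shot_json(spec.shot),
    )


def extract_shot(prompt: str) -> str:
    """Recover the serialized shot (the trailing JSON object) from a prompt."""
    start = prompt.index("{")
    return prompt[start:]


def parse_response(response: str, assoc_type: str) -> ParseOutcome:
    """Parse a generator response into associations; errors are data.

    A response that is not valid JSON at the top level yields an outcome
    whose single rejected record carries :data:`INVALID_JSON_MESSAGE`
    instead of raising.
    """
    try:
        return parse_associations(response, assoc_type)
    except AssociationParseError:
        return ParseOutcome(
            rejected=[RejectedRecord(raw=response, reason=INVALID_JSON_MESSAGE)]
        )


class TextGenerator(Protocol):
    """The pluggable generation capability: prompt text in, response text out."""

    def generate(self, prompt: str) -> str: ...


@dataclass
class MockGenerator:
    """Seed-deterministic stand-in for a live model.

    Emits a JSON array of two-key records for the configured spec. When
    ontologies are supplied, labels are sampled from their terms (ids
    matching); otherwise labels and ids are synthesized. Corruption knobs:

    * ``invalid_json_rate`` — probability the whole response is truncated
      mid-document;
    * ``bad_curie_rate`` — per-record probability of a malformed source id;
    * ``duplicate_rate`` — per-record probability of repeating an earlier
      record.

    ``emitted`` is the ground-truth log of the clean records behind the
    response, in emission order (duplicates included).
    """

    spec: PromptSpec
    seed: int = 0
    source_ontology: Ontology | None = None
    target_ontology: Ontology | None = None
    invalid_json_rate: float = 0.0
    bad_curie_rate: float = 0.0
    duplicate_rate: float = 0.0
    emitted: list[AssociationPair] = field(default_factory=list)
    truncated_last_response: bool = field(default=False, init=False)

    def _draw_endpoint(
        self, rng: random.Random, ontology: Ontology | None, prefix: str, i: int, side: str
    ) -> tuple[str, str]:
        if ontology is not None and ontology.terms_by_id:
            term = rng.choice(sorted(ontology.terms_by_id.values(), key=lambda t: t.id))
            return term.id, term.name
        local = 1_000_000 + i if prefix == "GO" else 1000 + i
        fmt = f"{prefix}:{local:07d}" if prefix == "GO" else f"{prefix}:{local}"
        from .fixtures import _word  # deterministic label machinery

        return fmt, _word(3000 + 2 * i + (0 if side == "src" else 1))

    def generate(self, prompt: str) -> str:
        rng = random.Random(f"{self.seed}|mock|{self.spec.model_name}")
        src_prefix, tgt_prefix = ASSOC_PREFIXES[self.spec.assoc_type]
        self.emitted = []
        records = []
        for i in range(self.spec.n_associations):
            if self.emitted and rng.random() < self.duplicate_rate:
                pair = rng.choice(self.emitted)
            else:
                sid, slabel = self._draw_endpoint(rng, self.source_ontology, src_prefix, i, "src")
                tid, tlabel = self._draw_endpoint(rng, self.target_ontology, tgt_prefix, i, "tgt")
                pair = AssociationPair(
                    source_id=sid,
                    source_label=slabel,
                    target_id=tid,
                    target_label=tlabel,
                    assoc_type=self.spec.assoc_type,
                )
            self.emitted.append(pair)
            sid_out = pair.source_id
            if rng.random() < self.bad_curie_rate:
                sid_out = sid_out.replace(":", ":X")  # malformed local id
            records.append({sid_out: pair.source_label, pair.target_id: pair.target_label})
        response = json.dumps(records, indent=2, ensure_ascii=False)
        self.truncated_last_response = rng.random() < self.invalid_json_rate
        if self.truncated_last_response:
            response = response[: max(len(response) - 15, 1)]
        return response
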