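"""Build a one-shot prompt and parse a (mock) generator's response.

The prompt embeds the requested record count, the association type, and one
worked example record. Any synchronous text generator satisfies the
contract; the seeded mock used here stands in for a live API and records
exactly what it emitted, including deliberate corruption for testing the
rejection paths.
"""

from assocverify import AssociationPair, MockGenerator, PromptSpec, build_prompt, parse_response

shot = AssociationPair(
    "DOID:11734", "Epistaxis", "SYMPTOM:1080", "Nosebleed", "disease_symptom"
)
spec = PromptSpec(assoc_type="disease_symptom", n_associations=10, shot=shot)

prompt = build_prompt(spec)
print(prompt)
print("---")

gen = MockGenerator(spec, seed=42, bad_curie_rate=0.2)
outcome = parse_response(gen.generate(prompt), "disease_symptom")
print(f"emitted {len(gen.emitted)} records -> "
      f"{len(outcome.pairs)} accepted, {len(outcome.rejected)} rejected")
for reject in outcome.rejected:
    print("  rejected:", reject.reason)

# With a 20% bad-CURIE rate the parser accepts the clean records and
# rejects the corrupted ones with machine-readable reasons; a generator
# returning broken JSON would instead yield a single
# "Invalid JSON format in response." outcome rather than an exception.
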