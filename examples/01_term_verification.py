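"""Verify generated disease terms against an ontology's names and synonyms.

Builds a tiny disease-ontology fixture containing the hypertension entry and
its scoped synonyms, then verifies a few generated labels. A label verifies
by NAME when it equals a term's primary name under normalization, by SYNONYM
when it equals any scoped synonym, and is UNVERIFIED otherwise.
"""

import io

from assocverify import load_obo, verify_term

OBO = """\
[Term]
id: DOID:10763
name: hypertension
synonym: "HTN" EXACT []
synonym: "hyperpiesia" EXACT []
synonym: "hypertensive disease" RELATED []
synonym: "vascular hypertensive disorder" EXACT []

[Term]
id: SYMP:0000184
name: blister
"""

doid = load_obo(io.StringIO(OBO), "DOID")

for label in (
    "hypertension",            # exact primary name
    "HTN",                     # EXACT synonym, case-normalized
    "Hypertensive-Disease",    # RELATED synonym despite punctuation/case
    "itchy blisters",          # lay paraphrase: no whole-label match
):
    verdict = verify_term(label, doid)
    print(f"{label!r:35} -> {verdict.status.value:17} {sorted(verdict.matched_ids)}")

# The first three labels resolve to DOID:10763 (one by name, two through
# synonym metadata); the lay paraphrase fails because matching is exact
# whole-label comparison after normalization, not substring or fuzzy search.
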