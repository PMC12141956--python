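"""Shared fixtures: the hypertension OBO stanza and small generated suites."""

from __future__ import annotations

import io

import pytest

from assocverify.fixtures import FixtureConfig, gen_suite
from assocverify.ontology import load_obo

# The Human Disease Ontology entry for hypertension, with its four scoped
# synonyms, plus a neighbour term and an obsolete term to exercise indexing.
HYPERTENSION_OBO = """\
format-version: 1.2
ontology: doid

[Term]
id: DOID:10763
name: hypertension
synonym: "HTN" EXACT []
synonym: "hyperpiesia" EXACT []
synonym: "hypertensive disease" RELATED []
synonym: "vascular hypertensive disorder" EXACT []

[Term]
id: DOID:1936
name: atherosclerosis

[Term]
id: DOID:9999
name: retired disorder
is_obsolete: true
"""


@pytest.fixture()
def doid_fixture():
    return load_obo(io.StringIO(HYPERTENSION_OBO), "DOID")


@pytest.fixture(scope="session")
def small_suite():
    """Default-scale synthetic suite shared by read-only tests."""
    return gen_suite(FixtureConfig(seed=7))


@pytest.fixture(scope="session")
def tiny_suite():
    """Oracle-scale suite: <= 50 terms, <= 100 abstracts."""
    return gen_suite(
        FixtureConfig(seed=13, n_terms=30, n_pairs=60, n_abstracts=80,
                      plant_fraction=0.5)
    )
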