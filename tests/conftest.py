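"""Shared fixtures: deterministic agents, documents, and a randomized
entity-collection factory exercising every selector type, curation chains
and branched sets."""

from __future__ import annotations

import pytest

from aokit.model import (
    Agent,
    AgentKind,
    Annotation,
    AnnotationSet,
    DocumentRef,
    SourceVersion,
)
from aokit.synth import random_entities  # noqa: F401  (shared fixture factory)

BASE = "http://fixtures.example.org/ao/"
T0 = "2011-05-17T00:00:00+00:00"


@pytest.fixture
def person():
    return Agent(BASE + "agents/curator", AgentKind.PERSON, "Ada Curator")


@pytest.fixture
def software():
    return Agent(BASE + "agents/miner", AgentKind.SOFTWARE, "EntityMiner 2.0")


@pytest.fixture
def page():
    return DocumentRef(
        page_uri="http://journal.example.org/articles/42",
        versions=(
            SourceVersion(
                uri="http://journal.example.org/articles/42?rev=1",
                accessed_on="2011-05-01T08:00:00+00:00",
                content_digest="ab12",
            ),
            SourceVersion(
                uri="http://journal.example.org/articles/42?rev=2",
                accessed_on="2011-05-10T08:00:00+00:00",
            ),
        ),
    )


def canonical(entity):
    """Order-insensitive comparison key for round-trip object equality."""
    from dataclasses import asdict

    if isinstance(entity, Annotation):
        d = asdict(entity)
        d["topics"] = sorted(d["topics"], key=lambda t: t["term"]["uri"])
        d["targets"] = sorted(
            (repr(sorted(t.items())) for t in d["targets"]), key=str
        )
        d["composed_types"] = sorted(d["composed_types"])
        return ("annotation", repr(sorted(d.items(), key=str)))
    if isinstance(entity, AnnotationSet):
        d = asdict(entity)
        d["item_uris"] = sorted(d["item_uris"])
        return ("set", repr(sorted(d.items(), key=str)))
    from dataclasses import asdict as ad

    return (type(entity).__name__, repr(sorted(ad(entity).items(), key=str)))
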