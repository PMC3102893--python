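"""Core domain model for stand-off annotation.

The annotation record lives apart from the document it describes: it points
at the document (or a fragment selector) rather than being embedded in it,
so no update control over the target is needed.  Every entity here is an
immutable (frozen) dataclass identified by an IRI.  Structural rules are
enforced two ways:

* :func:`validate` inspects any entity and returns a list of
  :class:`Violation` records (violations are data, not exceptions), and
* the constructors (:func:`new_annotation`, :func:`add_topic`) raise
  :class:`ValidationError` so that no invalid object escapes a
  construction path.

Annotations are typed: free-text kinds (``Note``, ``Errata``, ``Example``,
``Definition``) require a body, while the *qualifier* family associates the
target with an ontology term at a graded level of fit mirroring the SKOS
mapping properties (exact / close / broad / narrow / related).  A qualifier
with only a free-text body and no term is the degenerate case of a plain
tag.
"""

from __future__ import annotations

import datetime
import uuid
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union
from urllib.parse import urlsplit

__all__ = [
    "AgentKind",
    "AnnotationType",
    "MeaningLevel",
    "CurationStatus",
    "CORE_CURATION_STATUSES",
    "QUALIFIER_TYPES",
    "BODY_REQUIRED_TYPES",
    "LEVEL_TO_TYPE",
    "TYPE_TO_LEVEL",
    "Agent",
    "SourceVersion",
    "DocumentRef",
    "TermRef",
    "Topic",
    "Tagging",
    "Annotation",
    "CurationToken",
    "AnnotationSet",
    "Violation",
    "ValidationError",
    "mint_uri",
    "new_annotation",
    "add_topic",
    "validate",
    "is_absolute_iri",
    "parse_timestamp",
]

DEFAULT_BASE = "http://example.org/ao/"


class AgentKind(str, Enum):
    """Who (or what) created an annotation or curation judgment."""

    PERSON = "person"
    SOFTWARE = "software"
    GROUP = "group"
    ORGANIZATION = "organization"


class AnnotationType(str, Enum):
    NOTE = "Note"
    ERRATA = "Errata"
    EXAMPLE = "Example"
    DEFINITION = "Definition"
    QUALIFIER = "Qualifier"
    EXACT_QUALIFIER = "ExactQualifier"
    CLOSE_QUALIFIER = "CloseQualifier"
    BROAD_QUALIFIER = "BroadQualifier"
    NARROW_QUALIFIER = "NarrowQualifier"


class MeaningLevel(str, Enum):
    """How well a term fits the annotated content, SKOS-style."""

    RELATED = "related"
    EXACT = "exact"
    CLOSE = "close"
    BROAD = "broad"
    NARROW = "narrow"


QUALIFIER_TYPES = frozenset(
    {
        AnnotationType.QUALIFIER,
        AnnotationType.EXACT_QUALIFIER,
        AnnotationType.CLOSE_QUALIFIER,
        AnnotationType.BROAD_QUALIFIER,
        AnnotationType.NARROW_QUALIFIER,
    }
)

BODY_REQUIRED_TYPES = frozenset(
    {
        AnnotationType.NOTE,
        AnnotationType.ERRATA,
        AnnotationType.EXAMPLE,
        AnnotationType.DEFINITION,
    }
)

LEVEL_TO_TYPE: Mapping[MeaningLevel, AnnotationType] = {
    MeaningLevel.RELATED: AnnotationType.QUALIFIER,
    MeaningLevel.EXACT: AnnotationType.EXACT_QUALIFIER,
    MeaningLevel.CLOSE: AnnotationType.CLOSE_QUALIFIER,
    MeaningLevel.BROAD: AnnotationType.BROAD_QUALIFIER,
    MeaningLevel.NARROW: AnnotationType.NARROW_QUALIFIER,
}

TYPE_TO_LEVEL: Mapping[AnnotationType, MeaningLevel] = {
    t: l for l, t in LEVEL_TO_TYPE.items()
}

# Curation statuses are an open string vocabulary; these four are the core
# values and must be spelled exactly like this.
CORE_CURATION_STATUSES = ("created", "accepted", "rejected", "discussed")
CurationStatus = str


class ValidationError(ValueError):
    """Raised by constructors when the result would violate an invariant."""

    def __init__(self, violations: Sequence["Violation"]):
        self.violations = list(violations)
        super().__init__("; ".join(str(v) for v in self.violations) or "invalid")


@dataclass(frozen=True)
class Violation:
    """One broken structural rule: which entity, which field, which rule."""

    entity_uri: str
    field: str
    rule: str
    message: str = ""

    def __str__(self) -> str:  # pragma: no cover - repr sugar
        msg = f" ({self.message})" if self.message else ""
        return f"{self.entity_uri}: {self.field} violates {self.rule}{msg}"


def is_absolute_iri(value: object) -> bool:
    """True iff *value* is a string with a URI scheme (an absolute IRI)."""
    if not isinstance(value, str) or not value:
        return False
    try:
        parts = urlsplit(value)
    except ValueError:
        return False
    return bool(parts.scheme)


def parse_timestamp(value: str) -> Optional[datetime.datetime]:
    """Parse an ISO-8601 timestamp; None when it does not parse."""
    if not isinstance(value, str):
        return None
    try:
        return datetime.datetime.fromisoformat(value.replace("Z", "+00:00"))
    except ValueError:
        return None


@dataclass(frozen=True)
class Agent:
    """A person, software service, group or organization that creates or
    curates annotations."""

    uri: str
    kind: AgentKind
    name: str = ""


@dataclass(frozen=True)
class SourceVersion:
    """One detected state of a mutable web page.

    The page keeps a stable IRI while its content drifts; each observed
    state gets its own IRI plus the access time, so a selector can say
    which state it was created against.  ``content_digest`` optionally
    carries a hex digest of the raw content for change detection.
    """

    uri: str
    accessed_on: str
    content_digest: Optional[str] = None


@dataclass(frozen=True)
class DocumentRef:
    """A stable web-page identity with its observed versions (sorted by
    access time, oldest first)."""

    page_uri: str
    versions: tuple[SourceVersion, ...] = ()


@dataclass(frozen=True)
class TermRef:
    """A reference to an ontology class or individual.  ``is_class`` may be
    unknown (None) — both classes-only ontologies and SKOS-style instance
    terminologies are legitimate annotation vocabularies."""

    uri: str
    label: Optional[str] = None
    is_class: Optional[bool] = None


@dataclass(frozen=True)
class Topic:
    """One term attached to an annotation, optionally at a meaning level of
    its own (a multi-topic annotation records each topic's level)."""

    term: TermRef
    level: Optional[MeaningLevel] = None


@dataclass(frozen=True)
class Tagging:
    """A free-text tag plus zero or more graded term meanings (the
    folksonomy-interop record)."""

    tag_label: str
    meanings: tuple[tuple[MeaningLevel, TermRef], ...] = ()


@dataclass(frozen=True)
class CurationToken:
    """One curator judgment on an annotation; tokens chain through
    ``previous`` to record a multi-step review."""

    uri: str
    status: CurationStatus
    curated_by: Agent
    curated_on: str
    previous: Optional[str] = None


@dataclass(frozen=True)
class Annotation:
    uri: str
    ann_type: AnnotationType
    created_by: Agent
    created_on: str
    targets: tuple[object, ...]  # DocumentRef or a selector record
    body: Optional[str] = None
    topics: tuple[Topic, ...] = ()
    composed_types: tuple[str, ...] = ()
    curation_head: Optional[CurationToken] = None
    previous_version: Optional[str] = None
    version_number: Optional[int] = None
    supersedes: Optional[str] = None
    tagging: Optional[Tagging] = None


@dataclass(frozen=True)
class AnnotationSet:
    """A versionable, branchable container of annotation IRIs."""

    uri: str
    item_uris: tuple[str, ...]
    created_by: Agent
    created_on: str
    previous_version: Optional[str] = None
    version_number: Optional[int] = None
    derived_from: Optional[str] = None


# ---------------------------------------------------------------------------
# constructors


def mint_uri(base_namespace: str, entity_kind: str, seed: Optional[int] = None) -> str:
    """Mint an IRI ``base_namespace + entity_kind + "/" + token``.

    Without a seed the token is a UUID-v4 (globally unique); with a seed the
    token is a UUID-v5 of (namespace, kind, seed), so the same inputs always
    mint the same IRI — convenient for reproducible fixtures.
    """
    if not is_absolute_iri(base_namespace) or not base_namespace.endswith(("/", "#")):
        raise ValidationError(
            [
                Violation(
                    str(base_namespace),
                    "base_namespace",
                    "absolute-iri-with-trailing-separator",
                    "must be absolute and end with '/' or '#'",
                )
            ]
        )
    if seed is None:
        token = str(uuid.uuid4())
    else:
        token = str(uuid.uuid5(uuid.NAMESPACE_URL, f"{base_namespace}{entity_kind}|{seed}"))
    return f"{base_namespace}{entity_kind}/{token}"


def _as_topics(topics: Optional[Iterable[object]]) -> tuple[Topic, ...]:
    out: list[Topic] = []
    for t in topics or ():
        if isinstance(t, Topic):
            out.append(t)
        elif isinstance(t, TermRef):
            out.append(Topic(term=t))
        else:
            raise TypeError(f"topic must be Topic or TermRef, got {type(t).__name__}")
    return tuple(out)


def new_annotation(
    ann_type: AnnotationType,
    created_by: Agent,
    created_on: str,
    targets: Sequence[object],
    body: Optional[str] = None,
    topics: Optional[Iterable[object]] = None,
    *,
    composed_types: Sequence[str] = (),
    tagging: Optional[Tagging] = None,
    uri: Optional[str] = None,
    base_namespace: str = DEFAULT_BASE,
    seed: Optional[int] = None,
) -> Annotation:
    """Build and validate an annotation, minting its IRI if none is given.

    Raises :class:`ValidationError` when the result would break an
    invariant (e.g. no target, or a Note without a body).
    """
    ann = Annotation(
        uri=uri or mint_uri(base_namespace, "annotation", seed),
        ann_type=AnnotationType(ann_type),
        created_by=created_by,
        created_on=created_on,
        targets=tuple(targets),
        body=body,
        topics=_as_topics(topics),
        composed_types=tuple(composed_types),
        tagging=tagging,
    )
    violations = validate(ann)
    if violations:
        raise ValidationError(violations)
    return ann


def add_topic(
    annotation: Annotation,
    term: TermRef,
    level: Union[MeaningLevel, str],
    *,
    promote: bool = False,
) -> Annotation:
    """Return a copy of *annotation* with *term* appended at *level*.

    The annotation's type is refined to the qualifier subtype matching the
    level (related → Qualifier, exact → ExactQualifier, ...).  A
    non-qualifier annotation is only converted when ``promote=True``.
    """
    try:
        level = MeaningLevel(level)
    except ValueError:
        raise ValidationError(
            [Violation(annotation.uri, "level", "known-meaning-level", str(level))]
        )
    if annotation.ann_type not in QUALIFIER_TYPES and not promote:
        raise ValidationError(
            [
                Violation(
                    annotation.uri,
                    "ann_type",
                    "qualifier-family-required",
                    f"{annotation.ann_type.value} cannot carry topics without promote=True",
                )
            ]
        )
    refined = replace(
        annotation,
        ann_type=LEVEL_TO_TYPE[level],
        topics=annotation.topics + (Topic(term=term, level=level),),
    )
    violations = validate(refined)
    if violations:
        raise ValidationError(violations)
    return refined


# ---------------------------------------------------------------------------
# validation


def _check_agent(v: list[Violation], owner: str, agent: object, field_name: str) -> None:
    if not isinstance(agent, Agent):
        v.append(Violation(owner, field_name, "agent-required", repr(agent)))
        return
    if not is_absolute_iri(agent.uri):
        v.append(Violation(agent.uri or owner, "uri", "absolute-iri"))
    if not isinstance(agent.kind, AgentKind):
        v.append(Violation(agent.uri, "kind", "known-agent-kind", repr(agent.kind)))


def _check_timestamp(v: list[Violation], owner: str, value: str, field_name: str) -> None:
    if parse_timestamp(value) is None:
        v.append(Violation(owner, field_name, "iso-8601-timestamp", repr(value)))


def _validate_document_ref(doc: DocumentRef) -> list[Violation]:
    v: list[Violation] = []
    if not is_absolute_iri(doc.page_uri):
        v.append(Violation(str(doc.page_uri), "page_uri", "absolute-iri"))
    previous = None
    for sv in doc.versions:
        if not is_absolute_iri(sv.uri):
            v.append(Violation(str(sv.uri), "uri", "absolute-iri"))
        if sv.uri == doc.page_uri:
            v.append(
                Violation(sv.uri, "uri", "version-uri-differs-from-page-uri")
            )
        ts = parse_timestamp(sv.accessed_on)
        if ts is None:
            v.append(Violation(sv.uri, "accessed_on", "iso-8601-timestamp"))
        elif previous is not None and ts < previous:
            v.append(Violation(sv.uri, "accessed_on", "versions-sorted-by-access-time"))
        if ts is not None:
            previous = ts
    return v


def _validate_annotation(ann: Annotation) -> list[Violation]:
    v: list[Violation] = []
    if not is_absolute_iri(ann.uri):
        v.append(Violation(str(ann.uri), "uri", "absolute-iri"))
    if not isinstance(ann.ann_type, AnnotationType):
        v.append(Violation(ann.uri, "ann_type", "known-annotation-type", repr(ann.ann_type)))
        return v
    _check_agent(v, ann.uri, ann.created_by, "created_by")
    _check_timestamp(v, ann.uri, ann.created_on, "created_on")
    if not ann.targets:
        v.append(Violation(ann.uri, "targets", "at-least-one-target"))
    for target in ann.targets:
        if isinstance(target, DocumentRef):
            v.extend(_validate_document_ref(target))
    for topic in ann.topics:
        if not is_absolute_iri(topic.term.uri):
            v.append(Violation(ann.uri, "topics", "absolute-term-iri", str(topic.term.uri)))
    if ann.ann_type in BODY_REQUIRED_TYPES and not ann.body:
        v.append(Violation(ann.uri, "body", "body-required", ann.ann_type.value))
    if ann.ann_type in QUALIFIER_TYPES and not ann.topics and not ann.body:
        # a body-only qualifier is the tag case; topic-less AND body-less is not
        v.append(Violation(ann.uri, "topics", "qualifier-needs-topic-or-body"))
    if ann.topics and ann.ann_type not in QUALIFIER_TYPES:
        v.append(Violation(ann.uri, "topics", "topics-only-on-qualifiers"))
    if ann.previous_version is not None and ann.version_number is None:
        v.append(Violation(ann.uri, "version_number", "required-with-previous-version"))
    if ann.version_number is not None and ann.version_number < 1:
        v.append(Violation(ann.uri, "version_number", "positive-integer"))
    if ann.curation_head is not None:
        v.extend(_validate_token(ann.curation_head, None))
    if ann.tagging is not None and not ann.tagging.tag_label:
        v.append(Violation(ann.uri, "tagging", "non-empty-tag-label"))
    return v


def _validate_token(
    token: CurationToken, index: Optional[Mapping[str, CurationToken]]
) -> list[Violation]:
    v: list[Violation] = []
    if not is_absolute_iri(token.uri):
        v.append(Violation(str(token.uri), "uri", "absolute-iri"))
    if not isinstance(token.status, str) or not token.status:
        v.append(Violation(token.uri, "status", "non-empty-status"))
    elif token.status.lower() in CORE_CURATION_STATUSES and token.status not in CORE_CURATION_STATUSES:
        v.append(
            Violation(token.uri, "status", "core-status-exact-spelling", token.status)
        )
    _check_agent(v, token.uri, token.curated_by, "curated_by")
    _check_timestamp(v, token.uri, token.curated_on, "curated_on")
    if index is not None:
        seen = {token.uri}
        current = token
        while current.previous is not None:
            if current.previous in seen:
                v.append(Violation(token.uri, "previous", "acyclic-curation-chain"))
                break
            seen.add(current.previous)
            nxt = index.get(current.previous)
            if nxt is None:
                break  # dangling chains are a store-level warning, not a cycle
            current = nxt
    return v


def _validate_set(aset: AnnotationSet) -> list[Violation]:
    v: list[Violation] = []
    if not is_absolute_iri(aset.uri):
        v.append(Violation(str(aset.uri), "uri", "absolute-iri"))
    if len(set(aset.item_uris)) != len(aset.item_uris):
        v.append(Violation(aset.uri, "item_uris", "no-duplicate-items"))
    _check_agent(v, aset.uri, aset.created_by, "created_by")
    _check_timestamp(v, aset.uri, aset.created_on, "created_on")
    if aset.previous_version is not None and aset.version_number is None:
        v.append(Violation(aset.uri, "version_number", "required-with-previous-version"))
    if aset.version_number is not None and aset.version_number < 1:
        v.append(Violation(aset.uri, "version_number", "positive-integer"))
    return v


def validate(
    entity: object,
    token_index: Optional[Mapping[str, CurationToken]] = None,
) -> list[Violation]:
    """Check every invariant of *entity*; empty list iff all hold.

    ``token_index`` (uri → token) lets curation-chain cycles be detected
    when validating a :class:`CurationToken`.
    """
    if isinstance(entity, Annotation):
        return _validate_annotation(entity)
    if isinstance(entity, AnnotationSet):
        return _validate_set(entity)
    if isinstance(entity, CurationToken):
        return _validate_token(entity, token_index or {})
    if isinstance(entity, DocumentRef):
        return _validate_document_ref(entity)
    if isinstance(entity, Agent):
        v: list[Violation] = []
        _check_agent(v, entity.uri, entity, "self")
        return v
    raise TypeError(f"cannot validate {type(entity).__name__}")
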