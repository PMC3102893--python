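"""SKOS-graded qualifier semantics and folksonomy (MOAT-style) interop.

A qualifier annotation grades how well a term fits the annotated content,
and each grade parallels a SKOS mapping property:

====================  ==================
Qualifier             skos:relatedMatch
ExactQualifier        skos:exactMatch
CloseQualifier        skos:closeMatch
BroadQualifier        skos:broadMatch
NarrowQualifier       skos:narrowMatch
====================  ==================

When several qualifiers share one anchor (the same selector, or the same
whole document), their terms all describe the same content, which licenses
cross-ontology term-to-term mappings: if term A *exactly* represents the
fragment and term B represents it more broadly, then A skos:broadMatch B.
Pairs where neither side is exact only support the weakest claim,
skos:relatedMatch.

The tagging interop covers the free-text-tag world: a tag label with zero
or more graded term meanings converts to one qualifier annotation per
meaning (a meaning-less tag becomes a plain body-only Qualifier), and
back.  Note the direction of the meaning properties: an annotation that
``hasNarrowerMeaningThan`` a term says the *content* is narrower, i.e. the
term is broader — level ``broad``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Union

from .model import (
    Agent,
    Annotation,
    AnnotationType,
    DocumentRef,
    LEVEL_TO_TYPE,
    MeaningLevel,
    QUALIFIER_TYPES,
    TYPE_TO_LEVEL,
    Tagging,
    TermRef,
    Topic,
    ValidationError,
    Violation,
    new_annotation,
)

__all__ = [
    "MeaningLevel",
    "Tagging",
    "DerivedMapping",
    "SKOS",
    "qualifier_skos_property",
    "skos_property_level",
    "level_meaning_property",
    "meaning_property_level",
    "infer_cross_ontology",
    "moat_to_ao",
    "ao_to_moat",
    "tagging_of",
]

SKOS = "http://www.w3.org/2004/02/skos/core#"
AO = "http://purl.org/ao/"

_LEVEL_TO_SKOS = {
    MeaningLevel.RELATED: SKOS + "relatedMatch",
    MeaningLevel.EXACT: SKOS + "exactMatch",
    MeaningLevel.CLOSE: SKOS + "closeMatch",
    MeaningLevel.BROAD: SKOS + "broadMatch",
    MeaningLevel.NARROW: SKOS + "narrowMatch",
}
_SKOS_TO_LEVEL = {iri: lvl for lvl, iri in _LEVEL_TO_SKOS.items()}

# skos:exactMatch, closeMatch and relatedMatch are symmetric; the broad /
# narrow pair is directional.
_SYMMETRIC = frozenset(
    {SKOS + "exactMatch", SKOS + "closeMatch", SKOS + "relatedMatch"}
)

# Meaning properties on the annotation side.  "hasNarrowerMeaningThan"
# reads from the content: the content is narrower than the term, so the
# term sits at level broad.
_LEVEL_TO_MEANING_PROP = {
    MeaningLevel.RELATED: AO + "hasRelatedMeaning",
    MeaningLevel.EXACT: AO + "hasExactMeaning",
    MeaningLevel.CLOSE: AO + "hasCloseMeaning",
    MeaningLevel.BROAD: AO + "hasNarrowerMeaningThan",
    MeaningLevel.NARROW: AO + "hasBroaderMeaningThan",
}
_MEANING_PROP_TO_LEVEL = {iri: lvl for lvl, iri in _LEVEL_TO_MEANING_PROP.items()}


def qualifier_skos_property(level: Union[MeaningLevel, str]) -> str:
    """The SKOS mapping property IRI paralleling a meaning level."""
    return _LEVEL_TO_SKOS[MeaningLevel(level)]


def skos_property_level(iri: str) -> MeaningLevel:
    """Inverse of :func:`qualifier_skos_property`."""
    return _SKOS_TO_LEVEL[iri]


def level_meaning_property(level: Union[MeaningLevel, str]) -> str:
    """The annotation-side meaning property IRI for a level."""
    return _LEVEL_TO_MEANING_PROP[MeaningLevel(level)]


def meaning_property_level(iri: str) -> MeaningLevel:
    """Inverse of :func:`level_meaning_property`."""
    return _MEANING_PROP_TO_LEVEL[iri]


@dataclass(frozen=True)
class DerivedMapping:
    """A term-to-term SKOS mapping inferred from co-anchored qualifiers,
    with the contributing annotation IRIs as evidence."""

    subject_term: TermRef
    skos_property: str
    object_term: TermRef
    evidence: tuple[str, ...] = ()


def _anchor_keys(ann: Annotation) -> list[str]:
    keys = []
    for target in ann.targets:
        if isinstance(target, DocumentRef):
            keys.append(f"doc:{target.page_uri}")
        else:
            uri = getattr(target, "uri", None)
            if uri:
                keys.append(f"sel:{uri}")
    return keys


def _assertions(ann: Annotation) -> list[tuple[MeaningLevel, TermRef]]:
    """(level, term) claims made by one qualifier annotation.

    A topic's own level wins; otherwise the annotation subtype supplies it
    (a plain Qualifier contributes level ``related``).
    """
    if ann.ann_type not in QUALIFIER_TYPES:
        return []
    default = TYPE_TO_LEVEL.get(ann.ann_type, MeaningLevel.RELATED)
    return [(t.level or default, t.term) for t in ann.topics]


def infer_cross_ontology(annotations: Sequence[Annotation]) -> list[DerivedMapping]:
    """Derive SKOS term-to-term mappings from qualifiers sharing an anchor.

    For each ordered pair of distinct qualifier annotations on the same
    anchor, with terms A (level L1) and B (level L2), A ≠ B:

    * L1 exact  → A <skos property of L2> B  (exact/exact collapses to a
      single unordered exactMatch);
    * neither exact → A relatedMatch B (the weakest claim);

    duplicates — including symmetric duplicates of the symmetric
    properties — are collapsed, merging evidence.  Output order is
    deterministic (sorted), so the result is invariant under permutation
    of the input.  Mappings whose terms are known to be individuals rather
    than classes are still emitted, with a warning.
    """
    groups: dict[str, list[tuple[str, MeaningLevel, TermRef]]] = {}
    for ann in annotations:
        claims = _assertions(ann)
        if not claims:
            continue
        for key in _anchor_keys(ann):
            for level, term in claims:
                groups.setdefault(key, []).append((ann.uri, level, term))

    collected: dict[tuple[str, str, str], dict] = {}

    def emit(a: TermRef, prop: str, b: TermRef, ev: tuple[str, str]) -> None:
        if prop in _SYMMETRIC and b.uri < a.uri:
            a, b = b, a
        key = (a.uri, prop, b.uri)
        rec = collected.setdefault(
            key, {"subject": a, "object": b, "prop": prop, "evidence": set()}
        )
        rec["evidence"].update(ev)
        if a.is_class is False or b.is_class is False:
            warnings.warn(
                f"derived mapping {a.uri} -> {b.uri} involves an instance-level "
                "term; interpret as an assertion about individuals",
                stacklevel=2,
            )

    for members in groups.values():
        for ann1, l1, t1 in members:
            for ann2, l2, t2 in members:
                if ann1 == ann2 or t1.uri == t2.uri:
                    continue
                if l1 is MeaningLevel.EXACT:
                    emit(t1, qualifier_skos_property(l2), t2, (ann1, ann2))
                elif l2 is not MeaningLevel.EXACT:
                    emit(t1, SKOS + "relatedMatch", t2, (ann1, ann2))
                # l1 non-exact, l2 exact: handled by the mirrored pair

    out = [
        DerivedMapping(
            subject_term=rec["subject"],
            skos_property=rec["prop"],
            object_term=rec["object"],
            evidence=tuple(sorted(rec["evidence"])),
        )
        for rec in collected.values()
    ]
    out.sort(key=lambda m: (m.subject_term.uri, m.skos_property, m.object_term.uri))
    return out


# ---------------------------------------------------------------------------
# tagging interop


def moat_to_ao(
    tagging: Tagging,
    target: object,
    creator: Agent,
    *,
    created_on: str = "1970-01-01T00:00:00+00:00",
    base_namespace: str = "http://example.org/ao/",
    seed: Optional[int] = None,
) -> list[Annotation]:
    """Convert a tag (label + graded meanings) into qualifier annotations.

    One qualifier per meaning, subtyped by its level, all carrying the tag
    label as body; a meaning-less tagging yields a single plain Qualifier
    whose body is the label (a free-text qualifier *is* a tag).
    """
    if not tagging.tag_label:
        raise ValidationError([Violation("", "tag_label", "non-empty-tag-label")])
    if not tagging.meanings:
        return [
            new_annotation(
                AnnotationType.QUALIFIER,
                creator,
                created_on,
                [target],
                body=tagging.tag_label,
                base_namespace=base_namespace,
                seed=seed,
            )
        ]
    out = []
    for i, (level, term) in enumerate(tagging.meanings):
        out.append(
            new_annotation(
                LEVEL_TO_TYPE[MeaningLevel(level)],
                creator,
                created_on,
                [target],
                body=tagging.tag_label,
                topics=[Topic(term=term, level=MeaningLevel(level))],
                base_namespace=base_namespace,
                seed=None if seed is None else seed * 1000 + i,
            )
        )
    return out


def tagging_of(annotation: Annotation) -> Tagging:
    """The tagging view of a qualifier annotation: body as label, topics as
    graded meanings."""
    if annotation.ann_type not in QUALIFIER_TYPES:
        raise ValidationError(
            [Violation(annotation.uri, "ann_type", "qualifier-family-required")]
        )
    default = TYPE_TO_LEVEL.get(annotation.ann_type, MeaningLevel.RELATED)
    return Tagging(
        tag_label=annotation.body or "",
        meanings=tuple((t.level or default, t.term) for t in annotation.topics),
    )


def ao_to_moat(annotation: Annotation):
    """Emit a qualifier annotation as a restricted-tagging RDF structure
    (resource, tag, graded meanings, tagger).  Non-qualifiers are refused.

    Returns an :class:`rdflib.Graph`; see :mod:`aokit.rdf_io` for the
    namespace bindings used.
    """
    from . import rdf_io  # local import: rdf_io depends on this module

    return rdf_io.tagging_graph(annotation)
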