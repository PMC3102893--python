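"""RDF serialization and parsing of the annotation model.

The object model maps onto a fixed vocabulary spread over the AO namespace
family (core, selectors, types, Annotea-interop, FOAF-interop) plus PAV for
provenance/versioning/curation.  Serialization is lossless: ``parse`` is the
inverse of ``serialize`` up to graph isomorphism, in all four supported
syntaxes (Turtle, RDF/XML, N-Triples, JSON-LD).

Only terms from the vocabulary table below are ever emitted in the AO
namespaces; unknown predicates encountered while parsing are surfaced as
warnings, never errors.  Alignment triples declaring the annotation and set
classes as SIOC subclasses are included whenever a non-empty graph is
written.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.compare import isomorphic
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .anchoring import (
    ImageBoxSelector,
    OffsetRangeSelector,
    Selector,
    TextQuoteSelector,
    XPointerSelectorRec,
)
from .model import (
    Agent,
    AgentKind,
    Annotation,
    AnnotationSet,
    AnnotationType,
    CurationToken,
    DocumentRef,
    MeaningLevel,
    SourceVersion,
    Tagging,
    TermRef,
    Topic,
    ValidationError,
    validate,
)
from .semantics import level_meaning_property, meaning_property_level, tagging_of

__all__ = [
    "TABLE1_NAMESPACES",
    "NamespaceRegistry",
    "AO_VOCABULARY",
    "serialize",
    "parse",
    "graphs_isomorphic",
    "to_annotea",
    "from_annotea",
    "AnnoteaExport",
    "tagging_graph",
    "tagging_from_graph",
    "FORMATS",
]

# The nine canonical prefix bindings used throughout AO data.
TABLE1_NAMESPACES: dict[str, str] = {
    "ao": "http://purl.org/ao/",
    "aos": "http://purl.org/ao/selectors/",
    "aot": "http://purl.org/ao/types/",
    "aoa": "http://purl.org/ao/annotea/",
    "aof": "http://purl.org/ao/foaf/",
    "pav": "http://purl.org/pav/2.0/",
    "swan-agent": "http://purl.org/swan/2.0/agents/",
    "swan": "http://purl.org/swan/2.0/",
    "ann": "http://www.w3.org/2000/10/annotation-ns#",
}

_EXTRA_NAMESPACES: dict[str, str] = {
    "PRO": "http://purl.org/obo/owl/PRO#",
    "foaf": "http://xmlns.com/foaf/0.1/",
    "sioc": "http://rdfs.org/sioc/ns#",
    "skos": "http://www.w3.org/2004/02/skos/core#",
    "moat": "http://moat-project.org/ns#",
    "tags": "http://www.holygoat.co.uk/owl/redwood/0.1/tags/",
    "dc": "http://purl.org/dc/elements/1.1/",
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
    "owl": "http://www.w3.org/2002/07/owl#",
    "xsd": "http://www.w3.org/2001/XMLSchema#",
}

AO = Namespace(TABLE1_NAMESPACES["ao"])
AOS = Namespace(TABLE1_NAMESPACES["aos"])
AOT = Namespace(TABLE1_NAMESPACES["aot"])
AOF = Namespace(TABLE1_NAMESPACES["aof"])
PAV = Namespace(TABLE1_NAMESPACES["pav"])
SWAN_AGENT = Namespace(TABLE1_NAMESPACES["swan-agent"])
ANN = Namespace(TABLE1_NAMESPACES["ann"])
FOAF = Namespace(_EXTRA_NAMESPACES["foaf"])
SIOC = Namespace(_EXTRA_NAMESPACES["sioc"])
MOAT = Namespace(_EXTRA_NAMESPACES["moat"])
TAGS = Namespace(_EXTRA_NAMESPACES["tags"])
DC = Namespace(_EXTRA_NAMESPACES["dc"])

FORMATS = {
    "turtle": "turtle",
    "rdfxml": "xml",
    "xml": "xml",
    "ntriples": "nt",
    "nt": "nt",
    "jsonld": "json-ld",
    "json-ld": "json-ld",
}

# Annotation type <-> aot class IRI (bijection over the nine types).
TYPE_CLASS = {t: AOT[t.value] for t in AnnotationType}
CLASS_TYPE = {iri: t for t, iri in TYPE_CLASS.items()}

# Agent kind <-> class IRI.  With the FOAF flag off, person/group/
# organization fall back to AO-local classes (the FOAF coupling is an
# optional module, not a core dependency).
KIND_CLASS_FOAF = {
    AgentKind.PERSON: FOAF.Person,
    AgentKind.SOFTWARE: SWAN_AGENT.Software,
    AgentKind.GROUP: FOAF.Group,
    AgentKind.ORGANIZATION: FOAF.Organization,
}
KIND_CLASS_LOCAL = {
    AgentKind.PERSON: AO.Person,
    AgentKind.SOFTWARE: SWAN_AGENT.Software,
    AgentKind.GROUP: AO.Group,
    AgentKind.ORGANIZATION: AO.Organization,
}
CLASS_KIND = {iri: k for k, iri in KIND_CLASS_FOAF.items()}
CLASS_KIND.update({iri: k for k, iri in KIND_CLASS_LOCAL.items()})

SELECTOR_CLASS = {
    TextQuoteSelector: AOS.PrefixPostfixTextSelector,
    OffsetRangeSelector: AOS.OffsetRangeTextSelector,
    XPointerSelectorRec: AOS.XPointerSelector,
    ImageBoxSelector: AOS.InitEndCornerSelector,
}
CLASS_SELECTOR = {iri: cls for cls, iri in SELECTOR_CLASS.items()}

# Every AO-family (ao/aos/aot/aof) term this module will ever emit.
AO_VOCABULARY: frozenset[str] = frozenset(
    str(term)
    for term in [
        AO.Annotation,
        AO.AnnotationSet,
        AO.Person,
        AO.Group,
        AO.Organization,
        AO.hasTopic,
        AO.hasTagging,
        AO.context,
        AO.onSourceDocument,
        AO.item,
        AO.contentDigest,
        AO.hasRelatedMeaning,
        AO.hasExactMeaning,
        AO.hasCloseMeaning,
        AO.hasNarrowerMeaningThan,
        AO.hasBroaderMeaningThan,
        AOF.annotatesDocument,
        AOF.onDocument,
        AOS.Selector,
        AOS.TextSelector,
        AOS.PrefixPostfixTextSelector,
        AOS.OffsetRangeTextSelector,
        AOS.XPointerSelector,
        AOS.InitEndCornerSelector,
        AOS.prefix,
        AOS.exact,
        AOS.postfix,
        AOS.offset,
        AOS.range,
        AOS.xpointer,
        AOS.initX,
        AOS.initY,
        AOS.endX,
        AOS.endY,
    ]
    + [str(iri) for iri in TYPE_CLASS.values()]
)

_AO_PREFIXES = tuple(
    TABLE1_NAMESPACES[p] for p in ("ao", "aos", "aot", "aof")
)


@dataclass
class NamespaceRegistry:
    """Prefix → IRI map seeded with the nine canonical bindings; extra
    bindings (FOAF, SIOC, SKOS, MOAT, ...) ride along for readability."""

    bindings: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = dict(TABLE1_NAMESPACES)
        merged.update(_EXTRA_NAMESPACES)
        merged.update(self.bindings)
        for prefix, iri in TABLE1_NAMESPACES.items():
            if merged.get(prefix) != iri:
                raise ValueError(f"canonical binding for '{prefix}' must be {iri}")
        self.bindings = merged

    def bind_all(self, graph: Graph) -> None:
        for prefix, iri in self.bindings.items():
            graph.bind(prefix, Namespace(iri), override=True)

    def fresh_graph(self) -> Graph:
        g = Graph(bind_namespaces="none")
        self.bind_all(g)
        return g


# ---------------------------------------------------------------------------
# serialization


def _plain(value: str) -> Literal:
    return Literal(value)


def _emit_agent(g: Graph, agent: Agent, foaf: bool) -> URIRef:
    node = URIRef(agent.uri)
    kind_class = (KIND_CLASS_FOAF if foaf else KIND_CLASS_LOCAL)[agent.kind]
    g.add((node, RDF.type, kind_class))
    if agent.name:
        g.add((node, FOAF.name if foaf else RDFS.label, _plain(agent.name)))
    return node


def _emit_document(g: Graph, doc: DocumentRef, foaf: bool) -> URIRef:
    page = URIRef(doc.page_uri)
    if foaf:
        g.add((page, RDF.type, FOAF.Document))
    for sv in doc.versions:
        vnode = URIRef(sv.uri)
        g.add((page, PAV.hasVersion, vnode))
        g.add((vnode, RDF.type, PAV.SourceDocument))
        g.add((vnode, PAV.accessedOn, _plain(sv.accessed_on)))
        if sv.content_digest:
            g.add((vnode, AO.contentDigest, _plain(sv.content_digest)))
    return page


def _emit_selector(g: Graph, sel: Selector) -> URIRef:
    node = URIRef(sel.uri)
    g.add((node, RDF.type, SELECTOR_CLASS[type(sel)]))
    if isinstance(sel, TextQuoteSelector):
        g.add((node, AOS.prefix, _plain(sel.prefix)))
        g.add((node, AOS.exact, _plain(sel.exact)))
        g.add((node, AOS.postfix, _plain(sel.postfix)))
    elif isinstance(sel, OffsetRangeSelector):
        g.add((node, AOS.offset, Literal(sel.start, datatype=XSD.integer)))
        g.add((node, AOS.range, Literal(sel.length, datatype=XSD.integer)))
    elif isinstance(sel, XPointerSelectorRec):
        g.add((node, AOS.xpointer, _plain(sel.expression)))
    elif isinstance(sel, ImageBoxSelector):
        for prop, value in (
            (AOS.initX, sel.x_init),
            (AOS.initY, sel.y_init),
            (AOS.endX, sel.x_end),
            (AOS.endY, sel.y_end),
        ):
            g.add((node, prop, Literal(value, datatype=XSD.integer)))
    if sel.on_document:
        g.add((node, AOF.onDocument, URIRef(sel.on_document)))
    if sel.on_version:
        g.add((node, AO.onSourceDocument, URIRef(sel.on_version)))
    return node


def _emit_token(g: Graph, token: CurationToken, foaf: bool) -> URIRef:
    node = URIRef(token.uri)
    g.add((node, RDF.type, PAV.Curation))
    g.add((node, PAV.curationStatus, _plain(token.status)))
    g.add((node, PAV.curatedBy, _emit_agent(g, token.curated_by, foaf)))
    g.add((node, PAV.curatedOn, _plain(token.curated_on)))
    if token.previous:
        g.add((node, PAV.previousCuration, URIRef(token.previous)))
    return node


def _emit_tagging(g: Graph, ann_node: URIRef, tagging: Tagging) -> None:
    tag = BNode()
    g.add((ann_node, AO.hasTagging, tag))
    g.add((tag, RDF.type, MOAT.Tag))
    g.add((tag, TAGS.name, _plain(tagging.tag_label)))
    for level, term in tagging.meanings:
        meaning = BNode()
        g.add((tag, MOAT.hasMeaning, meaning))
        g.add((meaning, RDF.type, MOAT.Meaning))
        g.add((meaning, MOAT.meaningURI, URIRef(term.uri)))
        g.add((ann_node, URIRef(level_meaning_property(level)), meaning))


def _emit_term(g: Graph, term: TermRef) -> URIRef:
    node = URIRef(term.uri)
    if term.label:
        g.add((node, RDFS.label, _plain(term.label)))
    if term.is_class is True:
        g.add((node, RDF.type, OWL.Class))
    elif term.is_class is False:
        g.add((node, RDF.type, OWL.NamedIndividual))
    return node


def _emit_annotation(
    g: Graph,
    ann: Annotation,
    foaf: bool,
    class_topics_as_restriction: bool,
) -> URIRef:
    node = URIRef(ann.uri)
    g.add((node, RDF.type, AO.Annotation))
    g.add((node, RDF.type, TYPE_CLASS[ann.ann_type]))
    for extra in ann.composed_types:
        g.add((node, RDF.type, URIRef(extra)))
    if ann.body is not None:
        g.add((node, ANN.body, _plain(ann.body)))
    for topic in ann.topics:
        term_node = _emit_term(g, topic.term)
        if class_topics_as_restriction and topic.term.is_class is True:
            restriction = BNode()
            g.add((node, RDF.type, restriction))
            g.add((restriction, RDF.type, OWL.Restriction))
            g.add((restriction, OWL.onProperty, AO.hasTopic))
            g.add((restriction, OWL.hasValue, term_node))
        else:
            g.add((node, AO.hasTopic, term_node))
        if topic.level is not None:
            g.add((node, URIRef(level_meaning_property(topic.level)), term_node))
    for target in ann.targets:
        if isinstance(target, DocumentRef):
            g.add((node, AOF.annotatesDocument, _emit_document(g, target, foaf)))
        else:
            g.add((node, AO.context, _emit_selector(g, target)))
    g.add((node, PAV.createdBy, _emit_agent(g, ann.created_by, foaf)))
    g.add((node, PAV.createdOn, _plain(ann.created_on)))
    if ann.curation_head is not None:
        g.add((node, PAV.hasCuration, _emit_token(g, ann.curation_head, foaf)))
    if ann.previous_version:
        g.add((node, PAV.previousVersion, URIRef(ann.previous_version)))
    if ann.version_number is not None:
        g.add((node, PAV.versionNumber, Literal(ann.version_number, datatype=XSD.integer)))
    if ann.supersedes:
        g.add((node, PAV.supersedes, URIRef(ann.supersedes)))
    if ann.tagging is not None:
        _emit_tagging(g, node, ann.tagging)
    return node


def _emit_set(g: Graph, aset: AnnotationSet, foaf: bool) -> URIRef:
    node = URIRef(aset.uri)
    g.add((node, RDF.type, AO.AnnotationSet))
    for item in aset.item_uris:
        g.add((node, AO.item, URIRef(item)))
    g.add((node, PAV.createdBy, _emit_agent(g, aset.created_by, foaf)))
    g.add((node, PAV.createdOn, _plain(aset.created_on)))
    if aset.previous_version:
        g.add((node, PAV.previousVersion, URIRef(aset.previous_version)))
    if aset.version_number is not None:
        g.add((node, PAV.versionNumber, Literal(aset.version_number, datatype=XSD.integer)))
    if aset.derived_from:
        g.add((node, PAV.derivedFrom, URIRef(aset.derived_from)))
    return node


def build_graph(
    entities: Iterable[object],
    *,
    registry: Optional[NamespaceRegistry] = None,
    foaf: bool = True,
    sioc_set_compat: bool = True,
    class_topics_as_restriction: bool = False,
) -> Graph:
    """Assemble the RDF graph for a collection of model entities."""
    registry = registry or NamespaceRegistry()
    g = registry.fresh_graph()
    entities = list(entities)
    reports = []
    for e in entities:
        try:
            reports.extend(validate(e))
        except TypeError:
            pass  # selectors / agents validate structurally at emit time
    if reports:
        raise ValidationError(reports)
    for e in entities:
        if isinstance(e, Annotation):
            _emit_annotation(g, e, foaf, class_topics_as_restriction)
        elif isinstance(e, AnnotationSet):
            _emit_set(g, e, foaf)
        elif isinstance(e, CurationToken):
            _emit_token(g, e, foaf)
        elif isinstance(e, Agent):
            _emit_agent(g, e, foaf)
        elif isinstance(e, DocumentRef):
            _emit_document(g, e, foaf)
        elif isinstance(e, (TextQuoteSelector, OffsetRangeSelector, XPointerSelectorRec, ImageBoxSelector)):
            _emit_selector(g, e)
        else:
            raise TypeError(f"cannot serialize {type(e).__name__}")
    if entities:
        # schema alignment: annotations are SIOC items, sets are (as the
        # alignment table prints it) sioc:AnnotationSet containers
        g.add((AO.Annotation, RDFS.subClassOf, SIOC.Item))
        if sioc_set_compat:
            g.add((AO.AnnotationSet, RDFS.subClassOf, SIOC.AnnotationSet))
    return g


def _ensure_turtle_prefixes(text: str) -> str:
    """Guarantee the nine canonical @prefix lines in Turtle output."""
    missing = [
        f"@prefix {p}: <{iri}> ."
        for p, iri in TABLE1_NAMESPACES.items()
        if f"@prefix {p}: <{iri}> ." not in text
    ]
    if not missing:
        return text
    return "\n".join(missing) + "\n" + text


def serialize(
    entities: Iterable[object],
    format: str = "turtle",
    *,
    registry: Optional[NamespaceRegistry] = None,
    foaf: bool = True,
    sioc_set_compat: bool = True,
    class_topics_as_restriction: bool = False,
) -> bytes:
    """Serialize model entities to one of: turtle, rdfxml, ntriples, jsonld.

    Entities must pass :func:`aokit.model.validate`; otherwise a
    :class:`ValidationError` carrying the violation report is raised.
    """
    fmt = FORMATS.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}; expected one of {sorted(set(FORMATS))}")
    g = build_graph(
        entities,
        registry=registry,
        foaf=foaf,
        sioc_set_compat=sioc_set_compat,
        class_topics_as_restriction=class_topics_as_restriction,
    )
    text = g.serialize(format=fmt)
    if fmt == "turtle":
        text = _ensure_turtle_prefixes(text)
    return text.encode("utf-8")


# ---------------------------------------------------------------------------
# parsing


_KNOWN_PREDICATES = frozenset(
    str(p)
    for p in [
        RDF.type,
        RDFS.label,
        RDFS.subClassOf,
        ANN.body,
        AO.hasTopic,
        AO.hasTagging,
        AO.context,
        AO.onSourceDocument,
        AO.item,
        AO.contentDigest,
        AO.hasRelatedMeaning,
        AO.hasExactMeaning,
        AO.hasCloseMeaning,
        AO.hasNarrowerMeaningThan,
        AO.hasBroaderMeaningThan,
        AOF.annotatesDocument,
        AOF.onDocument,
        AOS.prefix,
        AOS.exact,
        AOS.postfix,
        AOS.offset,
        AOS.range,
        AOS.xpointer,
        AOS.initX,
        AOS.initY,
        AOS.endX,
        AOS.endY,
        PAV.createdBy,
        PAV.createdOn,
        PAV.curatedBy,
        PAV.curatedOn,
        PAV.curationStatus,
        PAV.previousCuration,
        PAV.hasCuration,
        PAV.previousVersion,
        PAV.versionNumber,
        PAV.supersedes,
        PAV.derivedFrom,
        PAV.hasVersion,
        PAV.accessedOn,
        FOAF.name,
        MOAT.hasMeaning,
        MOAT.meaningURI,
        TAGS.name,
    ]
)

_MEANING_PROPS = tuple(
    URIRef(iri)
    for iri in (
        str(AO.hasRelatedMeaning),
        str(AO.hasExactMeaning),
        str(AO.hasCloseMeaning),
        str(AO.hasNarrowerMeaningThan),
        str(AO.hasBroaderMeaningThan),
    )
)


def _one(g: Graph, s, p):
    for o in g.objects(s, p):
        return o
    return None


def _parse_agent(g: Graph, node, warnings: list[str]) -> Agent:
    kind = AgentKind.PERSON
    for t in g.objects(node, RDF.type):
        if t in CLASS_KIND:
            kind = CLASS_KIND[t]
            break
    else:
        warnings.append(f"agent {node} has no recognized kind class; assuming person")
    name = _one(g, node, FOAF.name) or _one(g, node, RDFS.label)
    return Agent(uri=str(node), kind=kind, name=str(name) if name else "")


def _parse_document(g: Graph, page) -> DocumentRef:
    versions = []
    for vnode in g.objects(page, PAV.hasVersion):
        accessed = _one(g, vnode, PAV.accessedOn)
        digest = _one(g, vnode, AO.contentDigest)
        versions.append(
            SourceVersion(
                uri=str(vnode),
                accessed_on=str(accessed) if accessed else "",
                content_digest=str(digest) if digest else None,
            )
        )
    versions.sort(key=lambda sv: (sv.accessed_on, sv.uri))
    return DocumentRef(page_uri=str(page), versions=tuple(versions))


def _parse_selector(g: Graph, node, warnings: list[str]) -> Optional[Selector]:
    sel_cls = None
    for t in g.objects(node, RDF.type):
        if t in CLASS_SELECTOR:
            sel_cls = CLASS_SELECTOR[t]
            break
    if sel_cls is None:
        warnings.append(f"context node {node} has no recognized selector class")
        return None
    on_document = _one(g, node, AOF.onDocument)
    on_version = _one(g, node, AO.onSourceDocument)
    common = {
        "uri": str(node),
        "on_document": str(on_document) if on_document else None,
        "on_version": str(on_version) if on_version else None,
    }
    if sel_cls is TextQuoteSelector:
        return TextQuoteSelector(
            prefix=str(_one(g, node, AOS.prefix) or ""),
            exact=str(_one(g, node, AOS.exact) or ""),
            postfix=str(_one(g, node, AOS.postfix) or ""),
            **common,
        )
    if sel_cls is OffsetRangeSelector:
        return OffsetRangeSelector(
            start=int(_one(g, node, AOS.offset) or 0),
            length=int(_one(g, node, AOS.range) or 0),
            **common,
        )
    if sel_cls is XPointerSelectorRec:
        return XPointerSelectorRec(
            expression=str(_one(g, node, AOS.xpointer) or ""), **common
        )
    return ImageBoxSelector(
        x_init=int(_one(g, node, AOS.initX) or 0),
        y_init=int(_one(g, node, AOS.initY) or 0),
        x_end=int(_one(g, node, AOS.endX) or 0),
        y_end=int(_one(g, node, AOS.endY) or 0),
        **common,
    )


def _parse_token(g: Graph, node, warnings: list[str]) -> CurationToken:
    previous = _one(g, node, PAV.previousCuration)
    curated_by = _one(g, node, PAV.curatedBy)
    return CurationToken(
        uri=str(node),
        status=str(_one(g, node, PAV.curationStatus) or ""),
        curated_by=(
            _parse_agent(g, curated_by, warnings)
            if curated_by is not None
            else Agent(uri="urn:unknown", kind=AgentKind.PERSON)
        ),
        curated_on=str(_one(g, node, PAV.curatedOn) or ""),
        previous=str(previous) if previous else None,
    )


def _parse_tagging(g: Graph, ann_node, tag_node) -> Tagging:
    label = _one(g, tag_node, TAGS.name)
    meanings = []
    for meaning in g.objects(tag_node, MOAT.hasMeaning):
        term = _one(g, meaning, MOAT.meaningURI)
        level = MeaningLevel.RELATED
        for prop in _MEANING_PROPS:
            if (ann_node, prop, meaning) in g:
                level = meaning_property_level(str(prop))
                break
        if term is not None:
            meanings.append((level, TermRef(uri=str(term))))
    meanings.sort(key=lambda m: (m[0].value, m[1].uri))
    return Tagging(tag_label=str(label) if label else "", meanings=tuple(meanings))


def _parse_term(g: Graph, node) -> TermRef:
    label = _one(g, node, RDFS.label)
    is_class: Optional[bool] = None
    types = set(g.objects(node, RDF.type))
    if OWL.Class in types:
        is_class = True
    elif OWL.NamedIndividual in types:
        is_class = False
    return TermRef(uri=str(node), label=str(label) if label else None, is_class=is_class)


def _parse_annotation(g: Graph, node, warnings: list[str]) -> Annotation:
    ann_type = None
    composed = []
    for t in g.objects(node, RDF.type):
        if t == AO.Annotation or isinstance(t, BNode):
            continue
        if t in CLASS_TYPE:
            if ann_type is None:
                ann_type = CLASS_TYPE[t]
            else:
                warnings.append(f"annotation {node} carries multiple aot types")
        else:
            composed.append(str(t))
    if ann_type is None:
        warnings.append(f"annotation {node} has no aot type; defaulting to Qualifier")
        ann_type = AnnotationType.QUALIFIER
    body = _one(g, node, ANN.body)
    topics = []
    for term_node in sorted(g.objects(node, AO.hasTopic), key=str):
        level = None
        for prop in _MEANING_PROPS:
            if (node, prop, term_node) in g:
                level = meaning_property_level(str(prop))
                break
        topics.append(Topic(term=_parse_term(g, term_node), level=level))
    targets: list[object] = []
    for page in sorted(g.objects(node, AOF.annotatesDocument), key=str):
        targets.append(_parse_document(g, page))
    for ctx in sorted(g.objects(node, AO.context), key=str):
        sel = _parse_selector(g, ctx, warnings)
        if sel is not None:
            targets.append(sel)
    created_by = _one(g, node, PAV.createdBy)
    head = _one(g, node, PAV.hasCuration)
    prev = _one(g, node, PAV.previousVersion)
    vnum = _one(g, node, PAV.versionNumber)
    supersedes = _one(g, node, PAV.supersedes)
    tag_node = _one(g, node, AO.hasTagging)
    return Annotation(
        uri=str(node),
        ann_type=ann_type,
        created_by=(
            _parse_agent(g, created_by, warnings)
            if created_by is not None
            else Agent(uri="urn:unknown", kind=AgentKind.PERSON)
        ),
        created_on=str(_one(g, node, PAV.createdOn) or ""),
        targets=tuple(targets),
        body=str(body) if body is not None else None,
        topics=tuple(topics),
        composed_types=tuple(sorted(composed)),
        curation_head=_parse_token(g, head, warnings) if head is not None else None,
        previous_version=str(prev) if prev else None,
        version_number=int(vnum) if vnum is not None else None,
        supersedes=str(supersedes) if supersedes else None,
        tagging=_parse_tagging(g, node, tag_node) if tag_node is not None else None,
    )


def _parse_set(g: Graph, node, warnings: list[str]) -> AnnotationSet:
    created_by = _one(g, node, PAV.createdBy)
    prev = _one(g, node, PAV.previousVersion)
    vnum = _one(g, node, PAV.versionNumber)
    derived = _one(g, node, PAV.derivedFrom)
    return AnnotationSet(
        uri=str(node),
        item_uris=tuple(sorted(str(i) for i in g.objects(node, AO.item))),
        created_by=(
            _parse_agent(g, created_by, warnings)
            if created_by is not None
            else Agent(uri="urn:unknown", kind=AgentKind.PERSON)
        ),
        created_on=str(_one(g, node, PAV.createdOn) or ""),
        previous_version=str(prev) if prev else None,
        version_number=int(vnum) if vnum is not None else None,
        derived_from=str(derived) if derived else None,
    )


def parse(
    data: Union[bytes, str], format: str = "turtle"
) -> tuple[list[object], list[str]]:
    """Parse RDF back into model entities.

    Returns ``(entities, warnings)``: annotations, sets, and every curation
    token found, sorted by URI.  Unknown predicates become warnings, never
    errors.  Structural violations of the reconstructed entities raise
    :class:`ValidationError` with the full report.
    """
    fmt = FORMATS.get(format)
    if fmt is None:
        raise ValueError(f"unknown format {format!r}")
    g = Graph(bind_namespaces="none")
    if isinstance(data, bytes):
        data = data.decode("utf-8")
    g.parse(data=data, format=fmt)
    warnings: list[str] = []

    for s, p, o in g:
        sp = str(p)
        if sp.startswith(_AO_PREFIXES) and sp not in AO_VOCABULARY:
            warnings.append(f"unknown AO-namespace predicate preserved: {sp}")
        elif sp not in _KNOWN_PREDICATES and sp not in AO_VOCABULARY:
            warnings.append(f"unknown predicate preserved: {sp}")

    annotations = sorted(
        set(g.subjects(RDF.type, AO.Annotation))
        | {s for cls in CLASS_TYPE for s in g.subjects(RDF.type, cls)},
        key=str,
    )
    sets = sorted(set(g.subjects(RDF.type, AO.AnnotationSet)), key=str)
    tokens = sorted(set(g.subjects(RDF.type, PAV.Curation)), key=str)

    entities: list[object] = []
    violations = []
    for node in annotations:
        ann = _parse_annotation(g, node, warnings)
        violations.extend(validate(ann))
        entities.append(ann)
    for node in sets:
        aset = _parse_set(g, node, warnings)
        violations.extend(validate(aset))
        entities.append(aset)
    for node in tokens:
        entities.append(_parse_token(g, node, warnings))
    if violations:
        raise ValidationError(violations)
    return entities, sorted(set(warnings))


def graphs_isomorphic(a: Graph, b: Graph) -> bool:
    """Equality up to blank-node relabeling."""
    return isomorphic(a, b)


# ---------------------------------------------------------------------------
# Annotea compatibility


@dataclass
class AnnoteaExport:
    """Annotea-style graph plus a lossiness flag (selectors with no stored
    XPointer expression cannot be represented as ann:context)."""

    graph: Graph
    lossy: bool
    warnings: list[str] = field(default_factory=list)


def to_annotea(annotation: Annotation) -> AnnoteaExport:
    """Down-convert an annotation to the Annotea vocabulary.

    Stored XPointer expressions pass through as ``ann:context`` string
    values.  Text-quote, offset and image selectors have no Annotea
    counterpart: unless the annotation also stored an XPointer expression,
    the export is flagged lossy.
    """
    violations = validate(annotation)
    if violations:
        raise ValidationError(violations)
    registry = NamespaceRegistry()
    g = registry.fresh_graph()
    node = URIRef(annotation.uri)
    g.add((node, RDF.type, ANN.Annotation))
    if annotation.body is not None:
        g.add((node, ANN.body, _plain(annotation.body)))
    g.add((node, DC.creator, _plain(annotation.created_by.name or annotation.created_by.uri)))
    g.add((node, ANN.created, _plain(annotation.created_on)))
    warnings: list[str] = []
    lossy = False
    has_xpointer = False
    for target in annotation.targets:
        if isinstance(target, DocumentRef):
            g.add((node, ANN.annotates, URIRef(target.page_uri)))
            continue
        if target.on_document:
            g.add((node, ANN.annotates, URIRef(target.on_document)))
        if isinstance(target, XPointerSelectorRec):
            g.add((node, ANN.context, _plain(target.expression)))
            has_xpointer = True
        else:
            warnings.append(
                f"selector {target.uri} ({type(target).__name__}) has no "
                "Annotea representation"
            )
    if warnings and not has_xpointer:
        lossy = True
    return AnnoteaExport(graph=g, lossy=lossy, warnings=warnings)


def from_annotea(graph: Graph) -> tuple[list[Annotation], list[str]]:
    """Best-effort reconstruction of Annotea annotations (body, document
    link, stored XPointer contexts)."""
    warnings: list[str] = []
    out: list[Annotation] = []
    for node in sorted(set(graph.subjects(RDF.type, ANN.Annotation)), key=str):
        body = _one(graph, node, ANN.body)
        if body is None:
            warnings.append(f"annotea annotation {node} has no body; skipped")
            continue
        created = _one(graph, node, ANN.created)
        creator = _one(graph, node, DC.creator)
        targets: list[object] = []
        for page in sorted(graph.objects(node, ANN.annotates), key=str):
            targets.append(DocumentRef(page_uri=str(page)))
        for i, ctx in enumerate(sorted(graph.objects(node, ANN.context), key=str)):
            targets.append(
                XPointerSelectorRec(
                    uri=f"{node}#context-{i}", expression=str(ctx)
                )
            )
        out.append(
            Annotation(
                uri=str(node),
                ann_type=AnnotationType.NOTE,
                created_by=Agent(
                    uri="urn:annotea:creator",
                    kind=AgentKind.PERSON,
                    name=str(creator) if creator else "",
                ),
                created_on=str(created) if created else "1970-01-01T00:00:00+00:00",
                targets=tuple(targets),
                body=str(body),
            )
        )
    return out, warnings


# ---------------------------------------------------------------------------
# MOAT / restricted tagging


def tagging_graph(annotation: Annotation) -> Graph:
    """Emit a qualifier annotation as a Newman-style restricted tagging:
    resource, tag (label), graded meanings, and the tagger agent."""
    tagging = tagging_of(annotation)  # raises for non-qualifiers
    registry = NamespaceRegistry()
    g = registry.fresh_graph()
    tg = BNode()
    g.add((tg, RDF.type, TAGS.RestrictedTagging))
    for target in annotation.targets:
        if isinstance(target, DocumentRef):
            g.add((tg, TAGS.taggedResource, URIRef(target.page_uri)))
        else:
            g.add((tg, TAGS.taggedResource, URIRef(target.uri)))
    tag = BNode()
    g.add((tg, TAGS.associatedTag, tag))
    g.add((tag, RDF.type, MOAT.Tag))
    if tagging.tag_label:
        g.add((tag, TAGS.name, _plain(tagging.tag_label)))
    g.add((tg, TAGS.taggedBy, URIRef(annotation.created_by.uri)))
    for level, term in tagging.meanings:
        meaning = BNode()
        g.add((tag, MOAT.hasMeaning, meaning))
        g.add((meaning, RDF.type, MOAT.Meaning))
        g.add((meaning, MOAT.meaningURI, URIRef(term.uri)))
        g.add((tg, URIRef(level_meaning_property(level)), meaning))
    return g


def tagging_from_graph(graph: Graph) -> list[Tagging]:
    """Recover tagging records (label + graded meanings) from a
    restricted-tagging graph."""
    out = []
    for tg in set(graph.subjects(RDF.type, TAGS.RestrictedTagging)):
        tag = _one(graph, tg, TAGS.associatedTag)
        label = _one(graph, tag, TAGS.name) if tag is not None else None
        meanings = []
        if tag is not None:
            for meaning in graph.objects(tag, MOAT.hasMeaning):
                term = _one(graph, meaning, MOAT.meaningURI)
                level = MeaningLevel.RELATED
                for prop in _MEANING_PROPS:
                    if (tg, prop, meaning) in graph:
                        level = meaning_property_level(str(prop))
                        break
                if term is not None:
                    meanings.append((level, TermRef(uri=str(term))))
        meanings.sort(key=lambda m: (m[0].value, m[1].uri))
        out.append(
            Tagging(tag_label=str(label) if label else "", meanings=tuple(meanings))
        )
    return out
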