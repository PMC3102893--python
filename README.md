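# aokit — stand-off annotation for web documents

Biomedical knowledge increasingly lives in two disconnected places: formal
ontologies (PRO, GO, BIRNLex, SKOS terminologies, ...) and the natural-language
documents scientists actually read.  `aokit` implements the bridge: a
**stand-off annotation** model in which metadata — ontology-term links, notes,
errata, definitions, free-text tags — is stored *apart* from the annotated
page and anchored to it by **selectors**.  No update control over the target
document is needed, and the annotation survives the document's evolution as
long as the annotated content does.

It is aimed at curators of online scientific communities, text-mining
pipelines that need human review of their output, and anyone publishing
document annotation as Linked Open Data.

## The model

An **Annotation** carries a type, an optional body, ontology-term topics,
one or more targets (a whole document or a selector), and full provenance
(creator, creation time, source-document version, version lineage).  It is
serialized in the AO namespace family (`ao:`, `aos:` selectors, `aot:`
types, `aoa:` Annotea interop, `aof:` FOAF interop) with PAV (`pav:`) for
provenance, versioning and curation.

**Qualifiers** grade how well a term fits the annotated content, mirroring
the SKOS mapping properties:

| annotation type   | SKOS property       | reading                               |
|-------------------|---------------------|---------------------------------------|
| `aot:Qualifier`       | `skos:relatedMatch` | term is related (a free-text-only qualifier is a tag) |
| `aot:ExactQualifier`  | `skos:exactMatch`   | term represents the content exactly  |
| `aot:CloseQualifier`  | `skos:closeMatch`   | term is close but not exact          |
| `aot:BroadQualifier`  | `skos:broadMatch`   | term is broader than the content     |
| `aot:NarrowQualifier` | `skos:narrowMatch`  | term is narrower than the content    |

When several qualifiers share one anchor, their terms describe the same
content, which licenses **cross-ontology inference**: if term *A* exactly
represents a fragment and term *B* represents it at level *L*, then
*A* `skos:<L>Match` *B*.

The robust anchor is the **text-quote selector**
(`aos:PrefixPostfixTextSelector`): the exact annotated string plus up to 32
characters of context on either side, all in *normalized space* (markup
stripped, whitespace collapsed), with an offset map back to raw character
positions.  Resolution is two-tier — full `prefix+exact+postfix` context
first, bare `exact` as a flagged fallback — and reports `unique`,
`ambiguous`, or `orphan`.  Offset-range, stored-XPointer and image-rectangle
selectors are also provided.

Curation is a chain of judgment tokens (`pav:Curation`:
created/accepted/rejected/discussed) ordered by `pav:previousCuration`
pointers, with curation dates as fallback.  The store is append-only:
edits mint new versions (`pav:previousVersion`, `pav:versionNumber`),
replacement is supersession (`pav:supersedes`, the original is retained),
and annotation sets can be versioned and branched (`pav:derivedFrom`).

## Worked example

```python
from aokit import *
from aokit.model import AnnotationType

agent = Agent("http://example.org/agents/miner", AgentKind.SOFTWARE, "EntityMiner")
raw = "<p>The protein <b>BACE1</b> cleaves APP at the beta site.</p>"

norm = normalize_document(raw)
i = norm.text.find("BACE1")
sel = make_text_selector(norm, i, i + 5, seed=1,
                         on_document="http://example.org/doc")
print(repr(norm.text))
print(repr(sel.prefix), repr(sel.exact))

pro = TermRef("http://purl.org/obo/owl/PRO#PRO_000004623", label="Beta-Secretase 1")
birnlex = TermRef("http://bioontology.org/projects/ontologies/birnlex#birnlex_23",
                  label="Protein")
t = "2011-05-17T00:00:00+00:00"
q1 = new_annotation(AnnotationType.EXACT_QUALIFIER, agent, t, [sel],
                    topics=[Topic(pro, MeaningLevel.EXACT)], seed=2)
q2 = new_annotation(AnnotationType.NARROW_QUALIFIER, agent, t, [sel],
                    topics=[Topic(birnlex, MeaningLevel.NARROW)], seed=3)

print(resolve_text_selector(sel, norm))
for m in infer_cross_ontology([q1, q2]):
    print(m.subject_term.uri, m.skos_property, m.object_term.uri)
```

prints

```
'The protein BACE1 cleaves APP at the beta site.'
'The protein ' 'BACE1'
ResolutionResult(status='unique', matches=((18, 23),), tier='full_context', ...)
http://purl.org/obo/owl/PRO#PRO_000004623 http://www.w3.org/2004/02/skos/core#narrowMatch http://bioontology.org/projects/ontologies/birnlex#birnlex_23
```

The mention "BACE1" was normalized out of its `<b>` markup, anchored with
its sentence context, and re-resolved uniquely to raw characters 18–23.
Because the exactly-matching PRO term and the narrower-graded BIRNLex term
share one selector, the toolkit derives that *Beta-Secretase 1* has a
narrower meaning than *Protein* — a cross-ontology `skos:narrowMatch`.
`serialize([q1], "turtle")` emits the same content as RDF:

```turtle
<...annotation...> a ao:Annotation, aot:ExactQualifier ;
    ao:hasTopic PRO:PRO_000004623 ; ao:context <...selector...> .
<...selector...> a aos:PrefixPostfixTextSelector ;
    aos:prefix "The protein " ; aos:exact "BACE1" ;
    aos:postfix " cleaves APP at the beta site." .
```

## Command line

A thin `ao` executable wraps the library: `ao annotate` (document + char
range + term IRI + level), `ao resolve` (selectors vs. a document, JSON
report), `ao convert` (Turtle/RDF-XML/N-Triples/JSON-LD), `ao validate`,
`ao infer`, `ao curate`, `ao version`, `ao branch`, and `ao bench` (the
selector-robustness benchmark).  Global flags: `--base-uri`,
`--context-len`, `--format`, `--seed`, `--log-level`.

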