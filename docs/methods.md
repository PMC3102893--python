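# Methods

## Scope and design stance

`aokit` implements a stand-off annotation model for mutable web documents:
typed annotation records with provenance, graded ontology-term qualifiers,
fragment selectors with re-anchoring algorithms, lossless RDF exchange in
the AO/PAV namespace family, tagging (MOAT-style) interoperability, and an
append-only lifecycle (curation chains, versioning, supersession, set
branching).  Out of scope by design: XPointer *evaluation* (expressions are
stored and round-tripped verbatim), DOM-path and audio/video selectors,
pixel-content matching for images, OWL reasoning, SPARQL hosting, and
multi-user concurrency (the store contract is single-writer append-only;
access control is not modeled).

## Normalization

Anchoring operates in a normalized text space:

* tags, comments and declarations are removed; `script`/`style` content is
  dropped wholesale;
* each run of Unicode whitespace collapses to a single space whose offset
  map entry is the raw index of the run's first character;
* a removed **block-level** tag (`p`, `div`, `li`, `br`, table cells, ...)
  also acts as a collapsible space mapped to the tag's `<`, so stripping
  markup never glues adjacent words together; inline tags (`b`, `i`,
  `span`, ...) are zero-width, so a word split by emphasis is not broken;
* leading/trailing whitespace is dropped; character entities are left
  verbatim (decoding them would break the per-character identity
  `text[i] == raw[offset_map[i]]` that all raw-range mapping relies on).

The scanner is a single-pass state machine written here rather than a DOM
parser because the offset map — every normalized character pointing back to
its raw index through tolerant handling of broken markup — *is* the
algorithm; DOM parsers do not expose raw character provenance.
Normalization is idempotent, and the map is strictly increasing, which the
property tests assert on randomized documents.

Degenerate inputs: plain text passes through with an identity map; a `<`
that does not open anything tag-like (not followed by a letter, `/`, `!` or
`?`) is kept as a literal character; an unterminated tag or comment
swallows the remainder (best effort on broken markup).

## Selectors and resolution

`make_text_selector` records `exact = text[start:end]` with up to
`context_len` normalized characters of prefix/postfix, truncated at
document edges.  The default `context_len` is **32**: long enough that two
occurrences of the same mention almost never share a full context window in
running prose, short enough that unrelated nearby edits rarely invalidate
the anchor.  It is a tunable keyword everywhere it matters.

Resolution is two-tier.  Tier 1 finds all (possibly overlapping)
occurrences of `prefix+exact+postfix` as a contiguous normalized substring
and reports the exact span of each, mapped to raw coordinates via the
offset map.  Only if tier 1 is empty does tier 2 search for `exact` alone;
the reported `tier` lets a curator treat context-less matches with
suspicion.  Status follows the match count exactly: `unique` ⟺ 1,
`ambiguous` ⟺ ≥ 2, `orphan` ⟺ 0.  Matching is case- and diacritic-exact;
fuzzy matching is deliberately absent.

Offset-range selectors resolve positionally (`orphan` when out of bounds).
Image boxes use a top-left origin, `init` = upper-left and `end` =
lower-right corner, half-open in pixels; validation is purely geometric
against the stated image dimensions (a box result reuses the
`ResolutionResult` shape with the validated box as its single "match").
Stored XPointer expressions pass through re-anchoring unevaluated with
`evaluated=False` and zero matches — under the status/match-count
invariant that surfaces as `orphan`, and consumers are expected to filter
on the flag rather than read it as a lost anchor.

## RDF exchange

Serialization targets a fixed vocabulary table; nothing outside it is ever
emitted in the `ao`/`aos`/`aot`/`aof` namespaces, and parsing surfaces
unknown predicates as warnings, never errors.  Nine canonical prefix
bindings (`ao`, `aos`, `aot`, `aoa`, `aof`, `pav`, `swan-agent`, `swan`,
`ann`) are guaranteed byte-exact in Turtle output; since the underlying
serializer prunes unused prefixes, the writer re-adds any missing
`@prefix` lines.  `rdflib` stands behind graph construction, the four
syntaxes (Turtle, RDF/XML, N-Triples, JSON-LD) and isomorphism testing.

Property spellings the source vocabulary leaves open were fixed once here:
qualifier classes are `aot:` + type name; curation tokens are
`pav:Curation` instances linked by `pav:previousCuration`, attached via
`pav:hasCuration`, with the judgment in `pav:curationStatus`; offset
selectors use `aos:offset`/`aos:range`; image boxes
`aos:initX/initY/endX/endY`; a selector's page and version links are
`aof:onDocument` and `ao:onSourceDocument`.  Topic grades are emitted
per-topic through the meaning-property family (`ao:hasExactMeaning`, ...,
see below) alongside `ao:hasTopic`, which keeps multi-level annotations
lossless.  Term identity notes (`is_class`) map to `owl:Class` /
`owl:NamedIndividual` typing.  Timestamps are ISO-8601 UTC strings stored
as plain literals to keep lexical forms stable across round trips.

Alignment triples declare `ao:Annotation rdfs:subClassOf sioc:Item`, and —
behind a compatibility flag, on by default — `ao:AnnotationSet
rdfs:subClassOf sioc:AnnotationSet`.  The latter class is not part of
standard SIOC; the string is emitted as the alignment table prints it, and
the flag exists precisely so deployments that object can drop it.

Two optional emission modes: `foaf=False` types agents with
`swan-agent:`/AO-local classes instead of FOAF (keeping the core
FOAF-independent), and `class_topics_as_restriction=True` re-expresses
class-valued topics as an `owl:Restriction` on `ao:hasTopic` (a valid-DL
encoding offered for emission only — it is not parsed back or reasoned
over).

Annotea down-conversion (`to_annotea`) emits `ann:` triples; only stored
XPointer expressions survive as `ann:context`, so exports of annotations
anchored solely by text-quote, offset or image selectors are flagged
`lossy`.

## Qualifier semantics and inference

The five meaning levels map bijectively onto the SKOS mapping properties
(related→`relatedMatch`, exact→`exactMatch`, close→`closeMatch`,
broad→`broadMatch`, narrow→`narrowMatch`).  The annotation-side meaning
properties read from the *content's* perspective:
`ao:hasNarrowerMeaningThan` says the content is narrower than the term, so
the term sits at level **broad**, and symmetrically
`ao:hasBroaderMeaningThan` ⇔ level **narrow**.  This direction is pinned
by the worked tagging example (a "Linear skull fracture" tag whose meaning
term "skull fracture" is more general converts to a `BroadQualifier`) and
guarded by an enumerated test, because it is the single easiest place to
introduce an inversion bug.

Cross-ontology inference groups qualifier assertions by shared anchor
(selector URI or whole-document page URI).  For terms A (level L1) and B
(level L2) from distinct annotations in a group: if L1 is exact, emit
A `skos:<L2>Match` B; exact/exact collapses to one unordered `exactMatch`;
pairs with no exact member emit only A `relatedMatch` B — the weakest
claim, because SKOS mapping semantics justify a strong conclusion only
when one side is an exact representation of the shared fragment.
Duplicates (including symmetric duplicates of the symmetric properties)
are collapsed with evidence merged, and the output is sorted, so the
result is invariant under permutation of the input.  Mappings built on
terms known to be individuals rather than classes are still emitted, with
a `UserWarning` (whether instance-level conclusions are wanted is left to
the user).

## Lifecycle

The store is append-only: no operation overwrites or removes a URI, which
the monotonicity tests assert after every random operation.  Version
numbers start at 1 and increment per lineage; an un-numbered record counts
as version 1 when first versioned.  Only content fields (body, topics,
targets, type, tagging) are editable across versions — provenance edits
are refused.  Curation tokens attach to the annotation version current at
curation time; whether adding a token also re-versions the annotation is a
store flag (`reversion_on_curation`, default off).  A curation date earlier
than the chain head's is recorded as a warning but the token is appended —
clocks drift, and the `previous` pointer is authoritative; timeline
reconstruction falls back to date order (ties broken by URI) only when
pointers are absent, and raises on cycles.  Removing items from a set is
allowed for the new version only and warned against (curation-rejection is
the monotone alternative).  Dangling lineage references are warnings, not
errors, since imported graphs legitimately point outside the store.

## Synthetic documents and the robustness benchmark

The generator emulates the *anchoring-relevant* structure of a web page:
paragraph markup, repetitive running text (seeded word salad over ~56
domain stems, 40 words per paragraph, 6 paragraphs by default), planted
entity mentions at exactly recorded raw offsets, and — by default — one
entity planted twice so ambiguity handling is always exercised.  Mutations
model how live pages drift: block insertions (ads, news boxes), span
deletions/rewrites, paragraph reshuffles, each placed by a location policy
(outside all context windows / inside a window / on a mention) that is
honored by construction and verified against the live windows.  Insertions
snap to whitespace so they never split a word, tag or mention.

What the generator does **not** emulate: real HTML entity usage, nested
inline markup around mentions, tables/figures, non-ASCII scripts, and
near-duplicate sentences that differ only beyond the 32-character window.
Passing tests therefore demonstrate the algorithms' contracts — not that
32 characters of context suffice for any particular real corpus; that
constant should be tuned against the target documents.

The benchmark (`robustness_experiment`) assigns each generated document a
mutation arm (insertion away from anchors, mention deletion, in-context
rewrite; intensity = fraction of paragraphs touched, default 0.3 in the
CLI/benchmark entry points), re-resolves every planted mention's text-quote
and offset selector, and tabulates unique/ambiguous/orphan counts that
partition the selector population.  An offset selector that resolves
in-bounds but onto the wrong text (detected against ground truth) is
counted as lost: positional anchors fail silently, and the benchmark's
point is to expose exactly that.

## Problem sizes

The shipped acceptance run uses 50 randomized entity collections × 4 RDF
syntaxes for round-trip isomorphism, 1,000 random (document, range) pairs
for anchor round-trip and brute-force agreement, 60 × 2 block insertions +
40 mention deletions + a 30-document benchmark for mutation robustness,
200 random qualifier groups against the pair-enumeration oracle, 100
random taggings for conversion identity, 200 random curation chains
(length ≤ 10), and 100 random lifecycle operations for monotonicity.  All
randomness derives from the single `--seed` argument.
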