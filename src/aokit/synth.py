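"""Synthetic HTML documents with planted entity mentions, controlled
mutations, and a selector-robustness benchmark.

Real annotated pages cannot ship with the test suite, so this module
manufactures them: seeded pseudo-random word salad wrapped in paragraph
markup, with entity names planted at known raw offsets (the ground truth
every anchoring test checks against).  Mutations emulate the ways live web
pages drift — inserted blocks (ads, news boxes), deleted or rewritten
spans, reshuffled paragraphs — with a location policy that places each edit
relative to the planted anchors: far from every selector context, inside a
context window, or on top of a mention.

Everything is deterministic per seed: identical (seed, params) give
byte-identical documents.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .anchoring import (
    DEFAULT_CONTEXT_LEN,
    NormalizedText,
    OffsetRangeSelector,
    TextQuoteSelector,
    make_text_selector,
    normalize_document,
    resolve_offset_selector,
    resolve_text_selector,
)

__all__ = [
    "Mention",
    "SyntheticDocument",
    "MutationOp",
    "generate_document",
    "mutate_document",
    "robustness_experiment",
    "mention_selectors",
    "DEFAULT_LEXICON",
]

# word salad vocabulary: enough distinct stems that unintended repeats of a
# whole context window are vanishingly rare, few enough that single words
# repeat constantly (realistic ambiguity pressure)
_WORDS = (
    "signal pathway neuron cortex plaque tangle amyloid synapse receptor "
    "ligand kinase substrate vesicle axon dendrite glia cohort assay blot "
    "lysate culture vector plasmid primer exon intron codon promoter "
    "enhancer silencer motif domain helix sheet loop fold complex dimer "
    "monomer oligomer fibril aggregate clearance uptake transport binding "
    "affinity titration gradient buffer reagent control baseline outcome"
).split()

DEFAULT_LEXICON = ("BACE1", "APP", "PSEN1", "tau", "ApoE4")


@dataclass(frozen=True)
class Mention:
    """A planted entity occurrence: which entity, and the half-open raw
    character range that slices exactly to its name."""

    entity_id: str
    raw_start: int
    raw_end: int


@dataclass(frozen=True)
class SyntheticDocument:
    raw_html: str
    mentions: tuple[Mention, ...]
    seed: int

    def check_ground_truth(self) -> None:
        """Assert every mention range slices to its entity string with no
        markup delimiters inside."""
        for m in self.mentions:
            got = self.raw_html[m.raw_start : m.raw_end]
            if got != m.entity_id or "<" in got or ">" in got:
                raise AssertionError(
                    f"mention {m.entity_id} at [{m.raw_start},{m.raw_end}) slices to {got!r}"
                )


@dataclass(frozen=True)
class MutationOp:
    """One document edit.

    ``kind``: insert_block | delete_span | replace_span | reorder_paragraphs.
    ``location_policy``: outside_all_contexts | inside_context | at_mention —
    where the edit lands relative to the live selector context windows.
    ``payload`` (insert/replace) and ``span`` (delete/replace) may be given
    explicitly; when omitted they are chosen by the seeded mutator, honoring
    the policy by construction.
    """

    kind: str
    location_policy: str = "outside_all_contexts"
    payload: Optional[str] = None
    span: Optional[tuple[int, int]] = None


def _paragraph(rng: random.Random, n_words: int) -> list[str]:
    return [rng.choice(_WORDS) for _ in range(n_words)]


def generate_document(
    seed: int,
    n_paragraphs: int = 6,
    entity_lexicon: Sequence[str] = DEFAULT_LEXICON,
    *,
    words_per_paragraph: int = 40,
    duplicate_first_entity: bool = True,
) -> SyntheticDocument:
    """Generate a paragraph-structured HTML document with planted mentions.

    Each lexicon entity is planted once at a random word position; with
    ``duplicate_first_entity`` (the default) the first entity is planted a
    second time in a different paragraph, so ambiguity handling is always
    exercised.  Mention offsets are recorded during assembly and are exact
    by construction.
    """
    if n_paragraphs < 1:
        raise ValueError("n_paragraphs must be >= 1")
    if not entity_lexicon:
        raise ValueError("entity lexicon must be non-empty")
    rng = random.Random(seed)
    paragraphs = [_paragraph(rng, words_per_paragraph) for _ in range(n_paragraphs)]

    plant: list[str] = list(entity_lexicon)
    if duplicate_first_entity:
        plant.append(entity_lexicon[0])
    # (paragraph index, word slot, entity) chosen up front so later plants
    # do not disturb earlier ones
    placements = []
    for entity in plant:
        p = rng.randrange(n_paragraphs)
        slot = rng.randrange(len(paragraphs[p]) + 1)
        placements.append((p, slot, entity))
    # insert deepest slots first within each paragraph so indices stay valid
    for p, slot, entity in sorted(placements, key=lambda t: (t[0], -t[1])):
        paragraphs[p].insert(slot, entity)

    entity_set = set(plant)
    pieces: list[str] = []
    mentions: list[Mention] = []
    pos = 0

    def emit(s: str) -> None:
        nonlocal pos
        pieces.append(s)
        pos += len(s)

    for i, words in enumerate(paragraphs):
        if i:
            emit("\n")
        emit("<p>")
        for j, word in enumerate(words):
            if j:
                emit(" ")
            if word in entity_set:
                mentions.append(Mention(word, pos, pos + len(word)))
            emit(word)
        emit("</p>")

    doc = SyntheticDocument(
        raw_html="".join(pieces), mentions=tuple(mentions), seed=seed
    )
    doc.check_ground_truth()
    return doc


# ---------------------------------------------------------------------------
# mutation


def _context_windows(
    doc: SyntheticDocument, context_len: int = DEFAULT_CONTEXT_LEN
) -> list[tuple[int, int]]:
    """Raw-space extents of every mention's prefix+exact+postfix window."""
    norm = normalize_document(doc.raw_html)
    windows = []
    for m in doc.mentions:
        s = norm.norm_index(m.raw_start)
        e = s + (m.raw_end - m.raw_start)
        ws = max(0, s - context_len)
        we = min(len(norm.text), e + context_len)
        windows.append(norm.raw_range(ws, we))
    return windows


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _policy_ok(
    policy: str,
    span: tuple[int, int],
    windows: Sequence[tuple[int, int]],
    mentions: Sequence[Mention],
) -> bool:
    mention_spans = [(m.raw_start, m.raw_end) for m in mentions]
    if policy == "outside_all_contexts":
        return not any(_overlaps(span, w) for w in windows)
    if policy == "inside_context":
        return any(_overlaps(span, w) for w in windows) and not any(
            _overlaps(span, ms) for ms in mention_spans
        )
    if policy == "at_mention":
        return any(_overlaps(span, ms) for ms in mention_spans)
    raise ValueError(f"unknown location policy {policy!r}")


def _choose_span(
    rng: random.Random,
    op: MutationOp,
    raw: str,
    windows: Sequence[tuple[int, int]],
    mentions: Sequence[Mention],
    width: int,
    snap_to_space: bool = False,
) -> tuple[int, int]:
    raw_len = len(raw)
    if op.span is not None:
        s, e = op.span
        if not (0 <= s <= e <= raw_len):
            raise ValueError(f"op span {op.span} out of bounds for length {raw_len}")
        probe = (s, e) if s < e else (s, min(s + 1, raw_len))
        if not _policy_ok(op.location_policy, probe, windows, mentions):
            raise ValueError(
                f"explicit span {op.span} violates location policy {op.location_policy}"
            )
        return s, e
    if op.location_policy == "at_mention" and mentions:
        m = mentions[rng.randrange(len(mentions))]
        return m.raw_start, m.raw_end
    for attempt in range(500):
        s = rng.randrange(max(1, raw_len - width + 1))
        e = min(raw_len, s + width)
        # late attempts drop the whitespace snap so placement cannot starve
        if snap_to_space and attempt < 400 and not raw[s].isspace():
            continue
        if _policy_ok(op.location_policy, (s, e), windows, mentions):
            return s, e
    raise ValueError(f"could not place a span honoring policy {op.location_policy!r}")


def _shift_mentions(
    mentions: Iterable[Mention], edit_start: int, edit_end: int, delta: int
) -> tuple[Mention, ...]:
    """Shift mention offsets across an edit; mentions overlapping the edited
    span are tombstoned (dropped)."""
    out = []
    for m in mentions:
        if m.raw_end <= edit_start:
            out.append(m)
        elif m.raw_start >= edit_end:
            out.append(replace(m, raw_start=m.raw_start + delta, raw_end=m.raw_end + delta))
        # else: overlapped -> tombstone
    return tuple(out)


def mutate_document(
    doc: SyntheticDocument,
    ops: Sequence[MutationOp],
    seed: int,
    *,
    context_len: int = DEFAULT_CONTEXT_LEN,
) -> tuple[SyntheticDocument, list[dict]]:
    """Apply edits in order, returning the new document and an edit log.

    Each log entry records the op kind, policy, the raw span edited (in the
    coordinates of the document state it applied to), its replacement span,
    and the mentions tombstoned by it.  Surviving mention offsets are
    updated and remain exact.
    """
    rng = random.Random(seed)
    raw = doc.raw_html
    mentions = doc.mentions
    log: list[dict] = []
    for op in ops:
        current = SyntheticDocument(raw_html=raw, mentions=mentions, seed=doc.seed)
        windows = _context_windows(current, context_len)
        if op.kind == "reorder_paragraphs":
            raw, mentions, entry = _reorder(rng, raw, mentions)
            log.append(entry)
            continue
        if op.kind == "insert_block":
            payload = op.payload or (
                "<p>" + " ".join(_paragraph(rng, 20)) + "</p>"
            )
            # insertions snap to whitespace so they do not split a word or tag
            s, _ = _choose_span(
                rng, op, raw, windows, mentions, width=1, snap_to_space=True
            )
            e = s
            new_raw = raw[:s] + payload + raw[s:]
            delta = len(payload)
        elif op.kind in ("delete_span", "replace_span"):
            if op.kind == "replace_span":
                payload = op.payload if op.payload is not None else " ".join(_paragraph(rng, 5))
            else:
                payload = ""
            s, e = _choose_span(rng, op, raw, windows, mentions, width=30)
            new_raw = raw[:s] + payload + raw[e:]
            delta = len(payload) - (e - s)
        else:
            raise ValueError(f"unknown mutation kind {op.kind!r}")
        tombstoned = [
            m.entity_id for m in mentions if m.raw_start < e and s < m.raw_end
        ] if s < e else [
            m.entity_id for m in mentions if m.raw_start < s < m.raw_end
        ]
        log.append(
            {
                "kind": op.kind,
                "policy": op.location_policy,
                "raw_span_before": (s, e),
                "raw_span_after": (s, e + delta),
                "tombstoned": tombstoned,
            }
        )
        raw, mentions = new_raw, _shift_mentions(mentions, s, e, delta)
    out = SyntheticDocument(raw_html=raw, mentions=mentions, seed=doc.seed)
    out.check_ground_truth()
    return out, log


def _reorder(
    rng: random.Random, raw: str, mentions: tuple[Mention, ...]
) -> tuple[str, tuple[Mention, ...], dict]:
    """Shuffle top-level paragraph blocks, remapping mention offsets."""
    import re

    blocks = [(m.start(), m.end()) for m in re.finditer(r"<p>.*?</p>", raw, re.S)]
    if len(blocks) < 2:
        return raw, mentions, {"kind": "reorder_paragraphs", "moved": 0}
    order = list(range(len(blocks)))
    rng.shuffle(order)
    pieces = []
    pos = 0
    new_mentions: list[Mention] = []
    for new_index, old_index in enumerate(order):
        if new_index:
            pieces.append("\n")
            pos += 1
        s, e = blocks[old_index]
        for m in mentions:
            if s <= m.raw_start and m.raw_end <= e:
                shift = pos - s
                new_mentions.append(
                    replace(m, raw_start=m.raw_start + shift, raw_end=m.raw_end + shift)
                )
        pieces.append(raw[s:e])
        pos += e - s
    new_mentions.sort(key=lambda m: m.raw_start)
    return (
        "".join(pieces),
        tuple(new_mentions),
        {"kind": "reorder_paragraphs", "moved": len(blocks), "order": order},
    )


# ---------------------------------------------------------------------------
# robustness benchmark


def mention_selectors(
    doc: SyntheticDocument,
    *,
    context_len: int = DEFAULT_CONTEXT_LEN,
    base_namespace: str = "http://example.org/ao/",
) -> list[tuple[Mention, TextQuoteSelector, OffsetRangeSelector]]:
    """A text-quote and an offset selector for every planted mention."""
    norm = normalize_document(doc.raw_html)
    out = []
    for i, m in enumerate(doc.mentions):
        s = norm.norm_index(m.raw_start)
        e = s + (m.raw_end - m.raw_start)
        tq = make_text_selector(
            norm,
            s,
            e,
            context_len,
            base_namespace=base_namespace,
            seed=doc.seed * 10_000 + 2 * i,
        )
        off = OffsetRangeSelector(
            uri=f"{base_namespace}selector/offset-{doc.seed}-{i}",
            start=s,
            length=e - s,
        )
        out.append((m, tq, off))
    return out


_MUTATION_ARMS = (
    ("insert_outside", MutationOp("insert_block", "outside_all_contexts")),
    ("delete_at_mention", MutationOp("delete_span", "at_mention")),
    ("replace_inside_context", MutationOp("replace_span", "inside_context")),
)


def robustness_experiment(
    seed: int,
    n_docs: int = 30,
    mutation_intensity: float = 0.3,
    *,
    n_paragraphs: int = 6,
    context_len: int = DEFAULT_CONTEXT_LEN,
) -> dict[str, dict[str, dict[str, int]]]:
    """How often each selector type survives each class of mutation.

    ``mutation_intensity`` is the fraction of paragraphs touched per
    document (0 → no edits).  Documents cycle through the mutation arms
    (block insertion away from anchors, mention deletion, in-context
    rewrites).  Returns
    ``table[mutation_class][selector_type] = {unique, ambiguous, orphan}``;
    the counts partition the full selector population.
    """
    if not (0.0 <= mutation_intensity <= 1.0):
        raise ValueError("mutation_intensity must be in [0, 1]")
    table: dict[str, dict[str, dict[str, int]]] = {}

    def bump(arm: str, sel_type: str, status: str) -> None:
        cell = table.setdefault(arm, {}).setdefault(
            sel_type, {"unique": 0, "ambiguous": 0, "orphan": 0}
        )
        cell[status] += 1

    n_ops = round(mutation_intensity * n_paragraphs)
    for i in range(n_docs):
        doc = generate_document(seed + i, n_paragraphs)
        selectors = mention_selectors(doc, context_len=context_len)
        if n_ops == 0:
            arm, mutated = "none", doc
        else:
            arm, op = _MUTATION_ARMS[i % len(_MUTATION_ARMS)]
            mutated, _ = mutate_document(
                doc, [op] * n_ops, seed * 7919 + i, context_len=context_len
            )
        norm = normalize_document(mutated.raw_html)
        for m, tq, off in selectors:
            bump(arm, "text_quote", resolve_text_selector(tq, norm).status)
            res = resolve_offset_selector(off, norm)
            status = res.status
            if status == "unique" and res.norm_matches:
                s, e = res.norm_matches[0]
                # positional anchors can land in-bounds on the wrong text
                # after an upstream edit; ground truth exposes that, and a
                # mis-anchored selector counts as lost
                if norm.text[s:e] != m.entity_id:
                    status = "orphan"
            bump(arm, "offset_range", status)
    return table


# ---------------------------------------------------------------------------
# random annotation-graph fixtures


def random_entities(rng: random.Random, tag: str) -> list:
    """A small random entity collection for serialization exercises: 2-4
    annotations covering every selector type plus whole-document targets, a
    curation chain of length up to 5, and a branched set pair.  ``tag``
    namespaces the minted IRIs so collections are disjoint."""
    from .anchoring import XPointerSelectorRec, ImageBoxSelector
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
    )
    from dataclasses import replace as _replace

    def ts() -> str:
        return (
            f"2011-{rng.randrange(1, 13):02d}-{rng.randrange(1, 29):02d}"
            f"T{rng.randrange(24):02d}:00:00+00:00"
        )

    b = f"http://fixtures.example.org/ao/{tag}/"
    person = Agent(b + "agent/p", AgentKind.PERSON, f"Person {tag}")
    software = Agent(b + "agent/s", AgentKind.SOFTWARE, "Miner")
    doc = DocumentRef(
        page_uri=b + "doc",
        versions=(SourceVersion(uri=b + "doc?rev=1", accessed_on=ts()),),
    )
    selectors = [
        TextQuoteSelector(
            uri=b + "sel/tq",
            prefix="the protein ",
            exact=f"GENE{rng.randrange(100)}",
            postfix=" is cleaved",
            on_document=doc.page_uri,
            on_version=doc.versions[0].uri,
        ),
        OffsetRangeSelector(
            uri=b + "sel/off",
            start=rng.randrange(200),
            length=1 + rng.randrange(30),
            on_document=doc.page_uri,
        ),
        XPointerSelectorRec(
            uri=b + "sel/xp",
            expression=(
                f"xpointer(string-range(/html/body/p[{rng.randrange(9) + 1}],"
                f"{rng.randrange(50)},10))"
            ),
            on_document=doc.page_uri,
        ),
        ImageBoxSelector(
            uri=b + "sel/box",
            x_init=5,
            y_init=5,
            x_end=5 + rng.randrange(1, 90),
            y_end=5 + rng.randrange(1, 90),
            on_document=doc.page_uri,
        ),
    ]
    term = TermRef(
        uri=f"http://purl.org/obo/owl/PRO#PRO_{rng.randrange(10**6):06d}",
        label="some protein",
        is_class=rng.choice([True, False, None]),
    )
    entities: list = []

    chain: list[CurationToken] = []
    for i in range(rng.randrange(6)):
        chain.append(
            CurationToken(
                uri=b + f"cur/{i}",
                status=rng.choice(["created", "accepted", "rejected", "discussed"]),
                curated_by=person,
                curated_on=ts(),
                previous=chain[-1].uri if chain else None,
            )
        )
    entities.extend(chain)

    level_type = {
        "related": AnnotationType.QUALIFIER,
        "exact": AnnotationType.EXACT_QUALIFIER,
        "close": AnnotationType.CLOSE_QUALIFIER,
        "broad": AnnotationType.BROAD_QUALIFIER,
        "narrow": AnnotationType.NARROW_QUALIFIER,
    }
    ann_uris = []
    for i in range(2 + rng.randrange(3)):
        level = rng.choice(list(MeaningLevel))
        kind = rng.choice(["note", "qualifier", "tagged"])
        common = dict(
            created_by=rng.choice([person, software]),
            created_on=ts(),
            targets=(rng.choice(selectors + [doc]),),
            curation_head=chain[-1] if chain and i == 0 else None,
        )
        if kind == "note":
            ann = Annotation(
                uri=b + f"ann/{i}",
                ann_type=rng.choice(
                    [
                        AnnotationType.NOTE,
                        AnnotationType.ERRATA,
                        AnnotationType.EXAMPLE,
                        AnnotationType.DEFINITION,
                    ]
                ),
                body=f"free text note {rng.randrange(1000)}",
                **common,
            )
        elif kind == "qualifier":
            ann = Annotation(
                uri=b + f"ann/{i}",
                ann_type=level_type[level.value],
                topics=(Topic(term=term, level=level),),
                composed_types=(
                    ("http://purl.org/swan/2.0/ResearchStatement",)
                    if rng.random() < 0.3
                    else ()
                ),
                **common,
            )
        else:
            ann = Annotation(
                uri=b + f"ann/{i}",
                ann_type=AnnotationType.QUALIFIER,
                body="linear skull fracture",
                tagging=Tagging(
                    tag_label="linear skull fracture",
                    meanings=((level, TermRef(uri=b + "term/fracture")),),
                ),
                **common,
            )
        if rng.random() < 0.3:
            ann = _replace(ann, previous_version=b + f"ann/{i}-v1", version_number=2)
        entities.append(ann)
        ann_uris.append(ann.uri)

    base_set = AnnotationSet(
        uri=b + "set/1",
        item_uris=tuple(ann_uris),
        created_by=person,
        created_on=ts(),
        version_number=1,
    )
    branch = AnnotationSet(
        uri=b + "set/2",
        item_uris=tuple(ann_uris[:1]),
        created_by=software,
        created_on=ts(),
        version_number=1,
        derived_from=base_set.uri,
    )
    entities.extend([base_set, branch])
    return entities
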