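"""Text normalization and selector anchoring.

Web pages mutate; a robust anchor must survive edits elsewhere in the
document.  The approach here is a *normalized text space*: markup is
stripped, whitespace runs collapse to single spaces, and every normalized
character keeps a pointer back to its raw-document index (the offset map).
Selectors are created and matched in normalized space and results are
reported as raw character ranges, so they are insensitive to markup
reflowing, attribute edits, and whitespace churn.

Resolution of a text-quote selector is two-tier: first the full
``prefix + exact + postfix`` context is searched; only if that fails is the
bare ``exact`` string searched, and the tier that produced the matches is
reported so reviewers can treat context-less matches with suspicion.
Matching is case- and diacritic-sensitive; no fuzzy matching is attempted.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

from .model import Annotation, DocumentRef, mint_uri

__all__ = [
    "NormalizedText",
    "TextQuoteSelector",
    "OffsetRangeSelector",
    "XPointerSelectorRec",
    "ImageBoxSelector",
    "Selector",
    "ResolutionResult",
    "normalize_document",
    "make_text_selector",
    "resolve_text_selector",
    "resolve_offset_selector",
    "validate_image_box",
    "reanchor_report",
    "DEFAULT_CONTEXT_LEN",
]

DEFAULT_CONTEXT_LEN = 32

# Elements whose text content is not rendered and is therefore dropped.
_SKIP_CONTENT = {"script", "style"}

# Elements that terminate a text run when rendered: stripping the tag must
# not glue adjacent words together, so these act as a (collapsible) space.
_BLOCK_TAGS = {
    "address", "article", "aside", "blockquote", "body", "br", "caption",
    "dd", "div", "dl", "dt", "fieldset", "figcaption", "figure", "footer",
    "form", "h1", "h2", "h3", "h4", "h5", "h6", "head", "header", "hr",
    "html", "li", "main", "nav", "ol", "p", "pre", "section", "table",
    "tbody", "td", "tfoot", "th", "thead", "title", "tr", "ul",
}


@dataclass(frozen=True)
class NormalizedText:
    """Markup-stripped, whitespace-collapsed text plus the map back to raw
    character indices (``offset_map[i]`` is the raw index of ``text[i]``;
    for a collapsed whitespace run it is the raw index of the run's first
    character)."""

    text: str
    offset_map: tuple[int, ...]

    def raw_range(self, start: int, end: int) -> tuple[int, int]:
        """Map a half-open normalized range to a half-open raw range."""
        if not (0 <= start < end <= len(self.text)):
            raise IndexError(f"normalized range [{start}, {end}) out of bounds")
        return self.offset_map[start], self.offset_map[end - 1] + 1

    def norm_index(self, raw_index: int) -> int:
        """Normalized index of the character at (or first after) raw_index."""
        return bisect_left(self.offset_map, raw_index)


@dataclass(frozen=True)
class TextQuoteSelector:
    """A fragment identified by its exact text plus surrounding context,
    all in normalized space."""

    uri: str
    prefix: str
    exact: str
    postfix: str
    on_document: Optional[str] = None
    on_version: Optional[str] = None


@dataclass(frozen=True)
class OffsetRangeSelector:
    """A fragment identified positionally: ``start`` (0-based, normalized
    space) and ``length``.  Cheap but brittle under upstream edits."""

    uri: str
    start: int
    length: int
    on_document: Optional[str] = None
    on_version: Optional[str] = None


@dataclass(frozen=True)
class XPointerSelectorRec:
    """A stored XPointer expression.  Kept and round-tripped verbatim; this
    toolkit does not evaluate XPointer."""

    uri: str
    expression: str
    on_document: Optional[str] = None
    on_version: Optional[str] = None


@dataclass(frozen=True)
class ImageBoxSelector:
    """A rectangular image region in pixels: origin top-left, ``init`` the
    upper-left corner, ``end`` the lower-right, half-open."""

    uri: str
    x_init: int
    y_init: int
    x_end: int
    y_end: int
    on_document: Optional[str] = None
    on_version: Optional[str] = None


Selector = Union[TextQuoteSelector, OffsetRangeSelector, XPointerSelectorRec, ImageBoxSelector]


@dataclass(frozen=True)
class ResolutionResult:
    """Outcome of resolving one selector against one document state.

    ``status`` follows the match count (unique ⟺ 1, ambiguous ⟺ ≥2,
    orphan ⟺ 0).  ``matches`` holds half-open raw character ranges (for an
    image box, the single validated box as a 4-tuple).  ``tier`` records
    whether the full context or only the exact string produced the matches.
    ``evaluated`` is False for pass-through selectors (stored XPointers)
    that this toolkit does not attempt to resolve.
    """

    status: str  # "unique" | "ambiguous" | "orphan"
    matches: tuple[tuple[int, ...], ...]
    tier: str  # "full_context" | "exact_only" | "none"
    evaluated: bool = True
    norm_matches: tuple[tuple[int, int], ...] = ()


def _status_for(n_matches: int) -> str:
    if n_matches == 0:
        return "orphan"
    return "unique" if n_matches == 1 else "ambiguous"


def _result(norm: NormalizedText, spans: Sequence[tuple[int, int]], tier: str) -> ResolutionResult:
    raw = tuple(norm.raw_range(s, e) for s, e in spans)
    return ResolutionResult(
        status=_status_for(len(spans)),
        matches=raw,
        tier=tier if spans else "none",
        norm_matches=tuple(spans),
    )


# ---------------------------------------------------------------------------
# normalization


def _tag_like(raw: str, i: int) -> bool:
    if raw[i] != "<" or i + 1 >= len(raw):
        return False
    c = raw[i + 1]
    return c.isalpha() or c in "/!?"


def _scan_tag(raw: str, i: int) -> tuple[int, str, bool]:
    """Scan a tag starting at raw[i] == '<'.

    Returns (index just past the tag, lowercased tag name, is_closing).
    Comments and declarations return an empty name.  An unterminated tag
    swallows the rest of the document (best-effort on broken markup).
    """
    n = len(raw)
    if raw.startswith("<!--", i):
        end = raw.find("-->", i + 4)
        return (n if end < 0 else end + 3), "", False
    if raw[i + 1] in "!?":
        end = raw.find(">", i)
        return (n if end < 0 else end + 1), "", False
    j = i + 1
    closing = raw[j] == "/"
    if closing:
        j += 1
    k = j
    while k < n and (raw[k].isalnum() or raw[k] in "-:"):
        k += 1
    name = raw[j:k].lower()
    end = raw.find(">", k)
    return (n if end < 0 else end + 1), name, closing


def normalize_document(raw: str) -> NormalizedText:
    """Strip markup and collapse whitespace, keeping the raw-index map.

    Rules:

    * tags, comments and declarations are removed; ``script``/``style``
      content is removed wholesale;
    * a run of Unicode whitespace becomes one space mapped to the raw index
      of the run's first character;
    * a removed block-level tag also acts as a (collapsible) space, mapped
      to the tag's ``<`` — inline tags are zero-width so words split by
      e.g. ``<b>`` are not broken apart;
    * leading and trailing whitespace is dropped;
    * character entities are left verbatim so every non-collapsed output
      character equals the raw character it maps to.

    Plain text passes through with an identity-like map; normalization is
    idempotent.
    """
    n = len(raw)
    chars: list[str] = []
    offsets: list[int] = []
    pending: Optional[int] = None  # raw index of the separator run's start
    i = 0
    while i < n:
        c = raw[i]
        if _tag_like(raw, i):
            j, name, closing = _scan_tag(raw, i)
            if not closing and name in _SKIP_CONTENT:
                # drop content up to the matching close tag
                close = raw.lower().find(f"</{name}", j)
                if close < 0:
                    j = n
                else:
                    j2, _, _ = _scan_tag(raw, close)
                    j = j2
            if name in _BLOCK_TAGS and chars and pending is None:
                pending = i
            i = j
            continue
        if c.isspace():
            if chars and pending is None:
                pending = i
            i += 1
            continue
        if pending is not None:
            chars.append(" ")
            offsets.append(pending)
            pending = None
        chars.append(c)
        offsets.append(i)
        i += 1
    return NormalizedText(text="".join(chars), offset_map=tuple(offsets))


# ---------------------------------------------------------------------------
# selector creation and resolution


def make_text_selector(
    norm: NormalizedText,
    start: int,
    end: int,
    context_len: int = DEFAULT_CONTEXT_LEN,
    *,
    uri: Optional[str] = None,
    on_document: Optional[str] = None,
    on_version: Optional[str] = None,
    base_namespace: str = "http://example.org/ao/",
    seed: Optional[int] = None,
) -> TextQuoteSelector:
    """Create a text-quote selector for normalized range [start, end).

    ``prefix``/``postfix`` are up to *context_len* normalized characters on
    either side, truncated at the document edges.
    """
    if not (0 <= start < end <= len(norm.text)):
        raise IndexError(
            f"range [{start}, {end}) out of bounds for text of length {len(norm.text)}"
        )
    return TextQuoteSelector(
        uri=uri or mint_uri(base_namespace, "selector", seed),
        prefix=norm.text[max(0, start - context_len) : start],
        exact=norm.text[start:end],
        postfix=norm.text[end : end + context_len],
        on_document=on_document,
        on_version=on_version,
    )


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (possibly overlapping) occurrence indices of needle."""
    out: list[int] = []
    if not needle:
        return out
    i = haystack.find(needle)
    while i >= 0:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def resolve_text_selector(sel: TextQuoteSelector, norm: NormalizedText) -> ResolutionResult:
    """Locate *sel* in *norm*, full context first, bare exact as fallback."""
    context = sel.prefix + sel.exact + sel.postfix
    spans = [
        (i + len(sel.prefix), i + len(sel.prefix) + len(sel.exact))
        for i in _find_all(norm.text, context)
    ]
    if spans:
        return _result(norm, spans, "full_context")
    spans = [(i, i + len(sel.exact)) for i in _find_all(norm.text, sel.exact)]
    if spans:
        return _result(norm, spans, "exact_only")
    return ResolutionResult(status="orphan", matches=(), tier="none")


def resolve_offset_selector(sel: OffsetRangeSelector, norm: NormalizedText) -> ResolutionResult:
    """Positional resolution: in bounds → unique; out of bounds → orphan."""
    if sel.start < 0 or sel.length < 1 or sel.start + sel.length > len(norm.text):
        return ResolutionResult(status="orphan", matches=(), tier="none")
    span = (sel.start, sel.start + sel.length)
    return _result(norm, [span], "full_context")


def validate_image_box(sel: ImageBoxSelector, width: int, height: int) -> ResolutionResult:
    """Check the box against the image dimensions (pixel content is never
    inspected — a rescaled or cropped image orphans the box)."""
    if width < 1 or height < 1:
        raise ValueError("image dimensions must be positive")
    ok = (
        0 <= sel.x_init < sel.x_end <= width
        and 0 <= sel.y_init < sel.y_end <= height
    )
    if not ok:
        return ResolutionResult(status="orphan", matches=(), tier="none")
    return ResolutionResult(
        status="unique",
        matches=((sel.x_init, sel.y_init, sel.x_end, sel.y_end),),
        tier="full_context",
    )


def reanchor_report(
    annotations: Iterable[Annotation], new_version_raw: str
) -> dict[str, ResolutionResult]:
    """Re-resolve every selector of every annotation against a new document
    state.

    Whole-document targets always resolve unique (the page identity is
    stable).  Stored XPointer expressions are passed through unevaluated
    (``evaluated=False``).  Image-box selectors are out of scope here.
    """
    norm = normalize_document(new_version_raw)
    report: dict[str, ResolutionResult] = {}
    for ann in annotations:
        for target in ann.targets:
            if isinstance(target, DocumentRef):
                report[target.page_uri] = ResolutionResult(
                    status="unique",
                    matches=(((0, len(new_version_raw))),),
                    tier="full_context",
                )
            elif isinstance(target, TextQuoteSelector):
                report[target.uri] = resolve_text_selector(target, norm)
            elif isinstance(target, OffsetRangeSelector):
                report[target.uri] = resolve_offset_selector(target, norm)
            elif isinstance(target, XPointerSelectorRec):
                report[target.uri] = ResolutionResult(
                    status="orphan", matches=(), tier="none", evaluated=False
                )
            else:
                raise ValueError(
                    f"cannot re-anchor selector of type {type(target).__name__}"
                )
    return report
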