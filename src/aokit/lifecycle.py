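"""Curation chains, versioning, supersession and set branching over an
append-only store.

The store is monotonic: no operation removes or overwrites a record.  An
edit produces a *new* record with a fresh IRI, a ``previous_version``
pointer and an incremented version number; replacing an annotation's
content wholesale is *supersession*, which likewise retains the original.
Curation judgments append tokens to a per-annotation chain ordered by
``previous`` pointers (falling back to dates when pointers are missing).
Deleting an item from a set is possible but warned against — rejecting it
through curation preserves more history.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

from .model import (
    Agent,
    Annotation,
    AnnotationSet,
    CurationToken,
    ValidationError,
    Violation,
    mint_uri,
    parse_timestamp,
    validate,
)

__all__ = [
    "Store",
    "CycleError",
    "add_curation",
    "curation_timeline",
    "effective_status",
    "new_annotation_version",
    "supersede",
    "version_set",
    "derive_set",
]

# fields an edit may touch when versioning an annotation
_MUTABLE_FIELDS = frozenset({"body", "topics", "targets", "ann_type", "tagging"})


class CycleError(ValueError):
    """A lineage or curation chain loops back on itself."""


@dataclass
class Store:
    """Append-only, single-writer record store.

    ``reversion_on_curation`` controls whether adding a curation token also
    mints a new annotation version carrying the token as its head (off by
    default: the head is tracked store-side and existing records stay
    untouched, matching the view that a curation judgment is an event
    about a version, not an edit of it).
    """

    base_namespace: str = "http://example.org/ao/"
    reversion_on_curation: bool = False
    annotations: dict[str, Annotation] = field(default_factory=dict)
    sets: dict[str, AnnotationSet] = field(default_factory=dict)
    tokens: dict[str, CurationToken] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    _heads: dict[str, str] = field(default_factory=dict)  # annotation -> head token
    _token_owner: dict[str, str] = field(default_factory=dict)  # token -> annotation
    _seed: Optional[int] = None
    _counter: int = 0

    # -- plumbing ----------------------------------------------------------

    def _mint(self, kind: str) -> str:
        self._counter += 1
        seed = None if self._seed is None else self._seed * 100_000 + self._counter
        return mint_uri(self.base_namespace, kind, seed)

    def _register(self, table: dict, entity) -> None:
        if entity.uri in self.annotations or entity.uri in self.sets or entity.uri in self.tokens:
            raise ValidationError(
                [Violation(entity.uri, "uri", "append-only-store", "URI already recorded")]
            )
        table[entity.uri] = entity

    def add(self, entity: Union[Annotation, AnnotationSet, CurationToken]) -> None:
        """Record a new entity; overwriting an existing URI is refused."""
        violations = validate(entity, self.tokens if isinstance(entity, CurationToken) else None)
        if violations:
            raise ValidationError(violations)
        if isinstance(entity, Annotation):
            self._register(self.annotations, entity)
            if entity.curation_head is not None:
                if entity.curation_head.uri not in self.tokens:
                    self._register(self.tokens, entity.curation_head)
                    self._token_owner[entity.curation_head.uri] = entity.uri
                self._heads[entity.uri] = entity.curation_head.uri
        elif isinstance(entity, AnnotationSet):
            self._register(self.sets, entity)
        elif isinstance(entity, CurationToken):
            self._register(self.tokens, entity)
        else:
            raise TypeError(f"cannot store {type(entity).__name__}")

    def attach_token(
        self, annotation_uri: str, token: CurationToken, set_head: bool = True
    ) -> None:
        """Record an externally built token against an annotation (used when
        importing graphs whose chains may lack ``previous`` pointers)."""
        if annotation_uri not in self.annotations:
            raise KeyError(f"unknown annotation {annotation_uri}")
        if token.uri not in self.tokens:
            self.add(token)
        self._token_owner[token.uri] = annotation_uri
        if set_head:
            self._heads[annotation_uri] = token.uri

    def get(self, uri: str):
        for table in (self.annotations, self.sets, self.tokens):
            if uri in table:
                return table[uri]
        raise KeyError(uri)

    def __len__(self) -> int:
        return len(self.annotations) + len(self.sets) + len(self.tokens)

    def record_uris(self) -> frozenset[str]:
        return frozenset(self.annotations) | frozenset(self.sets) | frozenset(self.tokens)

    def validate_references(self) -> list[str]:
        """Flag dangling lineage/curation references (warnings: imported
        graphs legitimately point outside the store)."""
        known = self.record_uris()
        dangling = []
        for ann in self.annotations.values():
            for attr in ("previous_version", "supersedes"):
                ref = getattr(ann, attr)
                if ref and ref not in known:
                    dangling.append(f"{ann.uri}: {attr} -> {ref} not in store")
        for aset in self.sets.values():
            for attr in ("previous_version", "derived_from"):
                ref = getattr(aset, attr)
                if ref and ref not in known:
                    dangling.append(f"{aset.uri}: {attr} -> {ref} not in store")
        for token in self.tokens.values():
            if token.previous and token.previous not in known:
                dangling.append(f"{token.uri}: previous -> {token.previous} not in store")
        return dangling

    def lineage(self, uri: str) -> list[str]:
        """Walk previous_version pointers, newest first; cycles raise."""
        chain = []
        seen = set()
        current: Optional[str] = uri
        while current is not None:
            if current in seen:
                raise CycleError(f"version lineage of {uri} contains a cycle at {current}")
            seen.add(current)
            chain.append(current)
            record = self.annotations.get(current) or self.sets.get(current)
            current = record.previous_version if record is not None else None
        return chain


# ---------------------------------------------------------------------------
# curation


def add_curation(
    store: Store,
    annotation_uri: str,
    status: str,
    curator: Agent,
    date: str,
) -> CurationToken:
    """Append a curation judgment to an annotation's chain.

    The new token's ``previous`` points at the prior head, if any.  A date
    earlier than the head's is recorded as a store warning but the token is
    still appended (clocks drift; the chain pointer is authoritative).
    """
    if annotation_uri not in store.annotations:
        raise KeyError(f"unknown annotation {annotation_uri}")
    prior = store._heads.get(annotation_uri)
    if prior is not None:
        prior_token = store.tokens[prior]
        t_new, t_old = parse_timestamp(date), parse_timestamp(prior_token.curated_on)
        if t_new is not None and t_old is not None and t_new < t_old:
            store.warnings.append(
                f"curation date {date} on {annotation_uri} precedes head token date "
                f"{prior_token.curated_on}"
            )
    token = CurationToken(
        uri=store._mint("curation"),
        status=status,
        curated_by=curator,
        curated_on=date,
        previous=prior,
    )
    store.add(token)
    store._heads[annotation_uri] = token.uri
    store._token_owner[token.uri] = annotation_uri
    if store.reversion_on_curation:
        old = store.annotations[annotation_uri]
        versioned = replace(
            old,
            uri=store._mint("annotation"),
            curation_head=token,
            previous_version=old.uri,
            version_number=(old.version_number or 1) + 1,
        )
        store._register(store.annotations, versioned)
        store._heads[versioned.uri] = token.uri
    return token


def curation_timeline(store: Store, annotation_uri: str) -> list[CurationToken]:
    """The annotation's curation tokens, oldest first.

    Follows the ``previous`` chain from the head when it is complete;
    otherwise sorts by curation date, breaking ties by URI.  A cyclic chain
    raises :class:`CycleError`.
    """
    token_uris = [
        t for t, owner in store._token_owner.items() if owner == annotation_uri
    ]
    if not token_uris:
        return []
    head = store._heads.get(annotation_uri)
    if head is not None:
        chain = []
        seen = set()
        current: Optional[str] = head
        while current is not None:
            if current in seen:
                raise CycleError(
                    f"curation chain of {annotation_uri} contains a cycle at {current}"
                )
            seen.add(current)
            token = store.tokens.get(current)
            if token is None:
                break  # dangling pointer: fall back to date order
            chain.append(token)
            current = token.previous
        else:
            if len(chain) == len(token_uris):
                return list(reversed(chain))
    tokens = [store.tokens[t] for t in token_uris]
    tokens.sort(key=lambda t: (parse_timestamp(t.curated_on) or t.curated_on, t.uri))
    return tokens


def effective_status(store: Store, annotation_uri: str) -> str:
    """Status of the newest curation token, or "uncurated" when none."""
    timeline = curation_timeline(store, annotation_uri)
    return timeline[-1].status if timeline else "uncurated"


# ---------------------------------------------------------------------------
# versioning


def new_annotation_version(store: Store, annotation_uri: str, edits: dict) -> Annotation:
    """Mint the next version of an annotation with the given edits.

    Only content fields (body, topics, targets, ann_type, tagging) may be
    edited; provenance is immutable.  The old record is untouched; the new
    one points back via ``previous_version`` with an incremented number.
    """
    if annotation_uri not in store.annotations:
        raise KeyError(f"unknown annotation {annotation_uri}")
    bad = set(edits) - _MUTABLE_FIELDS
    if bad:
        raise ValidationError(
            [
                Violation(
                    annotation_uri,
                    f,
                    "immutable-across-versions",
                    "only body/topics/targets/ann_type/tagging may be edited",
                )
                for f in sorted(bad)
            ]
        )
    old = store.annotations[annotation_uri]
    edits = dict(edits)
    if "topics" in edits:
        edits["topics"] = tuple(edits["topics"])
    if "targets" in edits:
        edits["targets"] = tuple(edits["targets"])
    new = replace(
        old,
        uri=store._mint("annotation"),
        previous_version=old.uri,
        version_number=(old.version_number or 1) + 1,
        curation_head=None,
        **edits,
    )
    store.add(new)
    return new


def supersede(store: Store, old_uri: str, new_annotation: Annotation) -> Annotation:
    """Record *new_annotation* as superseding *old_uri*; the superseded
    record stays retrievable."""
    if old_uri not in store.annotations:
        raise KeyError(f"unknown annotation {old_uri}")
    if new_annotation.uri == old_uri:
        raise ValidationError(
            [Violation(old_uri, "uri", "supersession-needs-fresh-uri")]
        )
    successor = replace(new_annotation, supersedes=old_uri)
    store.add(successor)
    return successor


def version_set(
    store: Store,
    set_uri: str,
    add_items: Sequence[str] = (),
    remove_items: Sequence[str] = (),
) -> AnnotationSet:
    """Next version of a set with membership changes.

    Removal only affects the new version (the old one keeps its members)
    and is warned against: rejecting through curation is the monotone
    alternative.  Removing a non-member is an error.
    """
    if set_uri not in store.sets:
        raise KeyError(f"unknown set {set_uri}")
    old = store.sets[set_uri]
    not_members = [r for r in remove_items if r not in old.item_uris]
    if not_members:
        raise ValidationError(
            [
                Violation(set_uri, "item_uris", "remove-requires-membership", r)
                for r in not_members
            ]
        )
    if remove_items:
        store.warnings.append(
            f"items removed from {set_uri}; prefer curation-rejection over removal "
            "to keep the record monotonic"
        )
    items = [u for u in old.item_uris if u not in set(remove_items)]
    items.extend(u for u in add_items if u not in items)
    new = replace(
        old,
        uri=store._mint("set"),
        item_uris=tuple(items),
        previous_version=old.uri,
        version_number=(old.version_number or 1) + 1,
    )
    store.add(new)
    return new


def derive_set(
    store: Store,
    set_uri: str,
    new_owner: Agent,
    created_on: Optional[str] = None,
) -> AnnotationSet:
    """Branch a set: identical membership, new creator, fresh version
    lineage, ``derived_from`` pointing at the source (so attribution of
    each line of work stays correct)."""
    if set_uri not in store.sets:
        raise KeyError(f"unknown set {set_uri}")
    old = store.sets[set_uri]
    branch = AnnotationSet(
        uri=store._mint("set"),
        item_uris=old.item_uris,
        created_by=new_owner,
        created_on=created_on or old.created_on,
        previous_version=None,
        version_number=1,
        derived_from=old.uri,
    )
    store.add(branch)
    return branch
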