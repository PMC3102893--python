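"""Curation chains, versioning, supersession, branching, and store
monotonicity under random operation sequences."""

import random

import pytest

from aokit.lifecycle import (
    CycleError,
    Store,
    add_curation,
    curation_timeline,
    derive_set,
    effective_status,
    new_annotation_version,
    supersede,
    version_set,
)
from aokit.model import (
    Agent,
    AgentKind,
    AnnotationSet,
    AnnotationType,
    CurationToken,
    DocumentRef,
    TermRef,
    Topic,
    ValidationError,
    new_annotation,
)

from conftest import BASE, T0


def _store(seed=1):
    return Store(base_namespace=BASE, _seed=seed)


def _note(store, person, page, body="note", seed=None):
    ann = new_annotation(
        AnnotationType.NOTE, person, T0, [page], body=body,
        base_namespace=BASE, seed=seed,
    )
    store.add(ann)
    return ann


class TestCuration:
    def test_person_accepts_software_annotation(self, person, software, page):
        store = _store()
        ann = _note(store, software, page, seed=1)
        token = add_curation(store, ann.uri, "accepted", person, "2011-05-18T00:00:00+00:00")
        assert token.previous is None
        assert effective_status(store, ann.uri) == "accepted"
        assert len(curation_timeline(store, ann.uri)) == 1

    def test_three_step_review_chain(self, person, software, page):
        store = _store()
        ann = _note(store, software, page, seed=2)
        for day, status in enumerate(["rejected", "discussed", "accepted"]):
            add_curation(store, ann.uri, status, person,
                         f"2011-05-{18 + day:02d}T00:00:00+00:00")
        timeline = curation_timeline(store, ann.uri)
        assert [t.status for t in timeline] == ["rejected", "discussed", "accepted"]
        assert effective_status(store, ann.uri) == "accepted"
        # chain pointers link each token to its predecessor
        assert timeline[1].previous == timeline[0].uri
        assert timeline[2].previous == timeline[1].uri

    def test_out_of_order_date_warns_but_appends(self, person, software, page):
        store = _store()
        ann = _note(store, software, page, seed=3)
        add_curation(store, ann.uri, "rejected", person, "2011-05-20T00:00:00+00:00")
        add_curation(store, ann.uri, "accepted", person, "2011-05-01T00:00:00+00:00")
        assert any("precedes" in w for w in store.warnings)
        assert len(curation_timeline(store, ann.uri)) == 2

    def test_uncurated_annotation(self, person, page):
        store = _store()
        ann = _note(store, person, page, seed=4)
        assert curation_timeline(store, ann.uri) == []
        assert effective_status(store, ann.uri) == "uncurated"

    def test_unknown_annotation_refused(self, person):
        with pytest.raises(KeyError):
            add_curation(_store(), BASE + "nope", "accepted", person, T0)

    def test_date_fallback_when_pointers_absent(self, person, software, page):
        store = _store()
        ann = _note(store, software, page, seed=5)
        dates = ["2011-05-19", "2011-05-17", "2011-05-18"]
        for i, d in enumerate(dates):
            token = CurationToken(
                uri=BASE + f"cur/loose{i}", status=f"step-{d}",
                curated_by=person, curated_on=f"{d}T00:00:00+00:00",
            )
            store.attach_token(ann.uri, token, set_head=False)
        timeline = curation_timeline(store, ann.uri)
        assert [t.curated_on[:10] for t in timeline] == sorted(dates)

    def test_cyclic_chain_detected(self, person, software, page):
        store = _store()
        ann = _note(store, software, page, seed=6)
        a = CurationToken(BASE + "cur/a", "accepted", person, T0, previous=BASE + "cur/b")
        b = CurationToken(BASE + "cur/b", "rejected", person, T0, previous=BASE + "cur/a")
        store.tokens[a.uri] = a  # bypass add() validation to inject the cycle
        store.tokens[b.uri] = b
        store._token_owner[a.uri] = ann.uri
        store._token_owner[b.uri] = ann.uri
        store._heads[ann.uri] = a.uri
        with pytest.raises(CycleError):
            curation_timeline(store, ann.uri)

    def test_random_chains_reconstruct_generation_order(self, person, software, page):
        rng = random.Random(8)
        for trial in range(200):
            store = _store(seed=trial + 10)
            ann = _note(store, software, page, seed=trial)
            statuses = [
                rng.choice(["created", "accepted", "rejected", "discussed"])
                for _ in range(rng.randrange(1, 11))
            ]
            for i, status in enumerate(statuses):
                add_curation(
                    store, ann.uri, status, person,
                    f"2011-{1 + (i // 27):02d}-{1 + i % 27:02d}T00:00:00+00:00",
                )
            got = [t.status for t in curation_timeline(store, ann.uri)]
            assert got == statuses


class TestVersioning:
    def test_first_reversion_gets_number_two(self, person, page):
        store = _store()
        ann = _note(store, person, page, seed=1)
        v2 = new_annotation_version(store, ann.uri, {"body": "edited"})
        assert v2.version_number == 2
        assert v2.previous_version == ann.uri
        assert store.annotations[ann.uri].body == "note"  # old untouched

    def test_five_version_lineage_walk(self, person, page):
        store = _store()
        ann = _note(store, person, page, seed=2)
        current = ann
        for i in range(4):
            current = new_annotation_version(store, current.uri, {"body": f"v{i + 2}"})
        chain = store.lineage(current.uri)
        assert len(chain) == 5
        numbers = [store.annotations[u].version_number or 1 for u in chain]
        assert numbers == [5, 4, 3, 2, 1]

    def test_provenance_edits_refused(self, person, software, page):
        store = _store()
        ann = _note(store, person, page, seed=3)
        with pytest.raises(ValidationError):
            new_annotation_version(store, ann.uri, {"created_by": software})

    def test_supersede_keeps_original(self, person, page):
        store = _store()
        tag_only = new_annotation(
            AnnotationType.QUALIFIER, person, T0, [page], body="BACE1 tag",
            base_namespace=BASE, seed=4,
        )
        store.add(tag_only)
        n_before = len(store)
        upgraded = new_annotation(
            AnnotationType.EXACT_QUALIFIER, person, T0, [page],
            topics=[Topic(TermRef("http://purl.org/obo/owl/PRO#PRO_000004623"), None)],
            base_namespace=BASE, seed=5,
        )
        successor = supersede(store, tag_only.uri, upgraded)
        assert successor.supersedes == tag_only.uri
        assert store.get(tag_only.uri) is tag_only
        assert len(store) == n_before + 1

    def test_self_supersession_refused(self, person, page):
        store = _store()
        ann = _note(store, person, page, seed=6)
        with pytest.raises(ValidationError):
            supersede(store, ann.uri, ann)


class TestSets:
    def _seed_set(self, store, person, items):
        aset = AnnotationSet(
            uri=BASE + "set/base", item_uris=tuple(items),
            created_by=person, created_on=T0, version_number=1,
        )
        store.add(aset)
        return aset

    def test_add_item_versions_the_set(self, person, page):
        store = _store()
        a1 = _note(store, person, page, seed=1)
        a2 = _note(store, person, page, body="other", seed=2)
        aset = self._seed_set(store, person, [a1.uri])
        v2 = version_set(store, aset.uri, add_items=[a2.uri])
        assert v2.version_number == 2 and len(v2.item_uris) == 2
        assert store.sets[aset.uri].item_uris == (a1.uri,)

    def test_removal_warns(self, person, page):
        store = _store()
        a1 = _note(store, person, page, seed=3)
        aset = self._seed_set(store, person, [a1.uri])
        v2 = version_set(store, aset.uri, remove_items=[a1.uri])
        assert a1.uri not in v2.item_uris
        assert any("curation-rejection" in w for w in store.warnings)

    def test_removing_non_member_refused(self, person, page):
        store = _store()
        aset = self._seed_set(store, person, [])
        with pytest.raises(ValidationError):
            version_set(store, aset.uri, remove_items=[BASE + "ghost"])

    def test_twenty_evolutions_number_strictly(self, person, page):
        store = _store()
        current = self._seed_set(store, person, [])
        numbers = [1]
        for i in range(20):
            a = _note(store, person, page, body=f"n{i}", seed=100 + i)
            current = version_set(store, current.uri, add_items=[a.uri])
            numbers.append(current.version_number)
        assert numbers == list(range(1, 22))
        assert store.lineage(current.uri)[-1] == BASE + "set/base"

    def test_branch_has_fresh_lineage(self, person, software, page):
        store = _store()
        a1 = _note(store, person, page, seed=5)
        aset = self._seed_set(store, person, [a1.uri])
        branch = derive_set(store, aset.uri, software)
        assert branch.derived_from == aset.uri
        assert branch.previous_version is None and branch.version_number == 1
        assert branch.item_uris == aset.item_uris
        assert branch.created_by is software
        # evolving the branch leaves the source lineage untouched
        b2 = version_set(store, branch.uri, remove_items=[a1.uri])
        assert store.lineage(b2.uri) == [b2.uri, branch.uri]
        assert store.lineage(aset.uri) == [aset.uri]

    def test_two_branches_share_one_source(self, person, software, page):
        store = _store()
        aset = self._seed_set(store, person, [])
        b1 = derive_set(store, aset.uri, software)
        b2 = derive_set(store, aset.uri, software)
        assert b1.uri != b2.uri
        assert b1.derived_from == b2.derived_from == aset.uri


class TestMonotonicity:
    def test_random_operation_sequences_never_lose_records(self, person, software, page):
        rng = random.Random(99)
        store = _store(seed=777)
        ann = _note(store, software, page, seed=0)
        aset = AnnotationSet(
            uri=BASE + "set/m", item_uris=(ann.uri,), created_by=person,
            created_on=T0, version_number=1,
        )
        store.add(aset)
        for step in range(100):
            seen = store.record_uris()
            count = len(store)
            op = rng.randrange(5)
            if op == 0:
                add_curation(
                    store, rng.choice(list(store.annotations)), "accepted",
                    person, T0,
                )
            elif op == 1:
                new_annotation_version(
                    store, rng.choice(list(store.annotations)),
                    {"body": f"edit {step}"},
                )
            elif op == 2:
                fresh = new_annotation(
                    AnnotationType.NOTE, person, T0, [page], body=f"s{step}",
                    base_namespace=BASE, seed=5000 + step,
                )
                supersede(store, rng.choice(list(store.annotations)), fresh)
            elif op == 3:
                target = rng.choice(list(store.annotations))
                version_set(store, rng.choice(list(store.sets)), add_items=[target])
            else:
                derive_set(store, rng.choice(list(store.sets)), software)
            assert seen <= store.record_uris(), "a record disappeared"
            assert len(store) > count, "store did not grow"
        # every lineage is acyclic with strictly increasing version numbers
        for uri in list(store.annotations) + list(store.sets):
            chain = store.lineage(uri)
            numbers = [
                (store.annotations.get(u) or store.sets.get(u)).version_number or 1
                for u in chain
            ]
            assert numbers == sorted(numbers, reverse=True)
            assert all(a > b for a, b in zip(numbers, numbers[1:])) or len(chain) == 1

    def test_overwriting_a_uri_is_refused(self, person, page):
        store = _store()
        ann = _note(store, person, page, seed=1)
        with pytest.raises(ValidationError):
            store.add(ann)

    def test_dangling_references_are_flagged(self, person, page):
        store = _store()
        ann = new_annotation(
            AnnotationType.NOTE, person, T0, [page], body="x",
            base_namespace=BASE, seed=9,
        )
        from dataclasses import replace

        store.add(replace(ann, previous_version=BASE + "ann/ghost", version_number=2))
        assert any("ghost" in d for d in store.validate_references())
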