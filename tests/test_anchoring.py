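"""Normalization and selector anchoring, checked against brute-force
oracles and hand-computable toys."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from aokit.anchoring import (
    ImageBoxSelector,
    OffsetRangeSelector,
    TextQuoteSelector,
    XPointerSelectorRec,
    make_text_selector,
    normalize_document,
    reanchor_report,
    resolve_offset_selector,
    resolve_text_selector,
    validate_image_box,
)
from aokit.model import AnnotationType, new_annotation
from aokit.synth import generate_document

from conftest import T0


def brute_force_spans(text: str, prefix: str, exact: str, postfix: str):
    """Every exact-span occurrence found by scanning all indices; the
    independent oracle for two-tier resolution."""
    context = prefix + exact + postfix
    full = [
        (i + len(prefix), i + len(prefix) + len(exact))
        for i in range(len(text) - len(context) + 1)
        if text[i : i + len(context)] == context
    ]
    if full:
        return full, "full_context"
    only = [
        (i, i + len(exact))
        for i in range(len(text) - len(exact) + 1)
        if text[i : i + len(exact)] == exact
    ]
    return only, ("exact_only" if only else "none")


class TestNormalize:
    def test_markup_stripped_and_whitespace_collapsed(self):
        n = normalize_document("<b>foo</b>  bar")
        assert n.text == "foo bar"
        # the collapsed space maps to the first raw char of the gap run
        assert n.offset_map == (3, 4, 5, 10, 12, 13, 14)
        raw = "<b>foo</b>  bar"
        assert all(
            raw[n.offset_map[i]] == c or c == " " for i, c in enumerate(n.text)
        )

    def test_plain_text_is_identity(self):
        n = normalize_document("abc")
        assert n.text == "abc" and n.offset_map == (0, 1, 2)

    def test_block_tags_separate_words_inline_tags_do_not(self):
        assert normalize_document("<p>foo</p><p>bar</p>").text == "foo bar"
        assert normalize_document("anti<i>body</i>").text == "antibody"

    def test_script_style_and_comments_dropped(self):
        raw = "<p>a</p><script>var x = 'b';</script><!-- c --><style>p{}</style><p>d</p>"
        assert normalize_document(raw).text == "a d"

    def test_idempotent(self):
        raw = "<p>alpha  beta</p>\n<p>gamma</p>"
        once = normalize_document(raw)
        twice = normalize_document(once.text)
        assert twice.text == once.text
        assert twice.offset_map == tuple(range(len(once.text)))

    @settings(max_examples=150, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_character_walk_oracle_on_random_html(self, seed):
        """Every normalized char equals the raw char it maps to, except
        collapse-point spaces; the map is strictly increasing."""
        doc = generate_document(seed, n_paragraphs=1 + seed % 4)
        raw = doc.raw_html
        n = normalize_document(raw)
        assert len(n.offset_map) == len(n.text)
        assert all(a < b for a, b in zip(n.offset_map, n.offset_map[1:]))
        for i, c in enumerate(n.text):
            assert c == raw[n.offset_map[i]] or c == " "
        assert "  " not in n.text
        assert n.text == n.text.strip()
        assert "<" not in n.text and ">" not in n.text


class TestTextSelector:
    def test_exact_captures_mention(self):
        n = normalize_document("<p>The protein <b>BACE1</b> cleaves APP.</p>")
        i = n.text.find("BACE1")
        sel = make_text_selector(n, i, i + 5, seed=1)
        assert sel.exact == "BACE1"
        assert sel.prefix.endswith("protein ")

    def test_prefix_truncates_at_document_start(self):
        n = normalize_document("alpha beta")
        sel = make_text_selector(n, 0, 5, seed=1)
        assert sel.prefix == "" and sel.exact == "alpha"

    def test_out_of_range_is_refused(self):
        n = normalize_document("short")
        for start, end in [(-1, 2), (2, 2), (0, 99), (4, 2)]:
            with pytest.raises(IndexError):
                make_text_selector(n, start, end)

    def test_resolve_after_create_round_trip(self):
        rng = random.Random(7)
        for trial in range(100):
            doc = generate_document(rng.randrange(10**6), 3)
            n = normalize_document(doc.raw_html)
            start = rng.randrange(len(n.text) - 1)
            end = start + 1 + rng.randrange(min(40, len(n.text) - start - 1) or 1)
            sel = make_text_selector(n, start, end, seed=trial)
            res = resolve_text_selector(sel, n)
            assert res.status == "unique"
            assert res.norm_matches == ((start, end),)
            assert res.tier == "full_context"

    def test_destroyed_anchor_is_orphan(self):
        n = normalize_document("<p>alpha beta gamma</p>")
        i = n.text.find("beta")
        sel = make_text_selector(n, i, i + 4, seed=1)
        changed = normalize_document("<p>alpha delta gamma</p>")
        assert resolve_text_selector(sel, changed).status == "orphan"

    def test_duplicate_mention_disambiguated_by_context(self):
        raw = "<p>first BACE1 here</p><p>second BACE1 there</p>"
        n = normalize_document(raw)
        second = n.text.rfind("BACE1")
        sel = make_text_selector(n, second, second + 5, seed=1)
        res = resolve_text_selector(sel, n)
        brute, tier = brute_force_spans(n.text, sel.prefix, sel.exact, sel.postfix)
        assert res.status == "unique" and res.tier == tier == "full_context"
        assert list(res.norm_matches) == brute == [(second, second + 5)]

    def test_exact_only_fallback_reported(self):
        n = normalize_document("<p>alpha BACE1 omega</p>")
        sel = TextQuoteSelector(
            uri="http://ex.org/s", prefix="NO SUCH CONTEXT ",
            exact="BACE1", postfix=" NOWHERE",
        )
        res = resolve_text_selector(sel, n)
        assert res.status == "unique" and res.tier == "exact_only"

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10**6), st.data())
    def test_resolution_agrees_with_brute_force(self, seed, data):
        doc = generate_document(seed, 2)
        n = normalize_document(doc.raw_html)
        start = data.draw(st.integers(0, len(n.text) - 2))
        end = data.draw(st.integers(start + 1, min(start + 30, len(n.text))))
        ctx = data.draw(st.sampled_from([0, 1, 4, 32]))
        sel = make_text_selector(n, start, end, context_len=ctx, seed=seed)
        res = resolve_text_selector(sel, n)
        brute, tier = brute_force_spans(n.text, sel.prefix, sel.exact, sel.postfix)
        assert sorted(res.norm_matches) == sorted(brute)
        assert res.tier == tier


class TestOffsetSelector:
    def test_simple_range(self):
        n = normalize_document("foo bar")
        res = resolve_offset_selector(
            OffsetRangeSelector(uri="http://ex.org/s", start=0, length=3), n
        )
        assert res.status == "unique"
        assert n.text[res.norm_matches[0][0] : res.norm_matches[0][1]] == "foo"

    def test_out_of_bounds_is_orphan(self):
        n = normalize_document("0123456789")
        res = resolve_offset_selector(
            OffsetRangeSelector(uri="http://ex.org/s", start=100, length=5), n
        )
        assert res.status == "orphan" and res.tier == "none"

    def test_mapped_raw_slice_renormalizes_to_selected_text(self):
        """Oracle: normalizing the raw slice reproduces the normalized
        selection (modulo boundary whitespace)."""
        rng = random.Random(3)
        for _ in range(60):
            doc = generate_document(rng.randrange(10**6), 2)
            n = normalize_document(doc.raw_html)
            start = rng.randrange(len(n.text) - 2)
            length = 1 + rng.randrange(min(25, len(n.text) - start - 1) or 1)
            res = resolve_offset_selector(
                OffsetRangeSelector(uri="http://ex.org/s", start=start, length=length), n
            )
            assert res.status == "unique"
            rs, re_ = res.matches[0]
            renorm = normalize_document(doc.raw_html[rs:re_]).text
            assert renorm == n.text[start : start + length].strip()


class TestImageBox:
    @pytest.mark.parametrize(
        "box,size,status",
        [
            ((0, 0, 10, 10), (100, 100), "unique"),
            ((90, 90, 110, 110), (100, 100), "orphan"),
            ((0, 0, 100, 100), (100, 100), "unique"),
            ((0, 0, 640, 480), (640, 480), "unique"),
        ],
    )
    def test_bounds(self, box, size, status):
        sel = ImageBoxSelector("http://ex.org/s", *box)
        assert validate_image_box(sel, *size).status == status

    def test_non_positive_dimensions_refused(self):
        sel = ImageBoxSelector("http://ex.org/s", 0, 0, 5, 5)
        with pytest.raises(ValueError):
            validate_image_box(sel, 0, 100)


class TestReanchor:
    def _annotated_doc(self, person):
        doc = generate_document(11, 4)
        n = normalize_document(doc.raw_html)
        targets = []
        for i, m in enumerate(doc.mentions[:3]):
            s = n.norm_index(m.raw_start)
            targets.append(
                make_text_selector(n, s, s + (m.raw_end - m.raw_start), seed=i)
            )
        ann = new_annotation(
            AnnotationType.NOTE, person, T0, targets, body="re-anchor me"
        )
        return doc, ann

    def test_identical_version_all_unique(self, person):
        doc, ann = self._annotated_doc(person)
        report = reanchor_report([ann], doc.raw_html)
        assert all(r.status == "unique" for r in report.values())

    def test_inserted_paragraph_keeps_text_anchors(self, person):
        doc, ann = self._annotated_doc(person)
        mutated = "<p>breaking news inserted at the top</p>\n" + doc.raw_html
        report = reanchor_report([ann], mutated)
        assert all(r.status == "unique" for r in report.values())
        # and the recovered text is the original exact string
        for sel in ann.targets:
            rs, re_ = report[sel.uri].matches[0]
            assert normalize_document(mutated[rs:re_]).text == sel.exact

    def test_all_anchors_deleted_all_orphan(self, person):
        doc, ann = self._annotated_doc(person)
        report = reanchor_report([ann], "<p>totally unrelated content</p>")
        assert all(r.status == "orphan" for r in report.values())

    def test_xpointer_passes_through_unevaluated(self, person, page):
        xp = XPointerSelectorRec(
            uri="http://ex.org/s/xp",
            expression="xpointer(string-range(/html/body/p[2],17,8))",
        )
        ann = new_annotation(AnnotationType.NOTE, person, T0, [xp, page], body="x")
        report = reanchor_report([ann], "<p>whatever</p>")
        assert report[xp.uri].evaluated is False
        assert report[xp.uri].tier == "none"
        assert report[page.page_uri].status == "unique"

    def test_edit_disjoint_from_context_window_preserves_exact_text(self, person):
        """An edit that never touches a selector's prefix+exact+postfix
        window cannot change what the selector resolves to."""
        doc, ann = self._annotated_doc(person)
        # edit at the very end, beyond every context window
        mutated = doc.raw_html + "\n<p>appendix paragraph added later</p>"
        before = reanchor_report([ann], doc.raw_html)
        after = reanchor_report([ann], mutated)
        for sel in ann.targets:
            b, a = before[sel.uri], after[sel.uri]
            assert a.status == b.status == "unique"
            rs, re_ = a.matches[0]
            assert normalize_document(mutated[rs:re_]).text == sel.exact
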