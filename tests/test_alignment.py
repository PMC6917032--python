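import re

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgxtext.alignment import align_mentions, build_mention_pattern
from pgxtext.corpus import AnnotationRecord, Document, Passage
from pgxtext.synthetic import GeneratorConfig, generate


def one_passage_doc(text, doc_id="d1"):
    return Document(doc_id=doc_id, passages=[Passage("abstract", text, 0)])


def naive_occurrences(needle, haystack):
    """Independent scanner: exact-substring positions with word boundaries."""
    hits = []
    for i in range(len(haystack) - len(needle) + 1):
        if haystack[i : i + len(needle)] != needle:
            continue
        before_ok = i == 0 or not (haystack[i - 1].isalnum() or haystack[i - 1] == "_")
        j = i + len(needle)
        after_ok = j == len(haystack) or not (haystack[j].isalnum() or haystack[j] == "_")
        if before_ok and after_ok:
            hits.append((i, j))
    return hits


class TestMentionPattern:
    @pytest.mark.parametrize("text,should_match", [
        ("TGF-alpha", True),
        ("TGF-α", True),
        ("TGF-Alpha", True),
        ("TGF-alphafoo", False),
    ])
    def test_greek_equivalence(self, text, should_match):
        pat = build_mention_pattern("TGF-alpha")
        assert bool(pat.search(text)) is should_match

    def test_metacharacters_are_literal(self):
        pat = build_mention_pattern("CYP2D6*2")
        assert pat.search("genotype CYP2D6*2 found")
        assert not pat.search("genotype CYP2D6x2 found")

    @pytest.mark.parametrize("candidate,should_match", [
        ("vitamin K", True),
        ("vitamin\nK", True),
        ("vitamin \t K", True),
        ("vitaminK", False),
        ("vitamin", False),
    ])
    def test_whitespace_runs(self, candidate, should_match):
        pat = build_mention_pattern("vitamin  K")
        assert bool(pat.search(candidate)) is should_match

    def test_word_boundaries_required(self):
        pat = build_mention_pattern("PON1")
        assert pat.search("the PON1 gene")
        assert not pat.search("the XPON1 gene")
        assert not pat.search("the PON12 gene")

    def test_non_word_edges_allowed(self):
        # a mention starting with a metacharacter still matches mid-text
        pat = build_mention_pattern("*2")
        assert pat.search("CYP2D6*2")

    @given(st.text(alphabet="abXY -", min_size=1, max_size=12).filter(str.strip))
    @settings(max_examples=60, derandomize=True)
    def test_pattern_matches_its_own_surface(self, mention):
        pat = build_mention_pattern(mention)
        assert pat.search(f"## {mention} ##") or pat.search(mention)


class TestAlignMentions:
    def test_exact_substrings(self):
        doc = one_passage_doc("PON1 Q192R affects paraoxonase.")
        records = [
            AnnotationRecord("d1", "gene", "PON1", "5444"),
            AnnotationRecord("d1", "variant", "Q192R", None),
        ]
        mentions = align_mentions(doc, records)
        assert [(m.start, m.end) for m in mentions] == [(0, 4), (5, 10)]
        assert [m.entity_class for m in mentions] == ["gene", "variant"]

    def test_abbreviation_not_suppressed_outside_long_span(self):
        text = "epidermal growth factor receptor (EGFR)"
        doc = one_passage_doc(text)
        records = [
            AnnotationRecord("d1", "gene", "epidermal growth factor receptor", "1956"),
            AnnotationRecord("d1", "gene", "EGFR", "1956"),
        ]
        mentions = align_mentions(doc, records)
        spans = [(m.start, m.end) for m in mentions]
        assert (0, 32) in spans and (34, 38) in spans
        # brute-force containment oracle: [34,38) is not inside [0,32)
        assert not (0 <= 34 and 38 <= 32)

    def test_short_mention_inside_longer_is_suppressed(self):
        text = "the irinotecan analog"
        doc = one_passage_doc(text)
        records = [
            AnnotationRecord("d1", "chemical", "irinotecan analog", "MESH:X"),
            AnnotationRecord("d1", "chemical", "irinotecan", "MESH:Y"),
        ]
        mentions = align_mentions(doc, records)
        assert [(m.start, m.end) for m in mentions] == [(4, 21)]

    def test_every_occurrence_annotated(self):
        text = "interferon was given; interferon response followed."
        doc = one_passage_doc(text)
        mentions = align_mentions(
            doc, [AnnotationRecord("d1", "chemical", "interferon", "MESH:Z")]
        )
        assert [(m.start, m.end) for m in mentions] == naive_occurrences("interferon", text)
        assert len(mentions) == 2

    def test_greek_perturbed_surface_recovered(self):
        text = "Response to interferon α was documented."
        doc = one_passage_doc(text)
        (m,) = align_mentions(
            doc, [AnnotationRecord("d1", "chemical", "interferon alpha", "MESH:A")]
        )
        assert doc.text[m.start : m.end] == "interferon α"

    def test_unalignable_record_dropped_not_fatal(self):
        doc = one_passage_doc("nothing relevant here.")
        assert align_mentions(
            doc, [AnnotationRecord("d1", "chemical", "warfarin", "M")]
        ) == []

    def test_idempotent(self):
        doc = one_passage_doc("PON1 Q192R affects warfarin response.")
        records = [
            AnnotationRecord("d1", "gene", "PON1", None),
            AnnotationRecord("d1", "variant", "Q192R", None),
            AnnotationRecord("d1", "chemical", "warfarin", None),
        ]
        assert align_mentions(doc, records) == align_mentions(doc, records)


class TestPlantedRecovery:
    @pytest.mark.parametrize("seed", [1, 11, 23])
    def test_all_planted_spans_recovered_exactly(self, seed):
        corpus = generate(GeneratorConfig(seed=seed, n_documents=20))
        by_doc = {}
        for r in corpus.records:
            by_doc.setdefault(r.doc_id, []).append(r)
        planted = {}
        for pm in corpus.ground_truth.mentions:
            planted.setdefault(pm.doc_id, set()).add(
                (pm.entity_class, pm.start, pm.end)
            )
        for doc in corpus.documents:
            got = {
                (m.entity_class, m.start, m.end)
                for m in align_mentions(doc, by_doc.get(doc.doc_id, []))
            }
            assert got == planted.get(doc.doc_id, set())

    def test_no_accepted_span_strictly_inside_longer_mention(self):
        corpus = generate(GeneratorConfig(seed=4, n_documents=20))
        by_doc = {}
        for r in corpus.records:
            by_doc.setdefault(r.doc_id, []).append(r)
        for doc in corpus.documents:
            mentions = align_mentions(doc, by_doc.get(doc.doc_id, []))
            for a in mentions:
                for b in mentions:
                    inside = (b.start <= a.start and a.end <= b.end
                              and (a.start, a.end) != (b.start, b.end))
                    if inside:
                        assert len(b.mention_text) <= len(a.mention_text), (
                            f"{a.mention_text!r} accepted inside longer "
                            f"{b.mention_text!r} in doc {doc.doc_id}"
                        )
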