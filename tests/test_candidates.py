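import pytest

from pgxtext.candidates import (
    ChemicalFilterConfig,
    attach_mentions,
    filter_chemicals,
    load_chemical_allowlist,
    segment_sentences,
    select_candidates,
    sentence_has_keyword,
)
from pgxtext.corpus import Document, EntityMention, Passage
from pgxtext.variants import classify_mention


def chem(text, mesh, start=0, doc_id="d"):
    return EntityMention(doc_id=doc_id, entity_class="chemical", start=start,
                         end=start + len(text), mention_text=text,
                         normalized_id=mesh)


class TestChemicalFilter:
    CONFIG = ChemicalFilterConfig(allowed_ids={"MESH:A", "MESH:B"})

    def test_short_term_removed(self):
        assert filter_chemicals([chem("ATP", "MESH:A")], self.CONFIG) == []

    def test_allowed_chemical_kept(self):
        m = chem("warfarin", "MESH:A")
        assert filter_chemicals([m], self.CONFIG) == [m]

    def test_disallowed_id_removed(self):
        assert filter_chemicals([chem("heparin", "MESH:Z")], self.CONFIG) == []

    def test_bulk_set_membership(self):
        mentions = [chem(f"chemical{i}", "MESH:A" if i < 160 else "MESH:Z")
                    for i in range(200)]
        assert len(filter_chemicals(mentions, self.CONFIG)) == 160

    def test_allowlist_category_exclusion(self, tmp_path):
        path = tmp_path / "allow.tsv"
        path.write_text(
            "MESH:A\twarfarin\tAnticoagulants\n"
            "MESH:B\tATP\tNucleotides\n"
            "MESH:C\tcisplatin\tAntineoplastic Agents;Platinum Compounds\n"
        )
        config = load_chemical_allowlist(path, {"Nucleotides"})
        assert config.allowed_ids == {"MESH:A", "MESH:C"}


class TestSegmentation:
    def passage_doc(self, text):
        return Document(doc_id="d", passages=[Passage("abstract", text, 0)])

    def test_two_sentences(self):
        sents = segment_sentences(self.passage_doc("A. B."))
        assert [s.text for s in sents] == ["A.", "B."]

    def test_abbreviation_not_split(self):
        sents = segment_sentences(self.passage_doc("Dosing was adjusted, i.e. dose halved."))
        assert len(sents) == 1

    @pytest.mark.parametrize("text,n", [
        ("", 0),
        ("One sentence only.", 1),
        ("First ends here. Second follows!", 2),
        ("Compare Fig. 2 for details.", 1),
        ("The c.521T>C variant was typed. It mattered.", 2),
        ("Results differ (P < 0.05). Conclusions follow.", 2),
    ])
    def test_curated_fixtures(self, text, n):
        assert len(segment_sentences(self.passage_doc(text))) == n

    def test_sentences_stay_within_passage_and_inherit_label(self):
        doc = Document(doc_id="d", passages=[
            Passage("title", "A title.", 0),
            Passage("abstract", "First. Second.", 9),
        ])
        sents = segment_sentences(doc)
        assert [s.section_label for s in sents] == ["title", "abstract", "abstract"]
        for s in sents:
            assert doc.text[s.start:s.end] == s.text

    def test_concatenation_covers_text_up_to_whitespace(self):
        text = "First here.  Second there. Third closes."
        sents = segment_sentences(self.passage_doc(text))
        assert "".join(s.text for s in sents).replace(" ", "") == text.replace(" ", "")


class TestKeywordGate:
    KEYWORDS = {"response", "metaboli*", "dose"}

    @pytest.mark.parametrize("text,hit", [
        ("Variant changed drug response.", True),
        ("It alters metabolism of codeine.", True),
        ("A poor metabolizer phenotype.", True),
        ("The dose was fixed.", True),
        ("Dosenberg et al. report...", False),
        ("Nothing pharmacological here.", False),
    ])
    def test_whole_word_and_stem_matching(self, text, hit):
        assert sentence_has_keyword(text, self.KEYWORDS) is hit


def build_sentence(text, entities):
    """entities: list of (surface, class, normalized_id); first occurrence used."""
    doc = Document(doc_id="d", passages=[Passage("abstract", text, 0)])
    sents = segment_sentences(doc)
    mentions = []
    for surface, cls, norm in entities:
        start = text.index(surface)
        mentions.append(EntityMention(doc_id="d", entity_class=cls, start=start,
                                      end=start + len(surface),
                                      mention_text=surface, normalized_id=norm))
    attach_mentions(sents, mentions)
    variants = [classify_mention(m) for m in mentions
                if m.entity_class in ("variant", "star_allele")]
    return sents, variants


class TestSelectCandidates:
    def test_dbsnp_exempts_keyword_gate(self):
        sents, variants = build_sentence(
            "rs662 modulates clopidogrel response.",
            [("rs662", "variant", None), ("clopidogrel", "chemical", "MESH:C")],
        )
        cands = select_candidates(sents, variants, keywords=set())
        assert len(cands) == 1 and cands[0].group == "group1"

    def test_no_keyword_no_rsid_gives_nothing(self):
        sents, variants = build_sentence(
            "T790M was sequenced in tumors; erlotinib was given later.",
            [("T790M", "variant", None), ("erlotinib", "chemical", "MESH:E")],
        )
        assert select_candidates(sents, variants,
                                 keywords={"response", "metabolism"}) == []

    def test_cross_product_counts(self):
        sents, variants = build_sentence(
            "Both warfarin and simvastatin response varied with rs1 and rs2.",
            [("warfarin", "chemical", "MESH:W"), ("simvastatin", "chemical", "MESH:S"),
             ("rs1", "variant", None), ("rs2", "variant", None)],
        )
        cands = select_candidates(sents, variants, keywords={"response"})
        assert len(cands) == 4
        n_chem = len({c.chemical.normalized_id for c in cands})
        n_var = len({c.variant.rsid for c in cands})
        assert len(cands) == n_chem * n_var

    def test_group_assignment_is_a_partition(self):
        sents, variants = build_sentence(
            "Dose of codeine varied with rs1 and T790M.",
            [("codeine", "chemical", "MESH:C"), ("rs1", "variant", None),
             ("T790M", "variant", None)],
        )
        cands = select_candidates(sents, variants, keywords={"dose"})
        groups = {c.variant.variant_kind: c.group for c in cands}
        assert groups == {"dbsnp": "group1", "protein_sub": "group2"}
        assert all(c.group in ("group1", "group2") for c in cands)

    def test_star_allele_exemption_is_configurable(self):
        sents, variants = build_sentence(
            "Carriers of CYP2D6*2 took codeine.",
            [("*2", "star_allele", "CYP2D6*2"), ("codeine", "chemical", "MESH:C")],
        )
        assert select_candidates(sents, variants, keywords=set()) == []
        widened = select_candidates(sents, variants, keywords=set(),
                                    exempt_star_alleles=True)
        assert len(widened) == 1
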