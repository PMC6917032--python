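"""Seeded synthetic corpora with planted ground truth.

The generator emulates the statistical structure the pipeline assumes:
documents with labeled passages; offset-free annotation records whose
surface forms may disagree with the document text (Greek-letter and
whitespace perturbations, mirroring the ASCII translation done by
upstream taggers); star-allele grammar in all its list forms; decoy
mentions that each filter stage must remove (sub-4-character chemicals,
disallowed chemical categories, cell-line variant look-alikes,
coordinate-free variants); and relation sentences built from lexically
separable positive/negative templates, with negative findings labeled
positive per annotation policy.  Everything is deterministic given the
seed, and every planted span, label and expected filter-survivor count is
recorded by construction — the generator never runs the pipeline.
"""

from __future__ import annotations

import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .candidates import CandidateRelation
from .classifier import LabeledCandidate
from .corpus import (
    AnnotationRecord,
    Document,
    EntityMention,
    Passage,
    Sentence,
    write_annotations,
    write_documents,
)
from .variants import VariantMention

# ---------------------------------------------------------------------------
# Default lexicons


@dataclass(frozen=True)
class ChemicalEntry:
    name: str
    mesh_id: str
    cancer: bool = False
    allowed: bool = True
    categories: tuple[str, ...] = ()


@dataclass(frozen=True)
class GeneEntry:
    name: str
    entrez_id: str


DEFAULT_CHEMICALS: tuple[ChemicalEntry, ...] = (
    ChemicalEntry("warfarin", "MESH:D014859"),
    ChemicalEntry("clopidogrel", "MESH:D000077144"),
    ChemicalEntry("simvastatin", "MESH:D019821"),
    ChemicalEntry("codeine", "MESH:D003061"),
    ChemicalEntry("abacavir", "MESH:D000068598"),
    ChemicalEntry("carbamazepine", "MESH:D002220"),
    ChemicalEntry("telmisartan", "MESH:D000077304"),
    ChemicalEntry("azathioprine", "MESH:D001379"),
    ChemicalEntry("metformin", "MESH:D008687"),
    ChemicalEntry("omeprazole", "MESH:D009853"),
    ChemicalEntry("efavirenz", "MESH:D000068679"),
    ChemicalEntry("interferon alpha", "MESH:D016898"),
    ChemicalEntry("interferon beta", "MESH:D016899"),
    ChemicalEntry("tamoxifen", "MESH:D013629", cancer=True),
    ChemicalEntry("erlotinib", "MESH:D000069347", cancer=True),
    ChemicalEntry("gefitinib", "MESH:D000077156", cancer=True),
    ChemicalEntry("irinotecan", "MESH:D000077146", cancer=True),
    # decoys: too short, or in an excluded category
    ChemicalEntry("ATP", "MESH:D000255", allowed=False,
                  categories=("Nucleotides",)),
    ChemicalEntry("glutathione", "MESH:D005978", allowed=False,
                  categories=("Amino Acids and Peptides",)),
)

DEFAULT_GENES: tuple[GeneEntry, ...] = (
    GeneEntry("CYP2D6", "1565"),
    GeneEntry("CYP2C9", "1559"),
    GeneEntry("CYP2C19", "1557"),
    GeneEntry("CYP3A5", "1577"),
    GeneEntry("CYP2A6", "1548"),
    GeneEntry("VKORC1", "79001"),
    GeneEntry("TPMT", "7172"),
    GeneEntry("SLCO1B1", "10599"),
    GeneEntry("UGT1A1", "54658"),
    GeneEntry("POR", "5447"),
)

DEFAULT_HLA_GENES: tuple[GeneEntry, ...] = (
    GeneEntry("HLA-B", "3106"),
    GeneEntry("HLA-A", "3105"),
)

DEFAULT_RSIDS: tuple[str, ...] = (
    "rs662", "rs12979860", "rs1057868", "rs4244285", "rs1799853",
    "rs3892097", "rs1045642", "rs9923231", "rs4149056", "rs1800462",
)

# (surface, upstream normalized id or None)
DEFAULT_PROTEIN_SUBS: tuple[tuple[str, Optional[str]], ...] = (
    ("Q192R", "p|SUB|Q|192|R;RS#:662"),
    ("T790M", "p|SUB|T|790|M"),
    ("Thr790Met", None),
    ("S768I", None),
    ("R144C", "p|SUB|R|144|C"),
)

DEFAULT_DNA_SUBS: tuple[tuple[str, Optional[str]], ...] = (
    ("c.521T>C", None),
    ("c.93G>A", "c|SUB|G|93|A"),
    ("c.1236C>T", None),
    ("g.1639G>A", None),
    ("681G>A", None),
)

# (text after the gene, allele labels as written, labels after normalization)
# HLA-compatible forms carry the colon-doubled normalization.
STAR_FORMS_SIMPLE: tuple[tuple[str, str, str], ...] = (
    ("*2", "2", "2"),
    ("*4A", "4A", "4A"),
    (" *1", "1", "1"),
    ("*3A", "3A", "3A"),
    ("*28", "28", "28"),
)
STAR_FORMS_HLA: tuple[tuple[str, str, str], ...] = (
    ("*57:01", "57:01", "57:01"),
    ("*05701", "05701", "57:01"),
    ("*3101", "3101", "31:01"),
)
STAR_FORMS_LIST: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("*1/*2", ("1", "2")),
    (" *1, *2 and *4", ("1", "2", "4")),
    ("*2 or *3", ("2", "3")),
    (" *1 *17", ("1", "17")),
)

DEFAULT_EXCLUSION_WORDS: tuple[str, ...] = ("T47D", "HEK293", "MCF7", "A549")
COORDINATE_FREE_DECOYS: tuple[str, ...] = ("c.G>A", "C>T")

DEFAULT_KEYWORDS: tuple[str, ...] = (
    "response", "resistance", "metaboli*", "efficacy", "toxicity",
    "adverse", "dose", "dosing", "dosage", "pharmacogen*", "genotype",
    "allele*", "polymorphism*", "clearance", "concentration",
)

# ---------------------------------------------------------------------------
# Relation templates.  Parts are literal strings or the slot markers "C"
# (chemical) and "V" (variant); has_keyword is known by construction.


@dataclass(frozen=True)
class RelationTemplate:
    parts: tuple[str, ...]
    label: bool
    has_keyword: bool


POSITIVE_TEMPLATES: tuple[RelationTemplate, ...] = (
    RelationTemplate(("The ", "V", " variant influences the response to ", "C", "."), True, True),
    RelationTemplate(("Patients carrying ", "V", " showed reduced ", "C", " metabolism."), True, True),
    RelationTemplate(("The ", "V", " allele is associated with increased ", "C", " toxicity."), True, True),
    # negative finding, still labeled positive per annotation policy
    RelationTemplate(("The ", "V", " variant does not affect the metabolism of ", "C", "."), True, True),
    RelationTemplate(("Dosing of ", "C", " depends on the ", "V", " genotype."), True, True),
)

NEGATIVE_TEMPLATES: tuple[RelationTemplate, ...] = (
    RelationTemplate(("The ", "V", " assay was calibrated with ", "C", " as the reference compound."), False, False),
    RelationTemplate(("Carriers of ", "V", " were recruited after ", "C", " therapy had ended."), False, False),
    RelationTemplate(("The ", "V", " allele frequency and the ", "C", " plasma concentration were reported in unrelated cohorts."), False, True),
    RelationTemplate(("Samples positive for ", "V", " were stored and ", "C", " was catalogued separately."), False, False),
    RelationTemplate(("The ", "V", " genotype records and ", "C", " charts were archived by separate registries."), False, True),
)

FILLER_SENTENCES: tuple[str, ...] = (
    "Further clinical work remains necessary.",
    "Study protocols were approved by the local committee.",
    "Recruitment took place at three academic centres.",
)


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus; defaults define the study conditions."""

    seed: int = 0
    n_documents: int = 50
    full_text_fraction: float = 0.3
    sentences_per_doc: tuple[int, int] = (2, 4)  # relation sentences, inclusive
    positive_fraction: float = 0.5
    greek_rate: float = 0.2
    whitespace_rate: float = 0.2
    exclusion_decoy_rate: float = 0.3
    short_chemical_decoy_rate: float = 0.3
    coordinate_free_decoy_rate: float = 0.3
    star_grammar_rate: float = 0.4
    multi_entity_rate: float = 0.0
    include_confusable_labels: bool = False
    chemicals: tuple[ChemicalEntry, ...] = DEFAULT_CHEMICALS
    genes: tuple[GeneEntry, ...] = DEFAULT_GENES
    hla_genes: tuple[GeneEntry, ...] = DEFAULT_HLA_GENES
    rsids: tuple[str, ...] = DEFAULT_RSIDS

    def __post_init__(self) -> None:
        for name in ("greek_rate", "whitespace_rate", "exclusion_decoy_rate",
                     "short_chemical_decoy_rate", "coordinate_free_decoy_rate",
                     "star_grammar_rate", "multi_entity_rate",
                     "full_text_fraction", "positive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.chemicals or not self.genes or not self.rsids:
            raise ValueError("lexicons must be non-empty")


@dataclass
class PlantedMention:
    doc_id: str
    entity_class: str
    start: int
    end: int
    surface: str        # as it appears in the document
    record_text: str    # as the annotation record reports it (ASCII form)
    normalized_id: Optional[str] = None


@dataclass
class PlantedRelation:
    doc_id: str
    chemical_mesh_id: str
    variant_id: str
    group: str
    label: bool
    confusable: bool = False


@dataclass
class GroundTruth:
    """By-construction record of everything the pipeline should find."""

    mentions: list[PlantedMention] = field(default_factory=list)
    star_alleles: list[tuple[str, str, tuple[int, int]]] = field(default_factory=list)
    relations: list[PlantedRelation] = field(default_factory=list)
    expected: dict[str, int] = field(default_factory=dict)


@dataclass
class SyntheticCorpus:
    documents: list[Document]
    records: list[AnnotationRecord]
    ground_truth: GroundTruth
    labeled_candidates: list[LabeledCandidate]


# ---------------------------------------------------------------------------
# Sentence assembly


class _SentenceDraft:
    """A sentence under construction, tracking entity placements locally."""

    def __init__(self) -> None:
        self.text = ""
        self.chems: list[dict] = []
        self.variants: list[dict] = []
        self.genes: list[dict] = []       # gene placements (records + star triggers)
        self.star_tokens: list[dict] = []
        self.has_keyword = False
        self.label: Optional[bool] = None
        self.pair_labels: list[tuple[int, int, bool]] = []  # (chem idx, var idx, label)
        self.confusable = False

    def add_text(self, s: str) -> None:
        self.text += s

    def add_chemical(self, entry: ChemicalEntry, surface: str) -> int:
        start = len(self.text)
        self.text += surface
        self.chems.append({
            "span": (start, start + len(surface)),
            "entry": entry,
            "surface": surface,
            "record_text": entry.name,
            "surviving": entry.allowed and len(surface) >= 4,
        })
        return len(self.chems) - 1

    def add_gene(self, gene: GeneEntry, surface: Optional[str] = None) -> None:
        surface = surface or gene.name
        start = len(self.text)
        self.text += surface
        self.genes.append({
            "span": (start, start + len(surface)),
            "gene": gene,
            "surface": surface,
        })

    def add_variant_record(self, surface: str, normalized_id: Optional[str],
                           kind: str, variant_id: Optional[str],
                           surviving: bool) -> int:
        start = len(self.text)
        self.text += surface
        self.variants.append({
            "span": (start, start + len(surface)),
            "surface": surface,
            "record_text": surface,
            "normalized_id": normalized_id,
            "kind": kind,
            "variant_id": variant_id,
            "surviving": surviving,
            "is_star": False,
        })
        return len(self.variants) - 1

    def add_star_variant(self, gene: GeneEntry, form: str, labels_written: list[str],
                         labels_normalized: list[str]) -> list[int]:
        """Gene mention followed by star-allele text; returns variant indices."""
        self.add_gene(gene)
        region_start = len(self.text)
        self.text += form
        idxs = []
        token_re = re.compile(r"\*\s*([0-9][0-9A-Za-z:]*)")
        matches = list(token_re.finditer(self.text, region_start))
        assert len(matches) == len(labels_written), (form, labels_written)
        gene_clean = re.sub(r"\s+", "", gene.name)
        for m, norm_label in zip(matches, labels_normalized):
            span = (m.start(), m.end())
            normalized = f"{gene_clean}*{norm_label}"
            self.variants.append({
                "span": span,
                "surface": self.text[span[0]:span[1]],
                "record_text": None,
                "normalized_id": None,
                "kind": "star_allele",
                "variant_id": normalized,
                "surviving": True,
                "is_star": True,
            })
            self.star_tokens.append({"span": span, "normalized": normalized,
                                     "gene": gene})
            idxs.append(len(self.variants) - 1)
        return idxs


def _perturb_chemical(entry: ChemicalEntry, rng: random.Random,
                      cfg: GeneratorConfig) -> str:
    """Document-side surface for a chemical; the record keeps the ASCII form."""
    from .alignment import GREEK_LETTERS

    surface = entry.name
    for name, chars in GREEK_LETTERS.items():
        if name in surface:
            # only the first name present: a failed roll must not fall
            # through to a name nested inside it (eta inside beta)
            if rng.random() < cfg.greek_rate:
                surface = surface.replace(name, chars[0])
            break
    if " " in surface and rng.random() < cfg.whitespace_rate:
        i = surface.index(" ")
        surface = surface[:i] + "  " + surface[i:]
    return surface


def _pick_variant(rng: random.Random, cfg: GeneratorConfig, draft: _SentenceDraft) -> int:
    """Insert a randomly-chosen variant slot; returns its index in draft.variants."""
    roll = rng.random()
    if roll < 0.35:
        rsid = rng.choice(cfg.rsids)
        return draft.add_variant_record(rsid, rsid, "dbsnp", rsid, True)
    if roll < 0.55:
        surface, norm = rng.choice(DEFAULT_PROTEIN_SUBS)
        from .variants import classify_and_parse
        kind, rsid, hgvs = classify_and_parse(surface, norm)
        return draft.add_variant_record(surface, norm, kind, rsid or hgvs, True)
    if roll < 0.7:
        surface, norm = rng.choice(DEFAULT_DNA_SUBS)
        from .variants import classify_and_parse
        kind, rsid, hgvs = classify_and_parse(surface, norm)
        return draft.add_variant_record(surface, norm, kind, rsid or hgvs, True)
    if rng.random() < 0.25:
        gene = rng.choice(cfg.hla_genes)
        form, written, norm = rng.choice(STAR_FORMS_HLA)
        return draft.add_star_variant(gene, form, [written], [norm])[0]
    gene = rng.choice(cfg.genes)
    form, written, norm = rng.choice(STAR_FORMS_SIMPLE)
    return draft.add_star_variant(gene, form, [written], [norm])[0]


def _build_relation_sentence(rng: random.Random, cfg: GeneratorConfig,
                             template: RelationTemplate) -> _SentenceDraft:
    draft = _SentenceDraft()
    draft.label = template.label
    draft.has_keyword = template.has_keyword
    chem_idx = var_idx = None
    for part in template.parts:
        if part == "C":
            entry = rng.choice([c for c in cfg.chemicals if c.allowed])
            chem_idx = draft.add_chemical(entry, _perturb_chemical(entry, rng, cfg))
        elif part == "V":
            var_idx = _pick_variant(rng, cfg, draft)
        else:
            draft.add_text(part)
    draft.pair_labels.append((chem_idx, var_idx, template.label))
    return draft


def _build_multi_entity_sentence(rng: random.Random, cfg: GeneratorConfig) -> _SentenceDraft:
    """Two chemicals and two variants in one sentence; only one pair related."""
    draft = _SentenceDraft()
    draft.confusable = True
    draft.has_keyword = True
    draft.add_text("The ")
    v1 = _pick_variant(rng, cfg, draft)
    draft.add_text(" variant influences the response to ")
    allowed = [c for c in cfg.chemicals if c.allowed]
    e1 = rng.choice(allowed)
    c1 = draft.add_chemical(e1, _perturb_chemical(e1, rng, cfg))
    draft.add_text(", whereas ")
    e2 = rng.choice([c for c in allowed if c.mesh_id != e1.mesh_id])
    c2 = draft.add_chemical(e2, _perturb_chemical(e2, rng, cfg))
    draft.add_text(" pharmacokinetics were unchanged in ")
    v2 = _pick_variant(rng, cfg, draft)
    draft.add_text(" carriers.")
    draft.pair_labels = [(c1, v1, True), (c1, v2, False), (c2, v1, False), (c2, v2, False)]
    return draft


def _build_chem_decoy_sentence(rng: random.Random, cfg: GeneratorConfig) -> _SentenceDraft:
    draft = _SentenceDraft()
    draft.add_text("The ")
    rsid = rng.choice(cfg.rsids)
    draft.add_variant_record(rsid, rsid, "dbsnp", rsid, True)
    draft.add_text(" assay used ")
    decoy = rng.choice([c for c in cfg.chemicals if not c.allowed])
    draft.add_chemical(decoy, decoy.name)
    draft.add_text(" as an internal standard.")
    return draft


def _build_variant_decoy_sentence(rng: random.Random, cfg: GeneratorConfig,
                                  coordinate_free: bool) -> _SentenceDraft:
    draft = _SentenceDraft()
    if coordinate_free:
        decoy = rng.choice(COORDINATE_FREE_DECOYS)
        draft.add_text("Substitutions reported only as ")
        draft.add_variant_record(decoy, None, "other", None, False)
        draft.add_text(" were excluded before ")
    else:
        decoy = rng.choice(DEFAULT_EXCLUSION_WORDS)
        draft.add_text("Cells of line ")
        draft.add_variant_record(decoy, None, "excluded", None, False)
        draft.add_text(" were treated with ")
    entry = rng.choice([c for c in cfg.chemicals if c.allowed])
    draft.add_chemical(entry, _perturb_chemical(entry, rng, cfg))
    if coordinate_free:
        draft.add_text(" exposure analysis.")
    else:
        draft.add_text(" to assess viability.")
    return draft


def _build_star_grammar_sentence(rng: random.Random, cfg: GeneratorConfig) -> _SentenceDraft:
    draft = _SentenceDraft()
    gene = rng.choice(cfg.genes)
    form, labels = rng.choice(STAR_FORMS_LIST)
    draft.add_text("Alleles ")
    draft.add_star_variant(gene, form, list(labels), list(labels))
    draft.add_text(" were typed across the cohort.")
    return draft


# ---------------------------------------------------------------------------
# Corpus generation


def generate(config: GeneratorConfig) -> SyntheticCorpus:
    """Build a deterministic corpus, records, ground truth and labels."""
    rng = random.Random(config.seed)
    documents: list[Document] = []
    all_records: list[AnnotationRecord] = []
    truth = GroundTruth()
    labeled: list[LabeledCandidate] = []
    counts = {
        "planted_mentions": 0,
        "aligned_mentions": 0,
        "chemical_mentions": 0,
        "chemicals_surviving": 0,
        "variant_mentions": 0,
        "variants_after_exclusion": 0,
        "variants_after_coordinate": 0,
        "star_alleles": 0,
        "eligible_sentences": 0,
        "candidates": 0,
        "candidates_group1": 0,
        "candidates_group2": 0,
        "labeled_candidates": 0,
        "labeled_positives": 0,
    }

    for i in range(config.n_documents):
        doc_id = str(30_000_000 + i)
        drafts: list[tuple[str, _SentenceDraft | str]] = []

        n_rel = rng.randint(*config.sentences_per_doc)
        for _ in range(n_rel):
            if rng.random() < config.positive_fraction:
                template = rng.choice(POSITIVE_TEMPLATES)
            else:
                template = rng.choice(NEGATIVE_TEMPLATES)
            drafts.append(("abstract", _build_relation_sentence(rng, config, template)))
        if rng.random() < config.multi_entity_rate:
            drafts.append(("abstract", _build_multi_entity_sentence(rng, config)))
        if rng.random() < config.short_chemical_decoy_rate:
            drafts.append(("abstract", _build_chem_decoy_sentence(rng, config)))
        if rng.random() < config.exclusion_decoy_rate:
            drafts.append(("abstract", _build_variant_decoy_sentence(rng, config, False)))
        if rng.random() < config.coordinate_free_decoy_rate:
            drafts.append(("abstract", _build_variant_decoy_sentence(rng, config, True)))
        if rng.random() < config.star_grammar_rate:
            drafts.append(("abstract", _build_star_grammar_sentence(rng, config)))
        if rng.random() < 0.5:
            drafts.append(("abstract", rng.choice(FILLER_SENTENCES)))

        full_text = rng.random() < config.full_text_fraction
        if full_text:
            # move the tail of the abstract into a results section
            n_move = max(1, len(drafts) // 3)
            moved = [("results", d) for _, d in drafts[-n_move:]]
            drafts = drafts[:-n_move] + moved

        title_text = f"Pharmacogenomic observations in cohort {i}."
        passages: list[Passage] = [Passage("title", title_text, 0)]
        sections: dict[str, list] = {}
        for section, d in drafts:
            sections.setdefault(section, []).append(d)

        offset = len(title_text) + 1
        doc_sentences: list[tuple[_SentenceDraft, int, str]] = []
        for section in ("abstract", "results"):
            if section not in sections:
                continue
            texts = []
            local = 0
            for d in sections[section]:
                text = d if isinstance(d, str) else d.text
                if not isinstance(d, str):
                    doc_sentences.append((d, offset + local, section))
                texts.append(text)
                local += len(text) + 1
            passages.append(Passage(section, " ".join(texts), offset))
            offset += len(" ".join(texts)) + 1

        metadata = {"title": title_text, "journal": "J Synth Pharmacogenomics",
                    "year": 2000 + (i % 20)}
        if full_text:
            metadata["pmcid"] = f"PMC{7_000_000 + i}"
        doc = Document(doc_id=doc_id, passages=passages, metadata=metadata)
        documents.append(doc)

        # records: one per unique (class, record_text, normalized_id) per doc
        record_keys: dict[tuple[str, str, Optional[str]], None] = {}
        planted_here: list[PlantedMention] = []

        for draft, base, section in doc_sentences:
            for chem in draft.chems:
                s, e = chem["span"]
                pm = PlantedMention(doc_id, "chemical", base + s, base + e,
                                    chem["surface"], chem["record_text"],
                                    chem["entry"].mesh_id)
                planted_here.append(pm)
                record_keys.setdefault(("chemical", chem["record_text"],
                                        chem["entry"].mesh_id))
                counts["chemical_mentions"] += 1
                if chem["surviving"]:
                    counts["chemicals_surviving"] += 1
            for gene in draft.genes:
                s, e = gene["span"]
                pm = PlantedMention(doc_id, "gene", base + s, base + e,
                                    gene["surface"], gene["gene"].name,
                                    gene["gene"].entrez_id)
                planted_here.append(pm)
                record_keys.setdefault(("gene", gene["gene"].name,
                                        gene["gene"].entrez_id))
            for var in draft.variants:
                if var["is_star"]:
                    s, e = var["span"]
                    truth.star_alleles.append(
                        (doc_id, var["variant_id"], (base + s, base + e)))
                    counts["star_alleles"] += 1
                    counts["variants_after_exclusion"] += 1
                    counts["variants_after_coordinate"] += 1
                    continue
                s, e = var["span"]
                pm = PlantedMention(doc_id, "variant", base + s, base + e,
                                    var["surface"], var["record_text"],
                                    var["normalized_id"])
                planted_here.append(pm)
                record_keys.setdefault(("variant", var["record_text"],
                                        var["normalized_id"]))
                counts["variant_mentions"] += 1
                if var["kind"] != "excluded":
                    counts["variants_after_exclusion"] += 1
                    if var["surviving"]:
                        counts["variants_after_coordinate"] += 1

            surviving_chems = [c for c in draft.chems if c["surviving"]]
            surviving_vars = [v for v in draft.variants if v["surviving"]]
            eligible = bool(surviving_chems) and bool(surviving_vars) and (
                draft.has_keyword
                or any(v["kind"] == "dbsnp" for v in surviving_vars)
            )
            if eligible:
                counts["eligible_sentences"] += 1
                n_pairs = len(surviving_chems) * len(surviving_vars)
                counts["candidates"] += n_pairs
                for v in surviving_vars:
                    n_chem = len(surviving_chems)
                    if v["kind"] in ("dbsnp", "star_allele"):
                        counts["candidates_group1"] += n_chem
                    else:
                        counts["candidates_group2"] += n_chem
                if draft.pair_labels and (not draft.confusable
                                          or config.include_confusable_labels):
                    sentence = Sentence(
                        doc_id=doc_id, start=base, end=base + len(draft.text),
                        text=draft.text, section_label=section,
                    )
                    for ci, vi, lab in draft.pair_labels:
                        cand = _make_candidate(sentence, doc_id, base,
                                               draft.chems[ci], draft.variants[vi])
                        truth.relations.append(PlantedRelation(
                            doc_id=doc_id,
                            chemical_mesh_id=draft.chems[ci]["entry"].mesh_id,
                            variant_id=draft.variants[vi]["variant_id"],
                            group=cand.group, label=lab,
                            confusable=draft.confusable,
                        ))
                        labeled.append(LabeledCandidate(candidate=cand, label=lab))
                        counts["labeled_candidates"] += 1
                        if lab:
                            counts["labeled_positives"] += 1

        truth.mentions.extend(planted_here)
        counts["planted_mentions"] += len(planted_here)
        for cls, text, norm in record_keys:
            all_records.append(AnnotationRecord(
                doc_id=doc_id, entity_class=cls, mention_text=text,
                normalized_id=norm,
            ))

    counts["aligned_mentions"] = counts["planted_mentions"]
    truth.expected = counts
    return SyntheticCorpus(
        documents=documents, records=all_records, ground_truth=truth,
        labeled_candidates=labeled,
    )


def _make_candidate(sentence: Sentence, doc_id: str, base: int,
                    chem: dict, var: dict) -> CandidateRelation:
    chem_mention = EntityMention(
        doc_id=doc_id, entity_class="chemical",
        start=base + chem["span"][0], end=base + chem["span"][1],
        mention_text=chem["surface"], normalized_id=chem["entry"].mesh_id,
    )
    var_class = "star_allele" if var["is_star"] else "variant"
    var_mention = EntityMention(
        doc_id=doc_id, entity_class=var_class,
        start=base + var["span"][0], end=base + var["span"][1],
        mention_text=var["surface"],
        normalized_id=var["variant_id"] if var["is_star"] else var["normalized_id"],
    )
    if var["is_star"]:
        vm = VariantMention(base=var_mention, variant_kind="star_allele")
    else:
        rsid = var["variant_id"] if var["kind"] == "dbsnp" else (
            var["variant_id"] if (var["variant_id"] or "").startswith("rs") else None)
        hgvs = None
        if var["kind"] in ("protein_sub", "dna_sub"):
            from .variants import classify_and_parse
            _, rsid2, hgvs = classify_and_parse(var["surface"], var["normalized_id"])
            rsid = rsid2
        vm = VariantMention(base=var_mention, variant_kind=var["kind"],
                            rsid=rsid, hgvs=hgvs)
    existing = {(m.entity_class, m.start, m.end) for m in sentence.mentions}
    for m in (chem_mention, var_mention):
        if (m.entity_class, m.start, m.end) not in existing:
            sentence.mentions.append(m)
    sentence.mentions.sort(key=lambda m: (m.start, m.end))
    return CandidateRelation(sentence=sentence, chemical=chem_mention, variant=vm)


# ---------------------------------------------------------------------------
# Stand-alone labeled-candidate generation for classifier experiments


def generate_labeled_candidates(
    n: int, group: str, seed: int, positive_fraction: float = 0.5
) -> list[LabeledCandidate]:
    """``n`` single-sentence labeled candidates of one group.

    Group 1 draws rs-id and star-allele variants; group 2 draws DNA and
    protein substitutions.  Positive and negative sentences come from the
    same lexically separable template families as the corpus generator.
    """
    cfg = GeneratorConfig(seed=seed)
    rng = random.Random(seed)
    out: list[LabeledCandidate] = []
    doc_counter = 0
    while len(out) < n:
        want_positive = rng.random() < positive_fraction
        template = rng.choice(POSITIVE_TEMPLATES if want_positive else NEGATIVE_TEMPLATES)
        draft = _build_relation_sentence(rng, cfg, template)
        ci, vi, lab = draft.pair_labels[0]
        if draft.variants[vi]["kind"] in ("dbsnp", "star_allele"):
            actual_group = "group1"
        else:
            actual_group = "group2"
        if actual_group != group:
            continue
        doc_id = f"synthetic-{seed}-{doc_counter}"
        doc_counter += 1
        sentence = Sentence(doc_id=doc_id, start=0, end=len(draft.text),
                            text=draft.text, section_label="abstract")
        cand = _make_candidate(sentence, doc_id, 0, draft.chems[ci], draft.variants[vi])
        out.append(LabeledCandidate(candidate=cand, label=lab))
    return out


# ---------------------------------------------------------------------------
# Serialization


def write_corpus(corpus: SyntheticCorpus, out_dir: str | Path) -> None:
    """Emit the BioC documents, annotation TSV and ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_documents(corpus.documents, out / "documents.bioc.xml", format="bioc")
    write_annotations(corpus.records, out / "annotations.tsv")
    gt = {
        "expected": corpus.ground_truth.expected,
        "mentions": [
            {"doc_id": m.doc_id, "entity_class": m.entity_class,
             "start": m.start, "end": m.end, "surface": m.surface,
             "record_text": m.record_text, "normalized_id": m.normalized_id}
            for m in corpus.ground_truth.mentions
        ],
        "star_alleles": [
            {"doc_id": d, "normalized": n, "span": list(s)}
            for d, n, s in corpus.ground_truth.star_alleles
        ],
        "relations": [
            {"doc_id": r.doc_id, "chemical_mesh_id": r.chemical_mesh_id,
             "variant_id": r.variant_id, "group": r.group, "label": r.label,
             "confusable": r.confusable}
            for r in corpus.ground_truth.relations
        ],
    }
    (out / "ground_truth.json").write_text(
        json.dumps(gt, indent=1, sort_keys=True), encoding="utf-8"
    )


def default_chemical_filter_config():
    """Allow-list built from the default lexicon (decoys excluded)."""
    from .candidates import ChemicalFilterConfig

    return ChemicalFilterConfig(
        allowed_ids={c.mesh_id for c in DEFAULT_CHEMICALS if c.allowed},
        excluded_categories={"Nucleotides", "Amino Acids and Peptides", "Metals"},
    )


def cancer_chemical_ids() -> set[str]:
    return {c.mesh_id for c in DEFAULT_CHEMICALS if c.cancer}


def default_keywords() -> set[str]:
    return set(DEFAULT_KEYWORDS)


def default_exclusion_words() -> set[str]:
    return set(DEFAULT_EXCLUSION_WORDS)
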