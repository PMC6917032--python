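"""End-to-end orchestration: align -> star alleles -> normalize ->
candidates -> score -> threshold -> cancer filter -> collate -> KB flags.

The pipeline is a pure function of (inputs, configuration, seeds): a rerun
on identical inputs produces byte-identical outputs.  A run manifest
records the configuration hash and stage-wise record counts so every
dropped record is auditable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import collate as collate_mod
from .alignment import align_mentions
from .candidates import (
    ChemicalFilterConfig,
    attach_mentions,
    filter_chemicals,
    load_chemical_allowlist,
    load_keywords,
    segment_sentences,
    select_candidates,
)
from .classifier import (
    DEFAULT_THRESHOLD,
    TrainedModel,
    apply_threshold,
    filter_cancer_chemicals,
    score_candidates,
)
from .collate import (
    COLLATED_FILENAME,
    FILTERED_FILENAME,
    UNFILTERED_FILENAME,
    ExtractedRelationRow,
    PharmGKBTable,
    annotate_pharmgkb,
    collate,
    load_pharmgkb_table,
    render_sentence_html,
    write_collated,
    write_relation_rows,
)
from .corpus import Document, EntityMention, read_annotations, read_documents
from .star_alleles import find_star_alleles, star_alleles_to_mentions
from .variants import (
    VariantMention,
    apply_exclusion_words,
    classify_mention,
    has_specific_coordinate,
    load_exclusion_words,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File-level configuration of one run."""

    documents: str
    annotations: str
    out_dir: str
    model_group1: str
    model_group2: str
    chemical_allowlist: Optional[str] = None
    excluded_categories: list[str] = field(default_factory=list)
    keywords: Optional[str] = None
    exclusion_words: Optional[str] = None
    pharmgkb: Optional[str] = None
    cancer_chemicals: list[str] = field(default_factory=list)
    threshold: float = DEFAULT_THRESHOLD
    exempt_star_alleles: bool = False
    document_format: str = "bioc"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class PipelineResult:
    unfiltered: list[ExtractedRelationRow]
    filtered: list[ExtractedRelationRow]
    collated: list
    stage_counts: dict[str, int]


def candidate_to_row(cand) -> ExtractedRelationRow:
    """Render one scored candidate into a curator-facing output row."""
    sent = cand.sentence
    meta = getattr(cand, "_doc_meta", {})
    chem_rel = sent.relative_span(cand.chemical)
    var_rel = sent.relative_span(cand.variant.base)
    gene_id = cand.variant.base.gene_id
    return ExtractedRelationRow(
        doc_id=sent.doc_id,
        pmid=sent.doc_id,
        title=str(meta.get("title", "")),
        journal=str(meta.get("journal", "")),
        year=int(meta.get("year", 0)),
        section_label=sent.section_label,
        chemical_mesh_id=cand.chemical.normalized_id or "",
        chemical_name=cand.chemical.mention_text,
        variant_id=cand.variant.variant_id,
        variant_kind=cand.variant.variant_kind,
        gene_id=gene_id,
        score=cand.score if cand.score is not None else 0.0,
        sentence_html=render_sentence_html(sent.text, chem_rel, var_rel),
    )


def process_corpus(
    documents: list[Document],
    records,
    *,
    chem_config: ChemicalFilterConfig,
    keywords: set[str],
    exclusion_words: set[str],
    models: dict[str, TrainedModel],
    threshold: float = DEFAULT_THRESHOLD,
    cancer_chemical_ids: set[str] = frozenset(),
    pharmgkb: Optional[PharmGKBTable] = None,
    exempt_star_alleles: bool = False,
) -> PipelineResult:
    """Run every stage over in-memory documents and annotation records."""
    by_doc: dict[str, list] = {}
    for rec in records:
        by_doc.setdefault(rec.doc_id, []).append(rec)

    counts = {
        "documents": len(documents),
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
        "accepted": 0,
        "after_cancer_filter": 0,
        "collated_associations": 0,
    }

    all_candidates = []
    for doc in documents:
        mentions = align_mentions(doc, by_doc.get(doc.doc_id, []))
        counts["aligned_mentions"] += len(mentions)

        gene_mentions = [m for m in mentions if m.entity_class == "gene"]
        star = find_star_alleles(doc, gene_mentions)
        star_mentions = star_alleles_to_mentions(doc, star)
        counts["star_alleles"] += len(star_mentions)

        chem_all = [m for m in mentions if m.entity_class == "chemical"]
        counts["chemical_mentions"] += len(chem_all)
        chems = filter_chemicals(chem_all, chem_config)
        counts["chemicals_surviving"] += len(chems)

        variant_mentions = [m for m in mentions if m.entity_class == "variant"]
        counts["variant_mentions"] += len(variant_mentions)
        classified = [classify_mention(m) for m in variant_mentions]
        classified += [classify_mention(m) for m in star_mentions]
        after_excl = apply_exclusion_words(classified, exclusion_words)
        counts["variants_after_exclusion"] += len(after_excl)
        variants = [v for v in after_excl if has_specific_coordinate(v)]
        counts["variants_after_coordinate"] += len(variants)

        sentences = segment_sentences(doc)
        attach_mentions(sentences, chems + [v.base for v in variants])
        cands = select_candidates(
            sentences, variants, keywords, exempt_star_alleles=exempt_star_alleles
        )
        counts["eligible_sentences"] += len(
            {(c.sentence.doc_id, c.sentence.start, c.sentence.end) for c in cands}
        )
        for c in cands:
            c._doc_meta = doc.metadata  # carried for output rows
        all_candidates.extend(cands)

    counts["candidates"] = len(all_candidates)
    counts["candidates_group1"] = sum(1 for c in all_candidates if c.group == "group1")
    counts["candidates_group2"] = sum(1 for c in all_candidates if c.group == "group2")

    scored = score_candidates(models, all_candidates)
    unfiltered_rows = [candidate_to_row(c) for c in scored]

    accepted = apply_threshold(scored, threshold)
    counts["accepted"] = len(accepted)
    accepted = filter_cancer_chemicals(accepted, set(cancer_chemical_ids))
    counts["after_cancer_filter"] = len(accepted)
    filtered_rows = [candidate_to_row(c) for c in accepted]

    collated = collate(filtered_rows)
    if pharmgkb is not None:
        collated = annotate_pharmgkb(collated, pharmgkb)
    counts["collated_associations"] = len(collated)

    return PipelineResult(
        unfiltered=unfiltered_rows,
        filtered=filtered_rows,
        collated=collated,
        stage_counts=counts,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute a configured run; returns the manifest (also written to disk).

    All inputs are checked before any stage executes; on a stage failure
    the partial outputs are removed and the manifest records the failure
    point.
    """
    from .synthetic import (
        default_chemical_filter_config,
        default_exclusion_words,
        default_keywords,
    )

    required = [config.documents, config.annotations,
                config.model_group1, config.model_group2]
    for p in [*required, config.chemical_allowlist, config.keywords,
              config.exclusion_words, config.pharmgkb]:
        if p is not None and not Path(p).exists():
            raise FileNotFoundError(f"pipeline input not found: {p}")

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = {
        "unfiltered": out_dir / UNFILTERED_FILENAME,
        "filtered": out_dir / FILTERED_FILENAME,
        "collated": out_dir / COLLATED_FILENAME,
    }
    manifest_path = out_dir / "manifest.json"
    manifest = {"config_hash": _config_hash(config), "status": "running"}

    try:
        documents = read_documents(config.documents, format=config.document_format)
        records = read_annotations(config.annotations)
        if config.chemical_allowlist:
            chem_config = load_chemical_allowlist(
                config.chemical_allowlist, set(config.excluded_categories)
            )
        else:
            chem_config = default_chemical_filter_config()
        keywords = (load_keywords(config.keywords)
                    if config.keywords else default_keywords())
        exclusion = (load_exclusion_words(config.exclusion_words)
                     if config.exclusion_words else default_exclusion_words())
        models = {
            "group1": TrainedModel.from_json(config.model_group1),
            "group2": TrainedModel.from_json(config.model_group2),
        }
        pharmgkb = load_pharmgkb_table(config.pharmgkb) if config.pharmgkb else None

        result = process_corpus(
            documents,
            records,
            chem_config=chem_config,
            keywords=keywords,
            exclusion_words=exclusion,
            models=models,
            threshold=config.threshold,
            cancer_chemical_ids=set(config.cancer_chemicals),
            pharmgkb=pharmgkb,
            exempt_star_alleles=config.exempt_star_alleles,
        )
        write_relation_rows(result.unfiltered, outputs["unfiltered"])
        write_relation_rows(result.filtered, outputs["filtered"])
        write_collated(result.collated, outputs["collated"])
    except Exception as exc:
        for path in outputs.values():
            path.unlink(missing_ok=True)
        manifest.update(status="failed", error=str(exc))
        manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
        raise

    manifest.update(
        status="ok",
        stage_counts=result.stage_counts,
        model_seeds={
            g: models[g].metadata.get("seed") for g in ("group1", "group2")
        },
        threshold=config.threshold,
        outputs={name: _sha256(path) for name, path in outputs.items()},
    )
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Mention TSV used by the step-wise CLI

MENTION_COLUMNS = ["doc_id", "entity_class", "start", "end",
                   "mention_text", "normalized_id", "gene_id"]


def write_mentions_tsv(mentions: list[EntityMention], path: str | Path) -> None:
    lines = ["\t".join(MENTION_COLUMNS)]
    for m in mentions:
        lines.append("\t".join([
            m.doc_id, m.entity_class, str(m.start), str(m.end),
            m.mention_text.replace("\t", " ").replace("\n", " "),
            m.normalized_id or "", m.gene_id or "",
        ]))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_mentions_tsv(path: str | Path) -> list[EntityMention]:
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    mentions = []
    for line in lines[1:]:
        doc_id, cls, start, end, text, norm, gene = line.split("\t")
        mentions.append(EntityMention(
            doc_id=doc_id, entity_class=cls, start=int(start), end=int(end),
            mention_text=text, normalized_id=norm or None, gene_id=gene or None,
        ))
    return mentions
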