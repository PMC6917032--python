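"""Chemical filtering, sentence segmentation and candidate selection.

A candidate relation is a (chemical mention, variant mention) pair inside
one sentence.  Sentences are eligible when they carry at least one
surviving chemical and one surviving variant, and either contain a
pharmacogenomics keyword or mention a specific dbSNP id — the latter being
a strong enough signal on its own.  Candidates split into two groups by
variant kind: group 1 for rs ids and star alleles (empirically enriched
for pharmacogenomic statements), group 2 for DNA/protein changes.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .corpus import Document, EntityMention, Sentence
from .variants import VariantMention

logger = logging.getLogger(__name__)

GROUP1_KINDS = frozenset({"dbsnp", "star_allele"})


@dataclass
class ChemicalFilterConfig:
    """Allow-list driven chemical filter.

    ``allowed_ids`` holds the normalized (MeSH) ids of drug-like chemicals,
    built from a curated table with category exclusions already applied;
    ``min_length`` drops very short surface strings (abbreviation noise
    such as "ATP").
    """

    allowed_ids: set[str] = field(default_factory=set)
    excluded_categories: set[str] = field(default_factory=set)
    min_length: int = 4

    def __post_init__(self) -> None:
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")


@dataclass
class CandidateRelation:
    """One chemical/variant pair in one sentence, prior to classification."""

    sentence: Sentence
    chemical: EntityMention
    variant: VariantMention
    group: str = field(init=False)
    score: Optional[float] = None

    def __post_init__(self) -> None:
        self.group = "group1" if self.variant.variant_kind in GROUP1_KINDS else "group2"


def load_chemical_allowlist(
    path: str | Path, excluded_categories: set[str] | None = None
) -> ChemicalFilterConfig:
    """Read a chemical allow-list TSV (id, preferred name, categories).

    Categories are ';'-separated in the third column; a row with any
    excluded category is left out of ``allowed_ids``.
    """
    excluded = set(excluded_categories or ())
    allowed: set[str] = set()
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), 1
    ):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        mesh_id, _name, categories = fields[0], fields[1], fields[2]
        cats = {c.strip() for c in categories.split(";") if c.strip()}
        if not cats & excluded:
            allowed.add(mesh_id)
    return ChemicalFilterConfig(allowed_ids=allowed, excluded_categories=excluded)


def filter_chemicals(
    mentions: Iterable[EntityMention], config: ChemicalFilterConfig
) -> list[EntityMention]:
    """Keep chemical mentions on the allow-list and at least min_length long."""
    kept = []
    for m in mentions:
        if m.entity_class != "chemical":
            continue
        if m.normalized_id in config.allowed_ids and len(m.mention_text) >= config.min_length:
            kept.append(m)
    return kept


# ---------------------------------------------------------------------------
# Sentence segmentation

_ABBREVIATIONS = {
    "i.e", "e.g", "etc", "vs", "cf", "ca", "al", "fig", "figs", "dr",
    "no", "approx", "resp", "ref", "refs", "inc", "st",
}
_BOUNDARY = re.compile(r"[.!?]+(?=\s)")


def _is_abbreviation(text: str, end: int) -> bool:
    """Does the token ending at ``end`` (exclusive of '.') look like an abbreviation?"""
    m = re.search(r"(\w[\w.]*)$", text[:end])
    if not m:
        return False
    token = m.group(1).rstrip(".").lower()
    return token in _ABBREVIATIONS


def segment_sentences(document: Document) -> list[Sentence]:
    """Split each passage into sentences; abbreviation-aware, punctuation kept.

    A boundary is sentence-final punctuation followed by whitespace and an
    upper-case letter, digit or quote, unless the preceding token is a known
    abbreviation.  Sentences inherit the passage's section label; spans are
    in document coordinates.
    """
    sentences: list[Sentence] = []
    for passage in document.passages:
        text = passage.text
        cut_points = [0]
        for m in _BOUNDARY.finditer(text):
            after = text[m.end() :].lstrip()
            if not after:
                continue
            if not (after[0].isupper() or after[0].isdigit() or after[0] in "\"'("):
                continue
            if _is_abbreviation(text, m.start()):
                continue
            cut_points.append(m.end())
        cut_points.append(len(text))
        for a, b in zip(cut_points, cut_points[1:]):
            raw = text[a:b]
            lead = len(raw) - len(raw.lstrip())
            trail = len(raw) - len(raw.rstrip())
            if not raw.strip():
                continue
            start = passage.offset + a + lead
            end = passage.offset + b - trail
            sentences.append(
                Sentence(
                    doc_id=document.doc_id,
                    start=start,
                    end=end,
                    text=document.text[start:end],
                    section_label=passage.section_label,
                )
            )
    return sentences


def attach_mentions(
    sentences: list[Sentence], mentions: Iterable[EntityMention]
) -> list[Sentence]:
    """Assign each mention to the sentence containing its span.

    Mentions straddling a sentence boundary are dropped with a log entry.
    Returns the same sentence objects with ``mentions`` populated in span order.
    """
    for s in sentences:
        s.mentions = []
    for m in mentions:
        hit = None
        for s in sentences:
            if s.doc_id == m.doc_id and s.start <= m.start and m.end <= s.end:
                hit = s
                break
        if hit is None:
            logger.info("mention %r at [%d,%d) crosses sentence bounds; dropped",
                        m.mention_text, m.start, m.end)
            continue
        hit.mentions.append(m)
    for s in sentences:
        s.mentions.sort(key=lambda m: (m.start, m.end))
    return sentences


# ---------------------------------------------------------------------------
# Keyword gate and candidate selection

_WORD = re.compile(r"\w+")


def load_keywords(path: str | Path) -> set[str]:
    """One keyword per line; '#' comments; a trailing '*' marks a prefix stem."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        term = line.split("#", 1)[0].strip()
        if term:
            words.add(term.lower())
    return words


def sentence_has_keyword(text: str, keywords: set[str]) -> bool:
    """Whole-word, case-insensitive match; keywords ending in '*' match any
    word with that prefix (so 'metaboli*' covers metabolism/metabolizer)."""
    exact = {k for k in keywords if not k.endswith("*")}
    stems = tuple(k[:-1] for k in keywords if k.endswith("*"))
    for tok in _WORD.findall(text.lower()):
        if tok in exact or (stems and tok.startswith(stems)):
            return True
    return False


def select_candidates(
    sentences: Iterable[Sentence],
    variants: Iterable[VariantMention],
    keywords: set[str],
    exempt_star_alleles: bool = False,
) -> list[CandidateRelation]:
    """Build every chemical x variant pair from each eligible sentence.

    ``variants`` are the surviving classified variant mentions; chemicals
    are the surviving chemical-class mentions attached to the sentences.
    Eligibility requires a keyword hit or a dbSNP-kind variant (optionally
    also a star allele when ``exempt_star_alleles``).
    """
    index = {
        (v.base.doc_id, v.base.start, v.base.end): v for v in variants
    }
    exempt_kinds = {"dbsnp"} | ({"star_allele"} if exempt_star_alleles else set())
    candidates: list[CandidateRelation] = []
    for s in sentences:
        chems = [m for m in s.mentions if m.entity_class == "chemical"]
        variants_here = [
            index[(m.doc_id, m.start, m.end)]
            for m in s.mentions
            if m.entity_class in ("variant", "star_allele")
            and (m.doc_id, m.start, m.end) in index
        ]
        if not chems or not variants_here:
            continue
        if not (
            sentence_has_keyword(s.text, keywords)
            or any(v.variant_kind in exempt_kinds for v in variants_here)
        ):
            continue
        for chem in chems:
            for var in variants_here:
                candidates.append(CandidateRelation(sentence=s, chemical=chem, variant=var))
    return candidates
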