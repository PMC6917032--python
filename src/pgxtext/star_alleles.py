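"""Star-allele detection and normalization.

Star alleles name haplotypes of pharmacogenes (CYP2D6*2, CYP2A6*4A) and,
for the HLA family, use colon-separated numeric fields (HLA-B*57:01).
They are found by scanning the text immediately after an aligned gene
mention for an asterisk followed by a token beginning with a digit, with
continuation lists ("*1/*2", "*1, *2 and *4") yielding one allele each.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .corpus import Document, EntityMention

logger = logging.getLogger(__name__)

# Allele token: starts with a digit; digits, letters and colons follow.
_ALLELE_TOKEN = re.compile(r"\*\s*([0-9][0-9A-Za-z:]*)")
# Separators between list items: whitespace, "/", ",", "and", "or".
_SEPARATOR = re.compile(r"(?:\s|/|,|\band\b|\bor\b)+")


@dataclass
class StarAllele:
    """One detected star allele, tied to the gene mention that triggered it."""

    gene_name: str
    allele_label: str
    span: tuple[int, int]  # document interval covering "*" + allele token
    gene_id: Optional[str] = None
    normalized: str = field(init=False)

    def __post_init__(self) -> None:
        if not self.allele_label or not self.allele_label[0].isdigit():
            raise ValueError(f"allele label must start with a digit: {self.allele_label!r}")
        gene = re.sub(r"\s+", "", self.gene_name)
        if gene.upper().startswith("HLA"):
            self.normalized = normalize_hla(gene, self.allele_label)
        else:
            self.normalized = f"{gene}*{self.allele_label}"


def normalize_hla(gene_name: str, allele_label: str) -> str:
    """Renormalize an HLA allele label into colon-doubled field form.

    Whitespace, colons and leading zeros are removed from the label, then
    colons are reinserted between character pairs from the left, e.g.
    ("HLA-B", "05701") -> "HLA-B*57:01".  Odd-length remainders keep the
    final character as a one-character field and are logged as suspicious.
    A label with no digits is returned unchanged with a warning.
    """
    gene = re.sub(r"\s+", "", gene_name)
    label = re.sub(r"[\s:]+", "", allele_label)
    if not any(ch.isdigit() for ch in label):
        logger.warning("HLA allele label %r contains no digits; left unchanged", allele_label)
        return f"{gene}*{label}"
    label = label.lstrip("0") or "0"
    pairs = [label[i : i + 2] for i in range(0, len(label), 2)]
    if len(label) % 2 == 1:
        logger.warning("odd-length HLA allele label %r after zero-stripping", label)
    return f"{gene}*{':'.join(pairs)}"


def strip_suballele(normalized: str) -> str:
    """Drop a trailing letter suffix from a star allele (CYP3A5*3A -> CYP3A5*3).

    HLA alleles are returned unchanged: their colon fields are not
    suballele designators.
    """
    if "*" not in normalized:
        return normalized
    gene, _, label = normalized.partition("*")
    if gene.upper().startswith("HLA"):
        return normalized
    m = re.match(r"^(.*\d)[A-Za-z]+$", label)
    if m:
        return f"{gene}*{m.group(1)}"
    return normalized


def find_star_alleles(
    document: Document, gene_mentions: Iterable[EntityMention]
) -> list[StarAllele]:
    """Scan after each gene mention for star-allele tokens and lists.

    Whitespace (only) may separate the gene from the first "*".  After a
    matched allele, separator runs of whitespace, "/", ",", "and" or "or"
    followed by another "*" token continue the list; anything else ends it.
    Alleles at identical spans from different gene mentions are emitted once.
    """
    text = document.text
    out: list[StarAllele] = []
    seen_spans: set[tuple[int, int]] = set()
    for gene in gene_mentions:
        if gene.entity_class != "gene":
            continue
        pos = gene.end
        # optional whitespace between gene and first asterisk
        ws = re.compile(r"\s*").match(text, pos)
        first = _ALLELE_TOKEN.match(text, ws.end())
        if first is None:
            continue
        matches = [first]
        pos = first.end()
        while True:
            sep = _SEPARATOR.match(text, pos)
            nxt = _ALLELE_TOKEN.match(text, sep.end() if sep else pos)
            if nxt is None:
                break
            matches.append(nxt)
            pos = nxt.end()
        for m in matches:
            span = (m.start(), m.end())
            if span in seen_spans:
                continue
            seen_spans.add(span)
            out.append(
                StarAllele(
                    gene_name=gene.mention_text,
                    allele_label=m.group(1),
                    span=span,
                    gene_id=gene.normalized_id,
                )
            )
    out.sort(key=lambda a: a.span)
    return out


def star_alleles_to_mentions(
    document: Document, alleles: Iterable[StarAllele]
) -> list[EntityMention]:
    """Merge star alleles into the mention stream as entity_class star_allele.

    The mention's normalized_id is the normalized allele string, and
    gene_id carries the triggering gene's Entrez id when known.
    """
    text = document.text
    return [
        EntityMention(
            doc_id=document.doc_id,
            entity_class="star_allele",
            start=a.span[0],
            end=a.span[1],
            mention_text=text[a.span[0] : a.span[1]],
            normalized_id=a.normalized,
            gene_id=a.gene_id,
        )
        for a in alleles
    ]
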