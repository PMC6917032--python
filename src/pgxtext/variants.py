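"""Variant mention classification, renormalization and filtering.

Upstream variant taggers emit dbSNP ids (rs12979860), protein substitutions
(T790M, Thr790Met, p.T790M) and DNA substitutions (c.93G>A).  This module
renormalizes parseable mentions to compact HGVS-like strings and filters
out mentions that carry no specific coordinate (e.g. "c.G>A"), plus
mentions matching a configurable exclusion-word list (cell-line names and
similar variant look-alikes).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

from .corpus import EntityMention

logger = logging.getLogger(__name__)

VARIANT_KINDS = ("dbsnp", "dna_sub", "protein_sub", "star_allele", "other")

# Three-letter -> one-letter codes for the 20 standard amino acids.
AA_THREE_TO_ONE = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C",
    "Gln": "Q", "Glu": "E", "Gly": "G", "His": "H", "Ile": "I",
    "Leu": "L", "Lys": "K", "Met": "M", "Phe": "F", "Pro": "P",
    "Ser": "S", "Thr": "T", "Trp": "W", "Tyr": "Y", "Val": "V",
}
_AA1 = "".join(sorted(AA_THREE_TO_ONE.values()))
_AA3 = "|".join(AA_THREE_TO_ONE)

_RSID_RE = re.compile(r"^rs\d+$", re.IGNORECASE)
_PROT1_RE = re.compile(rf"^(?:p\.)?([{_AA1}])(\d+)([{_AA1}])$")
_PROT3_RE = re.compile(rf"^(?:p\.)?({_AA3})(\d+)({_AA3})$", re.IGNORECASE)
_DNA_RE = re.compile(r"^(c\.|g\.)?(\d*)([ACGTacgt])>([ACGTacgt])$")
# tmVar component dialects, e.g. "p|SUB|Q|192|R" or "c|SUB|G|93|A"; an
# rs id may ride along as ";RS#:662".
_TMVAR_SUB_RE = re.compile(
    rf"^([pcg])\|SUB\|([A-Za-z]*)\|(\d*)\|([A-Za-z]*)$"
)
_TMVAR_RS_RE = re.compile(r"^RS#?:?(\d+)$", re.IGNORECASE)


@dataclass
class VariantMention:
    """A variant-class entity mention with its renormalized identity."""

    base: EntityMention
    variant_kind: str
    rsid: Optional[str] = None
    hgvs: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variant_kind not in VARIANT_KINDS:
            raise ValueError(f"unknown variant kind {self.variant_kind!r}")
        if self.variant_kind == "dbsnp" and not (
            self.rsid and re.fullmatch(r"rs\d+", self.rsid)
        ):
            raise ValueError("dbsnp kind requires an rs-id")

    @property
    def variant_id(self) -> str:
        """Preferred identifier: rsid, else star-allele name, else HGVS, else text."""
        if self.variant_kind == "star_allele":
            return self.base.normalized_id or self.base.mention_text
        return self.rsid or self.hgvs or self.base.mention_text


def _aa1(code: str) -> str:
    if len(code) == 1:
        return code.upper()
    return AA_THREE_TO_ONE[code.capitalize()]


def _parse_normalized_id(normalized_id: str) -> tuple[Optional[str], Optional[str]]:
    """Extract (rsid, hgvs) from an upstream id: an rs id or a component string."""
    rsid = None
    hgvs = None
    for part in normalized_id.split(";"):
        part = part.strip()
        if not part:
            continue
        if _RSID_RE.match(part):
            rsid = part.lower()
            continue
        m = _TMVAR_RS_RE.match(part)
        if m:
            rsid = "rs" + m.group(1)
            continue
        m = _TMVAR_SUB_RE.match(part)
        if m:
            level, ref, pos, alt = m.groups()
            if level == "p" and ref and alt:
                try:
                    hgvs = f"p.{_aa1(ref)}{pos}{_aa1(alt)}"
                except KeyError:
                    pass
            elif level in ("c", "g") and ref and alt:
                hgvs = f"{level}.{pos}{ref.upper()}>{alt.upper()}"
    return rsid, hgvs


def classify_and_parse(
    mention_text: str, normalized_id: Optional[str] = None
) -> tuple[str, Optional[str], Optional[str]]:
    """Classify a variant mention and renormalize it.

    Returns (variant_kind, rsid, hgvs).  Surface forms drive the kind;
    an rs id supplied via ``normalized_id`` (gene-context resolution done
    upstream) sets ``rsid`` regardless of the surface form.  Unparseable
    mentions are kind ``other``; if they contain a positive integer the raw
    text is kept as a best-effort normalization so the coordinate filter
    can retain coordinate-bearing forms (e.g. indels).
    """
    text = mention_text.strip()
    id_rsid, id_hgvs = (None, None)
    if normalized_id:
        id_rsid, id_hgvs = _parse_normalized_id(normalized_id)

    kind, rsid, hgvs = "other", None, None
    if _RSID_RE.match(text):
        kind, rsid = "dbsnp", text.lower()
    elif (m := _PROT1_RE.match(text)) or (m := _PROT3_RE.match(text)):
        ref, pos, alt = m.groups()
        try:
            kind, hgvs = "protein_sub", f"p.{_aa1(ref)}{pos}{_aa1(alt)}"
        except KeyError:
            kind = "other"
    elif m := _DNA_RE.match(text):
        prefix, pos, ref, alt = m.groups()
        if pos:  # coordinate-free substitutions stay unparsed
            prefix = prefix or "c."
            kind, hgvs = "dna_sub", f"{prefix}{pos}{ref.upper()}>{alt.upper()}"

    if kind == "other" and hgvs is None:
        if id_hgvs:
            hgvs = id_hgvs
            kind = "protein_sub" if id_hgvs.startswith("p.") else "dna_sub"
            if not re.search(r"[1-9]", id_hgvs):
                kind, hgvs = "other", None
        elif re.search(r"[1-9]\d*", text):
            hgvs = text
    rsid = id_rsid or rsid
    return kind, rsid, hgvs


def classify_mention(mention: EntityMention) -> VariantMention:
    """Wrap an aligned mention as a :class:`VariantMention`."""
    if mention.entity_class == "star_allele":
        return VariantMention(base=mention, variant_kind="star_allele")
    kind, rsid, hgvs = classify_and_parse(mention.mention_text, mention.normalized_id)
    return VariantMention(base=mention, variant_kind=kind, rsid=rsid, hgvs=hgvs)


def has_specific_coordinate(v: VariantMention) -> bool:
    """True iff the mention pins down a position: an rs id, a star allele,
    or an HGVS string containing a positive integer coordinate."""
    if v.rsid is not None:
        return True
    if v.variant_kind == "star_allele":
        return True
    return bool(v.hgvs and re.search(r"[1-9]\d*", v.hgvs))


def apply_exclusion_words(
    mentions: Iterable[VariantMention], exclusion_words: set[str]
) -> list[VariantMention]:
    """Drop variant mentions whose full text matches an exclusion word
    (case-insensitive); typical entries are cell-line names like T47D."""
    lowered = {w.lower() for w in exclusion_words}
    kept, dropped = [], 0
    for v in mentions:
        if v.base.mention_text.lower() in lowered:
            dropped += 1
        else:
            kept.append(v)
    if dropped:
        logger.info("exclusion words removed %d variant mention(s)", dropped)
    return kept


def load_exclusion_words(path: str | Path) -> set[str]:
    """Read one term per line; '#' starts a comment."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        term = line.split("#", 1)[0].strip()
        if term:
            words.add(term)
    return words
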