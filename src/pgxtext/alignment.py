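"""Regex-based alignment of offset-free entity records to document text.

Entity taggers applied upstream of this package report the surface string
of each mention but not its position, and they translate Unicode to ASCII
(so a document's "TGF-α" is reported as "TGF-alpha").  Alignment rebuilds
exact character spans by compiling each mention into a tolerant pattern:
word-bounded at both ends, whitespace-run agnostic, and Greek-letter
agnostic.  Records are aligned largest mention first so that no entity is
accepted strictly inside a longer entity's span.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable

from .corpus import AnnotationRecord, Document, EntityMention

logger = logging.getLogger(__name__)

# Spelled-out Greek letter names and their lower/upper/final characters.
GREEK_LETTERS: dict[str, str] = {
    "alpha": "αΑ",
    "beta": "βΒ",
    "gamma": "γΓ",
    "delta": "δΔ",
    "epsilon": "εΕ",
    "zeta": "ζΖ",
    "eta": "ηΗ",
    "theta": "θΘ",
    "iota": "ιΙ",
    "kappa": "κΚ",
    "lambda": "λΛ",
    "mu": "μΜ",
    "nu": "νΝ",
    "xi": "ξΞ",
    "omicron": "οΟ",
    "pi": "πΠ",
    "rho": "ρΡ",
    "sigma": "σΣς",
    "tau": "τΤ",
    "upsilon": "υΥ",
    "phi": "φΦ",
    "chi": "χΧ",
    "psi": "ψΨ",
    "omega": "ωΩ",
}

_GREEK_BY_LENGTH = sorted(GREEK_LETTERS, key=len, reverse=True)


def _expand_letter_run(run: str) -> str:
    """Regex for a run of letters, with Greek names matching either form."""
    out: list[str] = []
    i = 0
    low = run.lower()
    while i < len(run):
        for name in _GREEK_BY_LENGTH:
            if low.startswith(name, i):
                chars = GREEK_LETTERS[name]
                out.append(f"(?:(?i:{name})|[{chars}])")
                i += len(name)
                break
        else:
            out.append(re.escape(run[i]))
            i += 1
    return "".join(out)


def build_mention_pattern(mention_text: str) -> re.Pattern[str]:
    """Compile a mention string into its alignment pattern.

    The pattern matches the mention only at word boundaries (a transition
    between word and non-word characters, or a string edge), treats each
    maximal whitespace run as ``\\s+``, matches spelled-out Greek letter
    names as either the name or the Greek character, and treats all regex
    metacharacters in the mention as literals.
    """
    if not mention_text:
        raise ValueError("mention_text must be non-empty")
    parts: list[str] = []
    for token in re.findall(r"\s+|[^\W\d_]+|.", mention_text, flags=re.DOTALL):
        if token.isspace():
            parts.append(r"\s+")
        elif token[0].isalpha():
            parts.append(_expand_letter_run(token))
        else:
            parts.append(re.escape(token))
    core = "".join(parts)
    # Word-boundary assertions only where the mention edge is a word
    # character; a mention starting with e.g. "(" already sits at a boundary.
    stripped = mention_text.strip()
    prefix = r"(?<!\w)" if re.match(r"\w", stripped) else ""
    suffix = r"(?!\w)" if re.search(r"\w$", stripped) else ""
    return re.compile(prefix + core + suffix)


def _find_all(pattern: re.Pattern[str], text: str) -> list[tuple[int, int]]:
    """All match spans, including overlapping occurrences."""
    spans = []
    pos = 0
    while True:
        m = pattern.search(text, pos)
        if m is None:
            break
        spans.append((m.start(), m.end()))
        pos = m.start() + 1
    return spans


def _strictly_inside(inner: tuple[int, int], outer: tuple[int, int]) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1] and inner != outer


def align_mentions(
    document: Document, records: Iterable[AnnotationRecord]
) -> list[EntityMention]:
    """Anchor each annotation record at every matching position in the text.

    Records are processed in descending order of mention length (ties broken
    lexicographically); a match whose span lies strictly inside a span
    already accepted from a longer mention is suppressed.  Identical spans
    from different records are all kept.  Exact duplicate records are
    collapsed before alignment; records whose pattern matches nowhere are
    dropped and counted, never fatal.
    """
    unique: list[AnnotationRecord] = []
    seen: set[tuple[str, str, str | None]] = set()
    for rec in records:
        if rec.doc_id != document.doc_id:
            raise ValueError(
                f"record for {rec.doc_id!r} passed with document {document.doc_id!r}"
            )
        key = (rec.entity_class, rec.mention_text, rec.normalized_id)
        if key not in seen:
            seen.add(key)
            unique.append(rec)

    text = document.text
    ordered = sorted(unique, key=lambda r: (-len(r.mention_text), r.mention_text))
    accepted: list[tuple[tuple[int, int], int]] = []  # (span, mention_text length)
    mentions: list[EntityMention] = []
    unaligned = 0
    for rec in ordered:
        pattern = build_mention_pattern(rec.mention_text)
        spans = _find_all(pattern, text)
        kept_any = False
        for span in spans:
            if any(
                _strictly_inside(span, prior) and prior_len > len(rec.mention_text)
                for prior, prior_len in accepted
            ):
                continue
            mentions.append(
                EntityMention(
                    doc_id=document.doc_id,
                    entity_class=rec.entity_class,
                    start=span[0],
                    end=span[1],
                    mention_text=text[span[0] : span[1]],
                    normalized_id=rec.normalized_id,
                )
            )
            accepted.append((span, len(rec.mention_text)))
            kept_any = True
        if not kept_any:
            unaligned += 1
            logger.info(
                "document %s: mention %r did not align", document.doc_id, rec.mention_text
            )
    if unaligned:
        logger.info("document %s: %d unaligned record(s)", document.doc_id, unaligned)
    mentions.sort(key=lambda m: (m.start, m.end))
    return mentions


def align_corpus(
    documents: Iterable[Document], records: Iterable[AnnotationRecord]
) -> dict[str, list[EntityMention]]:
    """Align a whole corpus; returns mentions keyed by doc_id."""
    by_doc: dict[str, list[AnnotationRecord]] = {}
    for rec in records:
        by_doc.setdefault(rec.doc_id, []).append(rec)
    return {
        doc.doc_id: align_mentions(doc, by_doc.get(doc.doc_id, []))
        for doc in documents
    }
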