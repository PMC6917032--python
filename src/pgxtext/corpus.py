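"""Document, annotation and mention data model, with BioC-style I/O.

Coordinate convention used throughout the package: character offsets are
0-based, half-open, over the concatenation of a document's passages joined
by a single newline.  The joining newline is owned by the preceding
passage, so a passage of text ``t`` starting at offset ``o`` is followed by
the next passage at ``o + len(t) + 1``.
"""

from __future__ import annotations

import html
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

SECTION_LABELS = (
    "title",
    "abstract",
    "introduction",
    "methods",
    "results",
    "discussion",
    "other",
)

ENTITY_CLASSES = ("chemical", "gene", "variant", "star_allele")


class CorpusParseError(ValueError):
    """Raised when a document or annotation file cannot be parsed."""


def _coerce_section(label: Optional[str]) -> str:
    if label is None:
        return "other"
    label = label.strip().lower()
    return label if label in SECTION_LABELS else "other"


@dataclass
class Passage:
    """A contiguous block of document text with a coarse section label."""

    section_label: str
    text: str
    offset: int

    def __post_init__(self) -> None:
        self.section_label = _coerce_section(self.section_label)
        if self.offset < 0:
            raise ValueError("passage offset must be >= 0")


@dataclass
class Document:
    """One article: ordered passages plus bibliographic metadata."""

    doc_id: str
    passages: list[Passage] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate_offsets()

    def _validate_offsets(self) -> None:
        expected = 0
        for p in self.passages:
            if p.offset != expected:
                raise ValueError(
                    f"document {self.doc_id}: passage at offset {p.offset}, "
                    f"expected {expected} (single-newline join convention)"
                )
            expected = p.offset + len(p.text) + 1

    @property
    def text(self) -> str:
        return "\n".join(p.text for p in self.passages)

    def passage_at(self, pos: int) -> Passage:
        """Passage whose half-open interval contains character ``pos``."""
        for p in self.passages:
            if p.offset <= pos < p.offset + len(p.text):
                return p
        raise IndexError(f"position {pos} outside all passages of {self.doc_id}")


@dataclass
class AnnotationRecord:
    """An offset-free entity record: class, surface string, normalized id."""

    doc_id: str
    entity_class: str
    mention_text: str
    normalized_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.mention_text:
            raise ValueError("mention_text must be non-empty")
        if self.entity_class not in ("chemical", "gene", "variant"):
            raise ValueError(f"unknown entity class {self.entity_class!r}")


@dataclass
class EntityMention:
    """An entity anchored at a half-open character interval of a document."""

    doc_id: str
    entity_class: str
    start: int
    end: int
    mention_text: str
    normalized_id: Optional[str] = None
    gene_id: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad span [{self.start}, {self.end})")
        if self.entity_class not in ENTITY_CLASSES:
            raise ValueError(f"unknown entity class {self.entity_class!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Sentence:
    """A sentence in document coordinates, with the mentions it contains.

    Mention spans are stored in document coordinates; ``relative_span``
    converts one to sentence-local coordinates.
    """

    doc_id: str
    start: int
    end: int
    text: str
    section_label: str = "other"
    mentions: list[EntityMention] = field(default_factory=list)

    def relative_span(self, mention: EntityMention) -> tuple[int, int]:
        if not (self.start <= mention.start and mention.end <= self.end):
            raise ValueError("mention lies outside sentence span")
        return (mention.start - self.start, mention.end - self.start)


# ---------------------------------------------------------------------------
# Document I/O


def _doc_from_bioc_element(elem: ET.Element) -> Document:
    doc_id_el = elem.find("id")
    if doc_id_el is None or not (doc_id_el.text or "").strip():
        raise CorpusParseError("BioC document without an <id> element")
    doc_id = doc_id_el.text.strip()
    metadata: dict = {}
    for infon in elem.findall("infon"):
        key = infon.get("key", "")
        if key in ("title", "journal", "pmcid"):
            metadata[key] = infon.text or ""
        elif key == "year":
            try:
                metadata["year"] = int(infon.text or "0")
            except ValueError as exc:
                raise CorpusParseError(
                    f"document {doc_id}: non-integer year {infon.text!r}"
                ) from exc
    passages = []
    for p in elem.findall("passage"):
        label = None
        for infon in p.findall("infon"):
            if infon.get("key") in ("section", "type"):
                label = infon.text
                break
        offset_el = p.find("offset")
        text_el = p.find("text")
        if offset_el is None or text_el is None:
            raise CorpusParseError(f"document {doc_id}: passage missing offset or text")
        passages.append(
            Passage(
                section_label=_coerce_section(label),
                text=text_el.text or "",
                offset=int(offset_el.text),
            )
        )
    try:
        return Document(doc_id=doc_id, passages=passages, metadata=metadata)
    except ValueError as exc:
        raise CorpusParseError(f"document {doc_id}: {exc}") from exc


def read_documents(path: str | Path, format: str = "bioc") -> list[Document]:
    """Read documents from a BioC XML file or a flat TSV.

    The TSV dialect has columns doc_id, title, abstract, journal, year and
    yields two-passage documents.  Unlabeled passages default to section
    label ``other``; duplicate document ids are an error.
    """
    path = Path(path)
    docs: list[Document] = []
    if format == "bioc":
        content = path.read_text(encoding="utf-8").strip()
        if not content:
            return []
        try:
            root = ET.fromstring(content)
        except ET.ParseError as exc:
            raise CorpusParseError(f"{path}: not well-formed BioC XML: {exc}") from exc
        for elem in root.findall("document"):
            docs.append(_doc_from_bioc_element(elem))
    elif format == "plain_tsv":
        with path.open(encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 5:
                    raise CorpusParseError(
                        f"{path}:{lineno}: expected 5 columns, got {len(fields)}"
                    )
                doc_id, title, abstract, journal, year = fields
                passages = [Passage("title", title, 0)]
                if abstract:
                    passages.append(Passage("abstract", abstract, len(title) + 1))
                docs.append(
                    Document(
                        doc_id=doc_id,
                        passages=passages,
                        metadata={
                            "title": title,
                            "journal": journal,
                            "year": int(year) if year else 0,
                        },
                    )
                )
    else:
        raise ValueError(f"unknown document format {format!r}")
    seen: set[str] = set()
    for d in docs:
        if d.doc_id in seen:
            raise CorpusParseError(f"duplicate doc_id {d.doc_id!r} in {path}")
        seen.add(d.doc_id)
    return docs


def write_documents(docs: Iterable[Document], path: str | Path, format: str = "bioc") -> None:
    """Write documents; ``read_documents`` round-trips the output exactly."""
    path = Path(path)
    docs = list(docs)
    if format == "bioc":
        lines = ['<?xml version="1.0" encoding="UTF-8"?>', "<collection>"]
        lines.append("<source>pgxtext</source>")
        for doc in docs:
            lines.append("<document>")
            lines.append(f"<id>{html.escape(doc.doc_id)}</id>")
            for key in ("title", "journal", "year", "pmcid"):
                if key in doc.metadata:
                    val = html.escape(str(doc.metadata[key]))
                    lines.append(f'<infon key="{key}">{val}</infon>')
            for p in doc.passages:
                lines.append("<passage>")
                lines.append(f'<infon key="section">{p.section_label}</infon>')
                lines.append(f"<offset>{p.offset}</offset>")
                lines.append(f"<text>{html.escape(p.text)}</text>")
                lines.append("</passage>")
            lines.append("</document>")
        lines.append("</collection>")
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "plain_tsv":
        rows = []
        for doc in docs:
            title = doc.passages[0].text if doc.passages else ""
            abstract = doc.passages[1].text if len(doc.passages) > 1 else ""
            rows.append(
                "\t".join(
                    [
                        doc.doc_id,
                        title,
                        abstract,
                        str(doc.metadata.get("journal", "")),
                        str(doc.metadata.get("year", "")),
                    ]
                )
            )
        path.write_text("\n".join(rows) + ("\n" if rows else ""), encoding="utf-8")
    else:
        raise ValueError(f"unknown document format {format!r}")


# ---------------------------------------------------------------------------
# Annotation I/O (4-column TSV: doc_id, entity_class, mention_text, normalized_id)


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Read offset-free annotation records, preserving file order.

    An empty id column yields ``normalized_id=None`` rather than an empty
    string; the reader never deduplicates.
    """
    records: list[AnnotationRecord] = []
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise CorpusParseError(
                    f"{path}:{lineno}: expected 4 tab-separated columns, got {len(fields)}"
                )
            doc_id, entity_class, mention_text, normalized_id = fields
            try:
                records.append(
                    AnnotationRecord(
                        doc_id=doc_id,
                        entity_class=entity_class,
                        mention_text=mention_text,
                        normalized_id=normalized_id or None,
                    )
                )
            except ValueError as exc:
                raise CorpusParseError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_annotations(records: Iterable[AnnotationRecord], path: str | Path) -> None:
    lines = [
        "\t".join([r.doc_id, r.entity_class, r.mention_text, r.normalized_id or ""])
        for r in records
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")
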