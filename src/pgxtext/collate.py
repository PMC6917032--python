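"""Output tables, collation and knowledge-base cross-referencing.

Accepted relations become curator-facing TSV rows carrying paper metadata
and an HTML-highlighted sentence.  Rows are collated on the
(chemical, variant, gene) key, ranked by the number of distinct supporting
papers, and flagged against a curated pharmacogenomics knowledge base
(PharmGKB-style): has the chemical been seen, has the variant been seen,
and has this exact association been seen.  Star alleles are compared with
suballele suffixes stripped, and star alleles that map one-to-one onto an
rs id (e.g. POR*28 and rs1057868) are looked up under both names.
"""

from __future__ import annotations

import html
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

from .star_alleles import strip_suballele

UNFILTERED_FILENAME = "associations_unfiltered.tsv"
FILTERED_FILENAME = "associations_filtered.tsv"
COLLATED_FILENAME = "associations_collated.tsv"

ROW_COLUMNS = [
    "doc_id", "pmid", "title", "journal", "year", "section_label",
    "chemical_mesh_id", "chemical_name", "variant_id", "variant_kind",
    "gene_id", "score", "sentence_html",
]
COLLATED_COLUMNS = [
    "chemical_mesh_id", "chemical_name", "variant_id", "variant_kind",
    "gene_id", "paper_count", "pmids",
    "in_pharmgkb_chemical", "in_pharmgkb_variant", "in_pharmgkb_association",
]


@dataclass
class ExtractedRelationRow:
    """One accepted chemical/variant relation with provenance metadata."""

    doc_id: str
    pmid: str
    title: str
    journal: str
    year: int
    section_label: str
    chemical_mesh_id: str
    chemical_name: str
    variant_id: str
    variant_kind: str
    gene_id: Optional[str]
    score: float
    sentence_html: str


@dataclass
class CollatedAssociation:
    """A (chemical, variant, gene) key with its distinct-paper support."""

    chemical_mesh_id: str
    chemical_name: str
    variant_id: str
    variant_kind: str
    gene_id: Optional[str]
    pmids: set[str]
    in_pharmgkb_chemical: bool = False
    in_pharmgkb_variant: bool = False
    in_pharmgkb_association: bool = False

    @property
    def paper_count(self) -> int:
        return len(self.pmids)


@dataclass
class PharmGKBTable:
    """Local snapshot of knowledge-base content used for flagging.

    ``chemical_map`` maps MeSH ids to knowledge-base chemical ids;
    ``known_pairs`` holds unfolded one-chemical/one-variant associations;
    ``star_rsid`` maps normalized star alleles to their single equivalent
    rs id.  Known chemical/variant universes default to those appearing in
    the pairs.
    """

    chemical_map: dict[str, str] = field(default_factory=dict)
    known_pairs: set[tuple[str, str]] = field(default_factory=set)
    star_rsid: dict[str, str] = field(default_factory=dict)

    @property
    def known_chemicals(self) -> set[str]:
        return {c for c, _ in self.known_pairs}

    @property
    def known_variants(self) -> set[str]:
        return {v for _, v in self.known_pairs}


def render_sentence_html(
    sentence_text: str, span_a: tuple[int, int], span_b: tuple[int, int]
) -> str:
    """Escape a sentence and wrap the two entity spans in <b> tags.

    Spans are sentence-relative, half-open and must not overlap; escaping
    runs before tag insertion so the tags are the only markup in the
    output.
    """
    (a1, a2), (b1, b2) = sorted([span_a, span_b])
    if b1 < a2:
        raise ValueError("entity spans overlap")
    esc = lambda s: html.escape(s, quote=False)
    return (
        esc(sentence_text[:a1])
        + "<b>" + esc(sentence_text[a1:a2]) + "</b>"
        + esc(sentence_text[a2:b1])
        + "<b>" + esc(sentence_text[b1:b2]) + "</b>"
        + esc(sentence_text[b2:])
    )


def collate(rows: Iterable[ExtractedRelationRow]) -> list[CollatedAssociation]:
    """Group rows by (chemical, variant, gene) and count distinct papers.

    Sorted by paper_count descending; ties broken by chemical name then
    variant id so the ranking is deterministic.
    """
    groups: dict[tuple[str, str, Optional[str]], CollatedAssociation] = {}
    for row in rows:
        key = (row.chemical_mesh_id, row.variant_id, row.gene_id)
        assoc = groups.get(key)
        if assoc is None:
            groups[key] = CollatedAssociation(
                chemical_mesh_id=row.chemical_mesh_id,
                chemical_name=row.chemical_name,
                variant_id=row.variant_id,
                variant_kind=row.variant_kind,
                gene_id=row.gene_id,
                pmids={row.pmid},
            )
        else:
            assoc.pmids.add(row.pmid)
    return sorted(
        groups.values(),
        key=lambda a: (-a.paper_count, a.chemical_name, a.variant_id),
    )


def unfold_compound_associations(
    raw: Iterable[tuple[Iterable[str], str]]
) -> set[tuple[str, str]]:
    """Unfold (chemical set, variant) records into 1x1 pairs."""
    pairs = set()
    for chemicals, variant in raw:
        for chem in chemicals:
            pairs.add((chem, variant))
    return pairs


def _variant_keys(variant_id: str, table: PharmGKBTable) -> set[str]:
    """Lookup keys for a variant: itself (suballele-stripped) plus its
    star/rs equivalent in either direction."""
    base = strip_suballele(variant_id)
    keys = {base}
    if base in table.star_rsid:
        keys.add(table.star_rsid[base])
    for star, rsid in table.star_rsid.items():
        if rsid == base:
            keys.add(star)
    return keys


def annotate_pharmgkb(
    associations: Iterable[CollatedAssociation], table: PharmGKBTable
) -> list[CollatedAssociation]:
    """Set the three knowledge-base presence flags on each association.

    A chemical with no MeSH mapping simply gets false flags, never an
    error.  The association flag requires the mapped chemical paired with
    any equivalent variant key; it therefore implies both single flags.
    """
    out = []
    for assoc in associations:
        keys = _variant_keys(assoc.variant_id, table)
        assoc.in_pharmgkb_variant = bool(keys & table.known_variants)
        mapped = table.chemical_map.get(assoc.chemical_mesh_id)
        assoc.in_pharmgkb_chemical = mapped is not None and mapped in table.known_chemicals
        assoc.in_pharmgkb_association = mapped is not None and any(
            (mapped, k) in table.known_pairs for k in keys
        )
        out.append(assoc)
    return out


def load_pharmgkb_table(path: str | Path) -> PharmGKBTable:
    """Read a knowledge-base snapshot TSV.

    Record types, keyed by the first column:
      ``chem``  chem <TAB> mesh_id <TAB> pgkb_chemical_id
      ``assoc`` assoc <TAB> pgkb_chemical_ids (';'-separated) <TAB> variant
      ``star``  star <TAB> normalized_star_allele <TAB> rsid
    Compound associations are unfolded on load.
    """
    table = PharmGKBTable()
    raw_assocs: list[tuple[list[str], str]] = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ValueError(f"{path}:{lineno}: expected 3 columns")
        kind, a, b = fields
        if kind == "chem":
            table.chemical_map[a] = b
        elif kind == "assoc":
            raw_assocs.append(([c for c in a.split(";") if c], b))
        elif kind == "star":
            table.star_rsid[a] = b
        else:
            raise ValueError(f"{path}:{lineno}: unknown record type {kind!r}")
    table.known_pairs = unfold_compound_associations(raw_assocs)
    return table


# ---------------------------------------------------------------------------
# TSV writers (UTF-8, header row, no quoting; tabs/newlines in sentence
# fields are replaced by spaces)


def _clean(value) -> str:
    return str(value).replace("\t", " ").replace("\n", " ").replace("\r", " ")


def write_relation_rows(rows: Iterable[ExtractedRelationRow], path: str | Path) -> None:
    lines = ["\t".join(ROW_COLUMNS)]
    for r in rows:
        lines.append(
            "\t".join(
                _clean(v)
                for v in [
                    r.doc_id, r.pmid, r.title, r.journal, r.year, r.section_label,
                    r.chemical_mesh_id, r.chemical_name, r.variant_id, r.variant_kind,
                    r.gene_id or "", f"{r.score:.6f}", r.sentence_html,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_collated(assocs: Iterable[CollatedAssociation], path: str | Path) -> None:
    lines = ["\t".join(COLLATED_COLUMNS)]
    for a in assocs:
        lines.append(
            "\t".join(
                _clean(v)
                for v in [
                    a.chemical_mesh_id, a.chemical_name, a.variant_id, a.variant_kind,
                    a.gene_id or "", a.paper_count, ";".join(sorted(a.pmids)),
                    a.in_pharmgkb_chemical, a.in_pharmgkb_variant,
                    a.in_pharmgkb_association,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
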