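# pgxtext

Text mining of chemical–variant pharmacogenomic associations from
annotated biomedical literature, built to triage papers for knowledge-base
curators.

Curated pharmacogenomics resources such as PharmGKB depend on human
curators finding, reading and annotating papers that link a genetic
variant to a drug's efficacy, metabolism, concentration, resistance,
adverse events or addiction liability. `pgxtext` implements a
high-precision extraction pipeline over documents that have already been
tagged by named-entity recognizers (chemicals with MeSH ids, genes with
Entrez ids, variants with dbSNP ids where resolvable) but whose
annotations carry only the mention *string*, not its position:

1. **Alignment** — each offset-free annotation is compiled into a tolerant
   regular expression (word-bounded, whitespace-run agnostic, spelled-out
   Greek letters matching either `alpha` or `α`) and anchored at every
   matching position; mentions are processed largest first so no entity is
   accepted strictly inside a longer one.
2. **Star alleles** — the text immediately after each aligned gene mention
   is scanned for `*` followed by a digit-led token (colons included for
   HLA), with continuation lists (`*1/*2`, `*1, *2 and *4`) yielding one
   allele each. HLA alleles are renormalized into colon-doubled field form
   (`HLA-B*05701 → HLA-B*57:01`).
3. **Variant renormalization** — mentions are classified as dbSNP ids,
   protein substitutions (one-letter, three-letter or `p.`-prefixed, all
   emitted as one-letter HGVS such as `p.Q192R`) or DNA substitutions
   (`c.93G>A`); mentions with no specific coordinate (`c.G>A`) and
   configured exclusion words (cell-line names like `T47D`) are dropped.
4. **Candidate sentences** — sentences containing at least one allow-listed
   chemical (≥ 4 characters) and one surviving variant, gated by a
   pharmacogenomics keyword list unless the sentence mentions a specific
   dbSNP id.
5. **Relation classification** — two independent logistic regressions (one
   for rs-id/star-allele candidates, one for DNA/protein-change candidates)
   over sparse lexical count features score every chemical × variant pair;
   scores are thresholded at 0.75 to favour precision over recall, and
   cancer-drug/protein-change pairs are removed as likely somatic events.
   Sentences reporting explicitly *negative* findings ("does not affect…")
   count as associations, because curators want them.
6. **Collation** — accepted relations become three TSVs: all scored rows,
   the thresholded rows, and associations collated on
   (chemical, variant, gene) ranked by distinct supporting papers, each
   flagged for presence in a PharmGKB-style knowledge-base snapshot
   (star alleles suballele-stripped, star↔rs-id equivalences applied:
   `POR*28 ↔ rs1057868`).

A fully seeded synthetic-corpus generator (`pgxtext.synthetic`) plants
ground-truth offsets, decoys for every filter, and labeled relation
sentences, so the whole pipeline is testable without any downloads.

## Worked example

```python
from pgxtext import *
from pgxtext.corpus import Document, Passage, AnnotationRecord
from pgxtext.synthetic import default_chemical_filter_config, default_keywords

doc = Document(
    doc_id="30000001",
    passages=[
        Passage("title", "Pharmacogenomics of clopidogrel.", 0),
        Passage("abstract",
                "Patients carrying CYP2C19*2 showed reduced clopidogrel metabolism. "
                "The rs662 variant influences the response to interferon α.", 33),
    ],
)
records = [
    AnnotationRecord("30000001", "gene", "CYP2C19", "1557"),
    AnnotationRecord("30000001", "chemical", "clopidogrel", "MESH:D000077144"),
    AnnotationRecord("30000001", "variant", "rs662", "rs662"),
    AnnotationRecord("30000001", "chemical", "interferon alpha", "MESH:D016898"),
]
mentions = align_mentions(doc, records)
```

Alignment anchors every record, including the record whose ASCII surface
`interferon alpha` appears in the document as `interferon α`:

```
chemical  [ 20, 31)  'clopidogrel'
gene      [ 51, 58)  'CYP2C19'
chemical  [ 76, 87)  'clopidogrel'
variant   [104,109)  'rs662'
chemical  [145,157)  'interferon α'
```

Star-allele detection then finds `CYP2C19*2` after the gene mention, and
candidate selection pairs each surviving chemical with each surviving
variant in the same sentence:

```
star allele: CYP2C19*2 (58, 60)
candidate: group1 clopidogrel ~ CYP2C19*2
candidate: group1 interferon α ~ rs662
```

Both candidates are group 1 (star allele / rs id); the second sentence
needed no keyword because it mentions a specific dbSNP id. Scoring these
candidates with trained models and collating the accepted ones produces
the three output TSVs (see `pgxtext.pipeline.run_pipeline`, or the
`pgxtext run` CLI, which also writes a manifest with per-stage counts and
output hashes).

## Command line

```bash
pgxtext simulate --seed 1 --out-dir corpus/        # synthetic corpus + ground truth
pgxtext align --documents corpus/documents.bioc.xml \
              --annotations corpus/annotations.tsv --out aligned.tsv
pgxtext train --group 1 --seed 7 --out group1.json
pgxtext run --config run.json                      # full pipeline + manifest
```

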