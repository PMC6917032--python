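# Methods

This note documents the models, rules and numerical choices behind
`pgxtext`, the assumptions they rest on, and what the synthetic-corpus
evaluation does and does not demonstrate.

## Problem setting and assumptions

The pipeline consumes documents whose entities were tagged upstream by
named-entity recognizers: chemicals normalized to MeSH ids, genes to
Entrez ids, and variants to dbSNP ids where a gene co-mention allowed the
resolution. Two properties of that input shape the design:

* annotations report the mention **string only** — positions must be
  reconstructed; and
* the upstream taggers translate Unicode to ASCII, so the reported string
  may differ from the document text (`TGF-α` reported as `TGF-alpha`).

Association extraction is deliberately **sentence-local**: a chemical and
a variant must co-occur in one sentence. Cross-sentence and co-reference
links are out of scope, as are diplotypes (`*1/*2` as a genotype object —
each allele is extracted independently).

## Coordinate convention

All spans are 0-based half-open character intervals over the concatenation
of a document's passages joined by a single newline owned by the preceding
passage. Every stage indexes the same document string the readers
produced; this is asserted throughout the test suite.

## Alignment

Each mention string compiles to a pattern that (i) is word-bounded on any
edge that ends in a word character (a mention such as `(EGFR)` needs no
leading boundary), (ii) maps each maximal whitespace run to `\s+`,
(iii) matches each spelled-out Greek letter name, case-insensitively, as
either the name or the letter (both cases; the full alphabet alpha–omega,
including final sigma), and (iv) escapes all other characters, so `*`,
`(`, `.` in identifiers are literal. Greek names are located greedily,
longest name first, inside each letter run — so `beta` is recognized
before the `eta` nested inside it.

Records are aligned in descending order of mention length, ties broken
lexicographically for determinism. Every match position is kept except
those strictly contained in a span already accepted from a longer mention;
identical spans from different records are all kept (a string can
legitimately be tagged as two classes). Records that match nowhere are
dropped and counted, never fatal: occasional misses are expected
consequences of the upstream ASCII translation. Exact duplicate records
are collapsed before alignment.

## Star alleles

A scanner runs immediately after each aligned gene mention: optional
whitespace, then `*`, then a token that begins with a digit and may
contain letters and colons. After a matched token, separator runs drawn
from whitespace, `/`, `,`, `and`, `or` followed by another `*` token
continue the list; anything else ends it. The normalized form is the gene
name concatenated with `*` and the token, whitespace removed.

For genes whose name begins with `HLA`, the label is renormalized: strip
whitespace, colons and leading zeros, then reinsert colons between
character pairs from the left (`05701 → 57:01`). Odd-length remainders
keep the final character as a one-character field and are logged as
suspicious — the colon-doubling rule does not define them, and flagging is
safer than guessing. Suballele stripping removes a trailing letter run
after the final digit (`CYP3A5*3A → CYP3A5*3`); HLA alleles are exempt
because their colon fields are not suballele designators. Both
normalizations are idempotent (property-tested).

Detected alleles enter the variant stream as `star_allele` mentions so all
downstream stages treat them uniformly; alleles at identical spans
triggered by different gene mentions are deduplicated.

## Variant renormalization and filtering

Surface forms drive classification: `rs\d+` (case-insensitive) → dbSNP;
one-letter, three-letter or `p.`-prefixed protein substitutions → `p.`
one-letter HGVS (the three-to-one amino-acid map is a bijection over the
20 standard residues, tested as such); `c.`/`g.`-prefixed or bare DNA
substitutions → prefixed HGVS (bare forms default to `c.`). The upstream
normalized id may be an rs id or a pipe-delimited component string
(`p|SUB|Q|192|R;RS#:662`); when it supplies an rs id, the rs id is kept
regardless of surface form. Natural-language phrasings are *not* re-parsed
from the surface — they are handled only when the upstream id supplies
components, mirroring the division of labour with the upstream tagger.

A mention survives only if it pins down a position: an rs id, a star
allele, or an HGVS string containing a positive integer (`c.G>A` fails).
Unparseable mentions that do contain a positive integer (e.g. indels like
`c.35delG`) keep their raw text as a best-effort normalization and
therefore survive the coordinate filter; this is the literal reading of
"keep anything with a specific coordinate". Exclusion words (shipped
starter list: common cell-line names) remove variant look-alikes by exact
case-insensitive match on the full mention.

## Candidate selection

Chemicals are kept when their MeSH id is on an allow-list (category
exclusions applied when the list is built, not per mention) and the
surface is at least 4 characters — short abbreviations like `ATP` are
overwhelmingly noise. Sentence segmentation is a regex splitter:
sentence-final punctuation followed by whitespace and an upper-case
letter, digit or quote, unless the preceding token is a known abbreviation
(`i.e.`, `e.g.`, `Fig.` …); its quality is pinned by a curated fixture
list rather than a tool mandate.

A sentence is eligible when it has ≥ 1 surviving chemical, ≥ 1 surviving
variant, and either a keyword hit or a dbSNP-kind variant. Keyword
matching is whole-word and case-insensitive; a trailing `*` marks a prefix
stem (`metaboli*` covers metabolism/metabolizer). Only dbSNP-kind variants
exempt the keyword gate by default — star alleles can be added via a
config switch, since the narrower reading is the conservative one. Every
chemical × variant pair in an eligible sentence becomes one candidate.
Candidates partition into group 1 (dbSNP, star allele) and group 2
(DNA/protein substitution and other) — empirically the former co-occur
with pharmacogenomic statements far more often, so the two groups get
separate classifiers with separate vocabularies.

## Relation classifiers

Features are sparse counts: bag of lemma-like tokens over the sentence;
tokens strictly *between* the two entities, which in clause-local English
approximates the shortest syntactic path between them; the length of that
between-span (bucketed at 10); the entity-kind pair; and ±2-token windows
on each side of each entity. The lemmatizer is a deliberate small
stemmer (lowercasing plus plural/possessive stripping) — enough to merge
`modulates`/`modulate` without a parser dependency. Entity tokens are
excluded from window/between features only by position, so the model
learns contexts rather than memorizing entity names.

The classifier is an L2-regularized logistic regression (C = 1.0,
liblinear), deterministic given the training seed, which controls only the
data shuffle. Class weighting is off by default — the keyword gate already
performs the enrichment — with a balanced-weighting flag available.
Scoring is computed directly from the serialized weights (sigmoid of the
linear score), so a model JSON round-trips bit-exactly and unseen features
are ignored by construction. The operating threshold is 0.75, chosen to
favour precision over recall: curators tolerate missed associations far
better than false positives. Accepted candidates whose chemical is
cancer-flagged *and* whose variant is a DNA/protein change are removed as
likely somatic tumour events; rs-id and star-allele candidates are never
removed by this rule.

Evaluation reports (threshold, precision, recall) at every achievable
threshold; precision at thresholds with zero positive predictions is
reported as absent, never 0. Train/test splitting is stratified by label
(80/20 by default) and recorded in model metadata.

## Outputs and knowledge-base flags

Accepted relations are written as TSV rows carrying paper metadata and an
HTML-escaped sentence with the two entities wrapped in `<b>` tags
(escaping before tag insertion, so the tags are the only markup).
Collation groups on (chemical MeSH id, variant id, gene id) — the gene
participates in the key so the same rs id reached via different genes
stays separate — counts distinct PMIDs, and sorts by support with
deterministic tie-breaks. Knowledge-base flags are computed against a
local snapshot: compound associations are unfolded to one-chemical/
one-variant pairs; variant lookup tries the suballele-stripped key and its
star↔rs-id equivalent in both directions; the association flag implies
both single-entity flags by construction. The shipped
`synthetic_pharmgkb.tsv` is a constructed stand-in used by tests and
demos, not curated content.

## Synthetic corpus

The generator emulates exactly the features the pipeline's rules react
to: perturbed surfaces (Greek substitution and whitespace mangling at rate
0.2 each, with the annotation record keeping the ASCII single-space form),
star-allele list grammar in all separator forms, decoy mentions for every
filter (sub-4-character and disallowed-category chemicals, cell-line
variant look-alikes, coordinate-free substitutions), and relation
sentences from positive/negative template families that are lexically
separable by design, including negative-finding sentences labeled
positive. Default conditions: 50 documents, 2–4 relation sentences each,
30% with a full-text section, positives and negatives balanced. Expected
survivor counts at every stage are recorded by construction — the
generator never runs the pipeline, so the accounting comparison is a real
oracle.

Sentences with two chemicals and two variants (only one pair truly
related) are generated at a configurable rate to exercise the known
failure mode of sentence-local extraction — pairing a drug with a variant
from a different clause. Their pair labels are excluded from the default
labeled set (a flag includes them) because they are intentionally
confusable.

What passing these tests shows: the deterministic rules (alignment,
grammar, filters, collation) are exactly correct on inputs with the stated
structure, and the feature scheme plus classifier can recover a separable
lexical signal (precision ≥ 0.9 / recall ≥ 0.8 at threshold 0.75, five
seeds, 400 train / 100 test per group). What it does not show: performance
on real prose, where trigger vocabulary is unbounded, entities nest in
coordinated clauses, and upstream tagger errors are correlated — the
published precision of pipelines of this design on real annotated
sentences is substantially below 1.

## Problem sizes

Test and acceptance runs use 15–70 documents per corpus (≈ 500+ planted
mentions at 70), 400/100 train/test candidates per group over five seeds,
and 1,000 rows for the collation oracle. These sizes were chosen as the
smallest at which every rule and both classifiers are exercised with
stable statistics; the whole suite runs in seconds.

## Known limitations

* No dependency parser: the between-span features approximate a syntactic
  path and will degrade on long coordinated sentences.
* Sentence segmentation is heuristic; unusual abbreviations can split or
  merge sentences and silently drop straddling mentions (they are logged).
* The HLA colon-doubling rule is undefined for odd-length digit strings;
  the final singleton field is kept and logged.
* rs-id → gene resolution is consumed from upstream ids or an optional
  local table, never computed.
* The chemical allow-list, keyword list and exclusion words ship as small
  documented starter configs; production use should replace them with
  curated versions.
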