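# Methods

This note documents the models and procedures implemented in `gwaskit`, the
parameters that matter, the numerical and design choices made where the
design was genuinely open, and what the offline fixtures do and do not
emulate.

## Data model

A GDM *sample* pairs a region table with an attribute-value metadata list;
a *dataset* is a set of samples under one region schema.  The schema has a
fixed coordinate prefix (`chrom`, `start`, `stop`, `strand`) followed by
declared, typed variable fields.  On disk a sample is two files sharing the
identifier stem: `<id>.gdm` (headerless TSV, columns in schema order) and
`<id>.gdm.meta` (two-column TSV; attributes may repeat, order is
significant).  The schema itself is a declarative XML field list.

Coordinate convention: coordinates are copied from the source without
rebasing.  GWAS Catalog positions are 1-based and BED-style tools are
0-based half-open; because neither convention can be inferred reliably from
the dumps, the package does not guess a rebasing, and the schema document
header records `stop-exclusive` as the interval convention.  Both sources
report SNPs only, so every region is `stop = start + 1` on strand `*`.

Tabs are the format's only reserved character; writers replace embedded tabs
with spaces (the sources are tab-free in practice) so serialization is total.

## Transformation

- GWAS Catalog: the sample unit is one `Studies` entry (one study-trait
  pair; multi-trait accessions are split across entries, and their shared
  association set is replicated into each — later entries get an `__n`
  suffix to keep sample ids unique).  Coordinates come from `CHR_ID` +
  `CHR_POS` when present, else from a `chr<N>:<pos>` token before the first
  `-` in `STRONGEST SNP-RISK ALLELE`; anything else is unresolved and
  logged, never silently dropped.  Chromosome tokens are normalized to
  `chr`-prefixed form ("13" → "chr13") to match the convention of the other
  datasets such files are queried against.
- Ancestry metadata: each of a study's ancestry rows contributes pairs
  suffixed with a 1-based ordinal in file order
  (`broad_ancestral_category_1 … _n`, likewise country/stage/count fields).
- Cohort cardinalities: the relational Cohort row stores per-stage totals
  (cases / controls / individuals / trios, initial and replication).  The
  Catalog dump does not carry them as single fields, so the transformer
  derives `initial_individuals` / `replication_individuals` as stage-wise
  sums of the per-ancestry participant counts; FinnGen manifests carry
  `num_cases` / `num_controls` directly and the rules map them to the
  initial-stage columns.  This is the package's own derivation choice; the
  columns are nullable and any rule file can override the sourcing.
- FinnGen: one sample per manifest endpoint, one region per variant row
  (`#chrom`/`pos`), remaining columns copied verbatim as text.  Variable
  region attributes of both sources are declared `text` and copied as-is;
  numeric interpretation is deferred to consumers, which keeps file
  round-trips exact.

## Relational mapping

Mapping is data, not code: a YAML rules file per source lists anchored
regular-expression patterns over metadata attribute names with a
`table.column` target and a transform (`identity` or nullable `int` cast).
A named `ordinal` capture group routes matches into per-ordinal Ancestry
rows; ordinals must be contiguous from 1.  Unmatched attributes are
preserved verbatim in a spillover table, so mapping is lossless.  Two rules
claiming one attribute with different targets raise a conflict error when
the dataset is loaded.  Cardinality invariants: one Item and exactly one
Cohort per sample; one Ancestry row per distinct ordinal.  The store is
embedded SQLite; `export_store`/`load_store` provide a portable DDL + TSV
dump round trip (row multisets are preserved; SQLite's type affinity makes
the identity hold up to value formatting, which is how the tests compare).

Only the GWAS view of the conceptual model is modeled in detail
(Item–CaseStudy–Cohort–Ancestry plus the knowledge-base tables); the other
views are out of scope here and represented minimally (CaseStudy carries
`pubmed_id` and `source_site`).

## Annotation scoring

Word-level alignment: queries and labels are lowercased, whitespace-split,
and stripped of punctuation at token edges only — internal punctuation is
part of the word ("magnesium:creatinine", "pre-eclampsia" are single
tokens), which the reference examples force.  Raw values split on commas
into independent parsed values; a raw value counts as covered if any of its
parsed values is annotated.

The distance is the minimum-cost order-respecting alignment under
match 0 / adjacent swap 0.5 / label-insertion 1 / query-deletion 2 /
mismatch 2.5, computed by dynamic programming with a Damerau-style
adjacent-transposition extension.  The asymmetric gap costs are forced by
the worked examples: "sneeze" vs "Peroutka sneeze" scores 9 − 1 (extra
*label* word costs 1) while "anorexia nervosa" vs "Anorexia" scores 10 − 2
(extra *query* word costs 2).  A property test proves the DP equal to an
exhaustive enumeration of all alignments for all token lists of length ≤ 4
(deduplicated by token-equality pattern, which fully determines the
distance).

Match scores start from 10 (preferred label) or 9 (synonym); ties between
equally scored labels prefer the preferred label, then the lexicographically
smallest label.  Note one reference row ("magnesium:creatinine ratio
measurement") is a genuine P/S tie at 4.5 under these costs; the package
reports basis P there by the stated tie-break, and tests assert the score.

Suitability is per-ontology `coverage × mean(match_score)` over the run's
annotations, so an ontology that matches via preferred labels outranks one
that matches via synonyms at equal coverage.  Acceptance is consumed from a
configuration map (`data/ontology_acceptance.yaml` by default) — it encodes
community trust and is an input, not a computation.  The annotation score is
`match × (w_suit·suitability + w_acc·acceptance)`, rounded to 2 decimals.
The default weights are fitted by least squares over the packaged reference
table at first use (they land at 0.08 / 0.20 and reproduce all 37 reference
annotation scores within ±0.01); both are configurable.

### Ontology-set selection

Ontologies are ranked by suitability (or coverage, via a flag).  The
top-ranked ontology annotates what it can; each subsequent ontology is
consulted only for still-unmatched values and joins the set only if it makes
progress.  Selection stops at the coverage target (default 0.85) or at a
fixed point of the unmatched set, which guarantees termination; coverage is
monotone nondecreasing along the chosen sequence.  Set metrics are computed
over each covered value's annotation from the first ontology that covered
it: `SetCoverage` is the covered fraction; `SetScore` averages
`match_score × acceptance` over covered values (the literal reading of
"average match score weighted by acceptance" — the averaging denominator is
ambiguous, and this implementation uses annotated values); `SetSuitability`
applies the suitability formula to that same union of annotations.

### Enrichment procedure

For each unlinked cohort trait: knowledge-base lookup first (exact
case-insensitive match on stored preferred labels, then synonyms, within the
chosen ontologies) — a hit links immediately without querying the term
source.  Otherwise all candidate terms from the chosen ontologies are
scored; candidates with non-positive match score are discarded as
non-matches.  If the best candidate reaches the minimum match score
(default 5), the value is auto-linked and the term is materialized in the
knowledge base together with its ancestors and descendants up to a
configurable depth (default 3 levels), recording `is_a`/`part_of` kinds;
dangling hierarchy references are skipped with a warning.  Below-threshold
values are queued for manual curation with up to five ranked suggestions.
Original trait values are never modified, and reruns are no-ops on already
linked cohorts.  Cross-source common concepts are the vocabulary terms
referenced by cohorts of at least two distinct dataset names.

## Fixtures

Generators are pure functions of `(seed, parameters)` (stdlib `Random`), so
repeated calls are byte-identical.  They emulate the *structure* of the
sources: three-file Catalog dumps with multi-ancestry studies, a controlled
number of associations lacking `CHR_ID` (alternating between
risk-allele-resolvable and unresolvable), FinnGen manifests whose first
endpoints can reuse Catalog trait strings to exercise cross-source overlap,
and a JSON term corpus containing the reference-table exemplar terms plus a
five-deep hierarchy chain.  They do **not** emulate realistic p-value or
effect-size distributions, linkage structure, or corpus-scale trait
diversity — so passing tests demonstrate correctness of the mechanics
(conservation, scoring, round trips), not statistical properties of real
GWAS corpora.  Ground truth (planted counts and labels) is written as JSON
next to each fixture so tests never re-derive it by parsing.

Default problem sizes in tests and in `scripts/acceptance.py` (a few studies
× a few associations, 24-value selection fixtures, alignment oracle over all
length-≤4 word lists) are chosen so each check runs in seconds while still
exercising every code path; all scale linearly if enlarged.

## Known limitations

- Live download and live term-search services are out of scope; the
  `TermSource` interface ships an offline JSON-corpus backend (used
  everywhere) and a thin HTTP backend with the same surface, untested by the
  suite.
- Corpus-scale statistics (thousands of traits, hundreds of ontologies)
  require the real releases and services and are not reproduced here.
- The interval demo queries implement deliberately minimal semantics
  (gap distance, leftmost/shortest tie-break) — they demonstrate that
  integrated datasets are queryable, not a full genomic query engine.
- No allele normalization, liftover, or p-value filtering at transform time;
  region attributes ride along as text.
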