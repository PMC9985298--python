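# gwaskit

Genome-wide association studies (GWAS) publish their results as summary
statistics — per-variant associations between SNPs and phenotypic traits —
but every source ships them in its own shape: the NHGRI-EBI GWAS Catalog as
three joined TSV dumps (`Studies`, `Ancestry`, `Associations`), FinnGen as a
manifest of *endpoints* with one summary-statistics file each.  That
heterogeneity blocks the obvious next step: analysing GWAS hits *together
with* other genomic signals (somatic mutations, reference variation,
annotations, epigenetic marks) that already live in common formats.

`gwaskit` is a pipeline for researchers and data engineers who curate such
repositories.  It

1. **ingests** local dumps of both sources into typed rows,
2. **transforms** them into Genomic Data Model (GDM) datasets — each sample
   is a region file (1-bp SNP intervals with a fixed `chrom/start/stop/strand`
   prefix plus source attributes) paired with an attribute-value metadata
   file sharing the same identifier stem,
3. **maps** the metadata into a relational star schema (Item = one study,
   with exactly one Cohort carrying the trait and case/control cardinalities,
   and any number of ordinal-numbered Ancestry rows) driven entirely by
   declarative per-source rule files,
4. **enriches** cohort trait names with ontology terms (EFO, NCIT, ...)
   through a scored annotation algorithm, building a knowledge base of
   vocabulary / synonyms / cross-references / `is_a`-`part_of` hierarchies,
   and
5. **flattens** the integrated result back into GDM metadata files, leaving
   region data byte-identical.

Deterministic fixture generators emulate both sources and an ontology term
corpus, so the whole pipeline runs and is tested entirely offline.

## The annotation score

Trait labels are free text; ontology terms have a preferred label and
synonyms.  The match between a parsed trait value and a term label is scored
by a word-level global alignment in the Needleman–Wunsch style, aligning
*words* instead of characters with costs

| operation                     | cost |
|-------------------------------|------|
| matching word                 | 0    |
| adjacent-word swap            | 0.5  |
| label-only word (insertion)   | 1    |
| query-only word (deletion)    | 2    |
| mismatched word               | 2.5  |

so the alignment minimises deletions and prefers swaps to indels or
mismatches.  The **match_score** is `10 − distance` against a preferred
label, `9 − distance` against a synonym.  Per ontology *o*,

    coverage(o)    = fraction of raw values annotated by o
    suitability(o) = coverage(o) × mean(match_scores of o's annotations)

and every candidate annotation is ranked by

    annotation_score = match_score × (w_suit · suitability + w_acc · acceptance)

where *acceptance* is an externally supplied per-ontology trust score and
the default weights (w_suit = 0.08, w_acc = 0.20) are recovered at run time
by least squares from the packaged reference table of worked examples —
never hard-coded.  Values whose best candidate reaches match_score ≥ 5 are
linked automatically; the rest go to a manual-curation queue with ranked
suggestions.  A greedy selector builds a small ontology set, consulting
ontologies in rank order for the still-unmatched values until coverage
reaches a target (default 0.85) or a fixed point.

## Worked example

```python
from gwaskit import tokenize, word_distance, match_score, parse_raw_value, default_weights
from gwaskit.terms import TermRecord

word_distance(tokenize("anorexia nervosa"), tokenize("Anorexia"))
# 2.0                      -> match_score 10 - 2.0 = 8 against the preferred label

term = TermRecord("EFO", "EFO_0004919", "metastasis free survival",
                  synonyms=("metastasis free survival time",))
(pv,) = parse_raw_value("Event free survival time")
c = match_score(pv, term)
c.match_score, c.basis, c.matched_label
# (6.5, 'S', 'metastasis free survival time')
#   one substitution (2.5) against the synonym: 9 - 2.5 = 6.5

default_weights()
# (0.07998670529876499, 0.20001345798494807)   # least-squares fit, ~ (0.08, 0.20)
```

The same flows are scriptable from the shell; this runs the whole pipeline on
generated fixtures:

```
gwaskit fixtures catalog --seed 3 --n-studies 2 --out-dir src
gwaskit fixtures ontology --out terms.json
gwaskit transform --source gwas_catalog --input-dir src --out-dir gdm
# 2 samples, 10 regions -> gdm/gwas_catalog
gwaskit map --dataset-dir gdm/gwas_catalog --rules gwas_catalog --store store.db
# items=2 cohorts=2 ancestries=4
gwaskit enrich --store store.db --terms terms.json --ontologies EFO,NCIT,HP
# linked=2 queued=0 kb_hits=0
gwaskit flatten --store store.db --dataset-dir gdm/gwas_catalog --out-dir flat
gwaskit demo-query closest --reference gdm/gwas_catalog --experiment gdm/gwas_catalog
```

Each linked cohort gains a `trait_name_tid` pointing into the knowledge
base; the flattened metadata files carry the link as
`cohort.trait_name_tid` / `cohort.trait_ontology_id` pairs next to the
original, untouched source pairs.

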