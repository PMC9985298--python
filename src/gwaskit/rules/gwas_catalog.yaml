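# Mapping rules for GWAS Catalog metadata pairs.
# Patterns are anchored regexes over attribute names; the named group
# `ordinal` routes a match into the Ancestry row with that 1-based ordinal.
- {attribute_pattern: 'study_accession', target_table: item, target_column: source_id}
- {attribute_pattern: 'pubmed_id', target_table: case_study, target_column: pubmed_id}
- {attribute_pattern: 'disease_trait', target_table: cohort, target_column: trait_name}
- {attribute_pattern: 'initial_individuals', target_table: cohort, target_column: initial_individuals, value_transform: int}
- {attribute_pattern: 'replication_individuals', target_table: cohort, target_column: replication_individuals, value_transform: int}
- {attribute_pattern: 'initial_cases', target_table: cohort, target_column: initial_cases, value_transform: int}
- {attribute_pattern: 'initial_controls', target_table: cohort, target_column: initial_controls, value_transform: int}
- {attribute_pattern: 'initial_trios', target_table: cohort, target_column: initial_trios, value_transform: int}
- {attribute_pattern: 'replication_cases', target_table: cohort, target_column: replication_cases, value_transform: int}
- {attribute_pattern: 'replication_controls', target_table: cohort, target_column: replication_controls, value_transform: int}
- {attribute_pattern: 'replication_trios', target_table: cohort, target_column: replication_trios, value_transform: int}
- {attribute_pattern: 'broad_ancestral_category_(?P<ordinal>\d+)', target_table: ancestry, target_column: broad_ancestral_category}
- {attribute_pattern: 'country_of_origin_(?P<ordinal>\d+)', target_table: ancestry, target_column: country_of_origin}
- {attribute_pattern: 'country_of_recruitment_(?P<ordinal>\d+)', target_table: ancestry, target_column: country_of_recruitment}
- {attribute_pattern: 'number_of_individuals_(?P<ordinal>\d+)', target_table: ancestry, target_column: number_of_individuals, value_transform: int}
- {attribute_pattern: 'stage_(?P<ordinal>\d+)', target_table: ancestry, target_column: stage}
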