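# Mapping rules for FinnGen endpoint metadata pairs.
- {attribute_pattern: 'phenocode', target_table: item, target_column: source_id}
- {attribute_pattern: 'phenostring', target_table: cohort, target_column: trait_name}
- {attribute_pattern: 'num_cases', target_table: cohort, target_column: initial_cases, value_transform: int}
- {attribute_pattern: 'num_controls', target_table: cohort, target_column: initial_controls, value_transform: int}
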