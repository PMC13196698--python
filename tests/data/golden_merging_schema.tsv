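original_field	original_field_completeness	original_field_unique_values	curated_field	curated_field_completeness	curated_field_unique_values
age	0.7000	14	age	0.6500	13
drinks	0.5500	2	drink	0.5500	2
fruit_a	0.6000	4	fruit	0.8000	2
fruit_b	0.3000	4	fruit	0.8000	2
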