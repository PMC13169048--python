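# Default ICD-10 depressive-episode rule table, dialysis administration:
# appetite, weight and impairment items not asked or scored.
min_core_for_episode: 2
mild_total_range: [4, 5]
moderate_total_range: [6, 7]
severe_min_total: 8
severe_requires_all_core: true
min_duration_weeks: 2
somatic_min_count: 3
excluded_items: [appetite_change, weight_change, impairment]
imputation_mode: as_administered
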