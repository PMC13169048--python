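# Participant CSV data dictionary

One row per participant, wide format. Column names and levels are defined
machine-readably in `dialdep.schema`; `dialdep validate <csv>` enforces
this dictionary with per-row/column error reporting. Missing values are
empty cells; missing covariates exclude a row from regression
(complete-case) but not from descriptive denominators.

## Identity and demographics

| column | type | values |
|---|---|---|
| `participant_id` | string | opaque, unique |
| `age` | number | years, 0 < age < 120 |
| `sex` | categorical | `male`, `female` |
| `ethnicity` | categorical | `white_british`, `south_asian`, `black`, `other` |
| `education` | categorical | `none`, `school_incomplete`, `school_complete`, `university_or_apprenticeship`, `other` |
| `occupation` | categorical | `unemployed`, `employed`, `retired`, `student`, `housewife`, `off_sick`, `other` |
| `marital_status` | categorical | `single`, `married_or_cohabiting`, `separated_or_divorced`, `widowed` |
| `smoking` | categorical | `never`, `past`, `current` |
| `alcohol` | binary | 0/1, any current alcohol use |

## Threatening life events (previous 12 months), binary 0/1

`event_illness_self`, `event_illness_relative`,
`event_death_parent_child_spouse`, `event_death_friend_or_relative`,
`event_marital_separation`, `event_relationship_breakup`,
`event_friend_neighbour_problems`, `event_unemployment_seeking`,
`event_sacked_from_job`, `event_financial_crisis`,
`event_police_or_courts`, `event_loss_or_theft`

## Discrimination (previous 12 months), binary 0/1

`discrim_unfair_treatment_work`, `discrim_job_refusal`,
`discrim_physical_attack`, `discrim_property_damage`,
`discrim_racial_insults`

## Comorbidities (from clinical records), binary 0/1

`como_hypertension`, `como_diabetes_t1`, `como_diabetes_t2`,
`como_obesity`, `como_cardiovascular`, `como_cancer_current_or_past`,
`como_copd`, `como_autoimmune`

## CIS-R depression section

Binary endorsements (0/1): `cisr_depressed_mood`, `cisr_loss_of_interest`,
`cisr_fatigue` (core), `cisr_concentration`, `cisr_self_esteem_low`,
`cisr_guilt`, `cisr_pessimism_or_suicidality`, `cisr_sleep_disturbance`,
`cisr_agitation_or_retardation` (additional). The appetite-change,
weight-change and impairment items have no columns: they are not
administered under the default protocol (the sensitivity mode imputes
them, it does not read them).

`cisr_duration_weeks`: episode duration in weeks, ≥ 0.

Somatic-syndrome criteria, binary 0/1: `somatic_diurnal_variation`,
`somatic_early_waking`, `somatic_loss_of_reactivity`,
`somatic_libido_loss`, `somatic_observed_retardation_agitation`.

## Screening instruments

| column | range |
|---|---|
| `phq2_1`, `phq2_2` | integers 0–3 |
| `hamd_1` … `hamd_17` | integers, per-item maxima 4,4,4,2,2,2,4,4,4,4,4,2,2,2,4,2,2 |
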