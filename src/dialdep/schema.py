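"""Participant-table column dictionary shared across the pipeline.

One row per participant, wide format.  See ``docs/data_dictionary.md`` for
the full prose dictionary; this module is the single machine-readable
source of column names, categorical levels and item ranges.
"""

from __future__ import annotations

from .cisr import ADDITIONAL_ITEMS, CORE_ITEMS
from .screening import HAMD_ITEM_MAX

# 12-item threatening-life-events inventory (previous 12 months).
LIFE_EVENTS = (
    "illness_self",              # serious illness, injury or assault to self
    "illness_relative",          # serious illness, injury or assault to a close relative
    "death_parent_child_spouse", # death of a parent, child or spouse
    "death_friend_or_relative",  # death of a close family friend or other relative
    "marital_separation",        # separation due to marital difficulties
    "relationship_breakup",      # end of a steady relationship
    "friend_neighbour_problems", # serious problem with a close friend, neighbour or relative
    "unemployment_seeking",      # unemployed / seeking work unsuccessfully > 1 month
    "sacked_from_job",           # sacked or made redundant
    "financial_crisis",          # major financial crisis
    "police_or_courts",          # problems with police or a court appearance
    "loss_or_theft",             # something valued lost, stolen or damaged
)

# Five discrimination questions (previous 12 months).
DISCRIMINATION_ITEMS = (
    "unfair_treatment_work",
    "job_refusal",
    "physical_attack",
    "property_damage",
    "racial_insults",
)

COMORBIDITIES = (
    "hypertension",
    "diabetes_t1",
    "diabetes_t2",
    "obesity",
    "cardiovascular",
    "cancer_current_or_past",
    "copd",
    "autoimmune",
)

CATEGORICAL_LEVELS = {
    "sex": ("male", "female"),
    "ethnicity": ("white_british", "south_asian", "black", "other"),
    "education": (
        "none",
        "school_incomplete",
        "school_complete",
        "university_or_apprenticeship",
        "other",
    ),
    "occupation": (
        "unemployed",
        "employed",
        "retired",
        "student",
        "housewife",
        "off_sick",
        "other",
    ),
    "marital_status": ("single", "married_or_cohabiting", "separated_or_divorced", "widowed"),
    "smoking": ("never", "past", "current"),
}

SOMATIC_COLUMNS = (
    "somatic_diurnal_variation",
    "somatic_early_waking",
    "somatic_loss_of_reactivity",
    "somatic_libido_loss",
    "somatic_observed_retardation_agitation",
)

CISR_SYMPTOM_COLUMNS = tuple(f"cisr_{i}" for i in CORE_ITEMS + ADDITIONAL_ITEMS)
EVENT_COLUMNS = tuple(f"event_{e}" for e in LIFE_EVENTS)
DISCRIM_COLUMNS = tuple(f"discrim_{d}" for d in DISCRIMINATION_ITEMS)
COMORBIDITY_COLUMNS = tuple(f"como_{c}" for c in COMORBIDITIES)
PHQ2_COLUMNS = ("phq2_1", "phq2_2")
HAMD_COLUMNS = tuple(f"hamd_{i}" for i in range(1, 18))

ALL_COLUMNS = (
    ("participant_id", "age", "sex", "ethnicity", "education", "occupation",
     "marital_status", "smoking", "alcohol")
    + EVENT_COLUMNS
    + DISCRIM_COLUMNS
    + COMORBIDITY_COLUMNS
    + CISR_SYMPTOM_COLUMNS
    + ("cisr_duration_weeks",)
    + SOMATIC_COLUMNS
    + PHQ2_COLUMNS
    + HAMD_COLUMNS
)

BINARY_COLUMNS = (
    ("alcohol",)
    + EVENT_COLUMNS
    + DISCRIM_COLUMNS
    + COMORBIDITY_COLUMNS
    + CISR_SYMPTOM_COLUMNS
    + SOMATIC_COLUMNS
)

ITEM_RANGES = {**{c: (0, 3) for c in PHQ2_COLUMNS},
               **{c: (0, mx) for c, mx in zip(HAMD_COLUMNS, HAMD_ITEM_MAX)}}
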