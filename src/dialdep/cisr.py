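"""ICD-10 depressive-episode classification from CIS-R depression-section items.

The Clinical Interview Schedule-Revised (CIS-R) depression section records
endorsement of the three ICD-10 core symptoms (depressed mood, loss of
interest, fatigue), six further symptoms, episode duration, and the somatic
qualifier criteria.  An algorithmic rule table maps these to the ICD-10 F32
grades, here collapsed to ``none`` / ``mild`` / ``moderate_severe`` as used
in psychiatric-morbidity survey analyses.

The engine implements a dialysis-adapted administration in which the
appetite-change, weight-change and functional-impairment items are not asked
(their somatic burden is near-universal on haemodialysis), plus a sensitivity
mode that re-classifies every participant as if each excluded item were
present.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

__all__ = [
    "CORE_ITEMS",
    "ADDITIONAL_ITEMS",
    "OPTIONAL_ITEMS",
    "SOMATIC_CRITERIA",
    "Category",
    "ImputationMode",
    "SymptomProfile",
    "RuleTable",
    "DepressionDiagnosis",
    "classify",
    "apply_sensitivity",
    "classify_cohort",
    "ClassificationError",
    "RuleConfigError",
]

#: ICD-10 F32 core symptoms; exactly these three.
CORE_ITEMS = ("depressed_mood", "loss_of_interest", "fatigue")

#: Additional symptoms administered under the default (dialysis) protocol.
ADDITIONAL_ITEMS = (
    "concentration",
    "self_esteem_low",
    "guilt",
    "pessimism_or_suicidality",
    "sleep_disturbance",
    "agitation_or_retardation",
)

#: Items representable but unset under the default administration.
OPTIONAL_ITEMS = ("appetite_change", "weight_change", "impairment")

ALL_ITEMS = CORE_ITEMS + ADDITIONAL_ITEMS + OPTIONAL_ITEMS

#: ICD-10 somatic-syndrome criteria still assessable once appetite and
#: weight items are dropped from the interview.
SOMATIC_CRITERIA = frozenset(
    {
        "diurnal_variation",
        "early_waking",
        "loss_of_reactivity",
        "libido_loss",
        "observed_retardation_agitation",
    }
)


class Category(enum.IntEnum):
    """Ordered diagnosis bands; moderate and severe are reported combined."""

    none = 0
    mild = 1
    moderate_severe = 2

    def __str__(self) -> str:  # friendlier CSV/JSON output
        return self.name


class ImputationMode(str, enum.Enum):
    as_administered = "as_administered"
    impute_present = "impute_present"


class ClassificationError(ValueError):
    """Invalid participant input (e.g. negative duration)."""


class RuleConfigError(ValueError):
    """Invalid rule-table configuration (e.g. unknown excluded item)."""


@dataclass(frozen=True)
class SymptomProfile:
    """One participant's depression-section endorsements.

    ``appetite_change``, ``weight_change`` and ``impairment`` default to
    ``None`` (not administered); they are only consulted when a rule table
    imputes them.
    """

    depressed_mood: bool = False
    loss_of_interest: bool = False
    fatigue: bool = False
    concentration: bool = False
    self_esteem_low: bool = False
    guilt: bool = False
    pessimism_or_suicidality: bool = False
    sleep_disturbance: bool = False
    agitation_or_retardation: bool = False
    appetite_change: Optional[bool] = None
    weight_change: Optional[bool] = None
    impairment: Optional[bool] = None
    duration_weeks: float = 0.0
    somatic_flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.duration_weeks < 0:
            raise ClassificationError(
                f"duration_weeks must be >= 0, got {self.duration_weeks}"
            )
        flags = frozenset(self.somatic_flags)
        unknown = flags - SOMATIC_CRITERIA
        if unknown:
            raise ClassificationError(f"unknown somatic criteria: {sorted(unknown)}")
        object.__setattr__(self, "somatic_flags", flags)


@dataclass(frozen=True)
class RuleTable:
    """Declarative thresholds defining the classification algorithm.

    Defaults operationalise ICD-10 F32 as in the CIS-R / Adult Psychiatric
    Morbidity Survey tradition: an episode needs >= 2 weeks duration and
    >= 2 core symptoms; mild = 4-5 total symptoms, moderate = 6-7, severe
    >= 8 with all three core symptoms.  The somatic-syndrome threshold is
    3 of the 5 criteria still administered.
    """

    min_core_for_episode: int = 2
    mild_total_range: tuple[int, int] = (4, 5)
    moderate_total_range: tuple[int, int] = (6, 7)
    severe_min_total: int = 8
    severe_requires_all_core: bool = True
    min_duration_weeks: float = 2.0
    somatic_min_count: int = 3
    excluded_items: frozenset = frozenset(OPTIONAL_ITEMS)
    imputation_mode: ImputationMode = ImputationMode.as_administered

    def __post_init__(self):
        object.__setattr__(self, "excluded_items", frozenset(self.excluded_items))
        object.__setattr__(
            self, "imputation_mode", ImputationMode(self.imputation_mode)
        )
        unknown = self.excluded_items - set(ALL_ITEMS)
        if unknown:
            raise RuleConfigError(f"unknown item(s) in excluded_items: {sorted(unknown)}")
        if self.min_core_for_episode not in (2, 3):
            raise RuleConfigError("min_core_for_episode must be 2 or 3")
        lo_m, hi_m = self.mild_total_range
        lo_mod, hi_mod = self.moderate_total_range
        if not (lo_m <= hi_m < lo_mod <= hi_mod < self.severe_min_total):
            raise RuleConfigError(
                "severity bands must be disjoint and ordered mild < moderate < severe"
            )
        if self.min_duration_weeks < 0:
            raise RuleConfigError("min_duration_weeks must be >= 0")

    # ------------------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "RuleTable":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise RuleConfigError(f"unknown rule-table keys: {sorted(unknown)}")
        d = dict(d)
        for k in ("mild_total_range", "moderate_total_range"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)

    def to_dict(self) -> dict:
        return {
            "min_core_for_episode": self.min_core_for_episode,
            "mild_total_range": list(self.mild_total_range),
            "moderate_total_range": list(self.moderate_total_range),
            "severe_min_total": self.severe_min_total,
            "severe_requires_all_core": self.severe_requires_all_core,
            "min_duration_weeks": self.min_duration_weeks,
            "somatic_min_count": self.somatic_min_count,
            "excluded_items": sorted(self.excluded_items),
            "imputation_mode": self.imputation_mode.value,
        }

    @classmethod
    def from_yaml(cls, path) -> "RuleTable":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


#: The administration used in the source study: appetite / weight /
#: impairment neither asked nor scored.
PAPER_DEFAULT_RULES = RuleTable()

#: Post-hoc sensitivity re-run: every excluded item treated as present.
SENSITIVITY_RULES = RuleTable(imputation_mode=ImputationMode.impute_present)


@dataclass(frozen=True)
class DepressionDiagnosis:
    category: Category
    severe_subflag: bool
    somatic_syndrome: bool
    core_count: int
    additional_count: int

    @property
    def total_count(self) -> int:
        return self.core_count + self.additional_count


def apply_sensitivity(profile: SymptomProfile, rules: RuleTable) -> SymptomProfile:
    """Return a copy of ``profile`` with every excluded item set to endorsed.

    Mirrors the post-hoc re-analysis in which each un-administered item is
    treated as present for every participant.  Idempotent; all other fields
    are unchanged.
    """
    if rules.imputation_mode is not ImputationMode.impute_present:
        raise RuleConfigError("apply_sensitivity requires imputation_mode=impute_present")
    return replace(profile, **{item: True for item in rules.excluded_items})


def classify(profile: SymptomProfile, rules: RuleTable) -> DepressionDiagnosis:
    """Grade one profile against a rule table.

    Deterministic.  Under ``as_administered``, items listed in
    ``rules.excluded_items`` never influence the output, whatever their
    stored values; under ``impute_present`` they are counted as endorsed.
    """
    if rules.imputation_mode is ImputationMode.impute_present:
        profile = apply_sensitivity(profile, rules)

    def endorsed(item: str) -> bool:
        if item in rules.excluded_items and rules.imputation_mode is ImputationMode.as_administered:
            return False
        return bool(getattr(profile, item))

    core = sum(endorsed(i) for i in CORE_ITEMS)
    additional = sum(endorsed(i) for i in ADDITIONAL_ITEMS + OPTIONAL_ITEMS)
    total = core + additional

    category = Category.none
    severe = False
    if (
        profile.duration_weeks >= rules.min_duration_weeks
        and core >= rules.min_core_for_episode
        and total >= rules.mild_total_range[0]
    ):
        if total <= rules.mild_total_range[1]:
            category = Category.mild
        else:
            category = Category.moderate_severe
            severe = total >= rules.severe_min_total and (
                core == len(CORE_ITEMS) or not rules.severe_requires_all_core
            )

    somatic = (
        category is not Category.none
        and len(profile.somatic_flags) >= rules.somatic_min_count
    )
    return DepressionDiagnosis(
        category=category,
        severe_subflag=severe,
        somatic_syndrome=somatic,
        core_count=core,
        additional_count=additional,
    )


def classify_cohort(
    profiles: Sequence[SymptomProfile], rules: RuleTable
) -> list[DepressionDiagnosis]:
    """Element-wise :func:`classify`; order preserved, errors indexed."""
    if len(profiles) == 0:
        raise ClassificationError("empty cohort")
    out = []
    for i, p in enumerate(profiles):
        try:
            out.append(classify(p, rules))
        except ClassificationError as exc:
            raise ClassificationError(f"participant index {i}: {exc}") from exc
    return out
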