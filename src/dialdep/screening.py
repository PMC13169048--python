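"""PHQ-2 and HAMD-17 scoring, binary positivity, and concordance with the
ICD-10 reference diagnosis.

Thresholds follow routine clinical use: PHQ-2 total >= 3, HAMD-17 total
>= 19.  Partially missing administrations are never prorated; the record is
excluded from that instrument's summary and the exclusion is counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cisr import Category, DepressionDiagnosis

__all__ = [
    "PHQ2_THRESHOLD",
    "HAMD_THRESHOLD",
    "HAMD_ITEM_MAX",
    "ScreeningResult",
    "ConcordanceSummary",
    "score_phq2",
    "score_hamd",
    "concordance",
    "ScoringError",
    "MissingItemError",
]

PHQ2_THRESHOLD = 3
HAMD_THRESHOLD = 19

# Standard 17-item Hamilton scale: nine items rated 0-4 (mood, guilt,
# suicide, work/interests, retardation, agitation, psychic anxiety, somatic
# anxiety, hypochondriasis) and eight rated 0-2 (the three insomnias,
# gastrointestinal, general somatic, genital, weight loss, insight).
# Maximum total 9*4 + 8*2 = 52.
HAMD_ITEM_MAX = (4, 4, 4, 2, 2, 2, 4, 4, 4, 4, 4, 2, 2, 2, 4, 2, 2)
assert sum(HAMD_ITEM_MAX) == 52


class ScoringError(ValueError):
    """Item value outside its published range."""


class MissingItemError(ValueError):
    """Missing item under the no-proration policy."""


@dataclass(frozen=True)
class ScreeningResult:
    phq2_score: int
    phq2_positive: bool
    hamd_score: int
    hamd_positive: bool


def _check_items(items, maxima, instrument: str) -> list[int]:
    items = list(items)
    if len(items) != len(maxima):
        raise ScoringError(
            f"{instrument} expects {len(maxima)} items, got {len(items)}"
        )
    out = []
    for i, (v, mx) in enumerate(zip(items, maxima), start=1):
        if v is None or (isinstance(v, float) and np.isnan(v)):
            raise MissingItemError(f"{instrument} item {i} is missing (no proration)")
        iv = int(v)
        if iv != v or not 0 <= iv <= mx:
            raise ScoringError(f"{instrument} item {i} = {v!r} outside 0..{mx}")
        out.append(iv)
    return out


def score_phq2(items: Sequence[int]) -> tuple[int, bool]:
    """Sum the two PHQ-2 items (each 0-3); positive iff total >= 3."""
    vals = _check_items(items, (3, 3), "PHQ2")
    score = sum(vals)
    return score, score >= PHQ2_THRESHOLD


def score_hamd(items: Sequence[int]) -> tuple[int, bool]:
    """Sum the 17 HAMD items against per-item maxima; positive iff total >= 19."""
    vals = _check_items(items, HAMD_ITEM_MAX, "HAMD")
    score = sum(vals)
    return score, score >= HAMD_THRESHOLD


@dataclass(frozen=True)
class ConcordanceSummary:
    """Agreement between a binary screen and the reference diagnosis.

    ``two_by_two`` rows are screen +/-, columns diagnosis +/-:
    [[a, b], [c, d]] with a = true positives.  Proportions with a zero
    denominator are reported as ``None``, never 0.
    """

    two_by_two: tuple[tuple[int, int], tuple[int, int]]
    sensitivity: Optional[float]
    specificity: Optional[float]
    positive_predictive_value: Optional[float]
    negative_predictive_value: Optional[float]
    kappa: Optional[float]

    @property
    def n(self) -> int:
        (a, b), (c, d) = self.two_by_two
        return a + b + c + d


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def concordance(
    screen_positive: Sequence[bool],
    diagnoses: Sequence[DepressionDiagnosis | Category],
    positive_class: str = "moderate_severe",
) -> ConcordanceSummary:
    """Cross-tabulate screen positivity against the ICD-10 diagnosis.

    ``positive_class`` selects the diagnostic definition of a case:
    ``"moderate_severe"`` (the treatment-relevant band) or
    ``"any_depression"`` (mild or worse).
    """
    if positive_class not in ("moderate_severe", "any_depression"):
        raise ValueError(f"unknown positive_class {positive_class!r}")
    if len(screen_positive) != len(diagnoses):
        raise ValueError(
            f"length mismatch: {len(screen_positive)} screens vs {len(diagnoses)} diagnoses"
        )
    if len(diagnoses) == 0:
        raise ValueError("empty input")

    cut = Category.moderate_severe if positive_class == "moderate_severe" else Category.mild
    a = b = c = d = 0
    for s, dx in zip(screen_positive, diagnoses):
        cat = dx.category if isinstance(dx, DepressionDiagnosis) else Category(dx)
        case = cat >= cut
        if s and case:
            a += 1
        elif s:
            b += 1
        elif case:
            c += 1
        else:
            d += 1

    n = a + b + c + d
    p_obs = (a + d) / n
    # chance agreement from the margins (Cohen)
    p_exp = ((a + b) * (a + c) + (c + d) * (b + d)) / n**2
    kappa = None if p_exp == 1.0 else (p_obs - p_exp) / (1 - p_exp)

    return ConcordanceSummary(
        two_by_two=((a, b), (c, d)),
        sensitivity=_ratio(a, a + c),
        specificity=_ratio(d, b + d),
        positive_predictive_value=_ratio(a, a + b),
        negative_predictive_value=_ratio(d, c + d),
        kappa=kappa,
    )
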