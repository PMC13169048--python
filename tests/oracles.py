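"""Independent reference implementations used only to check the package.

These deliberately share no code with ``dialdep``: the diagnostic oracle is
a literal transcription of the ICD-10 F32 counting rules, and the Fisher
oracle enumerates the hypergeometric support directly.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import hypergeom

CORE = frozenset({"depressed_mood", "loss_of_interest", "fatigue"})
ADMINISTERED = CORE | {
    "concentration",
    "self_esteem_low",
    "guilt",
    "pessimism_or_suicidality",
    "sleep_disturbance",
    "agitation_or_retardation",
}
EXCLUDED = frozenset({"appetite_change", "weight_change", "impairment"})


def reference_icd10(
    endorsed: frozenset[str],
    duration_weeks: float,
    n_somatic: int,
    impute_excluded: bool = False,
) -> tuple[str, bool]:
    """Literal ICD-10 F32 transcription: (category, somatic_syndrome).

    Episode: duration >= 2 weeks, >= 2 of the 3 core symptoms, total >= 4.
    Mild 4-5 symptoms, moderate/severe >= 6.  Somatic syndrome: >= 3 of the
    5 administered somatic criteria, only when an episode is present.
    """
    items = set(endorsed & ADMINISTERED)
    if impute_excluded:
        items |= set(EXCLUDED)
    core = len(items & CORE)
    total = len(items)
    if duration_weeks < 2 or core < 2 or total < 4:
        return "none", False
    category = "mild" if total <= 5 else "moderate_severe"
    return category, n_somatic >= 3


def fisher_2x2_exact(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by full enumeration of the hypergeometric support.

    Sums P(A = k) over all k with fixed margins whose point probability does
    not exceed that of the observed table (small relative tolerance for
    floating-point ties).
    """
    n = a + b + c + d
    r1, c1 = a + b, a + c
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, c1, r1)
    p_obs = hypergeom.pmf(a, n, c1, r1)
    return float(pmf[pmf <= p_obs * (1 + 1e-7)].sum())
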