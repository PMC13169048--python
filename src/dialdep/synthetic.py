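"""Synthetic haemodialysis-cohort generator.

The study population this emulates is a 300-person maintenance-haemodialysis
cohort from a deprived, ethnically diverse urban catchment: mostly older
adults, heavy comorbidity burden, frequent adverse life events, and an
ICD-10 moderate/severe depression prevalence of about 8%.

Generation proceeds in layers:

1. covariates (demographics, comorbidities with ethnicity-specific
   prevalences, life events, discrimination) from configured marginals;
2. a true diagnosis label drawn from a logistic outcome model over named
   covariate effects (log odds ratios), mild cases assigned among
   non-cases at a fixed conditional rate;
3. a CIS-R symptom profile constructed conditional on the true label so the
   rule engine recovers it exactly (``fidelity=1``; lower values inject
   label-inconsistent profiles for misclassification studies);
4. PHQ-2 / HAMD-17 items from label-conditional distributions calibrated so
   screening positivity exceeds diagnosed prevalence, as observed when
   screening scales are compared with structured diagnostic interviews;
5. per-covariate missingness, so complete-case attrition is realistic.

Everything is driven by one :class:`CohortConfig`; ``preset_paperlike``
returns the configuration used throughout the documentation, whose four
outcome effects equal the published final-model odds ratios and whose
intercept is solved so marginal diagnosed prevalence is 8%.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from . import schema
from .cisr import ADDITIONAL_ITEMS, CORE_ITEMS, Category
from .screening import HAMD_ITEM_MAX

__all__ = ["CohortConfig", "generate", "preset_paperlike", "solve_intercept"]


# ---------------------------------------------------------------------------
# Defaults (documented in docs/methods.md)

DEFAULT_DEMOGRAPHICS = {
    "sex": {"male": 0.60, "female": 0.40},
    "ethnicity": {"white_british": 0.30, "south_asian": 0.35, "black": 0.25, "other": 0.10},
    "education": {
        "none": 0.10,
        "school_incomplete": 0.20,
        "school_complete": 0.35,
        "university_or_apprenticeship": 0.25,
        "other": 0.10,
    },
    "occupation": {
        "unemployed": 0.15,
        "employed": 0.20,
        "retired": 0.40,
        "student": 0.02,
        "housewife": 0.08,
        "off_sick": 0.10,
        "other": 0.05,
    },
    "marital_status": {
        "single": 0.25,
        "married_or_cohabiting": 0.45,
        "separated_or_divorced": 0.15,
        "widowed": 0.15,
    },
    "smoking": {"never": 0.55, "past": 0.30, "current": 0.15},
}

#: Mean age by ethnicity (the minority groups skew younger), common SD 14.
DEFAULT_AGE_MEANS = {"white_british": 64.0, "south_asian": 57.0, "black": 57.0, "other": 58.0}
DEFAULT_AGE_SD = 14.0

DEFAULT_ALCOHOL_P = 0.35

DEFAULT_COMORBIDITY = {
    "hypertension": 0.75,
    "diabetes_t1": 0.05,
    "diabetes_t2": 0.35,
    "obesity": 0.20,
    "cardiovascular": 0.30,
    "cancer_current_or_past": 0.12,
    "copd": 0.08,
    "autoimmune": 0.10,
}

#: Ethnicity-specific comorbidity prevalences (type 2 diabetes highest in
#: the South Asian group, hypertension in the Black group, cancer in the
#: White British group, autoimmune disease lowest in the White British group).
DEFAULT_COMORBIDITY_BY_ETHNICITY = {
    "diabetes_t2": {"south_asian": 0.50, "white_british": 0.35, "black": 0.22, "other": 0.30},
    "hypertension": {"black": 0.85},
    "cancer_current_or_past": {"white_british": 0.18},
    "autoimmune": {"white_british": 0.06},
}

DEFAULT_EVENT_PREVALENCES = {
    "illness_self": 0.30,
    "illness_relative": 0.20,
    "death_parent_child_spouse": 0.12,
    "death_friend_or_relative": 0.15,
    "marital_separation": 0.05,
    "relationship_breakup": 0.06,
    "friend_neighbour_problems": 0.10,
    "unemployment_seeking": 0.08,
    "sacked_from_job": 0.05,
    "financial_crisis": 0.15,
    "police_or_courts": 0.05,
    "loss_or_theft": 0.10,
}

DEFAULT_DISCRIMINATION_P = {d: 0.08 for d in schema.DISCRIMINATION_ITEMS}
#: Discrimination is reported more often by the minority ethnic groups.
DEFAULT_DISCRIMINATION_BY_ETHNICITY = {
    d: {"south_asian": 0.15, "black": 0.18} for d in schema.DISCRIMINATION_ITEMS
}

#: Label-conditional instrument parameters.  PHQ-2 items are Binomial(3, p);
#: HAMD totals are rounded Gaussians clipped to [0, 52] then spread over the
#: 17 items within their published maxima; somatic-criterion flags are
#: Binomial(5, p).  Calibrated so screen positivity sits far above the 8%
#: diagnosed prevalence (clinic-scale overestimation).
DEFAULT_LATENT_SEVERITY = {
    "phq2_item_p": {"none": 0.12, "mild": 0.45, "moderate_severe": 0.75},
    "hamd_mean": {"none": 12.0, "mild": 18.0, "moderate_severe": 26.0},
    "hamd_sd": {"none": 6.0, "mild": 6.0, "moderate_severe": 6.0},
    "somatic_flag_p": {"none": 0.08, "mild": 0.35, "moderate_severe": 0.60},
}

DEFAULT_MISSINGNESS = {
    "education": 0.03,
    "occupation": 0.02,
    "marital_status": 0.02,
    "smoking": 0.02,
    "alcohol": 0.02,
}

#: Conditional probability of a mild episode among those without
#: moderate/severe depression (53 mild among the 276 non-cases).
DEFAULT_MILD_GIVEN_NONCASE = 53 / 276


@dataclass(frozen=True)
class CohortConfig:
    """Full generative specification of a synthetic cohort."""

    n: int = 300
    seed: int = 0
    demographic_marginals: dict = field(default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS))
    age_means: dict = field(default_factory=lambda: dict(DEFAULT_AGE_MEANS))
    age_sd: float = DEFAULT_AGE_SD
    alcohol_p: float = DEFAULT_ALCOHOL_P
    comorbidity_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_COMORBIDITY))
    comorbidity_by_ethnicity: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_COMORBIDITY_BY_ETHNICITY.items()}
    )
    event_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_PREVALENCES))
    discrimination_prevalences: dict = field(default_factory=lambda: dict(DEFAULT_DISCRIMINATION_P))
    discrimination_by_ethnicity: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DISCRIMINATION_BY_ETHNICITY.items()}
    )
    outcome_intercept: float = -3.0
    outcome_effects: dict = field(default_factory=dict)  # name -> log odds ratio
    mild_given_noncase: float = DEFAULT_MILD_GIVEN_NONCASE
    latent_severity: dict = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_LATENT_SEVERITY.items()})
    fidelity: float = 1.0
    missingness_rates: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        for var, marg in self.demographic_marginals.items():
            if var not in schema.CATEGORICAL_LEVELS:
                raise ValueError(f"unknown demographic variable {var!r}")
            bad = set(marg) - set(schema.CATEGORICAL_LEVELS[var])
            if bad:
                raise ValueError(f"unknown level(s) {sorted(bad)} for {var!r}")
            if not math.isclose(sum(marg.values()), 1.0, abs_tol=1e-8):
                raise ValueError(f"marginals for {var!r} must sum to 1")
        for name, p in {
            **self.comorbidity_prevalences,
            **self.event_prevalences,
            **self.discrimination_prevalences,
            **self.missingness_rates,
        }.items():
            if not 0 <= p <= 1:
                raise ValueError(f"probability for {name!r} out of [0,1]: {p}")
        if not 0 <= self.fidelity <= 1:
            raise ValueError("fidelity must be in [0,1]")
        bad = set(self.event_prevalences) - set(schema.LIFE_EVENTS)
        if bad:
            raise ValueError(f"unknown life event(s): {sorted(bad)}")
        bad = set(self.comorbidity_prevalences) - set(schema.COMORBIDITIES)
        if bad:
            raise ValueError(f"unknown comorbidity(ies): {sorted(bad)}")


# ---------------------------------------------------------------------------
# Effect-name resolution


def _indicator(frame: pd.DataFrame, name: str) -> np.ndarray:
    """Map an outcome-effect name to a numeric covariate column.

    Accepted forms: a comorbidity id (``diabetes_t2``), an ``event_*`` /
    ``discrim_*`` column, ``age``, ``alcohol``, or ``var=level`` for a
    categorical indicator (e.g. ``education=university_or_apprenticeship``,
    ``sex=female``).
    """
    if name == "age":
        return frame["age"].to_numpy(dtype=float)
    if name == "alcohol":
        return frame["alcohol"].to_numpy(dtype=float)
    if name in schema.COMORBIDITIES:
        return frame[f"como_{name}"].to_numpy(dtype=float)
    if name in frame.columns and (name.startswith("event_") or name.startswith("discrim_")):
        return frame[name].to_numpy(dtype=float)
    if "=" in name:
        var, level = name.split("=", 1)
        if var in schema.CATEGORICAL_LEVELS and level in schema.CATEGORICAL_LEVELS[var]:
            return (frame[var] == level).to_numpy(dtype=float)
    raise KeyError(f"unknown outcome-effect name {name!r}")


def _linear_predictor(frame: pd.DataFrame, config: CohortConfig) -> np.ndarray:
    lp = np.full(len(frame), config.outcome_intercept, dtype=float)
    for name, beta in config.outcome_effects.items():
        lp += beta * _indicator(frame, name)
    return lp


# ---------------------------------------------------------------------------
# Covariate layer


def _draw_base_frame(config: CohortConfig, n: int, rng: np.random.Generator) -> pd.DataFrame:
    cols: dict[str, np.ndarray] = {"participant_id": np.array([f"P{i:06d}" for i in range(n)])}

    for var in ("sex", "ethnicity", "education", "occupation", "marital_status", "smoking"):
        marg = config.demographic_marginals[var]
        levels = [l for l in schema.CATEGORICAL_LEVELS[var] if l in marg]
        probs = np.array([marg[l] for l in levels])
        cols[var] = rng.choice(levels, size=n, p=probs / probs.sum())

    eth = cols["ethnicity"]
    mean_age = np.array([config.age_means.get(e, 60.0) for e in eth])
    cols["age"] = np.clip(np.round(rng.normal(mean_age, config.age_sd)), 18, 95)
    cols["alcohol"] = (rng.random(n) < config.alcohol_p).astype(int)

    for cond in schema.COMORBIDITIES:
        base = config.comorbidity_prevalences.get(cond, 0.0)
        override = config.comorbidity_by_ethnicity.get(cond, {})
        p = np.array([override.get(e, base) for e in eth])
        cols[f"como_{cond}"] = (rng.random(n) < p).astype(int)

    for ev in schema.LIFE_EVENTS:
        p = config.event_prevalences.get(ev, 0.0)
        cols[f"event_{ev}"] = (rng.random(n) < p).astype(int)

    for d in schema.DISCRIMINATION_ITEMS:
        base = config.discrimination_prevalences.get(d, 0.0)
        override = config.discrimination_by_ethnicity.get(d, {})
        p = np.array([override.get(e, base) for e in eth])
        cols[f"discrim_{d}"] = (rng.random(n) < p).astype(int)

    return pd.DataFrame(cols)


# ---------------------------------------------------------------------------
# Symptom layer


def _draw_profiles(
    categories: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Sample CIS-R endorsements consistent with each true label.

    Per label, a target core/total symptom count and duration are drawn
    inside the region of symptom space that the default rule table maps to
    that label, then the endorsed items are chosen at random.  With
    ``fidelity < 1`` a random label replaces the true one for profile
    construction with probability 1 - fidelity.
    """
    n = len(categories)
    core = np.array(CORE_ITEMS)
    addl = np.array(ADDITIONAL_ITEMS)
    sym = {i: np.zeros(n, dtype=int) for i in CORE_ITEMS + ADDITIONAL_ITEMS}
    duration = np.zeros(n)
    somatic_p = config.latent_severity["somatic_flag_p"]
    som = {c: np.zeros(n, dtype=int) for c in [s.removeprefix("somatic_") for s in schema.SOMATIC_COLUMNS]}
    som_names = list(som)

    eff = categories.copy()
    if config.fidelity < 1.0:
        flip = rng.random(n) >= config.fidelity
        eff[flip] = rng.choice(
            [Category.none, Category.mild, Category.moderate_severe], size=int(flip.sum())
        )

    for k in range(n):
        cat = Category(eff[k])
        if cat is Category.none:
            if rng.random() < 0.6:
                duration[k] = rng.integers(2, 27)
                t = int(rng.integers(0, 4))          # total < mild band
                chosen = rng.choice(9, size=t, replace=False)
                for j in chosen:
                    name = (CORE_ITEMS + ADDITIONAL_ITEMS)[j]
                    sym[name][k] = 1
            else:
                duration[k] = rng.integers(0, 2)     # too brief for an episode
                t = int(rng.integers(0, 6))
                chosen = rng.choice(9, size=t, replace=False)
                for j in chosen:
                    name = (CORE_ITEMS + ADDITIONAL_ITEMS)[j]
                    sym[name][k] = 1
        else:
            if cat is Category.mild:
                duration[k] = rng.integers(2, 27)
                n_core = 2 if rng.random() < 0.7 else 3
                total = int(rng.integers(4, 6))
            else:
                duration[k] = rng.integers(2, 53)
                n_core = 3 if rng.random() < 0.7 else 2
                hi = min(n_core + 6, 9)
                total = int(rng.integers(6, hi + 1))
            for c in rng.choice(core, size=n_core, replace=False):
                sym[c][k] = 1
            for a in rng.choice(addl, size=total - n_core, replace=False):
                sym[a][k] = 1

        p_som = somatic_p[cat.name]
        n_flags = rng.binomial(5, p_som)
        for c in rng.choice(som_names, size=n_flags, replace=False):
            som[c][k] = 1

    out = {f"cisr_{i}": v for i, v in sym.items()}
    out["cisr_duration_weeks"] = duration
    out.update({f"somatic_{c}": v for c, v in som.items()})
    return out


# ---------------------------------------------------------------------------
# Instrument layer


def _spread_total(totals: np.ndarray, maxima: tuple[int, ...], rng: np.random.Generator) -> np.ndarray:
    """Distribute integer totals uniformly at random over items subject to
    per-item maxima (multivariate hypergeometric with item capacities)."""
    n = len(totals)
    out = np.zeros((n, len(maxima)), dtype=int)
    for t in np.unique(totals):
        idx = np.flatnonzero(totals == t)
        if t == 0:
            continue
        out[idx] = rng.multivariate_hypergeometric(maxima, int(t), size=len(idx))
    return out


def _draw_instruments(
    categories: np.ndarray, config: CohortConfig, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    n = len(categories)
    ls = config.latent_severity
    names = np.array([Category(c).name for c in categories])

    phq_p = np.array([ls["phq2_item_p"][nm] for nm in names])
    phq_items = rng.binomial(3, phq_p[:, None].repeat(2, axis=1))

    hamd_mu = np.array([ls["hamd_mean"][nm] for nm in names])
    hamd_sd = np.array([ls["hamd_sd"][nm] for nm in names])
    totals = np.clip(np.round(rng.normal(hamd_mu, hamd_sd)), 0, 52).astype(int)
    hamd_items = _spread_total(totals, HAMD_ITEM_MAX, rng)

    out = {"phq2_1": phq_items[:, 0], "phq2_2": phq_items[:, 1]}
    out.update({f"hamd_{i+1}": hamd_items[:, i] for i in range(17)})
    return out


# ---------------------------------------------------------------------------
# Public API


def generate(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate one cohort.

    Returns ``(data, truth)``: ``data`` follows the participant-table
    schema (with configured missingness applied); ``truth`` carries the
    generative ground truth per participant (``true_category``,
    ``true_case``, ``linear_predictor``) for recovery tests.  Byte-identical
    for identical configs.
    """
    rng = np.random.default_rng(config.seed)
    data = _draw_base_frame(config, config.n, rng)

    lp = _linear_predictor(data, config)
    case = rng.random(config.n) < expit(lp)
    mild = ~case & (rng.random(config.n) < config.mild_given_noncase)
    categories = np.where(
        case, int(Category.moderate_severe), np.where(mild, int(Category.mild), int(Category.none))
    )

    for col, arr in _draw_profiles(categories, config, rng).items():
        data[col] = arr
    for col, arr in _draw_instruments(categories, config, rng).items():
        data[col] = arr

    truth = pd.DataFrame(
        {
            "participant_id": data["participant_id"],
            "true_category": [Category(c).name for c in categories],
            "true_case": case,
            "linear_predictor": lp,
        }
    )

    # missingness last, so truth is never masked
    for col, rate in config.missingness_rates.items():
        if rate > 0:
            mask = rng.random(config.n) < rate
            if mask.any():
                data[col] = data[col].astype(object)
                data.loc[mask, col] = None

    return data, truth


def solve_intercept(
    config: CohortConfig,
    target_prevalence: float,
    n_mc: int = 200_000,
    seed: int = 20_260_928,
) -> float:
    """Intercept giving the requested marginal diagnosed prevalence.

    Draws one large covariate sample (common random numbers), then
    root-finds the intercept at which the mean of the inverse-logit linear
    predictor equals the target.  The draw is fixed by ``seed`` so the
    solution is deterministic; Monte-Carlo error at the default size is
    about 0.0006 on the prevalence scale.
    """
    rng = np.random.default_rng(seed)
    frame = _draw_base_frame(config, n_mc, rng)
    lp0 = _linear_predictor(frame, replace(config, outcome_intercept=0.0))

    def gap(b0: float) -> float:
        return float(expit(b0 + lp0).mean()) - target_prevalence

    return float(brentq(gap, -15.0, 5.0, xtol=1e-10))


#: Published final-model odds ratios used as generative truth.
PAPERLIKE_EFFECTS = {
    "diabetes_t2": math.log(5.32),
    "event_death_parent_child_spouse": math.log(3.62),
    "event_financial_crisis": math.log(3.51),
    "education=university_or_apprenticeship": math.log(0.18),
}

PAPERLIKE_PREVALENCE = 0.08


def recover_preset_odds_ratios(n: int = 50_000, seed: int = 0) -> dict:
    """Generate-and-refit harness for the study-conditions preset.

    Generates ``n`` participants from :func:`preset_paperlike`, codes the
    diagnosis with the rule engine, builds the final-model design
    (age + sex + education + the two loss/strain events + type 2 diabetes)
    and refits the logistic model.  Returns the fitted odds ratios for the
    four generative effects plus the complete-case ``n_used``.
    """
    from .cisr import Category, PAPER_DEFAULT_RULES, classify_cohort
    from .exposures import CovariateSpec, build_design_matrix, profiles_from_frame
    from .inference import fit_final_model

    data, _ = generate(preset_paperlike(n=n, seed=seed))
    diagnoses = classify_cohort(profiles_from_frame(data), PAPER_DEFAULT_RULES)
    outcome = [d.category is Category.moderate_severe for d in diagnoses]
    specs = [
        CovariateSpec.continuous("age"),
        CovariateSpec.categorical("sex"),
        CovariateSpec.categorical("education"),
        CovariateSpec("event_death_parent_child_spouse"),
        CovariateSpec("event_financial_crisis"),
        CovariateSpec("diabetes_t2", source="como_diabetes_t2"),
    ]
    design = build_design_matrix(data, specs, outcome)
    result = fit_final_model(design.X, design.y)
    ors = result.odds_ratios()
    return {
        "diabetes_t2": ors["diabetes_t2"],
        "event_death_parent_child_spouse": ors["event_death_parent_child_spouse"],
        "event_financial_crisis": ors["event_financial_crisis"],
        "education=university_or_apprenticeship": ors["education[university_or_apprenticeship]"],
        "n_used": result.n_used,
    }


def preset_paperlike(n: int = 300, seed: int = 0) -> CohortConfig:
    """Study-conditions preset: n=300, the four published final-model odds
    ratios as generative effects, intercept solved so marginal
    moderate/severe prevalence is 8%, default marginals elsewhere."""
    base = CohortConfig(n=n, seed=seed, outcome_effects=dict(PAPERLIKE_EFFECTS))
    b0 = solve_intercept(base, PAPERLIKE_PREVALENCE)
    return replace(base, outcome_intercept=b0)
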