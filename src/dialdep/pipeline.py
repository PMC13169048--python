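"""End-to-end cohort analysis: validation, classification, descriptive
tables, prevalence, block-wise stepwise selection, the final model, and the
sensitivity re-run — with a JSON manifest for reproducibility.

Emits six tidy CSV artefacts per run:

1. ``descriptive_by_sex.csv`` — demographics, adversity, health, overall and by sex
2. ``descriptive_by_ethnicity.csv`` — the same by ethnic group
3. ``prevalence.csv`` — each depression definition with exact binomial CIs
4. ``stepwise_trace.csv`` — per-block removal sequences and retained variables
5. ``final_model.csv`` — the fully adjusted logistic model (OR, 95% CI, p)
6. ``sensitivity_comparison.csv`` — default vs impute-present classification

plus ``manifest.json`` recording seed, config hash, package version and the
artefact list.  Percentages are reported to 1 decimal place and odds ratios
to 2, full precision retained in the model JSON.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import schema
from .cisr import (
    Category,
    PAPER_DEFAULT_RULES,
    RuleTable,
    SENSITIVITY_RULES,
    classify_cohort,
)
from .exposures import (
    CovariateSpec,
    build_design_matrix,
    profiles_from_frame,
    screening_items_from_frame,
)
from .inference import backward_stepwise, fit_final_model, prevalence
from .screening import MissingItemError, score_hamd, score_phq2

log = logging.getLogger("dialdep")

__all__ = ["PipelineConfig", "ValidationReport", "validate_input", "run_full_pipeline"]


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class ValidationReport:
    n_rows: int
    errors: tuple[str, ...]

    @property
    def ok(self) -> bool:
        return len(self.errors) == 0


def validate_input(data: pd.DataFrame | str | Path, max_errors: int = 100) -> ValidationReport:
    """Schema, range and level checks with per-row/column error reporting."""
    if not isinstance(data, pd.DataFrame):
        data = pd.read_csv(data)
    errors: list[str] = []

    missing_cols = [c for c in schema.ALL_COLUMNS if c not in data.columns]
    for c in missing_cols:
        errors.append(f"missing column: {c}")
    if missing_cols:
        return ValidationReport(len(data), tuple(errors))

    def note(row, col, msg):
        if len(errors) < max_errors:
            errors.append(f"row {row}, column {col}: {msg}")

    for i, v in data["age"].items():
        if pd.isna(v) or not (0 < float(v) < 120):
            note(i, "age", f"age out of range: {v!r}")
    for col, levels in schema.CATEGORICAL_LEVELS.items():
        for i, v in data[col].items():
            if pd.isna(v):
                continue  # missing handled downstream by complete-case
            if v not in levels:
                note(i, col, f"unknown level {v!r}")
    for col in schema.BINARY_COLUMNS:
        for i, v in data[col].items():
            if pd.isna(v):
                continue
            if float(v) not in (0.0, 1.0):
                note(i, col, f"not binary: {v!r}")
    for i, v in data["cisr_duration_weeks"].items():
        if pd.isna(v) or float(v) < 0:
            note(i, "cisr_duration_weeks", f"negative or missing duration: {v!r}")
    for col, (lo, hi) in schema.ITEM_RANGES.items():
        for i, v in data[col].items():
            if pd.isna(v):
                continue
            if not lo <= float(v) <= hi:
                note(i, col, f"outside {lo}..{hi}: {v!r}")

    return ValidationReport(len(data), tuple(errors))


# ---------------------------------------------------------------------------
# Descriptive tables


def _summarize(data: pd.DataFrame, strata: list[tuple[str, pd.Series]]) -> pd.DataFrame:
    """Tidy counts/percentages for demographics, adversity and health flags."""
    rows = []

    def add(variable, level, name, mask_level, mask_stratum):
        sub = mask_level[mask_stratum]
        denom = int(sub.notna().sum())
        count = int(sub.dropna().astype(bool).sum())
        rows.append(
            {
                "variable": variable,
                "level": level,
                "stratum": name,
                "count": count,
                "n": denom,
                "percent": round(100 * count / denom, 1) if denom else None,
            }
        )

    for name, mask in strata:
        for var, levels in schema.CATEGORICAL_LEVELS.items():
            for lev in levels:
                add(var, lev, name, data[var] == lev, mask)
        for col in ("alcohol",) + schema.EVENT_COLUMNS + schema.DISCRIM_COLUMNS + schema.COMORBIDITY_COLUMNS:
            add(col, "yes", name, data[col].map(lambda v: v if pd.isna(v) else bool(v)), mask)
        for col in ("icd10_mild", "icd10_moderate_severe", "phq2_positive", "hamd_positive"):
            add(col, "yes", name, data[col], mask)
    return pd.DataFrame(rows)


def _strata(data: pd.DataFrame, by: str) -> list[tuple[str, pd.Series]]:
    out = [("overall", pd.Series(True, index=data.index))]
    for lev in schema.CATEGORICAL_LEVELS[by]:
        mask = data[by] == lev
        if mask.any():
            out.append((lev, mask))
    return out


# ---------------------------------------------------------------------------
# Analysis blocks

BLOCK_SPECS: dict[str, list[CovariateSpec]] = {
    "demographics": [
        CovariateSpec.continuous("age"),
        CovariateSpec.categorical("sex"),
        CovariateSpec.categorical("marital_status"),
        CovariateSpec.categorical("education"),
        CovariateSpec.categorical("occupation"),
        CovariateSpec.categorical("smoking"),
        CovariateSpec("alcohol"),
    ],
    "psychosocial": [CovariateSpec(c) for c in schema.EVENT_COLUMNS + schema.DISCRIM_COLUMNS],
    "conditions": [CovariateSpec(c) for c in schema.COMORBIDITY_COLUMNS],
}


@dataclass(frozen=True)
class PipelineConfig:
    input_path: Optional[str] = None
    rules: RuleTable = PAPER_DEFAULT_RULES
    sensitivity_rules: RuleTable = SENSITIVITY_RULES
    retention_threshold: float = 0.1
    ci_level: float = 0.95
    p_value_method: str = "wald"
    separation_policy: str = "firth"   # pipeline-level pragmatic default; logged
    out_dir: str = "dialdep_output"
    seed: Optional[int] = None

    def to_dict(self) -> dict:
        return {
            "input_path": self.input_path,
            "rules": self.rules.to_dict(),
            "sensitivity_rules": self.sensitivity_rules.to_dict(),
            "retention_threshold": self.retention_threshold,
            "ci_level": self.ci_level,
            "p_value_method": self.p_value_method,
            "separation_policy": self.separation_policy,
            "seed": self.seed,
        }


def _score_screens(data: pd.DataFrame) -> pd.DataFrame:
    phq2, hamd = screening_items_from_frame(data)
    phq_scores, phq_pos, hamd_scores, hamd_pos = [], [], [], []
    n_phq_excluded = n_hamd_excluded = 0
    for k in range(len(data)):
        try:
            s, p = score_phq2(phq2[k])
        except MissingItemError:
            s, p = np.nan, None
            n_phq_excluded += 1
        phq_scores.append(s), phq_pos.append(p)
        try:
            s, p = score_hamd(hamd[k])
        except MissingItemError:
            s, p = np.nan, None
            n_hamd_excluded += 1
        hamd_scores.append(s), hamd_pos.append(p)
    if n_phq_excluded or n_hamd_excluded:
        log.info(
            "screening exclusions (missing items, no proration): PHQ2 %d, HAMD %d",
            n_phq_excluded, n_hamd_excluded,
        )
    out = data.copy()
    out["phq2_score"], out["phq2_positive"] = phq_scores, phq_pos
    out["hamd_score"], out["hamd_positive"] = hamd_scores, hamd_pos
    return out


def analyze_cohort(data: pd.DataFrame, config: PipelineConfig) -> dict:
    """Run the full analysis in memory; returns a dict of result frames."""
    report = validate_input(data)
    if not report.ok:
        raise ValueError(
            f"input failed validation with {len(report.errors)} error(s); first: {report.errors[0]}"
        )
    n = len(data)
    log.info("cohort loaded: n=%d", n)

    diagnoses = classify_cohort(profiles_from_frame(data), config.rules)
    sens_diagnoses = classify_cohort(profiles_from_frame(data), config.sensitivity_rules)
    data = _score_screens(data)
    data["icd10_category"] = [str(d.category) for d in diagnoses]
    data["icd10_mild"] = [d.category is Category.mild for d in diagnoses]
    data["icd10_moderate_severe"] = [d.category is Category.moderate_severe for d in diagnoses]
    data["somatic_syndrome"] = [d.somatic_syndrome for d in diagnoses]

    desc_sex = _summarize(data, _strata(data, "sex"))
    desc_eth = _summarize(data, _strata(data, "ethnicity"))

    prev_rows = []
    for name, col in [
        ("icd10_mild", "icd10_mild"),
        ("icd10_moderate_severe", "icd10_moderate_severe"),
        ("phq2_positive", "phq2_positive"),
        ("hamd_positive", "hamd_positive"),
    ]:
        vals = data[col].dropna().astype(bool)
        est = prevalence(int(vals.sum()), len(vals), level=config.ci_level)
        prev_rows.append(
            {
                "definition": name,
                "count": est.count,
                "n": est.n,
                "percent": round(100 * est.proportion, 1),
                "ci_low_percent": round(100 * est.ci_low, 1),
                "ci_high_percent": round(100 * est.ci_high, 1),
            }
        )
    prevalence_table = pd.DataFrame(prev_rows)

    outcome = data["icd10_moderate_severe"].astype(bool)

    retained_specs: list[CovariateSpec] = []
    trace_rows = []
    for block, specs in BLOCK_SPECS.items():
        design = build_design_matrix(data, specs, outcome)
        log.info("block %s: complete cases %d of %d", block, design.n_used, n)
        trace = backward_stepwise(
            design.X,
            design.y,
            groups=design.groups,
            threshold=config.retention_threshold,
            block_id=block,
            p_value_method=config.p_value_method,
            separation_policy=config.separation_policy,
        )
        for var, p in trace.removal_sequence:
            trace_rows.append({"block": block, "variable": var, "action": "removed", "p": round(p, 4)})
        for var, p in trace.retained.items():
            trace_rows.append({"block": block, "variable": var, "action": "retained", "p": round(p, 4)})
        by_name = {s.name: s for s in specs}
        retained_specs.extend(
            by_name[v] for v in trace.retained if by_name[v].name not in ("age", "sex")
        )
    stepwise_table = pd.DataFrame(trace_rows)

    # age and sex always forced into the final model as confounders
    final_specs = [CovariateSpec.continuous("age"), CovariateSpec.categorical("sex")]
    final_specs += [s for s in retained_specs if s.name not in ("age", "sex")]
    design = build_design_matrix(data, final_specs, outcome)
    log.info("final model: complete cases %d of %d", design.n_used, n)
    final = fit_final_model(
        design.X, design.y, level=config.ci_level, separation_policy=config.separation_policy
    )
    final_table = final.to_frame()
    final_table["odds_ratio"] = final_table["odds_ratio"].round(2)
    final_table["ci_low"] = final_table["ci_low"].round(2)
    final_table["ci_high"] = final_table["ci_high"].round(2)
    final_table["p_value"] = final_table["p_value"].round(4)

    base_counts = pd.Series([str(d.category) for d in diagnoses]).value_counts()
    sens_counts = pd.Series([str(d.category) for d in sens_diagnoses]).value_counts()
    sensitivity_table = pd.DataFrame(
        {
            "category": [c.name for c in Category],
            "as_administered": [int(base_counts.get(c.name, 0)) for c in Category],
            "impute_present": [int(sens_counts.get(c.name, 0)) for c in Category],
        }
    )

    return {
        "data": data,
        "descriptive_by_sex": desc_sex,
        "descriptive_by_ethnicity": desc_eth,
        "prevalence": prevalence_table,
        "stepwise_trace": stepwise_table,
        "final_model": final_table,
        "final_model_result": final,
        "final_n_used": design.n_used,
        "sensitivity_comparison": sensitivity_table,
    }


TABLE_ARTEFACTS = (
    "descriptive_by_sex",
    "descriptive_by_ethnicity",
    "prevalence",
    "stepwise_trace",
    "final_model",
    "sensitivity_comparison",
)


def run_full_pipeline(
    data: pd.DataFrame | str | Path, config: PipelineConfig
) -> dict:
    """Analyse a cohort and write the six table artefacts plus a manifest.

    Deterministic: identical input and config produce identical artefacts
    and an identical manifest hash.  On failure nothing but a
    ``FAILED`` marker is left in the output directory.
    """
    if not isinstance(data, pd.DataFrame):
        data = pd.read_csv(data)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    marker = out / "FAILED"
    try:
        results = analyze_cohort(data, config)
    except Exception:
        marker.write_text("pipeline failed; artefacts incomplete\n")
        raise
    if marker.exists():
        marker.unlink()

    hasher = hashlib.sha256()
    artefacts = []
    for name in TABLE_ARTEFACTS:
        path = out / f"{name}.csv"
        csv_bytes = results[name].to_csv(index=False).encode()
        path.write_bytes(csv_bytes)
        hasher.update(name.encode())
        hasher.update(csv_bytes)
        artefacts.append(path.name)

    config_hash = hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()
    hasher.update(config_hash.encode())

    from . import __version__

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "n_input": int(len(data)),
        "n_final_model": int(results["final_n_used"]),
        "config_hash": config_hash,
        "tables": artefacts,
        "manifest_hash": hasher.hexdigest(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
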