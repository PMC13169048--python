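"""Covariate coding: demographics, life events, discrimination, comorbidity.

Turns the participant table into a reference-coded design matrix for the
logistic models, and computes per-item life-event endorsement with exact
binomial confidence intervals, overall and by stratum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import schema
from .cisr import (
    ADDITIONAL_ITEMS,
    CORE_ITEMS,
    SOMATIC_CRITERIA,
    SymptomProfile,
)
from .inference import prevalence

__all__ = [
    "CovariateSpec",
    "DesignMatrix",
    "build_design_matrix",
    "event_prevalence",
    "profiles_from_frame",
    "screening_items_from_frame",
    "DEFAULT_REFERENCES",
]

#: Reference levels for categorical covariates.  School completion is the
#: reference for education because it is the largest group; other references
#: are the conventional unexposed/majority levels.
DEFAULT_REFERENCES = {
    "sex": "male",
    "ethnicity": "white_british",
    "education": "school_complete",
    "occupation": "employed",
    "marital_status": "married_or_cohabiting",
    "smoking": "never",
}


@dataclass(frozen=True)
class CovariateSpec:
    """How one source column enters the design matrix.

    encoding: ``"binary"`` (0/1 indicator), ``"categorical"``
    (reference-coded k-1 indicators) or ``"continuous"``.
    """

    name: str
    source: Optional[str] = None
    encoding: str = "binary"
    reference: Optional[str] = None

    def __post_init__(self):
        if self.encoding not in ("binary", "categorical", "continuous"):
            raise ValueError(f"unknown encoding {self.encoding!r}")
        if self.source is None:
            object.__setattr__(self, "source", self.name)

    @classmethod
    def categorical(cls, name: str, reference: Optional[str] = None) -> "CovariateSpec":
        ref = reference or DEFAULT_REFERENCES.get(name)
        return cls(name=name, encoding="categorical", reference=ref)

    @classmethod
    def continuous(cls, name: str) -> "CovariateSpec":
        return cls(name=name, encoding="continuous")


@dataclass(frozen=True)
class DesignMatrix:
    """Reference-coded design with complete-case bookkeeping.

    ``X`` and ``y`` are restricted to complete cases; ``complete_mask``
    indexes the original rows.  ``groups`` maps each covariate name to its
    design-column names, so multi-level categoricals can be stepped in and
    out of models as whole variables.
    """

    X: pd.DataFrame
    y: pd.Series
    complete_mask: pd.Series
    groups: dict[str, list[str]]

    @property
    def n_used(self) -> int:
        return len(self.X)


def build_design_matrix(
    data: pd.DataFrame,
    specs: Sequence[CovariateSpec],
    outcome: Sequence[bool] | pd.Series | np.ndarray,
) -> DesignMatrix:
    """Reference-code covariates and apply complete-case selection.

    Column order is deterministic: specs in declared order, categorical
    levels in schema order with the reference dropped.  Rows missing any
    required covariate (or the outcome) are excluded and counted via
    ``complete_mask``.
    """
    if len(data) == 0:
        raise ValueError("empty cohort")
    if len(specs) == 0:
        raise ValueError("no covariates specified")
    y = pd.Series(np.asarray(outcome, dtype=float), index=data.index, name="outcome")
    if len(y) != len(data):
        raise ValueError("outcome length mismatch")

    cols: dict[str, pd.Series] = {}
    groups: dict[str, list[str]] = {}
    for spec in specs:
        if spec.source not in data.columns:
            raise KeyError(f"covariate source column {spec.source!r} not in data")
        col = data[spec.source]
        if spec.encoding == "continuous":
            cols[spec.name] = pd.to_numeric(col)
            groups[spec.name] = [spec.name]
        elif spec.encoding == "binary":
            vals = col.map(lambda v: v if pd.isna(v) else float(bool(v)))
            cols[spec.name] = pd.to_numeric(vals)
            groups[spec.name] = [spec.name]
        else:
            levels = schema.CATEGORICAL_LEVELS.get(spec.source)
            observed = set(col.dropna().unique())
            if levels is None:
                levels = tuple(sorted(observed))
            unknown = observed - set(levels)
            if unknown:
                raise ValueError(
                    f"unknown level(s) {sorted(unknown)} in column {spec.source!r}"
                )
            ref = spec.reference if spec.reference is not None else levels[0]
            if ref not in levels:
                raise ValueError(
                    f"reference level {ref!r} not among levels of {spec.source!r}"
                )
            names = []
            for lev in levels:
                if lev == ref:
                    continue
                name = f"{spec.name}[{lev}]"
                cols[name] = col.map(
                    lambda v, lev=lev: np.nan if pd.isna(v) else float(v == lev)
                )
                names.append(name)
            groups[spec.name] = names

    X = pd.DataFrame(cols, index=data.index)
    complete = X.notna().all(axis=1) & y.notna()
    return DesignMatrix(
        X=X.loc[complete].astype(float),
        y=y.loc[complete],
        complete_mask=complete,
        groups=groups,
    )


def event_prevalence(
    data: pd.DataFrame,
    by: Optional[str] = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Per-item life-event endorsement proportions with exact binomial CIs.

    ``by`` optionally stratifies (e.g. ``"sex"`` or ``"ethnicity"``).
    Strata with n = 0 are omitted with a warning.  Returns a tidy frame
    with columns item, stratum, count, n, proportion, ci_low, ci_high.
    """
    if len(data) == 0:
        raise ValueError("empty cohort")
    strata = [("overall", data)]
    if by is not None:
        levels = schema.CATEGORICAL_LEVELS.get(by)
        if levels is None:
            levels = tuple(sorted(data[by].dropna().unique()))
        for lev in levels:
            sub = data[data[by] == lev]
            if len(sub) == 0:
                warnings.warn(f"stratum {by}={lev} has no participants; omitted")
                continue
            strata.append((lev, sub))

    rows = []
    for col in schema.EVENT_COLUMNS:
        item = col.removeprefix("event_")
        for name, sub in strata:
            vals = sub[col].dropna().astype(bool)
            n = len(vals)
            if n == 0:
                continue
            est = prevalence(int(vals.sum()), n, level=level)
            rows.append(
                {
                    "item": item,
                    "stratum": name,
                    "count": est.count,
                    "n": est.n,
                    "proportion": est.proportion,
                    "ci_low": est.ci_low,
                    "ci_high": est.ci_high,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bridges from the participant table to the domain objects


def profiles_from_frame(data: pd.DataFrame) -> list[SymptomProfile]:
    """Build a SymptomProfile per row from the ``cisr_*``/``somatic_*`` columns."""
    items = CORE_ITEMS + ADDITIONAL_ITEMS
    sym = {i: data[f"cisr_{i}"].to_numpy(dtype=bool) for i in items}
    som = {c: data[f"somatic_{c}"].to_numpy(dtype=bool) for c in sorted(SOMATIC_CRITERIA)}
    dur = data["cisr_duration_weeks"].to_numpy(dtype=float)
    profiles = []
    for k in range(len(data)):
        flags = frozenset(c for c, v in som.items() if v[k])
        profiles.append(
            SymptomProfile(
                duration_weeks=dur[k],
                somatic_flags=flags,
                **{i: bool(v[k]) for i, v in sym.items()},
            )
        )
    return profiles


def screening_items_from_frame(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Return (phq2 items n x 2, hamd items n x 17) as integer arrays."""
    phq2 = data[list(schema.PHQ2_COLUMNS)].to_numpy()
    hamd = data[list(schema.HAMD_COLUMNS)].to_numpy()
    return phq2, hamd
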