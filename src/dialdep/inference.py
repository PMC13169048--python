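"""Statistical procedures: exact binomial CIs, contingency testing with the
small-cell switching rule, block-wise backward stepwise logistic regression,
and the final multivariable model.

Conventions
-----------
* Prevalence intervals are Clopper-Pearson (exact beta quantiles); these are
  conservative but reproduce the printed-band convention of survey reports.
* Cross-tabulations use Pearson chi-squared without continuity correction
  when every expected cell count is >= 5, otherwise Fisher's exact test
  (hypergeometric for 2x2, full enumeration for small r x c tables).  The
  switch is keyed on expected counts; ``min_expected`` on the result makes
  the rule auditable.
* Stepwise removal and reporting use Wald z statistics, matching the
  OR / 95% CI / p triplets of the outputs being emulated; a likelihood-ratio
  stepping mode is available via ``p_value_method="lr"``.
* Multi-level categoricals step in and out as whole variables, with the
  variable's removal p equal to its smallest single-indicator p.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationError,
    PerfectSeparationWarning,
)

__all__ = [
    "PrevalenceEstimate",
    "ContingencyResult",
    "StepwiseTrace",
    "LogisticModelResult",
    "prevalence",
    "contingency_test",
    "backward_stepwise",
    "fit_logistic",
    "fit_final_model",
    "SeparationError",
    "DegenerateTableError",
]


class SeparationError(RuntimeError):
    """Complete or quasi-complete separation: ML estimates do not exist."""


class DegenerateTableError(ValueError):
    """Contingency table with a zero margin or fewer than 2 rows/columns."""


# ---------------------------------------------------------------------------
# Prevalence


@dataclass(frozen=True)
class PrevalenceEstimate:
    count: int
    n: int
    proportion: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    method: str = "clopper_pearson"


def prevalence(count: int, n: int, level: float = 0.95) -> PrevalenceEstimate:
    """Binomial point estimate with an exact Clopper-Pearson interval."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 <= count <= n:
        raise ValueError(f"count must be in 0..{n}, got {count}")
    ci = stats.binomtest(count, n).proportion_ci(confidence_level=level, method="exact")
    return PrevalenceEstimate(
        count=count, n=n, proportion=count / n,
        ci_low=float(ci.low), ci_high=float(ci.high), level=level,
    )


# ---------------------------------------------------------------------------
# Contingency testing


@dataclass(frozen=True)
class ContingencyResult:
    table: np.ndarray
    method: str                      # "chi_squared" | "fisher_exact"
    statistic: Optional[float]       # chi-squared only
    p_value: float
    min_expected_cell: float


def _fisher_rxc_pvalue(table: np.ndarray) -> float:
    """Exact conditional p for an r x c table by enumeration.

    Enumerates every non-negative integer table with the observed margins,
    scoring each by its multivariate hypergeometric probability; the p-value
    sums probabilities <= that of the observed table (with a small relative
    tolerance against floating-point ties).  Feasible for the small tables
    the switching rule routes here.
    """
    table = np.asarray(table, dtype=np.int64)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    from math import lgamma

    def lfact(x):
        return lgamma(x + 1)

    log_const = sum(lfact(r) for r in rows) + sum(lfact(c) for c in cols) - lfact(n)

    def log_prob(t):
        return log_const - sum(lfact(v) for row in t for v in row)

    p_obs = log_prob(table)
    r, c = table.shape
    total = 0.0

    def rec(i, remaining_cols, acc):
        nonlocal total
        if i == r - 1:
            last = remaining_cols
            if np.all(last >= 0) and last.sum() == rows[-1]:
                lp = log_prob(acc + [list(last)])
                if lp <= p_obs + 1e-10:
                    total += np.exp(lp)
            return
        # enumerate row i summing to rows[i], cell-wise bounded by remaining cols
        def cells(j, left, row):
            if j == c - 1:
                if left <= remaining_cols[j]:
                    rec(i + 1, remaining_cols - np.array(row + [left]), acc + [row + [left]])
                return
            for v in range(min(left, remaining_cols[j]) + 1):
                cells(j + 1, left - v, row + [v])

        cells(0, int(rows[i]), [])

    rec(0, cols.copy(), [])
    return min(total, 1.0)


def contingency_test(table) -> ContingencyResult:
    """Test association in an r x c table with the small-cell switching rule.

    Pearson chi-squared (no Yates correction) when every expected cell is
    >= 5; Fisher's exact test otherwise.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise DegenerateTableError("table must be at least 2x2")
    if (table < 0).any():
        raise DegenerateTableError("negative cell count")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise DegenerateTableError("zero row or column margin")

    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    min_expected = float(expected.min())

    if min_expected >= 5:
        stat, p, _, _ = stats.chi2_contingency(table, correction=False)
        return ContingencyResult(table, "chi_squared", float(stat), float(p), min_expected)

    if table.shape == (2, 2):
        _, p = stats.fisher_exact(table)
    else:
        if table.sum() > 200:
            raise ValueError(
                "exact r x c test not attempted for n > 200; collapse categories"
            )
        p = _fisher_rxc_pvalue(table)
    return ContingencyResult(table, "fisher_exact", None, float(p), min_expected)


# ---------------------------------------------------------------------------
# Logistic modelling


@dataclass(frozen=True)
class TermEstimate:
    term: str
    coefficient: float
    odds_ratio: float
    wald_ci_low: float
    wald_ci_high: float
    p_value: float
    significant: bool  # p <= 0.05


@dataclass(frozen=True)
class LogisticModelResult:
    terms: tuple[TermEstimate, ...]
    intercept: float
    n_used: int
    model_chi2: float
    df: int
    pseudo_r2: float      # McFadden
    converged: bool
    log_likelihood: float

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    def odds_ratios(self) -> dict[str, float]:
        return {t.term: t.odds_ratio for t in self.terms}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "term": t.term,
                    "odds_ratio": t.odds_ratio,
                    "ci_low": t.wald_ci_low,
                    "ci_high": t.wald_ci_high,
                    "p_value": t.p_value,
                    "significant": t.significant,
                }
                for t in self.terms
            ]
        )


def _firth_logit(X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8):
    """Firth-penalized logistic fit (Jeffreys-prior score correction).

    Newton iterations on the modified score U*(b) = U(b) + 0.5 * tr-adjusted
    hat correction; keeps estimates finite under separation.
    """
    n, k = X.shape
    beta = np.zeros(k)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1 - mu)
        XtW = X.T * w
        info = XtW @ X
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError as exc:
            raise SeparationError("singular information matrix in Firth fit") from exc
        h = np.einsum("ij,jk,ik->i", X, cov, X) * w  # hat diagonal
        score = X.T @ (y - mu + h * (0.5 - mu))
        step = cov @ score
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    return beta, cov


def fit_logistic(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    level: float = 0.95,
    separation_policy: str = "raise",
) -> LogisticModelResult:
    """Maximum-likelihood logistic fit with Wald intervals.

    ``separation_policy``: ``"raise"`` fails loudly on complete separation
    (the default — unstable odds ratios are never reported silently);
    ``"firth"`` falls back to a Firth-penalized fit.
    """
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both classes")
    Xc = sm.add_constant(X, has_constant="add")
    z = stats.norm.ppf(0.5 + level / 2)

    separated = False
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        # non-convergence is detected below via mle_retvals / SE blow-up
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = sm.Logit(y, Xc).fit(disp=0, maxiter=200)
            params = fit.params
            bse = fit.bse
            converged = bool(fit.mle_retvals.get("converged", True))
            llf, llnull = fit.llf, fit.llnull
            # huge standard errors betray quasi-separation even when the
            # optimizer nominally converges
            if not converged or np.any(np.asarray(bse) > 1e3):
                separated = True
        except (PerfectSeparationWarning, PerfectSeparationError, np.linalg.LinAlgError):
            separated = True

    if separated:
        if separation_policy == "raise":
            raise SeparationError(
                "complete or quasi-complete separation detected; "
                "set separation_policy='firth' for a penalized fit"
            )
        beta, cov = _firth_logit(Xc.to_numpy(dtype=float), y)
        params = pd.Series(beta, index=Xc.columns)
        bse = pd.Series(np.sqrt(np.diag(cov)), index=Xc.columns)
        eta = Xc.to_numpy(dtype=float) @ beta
        llf = float(np.sum(y * eta - np.log1p(np.exp(eta))))
        p0 = y.mean()
        llnull = float(len(y) * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0)))
        converged = True

    terms = []
    for name in Xc.columns:
        if name == "const":
            continue
        b, se = float(params[name]), float(bse[name])
        pv = float(2 * stats.norm.sf(abs(b) / se)) if se > 0 else np.nan
        terms.append(
            TermEstimate(
                term=name,
                coefficient=b,
                odds_ratio=float(np.exp(b)),
                wald_ci_low=float(np.exp(b - z * se)),
                wald_ci_high=float(np.exp(b + z * se)),
                p_value=pv,
                significant=pv <= 0.05,
            )
        )
    df = len(terms)
    return LogisticModelResult(
        terms=tuple(terms),
        intercept=float(params["const"]),
        n_used=len(y),
        model_chi2=float(2 * (llf - llnull)),
        df=df,
        pseudo_r2=float(1 - llf / llnull) if llnull != 0 else np.nan,
        converged=converged,
        log_likelihood=float(llf),
    )


# ---------------------------------------------------------------------------
# Backward stepwise selection


@dataclass(frozen=True)
class StepwiseTrace:
    block_id: str
    removal_sequence: tuple[tuple[str, float], ...]
    retained: dict[str, float]       # variable -> final p
    final_model: Optional[LogisticModelResult]


def _group_pvalues(
    result: LogisticModelResult,
    groups: dict[str, list[str]],
    X: pd.DataFrame,
    y,
    method: str,
    separation_policy: str,
) -> dict[str, float]:
    """Removal p per variable: min Wald p over its indicator columns, or a
    likelihood-ratio drop test when ``method="lr"``."""
    pvals = {}
    for var, cols in groups.items():
        if method == "wald":
            pvals[var] = min(result.term(c).p_value for c in cols)
        else:
            reduced_cols = [c for c in X.columns if c not in cols]
            if reduced_cols:
                reduced = fit_logistic(
                    X[reduced_cols], y, separation_policy=separation_policy
                )
                ll0 = reduced.log_likelihood
            else:
                p0 = np.asarray(y, dtype=float).mean()
                n = len(y)
                ll0 = n * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0))
            lr = 2 * (result.log_likelihood - ll0)
            pvals[var] = float(stats.chi2.sf(max(lr, 0.0), df=len(cols)))
    return pvals


def backward_stepwise(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    groups: Optional[dict[str, list[str]]] = None,
    threshold: float = 0.1,
    block_id: str = "block",
    p_value_method: str = "wald",
    separation_policy: str = "raise",
) -> StepwiseTrace:
    """Backward elimination at the given retention threshold.

    Starting from the full model, repeatedly drop the variable with the
    largest removal p-value >= ``threshold`` and refit, until every
    remaining variable has p < ``threshold`` (or none remain).  Multi-level
    categoricals (via ``groups``) leave as whole variables; equal p-values
    are broken by dropping the variable declared latest.  Deterministic.
    """
    if groups is None:
        groups = {c: [c] for c in X.columns}
    order = list(groups)  # declaration order for tie-breaking
    active = list(order)
    removals: list[tuple[str, float]] = []

    while active:
        cols = [c for v in active for c in groups[v]]
        result = fit_logistic(X[cols], y, separation_policy=separation_policy)
        pvals = _group_pvalues(
            result, {v: groups[v] for v in active}, X[cols], y,
            p_value_method, separation_policy,
        )
        worst_p = max(pvals.values())
        if worst_p < threshold:
            return StepwiseTrace(
                block_id=block_id,
                removal_sequence=tuple(removals),
                retained=pvals,
                final_model=result,
            )
        # ties: drop the variable latest in declared order
        candidates = [v for v in active if pvals[v] == worst_p]
        drop = max(candidates, key=order.index)
        removals.append((drop, worst_p))
        active.remove(drop)

    return StepwiseTrace(
        block_id=block_id,
        removal_sequence=tuple(removals),
        retained={},
        final_model=None,
    )


def fit_final_model(
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    level: float = 0.95,
    separation_policy: str = "raise",
) -> LogisticModelResult:
    """Fit the fully adjusted multivariable model on the block-retained
    covariates (plus any forced adjusters such as age and sex, which the
    caller includes in ``X``)."""
    return fit_logistic(X, y, level=level, separation_policy=separation_policy)
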