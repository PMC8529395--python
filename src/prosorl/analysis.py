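"""Behavioral summaries and correlation analyses.

Implements the operationally defined statistics: per-condition learning
curves averaged across blocks, one-sample above-chance t-tests on
per-agent accuracy, age-trend correlation screening, and partial Spearman
correlations by rank residualization. "Correct" means choosing the
high-reward-contingency picture, regardless of the realized outcome;
missed trials are excluded from all denominators.

Mixed-model fits (GLMM/robust LMM) are deliberately not reimplemented
here: the tidy tables this module consumes and produces are ready for any
standard mixed-model tool.
"""

from __future__ import annotations

import warnings
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "learning_curves",
    "performance_summary",
    "above_chance_test",
    "partial_spearman",
    "age_trend",
]


def _correct_frame(table: pd.DataFrame) -> pd.DataFrame:
    out = table[~table["missed"].astype(bool)].copy()
    out["correct"] = out["chosen_good"].astype(bool).astype(float)
    return out


def learning_curves(table: pd.DataFrame) -> pd.DataFrame:
    """Group learning curves: fraction correct per condition x trial position.

    Positions are averaged across blocks within each agent first; the
    reported fraction and SEM are then the mean and standard error across
    agents. Returns columns condition, trial_in_block, fraction_correct,
    n, sem.
    """
    frame = _correct_frame(table)
    per_agent = (
        frame.groupby(["condition", "trial_in_block", "agent_id"], observed=True)["correct"]
        .mean()
        .reset_index()
    )
    grouped = per_agent.groupby(["condition", "trial_in_block"], observed=True)["correct"]
    curve = grouped.agg(
        fraction_correct="mean",
        n="count",
        sem=lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else np.nan,
    ).reset_index()
    return curve


def performance_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Per agent x condition fraction of correct choices over non-missed trials.

    Carries age/empathy columns through when present, so the output joins
    directly with fitted parameters for correlational analyses.
    """
    frame = _correct_frame(table)
    keys = ["agent_id", "condition"]
    carry = [c for c in ("age", "empathy") if c in frame.columns]
    grouped = frame.groupby(keys + carry, observed=True)["correct"]
    out = grouped.agg(fraction_correct="mean", n_trials="count").reset_index()
    return out


class TTestResult(NamedTuple):
    t: float
    df: int
    p: float
    zero_variance: bool = False


def above_chance_test(fractions: Sequence[float], chance: float = 0.5) -> TTestResult:
    """One-sample t-test of per-agent accuracies against chance (df = n - 1).

    A zero-variance sample off chance yields an infinite t with a flag
    rather than an error.
    """
    x = np.asarray(fractions, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 agents")
    df = int(x.size - 1)
    if np.ptp(x) == 0:
        if x[0] == chance:
            return TTestResult(t=0.0, df=df, p=1.0, zero_variance=True)
        t = float(np.inf) if x[0] > chance else float(-np.inf)
        return TTestResult(t=t, df=df, p=0.0, zero_variance=True)
    res = stats.ttest_1samp(x, chance)
    return TTestResult(t=float(res.statistic), df=df, p=float(res.pvalue))


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Optional[Sequence[Sequence[float]]] = None,
) -> tuple[float, float]:
    """Spearman correlation of x and y, partialling out covariates on ranks.

    All variables are rank-transformed; the ranks of x and y are each
    residualized on the covariate ranks (linear least squares with
    intercept) and the residuals Pearson-correlated. With no covariates
    this is the ordinary Spearman rho. The two-sided p-value uses the
    t-approximation with df = n - 2 - (#covariates).

    A variable that is perfectly explained by the covariates leaves
    (numerically) zero residual variance; this degenerate limit is flagged
    with a warning and returned as rho = 0, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    covs = [np.asarray(c, dtype=float) for c in (covariates or [])]
    n = x.size
    if y.size != n or any(c.size != n for c in covs):
        raise ValueError("all inputs must have equal length")
    if n < 4:
        raise ValueError("need at least 4 observations")
    for c in covs:
        if np.ptp(c) == 0:
            raise ValueError("constant covariate")

    rx, ry = _rank(x), _rank(y)
    if covs:
        design = np.column_stack([np.ones(n)] + [_rank(c) for c in covs])
        rx = rx - design @ np.linalg.lstsq(design, rx, rcond=None)[0]
        ry = ry - design @ np.linalg.lstsq(design, ry, rcond=None)[0]
    scale = np.sqrt(np.sum((_rank(x) - _rank(x).mean()) ** 2))  # rank variance scale
    tol = 1e-10 * max(scale, 1.0)
    if np.sqrt(np.sum(rx**2 if covs else (rx - rx.mean()) ** 2)) < tol or np.sqrt(
        np.sum(ry**2 if covs else (ry - ry.mean()) ** 2)
    ) < tol:
        warnings.warn("variable perfectly explained by covariates; partial rho degenerate")
        return 0.0, 1.0
    if covs:
        rho = float(np.dot(rx, ry) / np.sqrt(np.dot(rx, rx) * np.dot(ry, ry)))
    else:
        rho = float(stats.spearmanr(x, y).statistic)
    df = n - 2 - len(covs)
    if df < 1:
        raise ValueError("not enough observations for the covariate count")
    rho_c = min(max(rho, -1.0 + 1e-15), 1.0 - 1e-15)
    t = rho_c * np.sqrt(df / (1.0 - rho_c**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p


class AgeTrend(NamedTuple):
    pearson_r: float
    pearson_p: float
    spearman_rho: float
    spearman_p: float


def age_trend(values: Sequence[float], ages: Sequence[float]) -> AgeTrend:
    """Pearson and Spearman correlation of a per-agent quantity with age.

    Correlation screening, not a mixed model. Constant inputs are flagged
    (NaN) rather than raised.
    """
    v = np.asarray(values, dtype=float)
    a = np.asarray(ages, dtype=float)
    if v.size != a.size:
        raise ValueError("values and ages must have equal length")
    if v.size < 4:
        raise ValueError("need at least 4 agents")
    if np.ptp(v) == 0 or np.ptp(a) == 0:
        warnings.warn("constant input: age trend undefined")
        return AgeTrend(np.nan, np.nan, np.nan, np.nan)
    pr = stats.pearsonr(v, a)
    sr = stats.spearmanr(v, a)
    return AgeTrend(
        pearson_r=float(pr.statistic),
        pearson_p=float(pr.pvalue),
        spearman_rho=float(sr.statistic),
        spearman_p=float(sr.pvalue),
    )
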