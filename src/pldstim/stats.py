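"""Repeated-measures statistics for participant x condition accuracy tables.

A score table is a pandas DataFrame with one row per participant and one
column per condition, values in percent (0-100).  The tests are the two
used for such tables: a one-way repeated-measures ANOVA from explicit
sums of squares, and the rank-based Friedman chi-square with average-rank
tie correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsError(ValueError):
    """Invalid table for the requested statistic."""


@dataclass(frozen=True)
class StatResult:
    """Test outcome: statistic, degrees of freedom, p, effect size.

    ``effect_size`` is partial eta squared (SS_cond / (SS_cond + SS_resid))
    for the ANOVA and None for Friedman.  ``degenerate`` flags a zero
    residual-variance table, where F is undefined.
    """

    statistic: float
    df: tuple[float, ...]
    p_value: float
    effect_size: float | None = None
    name: str = ""
    degenerate: bool = False


def _as_matrix(table: pd.DataFrame) -> np.ndarray:
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise StatsError(f"need a participants x conditions table, got shape {x.shape}")
    if np.isnan(x).any():
        raise StatsError("table has missing cells; exclude or impute before testing")
    return x


def rm_anova(table: pd.DataFrame) -> StatResult:
    """One-way repeated-measures ANOVA from explicit sums of squares.

    Partitions total variation into subjects, condition, and residual:
    F = MS_cond / MS_resid with df (k-1, (n-1)(k-1)).
    """
    x = _as_matrix(table)
    n, k = x.shape
    grand = x.mean()
    ss_subj = k * np.sum((x.mean(axis=1) - grand) ** 2)
    ss_cond = n * np.sum((x.mean(axis=0) - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_resid = ss_total - ss_subj - ss_cond
    df1, df2 = k - 1, (n - 1) * (k - 1)
    eta_p2 = ss_cond / (ss_cond + ss_resid) if (ss_cond + ss_resid) > 0 else 0.0
    if ss_resid <= 1e-12 * max(ss_total, 1.0):
        return StatResult(np.inf if ss_cond > 0 else 0.0, (df1, df2), 0.0 if ss_cond > 0 else 1.0,
                          eta_p2, name="rm_anova", degenerate=True)
    F = (ss_cond / df1) / (ss_resid / df2)
    p = float(sps.f.sf(F, df1, df2))
    return StatResult(float(F), (df1, df2), p, float(eta_p2), name="rm_anova")


def friedman(table: pd.DataFrame) -> StatResult:
    """Friedman rank test across repeated measures, with tie correction.

    Each participant's row is ranked (average ranks for ties); the
    chi-square statistic 12/(nk(k+1)) * sum(R_j^2) - 3n(k+1) is divided by
    the standard tie-correction factor.  df = k - 1.
    """
    x = _as_matrix(table)
    n, k = x.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, x)
    R = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * np.sum(R**2) - 3.0 * n * (k + 1)
    # tie correction: 1 - sum(t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    denom = 1.0 - ties / (n * k * (k**2 - 1))
    if denom <= 0:
        # every row fully tied: no evidence of any condition effect
        return StatResult(0.0, (k - 1,), 1.0, None, name="friedman", degenerate=True)
    chi2 = chi2 / denom
    p = float(sps.chi2.sf(chi2, k - 1))
    return StatResult(float(chi2), (k - 1,), p, None, name="friedman")


def exclude_outliers(
    table: pd.DataFrame, z: float = 3.0, min_conditions: int = 2
) -> pd.DataFrame:
    """Drop participants deviating more than ``z`` SDs in enough conditions.

    Column means and SDs are computed including the candidate participant.
    A participant is excluded when the criterion fires in at least
    ``min_conditions`` conditions.
    """
    x = _as_matrix(table)
    if x.shape[0] < 3:
        raise StatsError("need at least 3 participants for outlier screening")
    mean = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        flags = np.abs(x - mean) > z * np.where(sd > 0, sd, np.inf)
    drop = flags.sum(axis=1) >= min_conditions
    kept = table.loc[~drop]
    if len(kept) < 2:
        raise StatsError("outlier exclusion would leave fewer than 2 participants")
    return kept
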