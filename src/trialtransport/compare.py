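"""Standardized-mean-difference comparison of trial and target cohorts.

The SMD standardizes the trial-minus-target difference by the pooled
standard deviation:

    continuous:  (m1 - m2) / sqrt((s1^2 + s2^2) / 2)
    binary:      (p1 - p2) / sqrt((p1(1-p1) + p2(1-p2)) / 2)

Categorical variables are compared one level at a time, each level treated
as binary.  |SMD| > 0.1 flags a meaningful difference between the cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohorts import BINARY, CATEGORICAL, CONTINUOUS, CohortTable

__all__ = ["SMDRow", "smd_continuous", "smd_binary", "compare_table",
           "MEANINGFUL_SMD"]

MEANINGFUL_SMD = 0.1


@dataclass(frozen=True)
class SMDRow:
    """One comparison row: a variable (or categorical level) and its SMD."""

    variable: str
    var_type: str                       # continuous | binary | categorical-level
    trial_summary: tuple                # (mean, sd) or (proportion,)
    target_summary: tuple
    smd: float | None                   # None when undefined (degenerate proportion)
    n_trial: int = 0                    # non-missing counts (pairwise deletion)
    n_target: int = 0
    degenerate: bool = False            # proportion exactly 0 or 1 in a cohort

    @property
    def meaningful(self) -> bool:
        return self.smd is not None and abs(self.smd) > MEANINGFUL_SMD


def smd_continuous(m1: float, s1: float, m2: float, s2: float) -> float:
    """Pooled-SD standardized difference of two means (trial minus target)."""
    for v in (m1, s1, m2, s2):
        if not math.isfinite(v):
            raise ValueError("non-finite input to smd_continuous")
    if s1 <= 0 or s2 <= 0:
        raise ValueError("standard deviations must be positive")
    return (m1 - m2) / math.sqrt((s1 * s1 + s2 * s2) / 2.0)


def smd_binary(p1: float, p2: float) -> float:
    """Pooled-variance standardized difference of two proportions."""
    for v in (p1, p2):
        if not math.isfinite(v):
            raise ValueError("non-finite input to smd_binary")
    if not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0):
        raise ValueError("proportions must lie strictly inside (0, 1); "
                         "degenerate cells are reported with a flag instead")
    return (p1 - p2) / math.sqrt((p1 * (1 - p1) + p2 * (1 - p2)) / 2.0)


def compare_table(trial: CohortTable, target: CohortTable,
                  variables: list[str] | None = None) -> list[SMDRow]:
    """Baseline-characteristics comparison, one row per variable or level.

    Missing cells are excluded pairwise, with the non-missing counts carried
    on each row.  A proportion of exactly 0 or 1 in either cohort leaves the
    SMD undefined: the row is emitted with ``smd=None`` and ``degenerate``.
    """
    if trial.n == 0 or target.n == 0:
        raise ValueError("cannot compare an empty cohort")
    if variables is None:
        variables = [v for v in trial.covariate_names
                     if v in set(target.covariate_names)]
    rows: list[SMDRow] = []
    for name in variables:
        for cohort in (trial, target):
            if name not in cohort.data.columns:
                raise KeyError(f"variable {name!r} absent from {cohort.role} cohort")
        kind = trial.schema.get(name) or target.schema.get(name)
        a = trial.data[name].dropna()
        b = target.data[name].dropna()
        if kind == CONTINUOUS:
            rows.append(_continuous_row(name, a, b))
        elif kind == BINARY:
            rows.append(_binary_row(name, kind, a.astype(float).mean(),
                                    b.astype(float).mean(), len(a), len(b)))
        elif kind == CATEGORICAL:
            levels = sorted(set(a.unique()) | set(b.unique()), key=str)
            for lev in levels:
                rows.append(_binary_row(
                    f"{name}={lev}", "categorical-level",
                    float((a == lev).mean()), float((b == lev).mean()),
                    len(a), len(b)))
        else:
            raise ValueError(f"variable {name!r} has no declared type")
    return rows


def _continuous_row(name, a: pd.Series, b: pd.Series) -> SMDRow:
    m1, s1 = float(a.mean()), float(a.std(ddof=1))
    m2, s2 = float(b.mean()), float(b.std(ddof=1))
    smd = smd_continuous(m1, s1, m2, s2) if s1 > 0 and s2 > 0 else None
    return SMDRow(name, CONTINUOUS, (m1, s1), (m2, s2), smd,
                  n_trial=len(a), n_target=len(b),
                  degenerate=smd is None)


def _binary_row(name, var_type, p1, p2, n1, n2) -> SMDRow:
    degenerate = not (0.0 < p1 < 1.0 and 0.0 < p2 < 1.0)
    smd = None if degenerate else smd_binary(p1, p2)
    return SMDRow(name, var_type, (p1,), (p2,), smd,
                  n_trial=n1, n_target=n2, degenerate=degenerate)


def smd_frame(rows: list[SMDRow]) -> pd.DataFrame:
    """Tidy DataFrame view of a comparison table."""
    return pd.DataFrame([
        {
            "variable": r.variable,
            "type": r.var_type,
            "trial_summary": "/".join(f"{v:.3g}" for v in r.trial_summary),
            "target_summary": "/".join(f"{v:.3g}" for v in r.target_summary),
            "smd": np.nan if r.smd is None else round(r.smd, 2),
            "meaningful": r.meaningful,
            "n_trial": r.n_trial,
            "n_target": r.n_target,
        }
        for r in rows
    ])
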