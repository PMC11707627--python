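"""Counterfactual standardization of trial treatment effects to targets.

The trial mean effect refits the arm contrast inside the trial: a survival
model with treatment as the only covariate, standardized risks under "all in
the intensive arm" and "all in the standard arm", and their ratio/difference
at the horizon.  Transport fits arm-specific outcome models on the trial over
baseline covariates, predicts each target subject's counterfactual risks, and
averages over the target (the outcome-model / g-formula estimator).
"""

from __future__ import annotations

import math
import operator
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohorts import CohortTable
from .survival import RPSplineModel, fit_rp

__all__ = [
    "RiskEstimate",
    "TransportResult",
    "EligibilityRule",
    "apply_eligibility",
    "trial_mean_effect",
    "transport_effect",
    "subgroup_transport",
    "nnt_from_rd",
    "NNTResult",
    "UndefinedNNTError",
    "estimate_agreement",
    "fit_arm_models",
    "standardize",
]


# ---------------------------------------------------------------------------
# result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskEstimate:
    """Standardized counterfactual risks at a horizon with their contrast.

    ``risk1``/``risk0`` are the population mean outcome probabilities had
    everyone been treated to the intensive / standard regime; ``rr`` and
    ``rd`` are derived from them, never stored independently.
    """

    risk1: float
    risk0: float
    horizon: float
    population_id: str = ""
    outcome: str = ""
    n: int = 0

    def __post_init__(self):
        for name, r in (("risk0", self.risk0), ("risk1", self.risk1)):
            if not (0.0 <= r <= 1.0):
                raise ValueError(f"{name}={r} outside [0, 1]")
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")

    @property
    def rr(self) -> float:
        return self.risk1 / self.risk0 if self.risk0 > 0 else math.inf

    @property
    def rd(self) -> float:
        return self.risk1 - self.risk0


@dataclass(frozen=True)
class NNTResult:
    """Nearest-integer 1/|RD|, labelled NNT (benefit) or NNH (harm)."""

    value: int
    label: str  # "NNT" | "NNH"


@dataclass
class TransportResult:
    """A transported (or trial) estimate with its bootstrap intervals."""

    estimate: RiskEstimate
    rr_ci: tuple[float, float] | None = None
    rd_ci: tuple[float, float] | None = None
    nnt: NNTResult | None = None
    agrees_with_trial: bool | None = None
    n_boot_used: int = 0
    n_boot_skipped: int = 0
    extrapolation_count: int | None = None
    #: pooled point estimates when imputation pooling makes the mean of
    #: per-imputation RRs differ from the ratio of pooled risks; default to
    #: the contrasts of ``estimate``.
    rr_point: float | None = None
    rd_point: float | None = None

    def __post_init__(self):
        for ci in (self.rr_ci, self.rd_ci):
            if ci is not None and ci[0] > ci[1]:
                raise ValueError(f"interval reversed: {ci}")
        if self.rr_point is None:
            self.rr_point = self.estimate.rr
        if self.rd_point is None:
            self.rd_point = self.estimate.rd


# ---------------------------------------------------------------------------
# eligibility rules
# ---------------------------------------------------------------------------

_COMPARATORS = {
    "<": operator.lt,
    "<=": operator.le,
    ">": operator.gt,
    ">=": operator.ge,
    "==": operator.eq,
    "=": operator.eq,
}


@dataclass(frozen=True)
class EligibilityRule:
    """One inclusion rule: keep rows where ``variable <comparator> bound``.

    ``comparator`` is one of ``< <= > >= = in-set in-range`` (in-range is the
    half-open interval [lo, hi)).  ``on_missing`` says what to do with rows
    whose value is missing: ``exclude`` (drop and count) or ``keep``.
    """

    variable: str
    comparator: str
    bound: object
    on_missing: str = "exclude"

    def __post_init__(self):
        if self.comparator not in (*_COMPARATORS, "in-set", "in-range"):
            raise ValueError(f"unknown comparator {self.comparator!r}")
        if self.on_missing not in ("exclude", "keep"):
            raise ValueError(f"on_missing must be 'exclude' or 'keep', got {self.on_missing!r}")
        if self.comparator == "in-range":
            lo, hi = self.bound  # type: ignore[misc]
            if not lo < hi:
                raise ValueError("in-range bound must be (lo, hi) with lo < hi")
        if self.comparator == "in-set" and not isinstance(self.bound, (list, tuple, set, frozenset)):
            raise ValueError("in-set bound must be a collection")

    def mask(self, df: pd.DataFrame) -> np.ndarray:
        if self.variable not in df.columns:
            raise KeyError(f"rule variable {self.variable!r} not in cohort schema")
        col = df[self.variable]
        missing = col.isna().to_numpy()
        if self.comparator == "in-set":
            ok = col.isin(list(self.bound)).to_numpy()
        elif self.comparator == "in-range":
            lo, hi = self.bound
            ok = ((col >= lo) & (col < hi)).to_numpy()
        else:
            ok = _COMPARATORS[self.comparator](col, self.bound).to_numpy()
        ok = np.where(missing, self.on_missing == "keep", ok)
        return ok.astype(bool)


def apply_eligibility(
    cohort: CohortTable, rules: list[EligibilityRule], return_report: bool = False
):
    """Subset a cohort to rows satisfying the conjunction of rules.

    Rules are applied in order; the report counts rows removed by each rule
    among those surviving the previous ones.
    """
    keep = np.ones(cohort.n, dtype=bool)
    report: list[tuple[str, int]] = []
    for rule in rules:
        ok = rule.mask(cohort.data)
        removed = int(np.sum(keep & ~ok))
        report.append((f"{rule.variable} {rule.comparator} {rule.bound}", removed))
        keep &= ok
    out = cohort.subset(keep)
    return (out, report) if return_report else out


# ---------------------------------------------------------------------------
# estimators
# ---------------------------------------------------------------------------

def trial_mean_effect(
    trial: CohortTable, horizon: float = 4.0, n_internal_knots: int = 2,
    outcome: str = "",
) -> RiskEstimate:
    """Trial mean treatment effect: counterfactual RR/RD at the horizon from a
    model with treatment group as the only covariate, standardized over the
    trial (degenerate here: the standardized risk under arm a is the model's
    predicted risk at arm a)."""
    arms = trial.data["arm"].to_numpy()
    if len(np.unique(arms)) < 2:
        raise ValueError("trial has a single arm; cannot estimate a contrast")
    work = trial.with_data(trial.data.assign(_treat=trial.data["arm"].astype(float)))
    work.schema["_treat"] = "binary"
    model = fit_rp(work, ["_treat"], n_internal_knots=n_internal_knots)
    risk0 = model.predict_risk({"_treat": 0.0}, horizon)
    risk1 = model.predict_risk({"_treat": 1.0}, horizon)
    return RiskEstimate(risk1=risk1, risk0=risk0, horizon=horizon,
                        population_id=trial.population_id, outcome=outcome,
                        n=trial.n)


def fit_arm_models(
    trial: CohortTable, covariates: list[str], n_internal_knots: int = 2,
) -> tuple[RPSplineModel, RPSplineModel]:
    """Arm-specific outcome models fitted on the trial subsets (standard, intensive)."""
    models = []
    for a in (0, 1):
        sub = trial.subset(trial.data["arm"].to_numpy() == a)
        models.append(fit_rp(sub, covariates, n_internal_knots=n_internal_knots))
    return models[0], models[1]


def standardize(
    model0: RPSplineModel, model1: RPSplineModel,
    target: CohortTable, horizon: float, outcome: str = "",
) -> RiskEstimate:
    """Mean counterfactual risks of a target under each fitted arm model."""
    if target.n == 0:
        raise ValueError("target cohort is empty")
    df = target.data
    risk0 = float(np.mean(model0.predict_risk_frame(df, horizon)))
    risk1 = float(np.mean(model1.predict_risk_frame(df, horizon)))
    return RiskEstimate(risk1=risk1, risk0=risk0, horizon=horizon,
                        population_id=target.population_id, outcome=outcome,
                        n=target.n)


def transport_effect(
    trial: CohortTable,
    target: CohortTable,
    covariates: list[str],
    horizon: float = 4.0,
    n_internal_knots: int = 2,
    outcome: str = "",
) -> RiskEstimate:
    """Outcome-model transport of the trial contrast into the target.

    Fits one model per arm on the trial over ``covariates``, predicts each
    target subject's risk under both regimes at ``horizon`` and averages over
    the target.  Covariates must be complete (run after imputation).
    """
    for name in covariates:
        if name not in trial.data.columns:
            raise KeyError(f"covariate {name!r} absent from trial cohort")
        if name not in target.data.columns:
            raise KeyError(f"covariate {name!r} absent from target cohort")
    m0, m1 = fit_arm_models(trial, covariates, n_internal_knots)
    return standardize(m0, m1, target, horizon, outcome=outcome)


def subgroup_transport(
    trial: CohortTable,
    target: CohortTable,
    covariates: list[str],
    horizon: float,
    predicate: list[EligibilityRule],
    n_internal_knots: int = 2,
    restrict_trial: bool = False,
    outcome: str = "",
) -> RiskEstimate:
    """Transport restricted to the target subgroup selected by ``predicate``.

    The outcome models stay fitted on the full trial unless ``restrict_trial``
    explicitly requests refitting on the analogous trial subgroup.
    """
    sub = apply_eligibility(target, predicate)
    if sub.n == 0:
        raise ValueError("subgroup predicate leaves an empty target")
    trial_used = apply_eligibility(trial, predicate) if restrict_trial else trial
    return transport_effect(trial_used, sub, covariates, horizon,
                            n_internal_knots=n_internal_knots, outcome=outcome)


def extrapolation_count(trial: CohortTable, target: CohortTable,
                        covariates: list[str]) -> int:
    """Number of target subjects with any continuous covariate outside the
    trial's observed range (the outcome-model approach extrapolates there)."""
    out = np.zeros(target.n, dtype=bool)
    for name in covariates:
        if trial.schema.get(name) != "continuous":
            continue
        lo, hi = trial.data[name].min(), trial.data[name].max()
        v = target.data[name]
        out |= ((v < lo) | (v > hi)).fillna(False).to_numpy()
    return int(out.sum())


# ---------------------------------------------------------------------------
# effect summaries
# ---------------------------------------------------------------------------

class UndefinedNNTError(ValueError):
    """RD is exactly zero: neither NNT nor NNH is defined."""


def nnt_from_rd(rd: float) -> NNTResult:
    """Number needed to treat/harm from a risk difference.

    Nearest integer of 1/|rd|; NNT when the intensive regime lowers risk
    (rd < 0), NNH when it raises it (rd > 0).
    """
    if not np.isfinite(rd):
        raise ValueError("risk difference must be finite")
    if rd == 0:
        raise UndefinedNNTError("risk difference is zero; NNT/NNH undefined")
    return NNTResult(value=int(round(1.0 / abs(rd))),
                     label="NNT" if rd < 0 else "NNH")


def estimate_agreement(target_point: float, trial_ci: tuple[float, float]) -> bool:
    """Estimate-agreement criterion: the target point estimate falls inside
    the trial's 95% CI (closed interval)."""
    lo, hi = trial_ci
    if not (np.isfinite(target_point) and np.isfinite(lo) and np.isfinite(hi)):
        raise ValueError("non-finite input to estimate_agreement")
    if lo > hi:
        raise ValueError("trial CI has lower > upper")
    return bool(lo <= target_point <= hi)
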