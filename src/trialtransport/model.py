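"""Model/results interface for a full transport analysis.

:class:`TransportAnalysis` is constructed from a trial cohort and a target
cohort; ``fit()`` runs the whole procedure — baseline comparison, eligibility
filtering, trial mean effect with bootstrap CI, transported effect with the
nested-imputation bootstrap, subgroup transports, estimate agreement and
NNT/NNH — and returns a :class:`TransportAnalysisResults` carrying the
estimates, their intervals and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .cohorts import CohortTable
from .compare import SMDRow, compare_table, smd_frame
from .inference import BootstrapSpec, bootstrap_trial_ci, transported_ci
from .transport import (EligibilityRule, TransportResult, apply_eligibility,
                        estimate_agreement, extrapolation_count, nnt_from_rd,
                        UndefinedNNTError)

__all__ = ["TransportAnalysis", "TransportAnalysisResults"]


class TransportAnalysis:
    """Transportability analysis of a two-arm trial into one target cohort.

    Parameters
    ----------
    trial, target
        Trial-role and target-role cohorts (the target may still contain
        missing covariates; imputation runs inside ``fit``).
    covariates
        Baseline covariates for the arm-specific outcome models (default:
        all covariates shared by the two cohorts).
    horizon
        Risk horizon in years (default 4).
    eligibility
        Rules applied to the target before anything else.
    subgroups
        Mapping subgroup label -> predicate (list of rules) for restricted
        transports, e.g. advanced-CKD strata.
    """

    def __init__(self, trial: CohortTable, target: CohortTable,
                 covariates: list[str] | None = None, horizon: float = 4.0,
                 eligibility: list[EligibilityRule] | None = None,
                 subgroups: dict[str, list[EligibilityRule]] | None = None,
                 n_internal_knots: int = 2, outcome: str = "primary"):
        self.trial = trial
        self.target = target
        shared = [c for c in trial.covariate_names
                  if c in set(target.covariate_names)]
        self.covariates = list(covariates) if covariates is not None else shared
        self.horizon = horizon
        self.eligibility = list(eligibility or [])
        self.subgroups = dict(subgroups or {})
        self.n_internal_knots = n_internal_knots
        self.outcome = outcome

    @classmethod
    def from_dataframes(cls, trial_df: pd.DataFrame, target_df: pd.DataFrame,
                        population_id: str = "target", **kwargs) -> "TransportAnalysis":
        return cls(CohortTable(trial_df, role="trial"),
                   CohortTable(target_df, role="target", population_id=population_id),
                   **kwargs)

    def fit(self, trial_boot: BootstrapSpec | None = None,
            transport_boot: BootstrapSpec | None = None,
            seed: int = 0) -> "TransportAnalysisResults":
        trial_boot = trial_boot or BootstrapSpec(B=1000, seed=seed)
        transport_boot = transport_boot or BootstrapSpec(B=500, m_within=10, seed=seed)

        target, elig_report = apply_eligibility(
            self.target, self.eligibility, return_report=True)
        if target.n == 0:
            raise ValueError("eligibility rules exclude the whole target")

        smd_rows = compare_table(self.trial, target, self.covariates)
        trial_fit = bootstrap_trial_ci(self.trial, self.horizon, trial_boot,
                                       n_internal_knots=self.n_internal_knots)
        transported = transported_ci(
            self.trial, target, self.covariates, self.horizon, transport_boot,
            n_internal_knots=self.n_internal_knots,
            trial_rr_ci=trial_fit["rr_ci"], outcome=self.outcome)
        transported.extrapolation_count = extrapolation_count(
            self.trial, target, self.covariates)

        subgroup_results = {}
        for label, predicate in self.subgroups.items():
            sub = apply_eligibility(target, predicate)
            if sub.n == 0:
                raise ValueError(f"subgroup {label!r} is empty")
            subgroup_results[label] = transported_ci(
                self.trial, sub, self.covariates, self.horizon, transport_boot,
                n_internal_knots=self.n_internal_knots,
                trial_rr_ci=trial_fit["rr_ci"], outcome=self.outcome)

        return TransportAnalysisResults(
            model=self, target_used=target, eligibility_report=elig_report,
            smd_rows=smd_rows, trial_fit=trial_fit, transported=transported,
            subgroups=subgroup_results)


@dataclass
class TransportAnalysisResults:
    """Fitted estimates, intervals and diagnostics of a transport analysis."""

    model: TransportAnalysis
    target_used: CohortTable
    eligibility_report: list[tuple[str, int]]
    smd_rows: list[SMDRow]
    trial_fit: dict
    transported: TransportResult
    subgroups: dict[str, TransportResult] = field(default_factory=dict)

    # ------------------------------------------------------------------
    @property
    def trial_estimate(self):
        return self.trial_fit["estimate"]

    @property
    def smd_table(self) -> pd.DataFrame:
        return smd_frame(self.smd_rows)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format results: one row per (population, scale)."""
        rows = []
        tr = self.trial_estimate
        rows.append(_row("trial", self.model.outcome, "full", "rr", tr.rr,
                         self.trial_fit["rr_ci"], None, None))
        rows.append(_row("trial", self.model.outcome, "full", "rd", tr.rd,
                         self.trial_fit["rd_ci"], None, _nnt(tr.rd)))
        items = [("full", self.transported)] + list(self.subgroups.items())
        pop = self.target_used.population_id or "target"
        for label, res in items:
            rows.append(_row(pop, self.model.outcome, label, "rr",
                             res.rr_point, res.rr_ci, res.agrees_with_trial, None))
            rows.append(_row(pop, self.model.outcome, label, "rd",
                             res.rd_point, res.rd_ci, None, res.nnt))
        return pd.DataFrame(rows)

    def summary(self) -> str:
        h = self.model.horizon
        tr = self.trial_estimate
        lines = [
            "Transportability analysis".center(72),
            "=" * 72,
            f"Outcome: {self.model.outcome}    Horizon: {h:g} y    "
            f"Covariates: {len(self.model.covariates)}",
            f"Trial n = {self.model.trial.n}; target ({self.target_used.population_id}) "
            f"n = {self.target_used.n} after eligibility",
            "-" * 72,
            f"{'population':<16}{'scale':<7}{'estimate':>10}{'95% CI':>22}{'agree':>8}",
            "-" * 72,
            _fmt("trial", "RR", tr.rr, self.trial_fit["rr_ci"], ""),
            _fmt("trial", "RD", tr.rd, self.trial_fit["rd_ci"], ""),
        ]
        pop = self.target_used.population_id or "target"
        items = [(pop, self.transported)] + [
            (f"{pop}:{k}", v) for k, v in self.subgroups.items()]
        for label, res in items:
            agree = {True: "yes", False: "no", None: ""}[res.agrees_with_trial]
            lines.append(_fmt(label, "RR", res.rr_point, res.rr_ci, agree))
            nnt = f"{res.nnt.label} {res.nnt.value}" if res.nnt else ""
            lines.append(_fmt(label, "RD", res.rd_point, res.rd_ci, nnt))
        lines.append("-" * 72)
        lines.append(f"meaningful baseline differences (|SMD| > 0.1): "
                     f"{sum(r.meaningful for r in self.smd_rows)}/{len(self.smd_rows)}")
        if self.transported.extrapolation_count is not None:
            lines.append(f"target subjects outside trial covariate support: "
                         f"{self.transported.extrapolation_count}")
        return "\n".join(lines)


def _nnt(rd):
    try:
        return nnt_from_rd(rd)
    except UndefinedNNTError:
        return None


def _row(pop, outcome, subgroup, scale, est, ci, agree, nnt):
    return {
        "population": pop, "outcome": outcome, "subgroup": subgroup,
        "scale": scale, "estimate": est,
        "ci_low": ci[0] if ci else None, "ci_high": ci[1] if ci else None,
        "agreement": agree,
        "nnt_label": nnt.label if nnt else None,
        "nnt_value": nnt.value if nnt else None,
    }


def _fmt(label, scale, est, ci, extra):
    ci_s = f"({ci[0]:.3f}, {ci[1]:.3f})" if ci else ""
    return f"{label:<16}{scale:<7}{est:>10.3f}{ci_s:>22}{extra:>8}"
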