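"""Fully-conditional-specification (chained-equations) multiple imputation.

Trial and target cohorts are stacked into one table and each incomplete
covariate is imputed conditionally on all other covariates plus three
auxiliary columns: the selection indicator S (1 = trial row), the treatment
indicator A (the randomized arm; a constant 0 fill for target rows, which
have no arm by construction), and the Nelson-Aalen estimate of the primary
outcome's cumulative hazard evaluated at the subject's own time (constant 0
fill for target rows).  S separates the two fill regimes, so the constant
codes carry no information beyond it.

Conditional models follow the chained-equations defaults: Bayesian-draw
linear regression for continuous variables, logistic regression with a
posterior coefficient draw for binary, multinomial logit for categorical.
Observed cells are never altered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cohorts import BINARY, CATEGORICAL, CONTINUOUS, CohortTable
from .survival import nelson_aalen

__all__ = ["ImputedStack", "fcs_impute", "ImputationError"]

_AUX = ["_S", "_A", "_naH"]


class ImputationError(ValueError):
    pass


@dataclass
class ImputedStack:
    """m completed datasets sharing every observed cell."""

    m: int
    completed: list[pd.DataFrame]           # stacked tables incl. auxiliaries
    n_trial: int
    trial_template: CohortTable
    target_template: CohortTable
    methods: dict[str, str] = field(default_factory=dict)
    seed: int = 0
    had_missing: bool = True

    def trial(self, i: int) -> CohortTable:
        df = self.completed[i].iloc[: self.n_trial].reset_index(drop=True)
        out = self.trial_template.data.copy()
        for c in self.trial_template.covariate_names:
            out[c] = df[c].to_numpy()
        return self.trial_template.with_data(out)

    def target(self, i: int) -> CohortTable:
        df = self.completed[i].iloc[self.n_trial:].reset_index(drop=True)
        out = self.target_template.data.copy()
        for c in self.target_template.covariate_names:
            out[c] = df[c].to_numpy()
        return self.target_template.with_data(out)


def fcs_impute(
    trial: CohortTable,
    target: CohortTable,
    m: int = 10,
    n_cycles: int = 10,
    seed: int = 0,
    variables: list[str] | None = None,
) -> ImputedStack:
    """Impute missing covariates over the stacked trial + target table.

    Parameters
    ----------
    variables
        Covariates eligible for imputation (default: all shared covariates).
    """
    if m < 1:
        raise ImputationError("m must be >= 1")
    shared = [c for c in trial.covariate_names if c in set(target.covariate_names)]
    variables = list(variables) if variables is not None else shared
    for v in variables:
        if v not in shared:
            raise ImputationError(f"variable {v!r} not shared by trial and target")

    # stacked working table: shared covariates + auxiliaries
    na = nelson_aalen(trial.data["time"].to_numpy(), trial.data["event"].to_numpy())
    tr = trial.data[shared].copy()
    tr["_S"] = 1.0
    tr["_A"] = trial.data["arm"].to_numpy(dtype=float)
    tr["_naH"] = na.at_subject_times
    tg = target.data[shared].copy()
    tg["_S"] = 0.0
    tg["_A"] = 0.0
    tg["_naH"] = 0.0
    base = pd.concat([tr, tg], ignore_index=True)

    masks = {v: base[v].isna().to_numpy() for v in variables}
    incomplete = [v for v in variables if masks[v].any()]
    for v in incomplete:
        if masks[v].all():
            raise ImputationError(f"variable {v!r} is 100% missing; cannot impute")
    other_missing = base.drop(columns=variables, errors="ignore").isna().any().any()
    if other_missing:
        raise ImputationError("missing values outside the declared imputation variables")

    kinds = {v: trial.schema.get(v, CONTINUOUS) for v in shared}
    methods = {v: {CONTINUOUS: "bayes-linear", BINARY: "logistic",
                   CATEGORICAL: "multinomial"}[kinds[v]] for v in incomplete}

    if not incomplete:
        warnings.warn("no missing data: returning m identical completed copies",
                      stacklevel=2)
        return ImputedStack(m=m, completed=[base.copy() for _ in range(m)],
                            n_trial=trial.n, trial_template=trial,
                            target_template=target, methods={}, seed=seed,
                            had_missing=False)

    order = sorted(incomplete, key=lambda v: masks[v].sum())
    root = np.random.SeedSequence(seed)
    completed = []
    for child in root.spawn(m):
        rng = np.random.default_rng(child)
        work = base.copy()
        for v in order:  # initial fill: draws from the observed margin
            obs = work.loc[~masks[v], v].to_numpy()
            work.loc[masks[v], v] = rng.choice(obs, size=int(masks[v].sum()))
        for _ in range(n_cycles):
            for v in order:
                _impute_one(work, v, masks[v], kinds, shared, rng)
        completed.append(work)

    return ImputedStack(m=m, completed=completed, n_trial=trial.n,
                        trial_template=trial, target_template=target,
                        methods=methods, seed=seed)


# ---------------------------------------------------------------------------
# univariate conditional draws
# ---------------------------------------------------------------------------

def _predictor_matrix(work: pd.DataFrame, v: str, kinds: dict[str, str],
                      shared: list[str]) -> np.ndarray:
    cols = [np.ones(len(work))]
    for name in shared + _AUX:
        if name == v:
            continue
        if kinds.get(name) == CATEGORICAL:
            levels = sorted(map(str, pd.unique(work[name].astype(str))))[1:]
            for lev in levels:
                cols.append((work[name].astype(str) == lev).to_numpy(dtype=float))
        else:
            cols.append(work[name].to_numpy(dtype=float))
    return np.column_stack(cols)


def _impute_one(work, v, mask, kinds, shared, rng):
    X = _predictor_matrix(work, v, kinds, shared)
    Xo, Xm = X[~mask], X[mask]
    kind = kinds[v]
    if kind == CONTINUOUS:
        y = work.loc[~mask, v].to_numpy(dtype=float)
        work.loc[mask, v] = _bayes_linear_draw(Xo, y, Xm, rng)
    elif kind == BINARY:
        y = work.loc[~mask, v].to_numpy(dtype=float)
        p = _logistic_draw(Xo, y, Xm, rng)
        work.loc[mask, v] = (rng.uniform(size=len(Xm)) < p).astype(float)
    else:
        y = work.loc[~mask, v].astype(str)
        work.loc[mask, v] = _multinomial_draw(Xo, y, Xm, rng)


def _bayes_linear_draw(Xo, y, Xm, rng):
    """mice-style 'norm': draw sigma^2 and beta from their posterior, then
    predictive draws for the missing rows."""
    n, p = Xo.shape
    XtX = Xo.T @ Xo + 1e-8 * np.eye(p)
    XtX_inv = np.linalg.pinv(XtX)
    bhat = XtX_inv @ (Xo.T @ y)
    resid = y - Xo @ bhat
    dof = max(n - p, 1)
    sigma2 = float(resid @ resid) / rng.chisquare(dof)
    L = np.linalg.cholesky(XtX_inv + 1e-12 * np.eye(p))
    beta = bhat + np.sqrt(sigma2) * (L @ rng.standard_normal(p))
    return Xm @ beta + np.sqrt(sigma2) * rng.standard_normal(len(Xm))


def _logistic_draw(Xo, y, Xm, rng):
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, Xo).fit(disp=0, maxiter=100)
            cov = np.asarray(res.cov_params())
        if not np.all(np.isfinite(cov)):
            raise np.linalg.LinAlgError
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
        beta = res.params + L @ rng.standard_normal(len(res.params))
        eta = np.clip(Xm @ beta, -30, 30)
        return 1.0 / (1.0 + np.exp(-eta))
    except Exception:
        # separation / singular fit: fall back to the observed margin
        return np.full(len(Xm), float(np.mean(y)))


def _multinomial_draw(Xo, y, Xm, rng):
    levels = np.array(sorted(y.unique()))
    codes = pd.Categorical(y, categories=levels).codes
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.MNLogit(codes, Xo).fit(disp=0, maxiter=100)
        params = np.asarray(res.params)  # (p, K-1)
        cov = np.asarray(res.cov_params())
        flat = params.flatten(order="F")
        L = np.linalg.cholesky(cov + 1e-10 * np.eye(cov.shape[0]))
        draw = flat + L @ rng.standard_normal(flat.size)
        params = draw.reshape(params.shape, order="F")
        eta = np.column_stack([np.zeros(len(Xm)), Xm @ params])
        eta -= eta.max(axis=1, keepdims=True)
        prob = np.exp(eta)
        prob /= prob.sum(axis=1, keepdims=True)
    except Exception:
        counts = pd.Series(codes).value_counts(normalize=True).sort_index()
        prob = np.tile(counts.to_numpy(), (len(Xm), 1))
    cum = np.cumsum(prob, axis=1)
    u = rng.uniform(size=len(Xm))[:, None]
    idx = (u > cum).sum(axis=1).clip(0, len(levels) - 1)
    return levels[idx]
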