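"""Flexible parametric survival models and the Nelson-Aalen estimator.

The model family expresses the log cumulative hazard as a restricted (natural)
cubic spline in log time with covariates acting proportionally on the hazard:

    log H(t | x) = s(u; knots)' gamma + x' beta,   u = log t,

where ``s(u) = [1, u, v_1(u), ..., v_K(u)]`` and each ``v_j`` is a restricted
cubic term that is linear beyond the boundary knots.  With zero internal knots
the basis collapses to ``[1, u]`` and the model is exactly Weibull
(``H = exp(gamma_0) t^{gamma_1}``), which supplies a closed-form oracle for
testing.  Fitting maximizes the right-censored log-likelihood

    sum_i d_i log h(t_i | x_i) - H(t_i | x_i)

by quasi-Newton with an analytic gradient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .cohorts import CohortTable

__all__ = [
    "spline_basis",
    "spline_basis_deriv",
    "default_knots",
    "RPSplineModel",
    "fit_rp",
    "predict_risk",
    "nelson_aalen",
    "HazardPath",
    "FitError",
]


class FitError(RuntimeError):
    """Model fitting failed; carries convergence diagnostics when available."""


# ---------------------------------------------------------------------------
# restricted cubic spline basis on the log-time axis
# ---------------------------------------------------------------------------

def spline_basis(u, knots) -> np.ndarray:
    """Evaluate the restricted cubic basis ``[1, u, v_1(u), ..., v_K(u)]``.

    ``knots`` are strictly increasing positions on the log-time axis; the
    first and last are boundary knots, the rest internal.  Each internal term

        v_j(u) = (u - k_j)_+^3 - l_j (u - k_min)_+^3 - (1 - l_j)(u - k_max)_+^3,
        l_j = (k_max - k_j) / (k_max - k_min),

    has zero second derivative beyond the boundary knots, so the fitted log
    cumulative hazard is linear in log time outside them.
    """
    u = np.atleast_1d(np.asarray(u, dtype=float))
    knots = _check_knots(knots)
    kmin, kmax = knots[0], knots[-1]
    cols = [np.ones_like(u), u]
    for kj in knots[1:-1]:
        lj = (kmax - kj) / (kmax - kmin)
        cols.append(
            _pos3(u - kj) - lj * _pos3(u - kmin) - (1.0 - lj) * _pos3(u - kmax)
        )
    return np.column_stack(cols)


def spline_basis_deriv(u, knots) -> np.ndarray:
    """d/du of :func:`spline_basis`, needed for the hazard."""
    u = np.atleast_1d(np.asarray(u, dtype=float))
    knots = _check_knots(knots)
    kmin, kmax = knots[0], knots[-1]
    cols = [np.zeros_like(u), np.ones_like(u)]
    for kj in knots[1:-1]:
        lj = (kmax - kj) / (kmax - kmin)
        cols.append(
            3.0 * (_pos2(u - kj) - lj * _pos2(u - kmin) - (1.0 - lj) * _pos2(u - kmax))
        )
    return np.column_stack(cols)


def _pos3(x):
    return np.where(x > 0, x, 0.0) ** 3


def _pos2(x):
    return np.where(x > 0, x, 0.0) ** 2


def _check_knots(knots) -> np.ndarray:
    knots = np.asarray(knots, dtype=float)
    if knots.ndim != 1 or knots.size < 2:
        raise ValueError("need at least 2 knots (the boundaries)")
    if np.any(np.diff(knots) <= 0):
        raise ValueError("knots must be strictly increasing")
    return knots


def default_knots(times, events, n_internal: int) -> np.ndarray:
    """Boundary knots at min/max uncensored log event times, internal knots at
    equally spaced centiles of the uncensored log event times."""
    lt = np.log(np.asarray(times, dtype=float)[np.asarray(events).astype(bool)])
    if lt.size < 2:
        raise FitError("need at least 2 distinct event times to place knots")
    if n_internal == 0:
        qs = np.array([0.0, 1.0])
    else:
        qs = np.linspace(0.0, 1.0, n_internal + 2)
    knots = np.quantile(lt, qs)
    # collapse ties from heavily duplicated event times
    knots = np.unique(knots)
    if knots.size < 2:
        raise FitError("degenerate knot placement: all event times equal")
    return knots


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class RPSplineModel:
    """A fitted spline log-cumulative-hazard survival model."""

    knots: np.ndarray
    gamma: np.ndarray
    beta_cov: np.ndarray
    covariate_names: list[str]
    encoding: dict[str, list] = field(default_factory=dict)  # categorical -> non-reference levels
    loglike: float = np.nan
    n_iter: int = 0
    converged: bool = False
    n_events: int = 0
    n_obs: int = 0

    # -- prediction -------------------------------------------------------
    def design_row(self, x) -> np.ndarray:
        """Encode one covariate row (mapping or Series) per the training schema."""
        return self.design_matrix(pd.DataFrame([dict(x)]))[0]

    def design_matrix(self, df: pd.DataFrame) -> np.ndarray:
        cols = []
        for name in self.covariate_names:
            if name not in df.columns:
                raise KeyError(f"covariate {name!r} absent from input")
            if name in self.encoding:
                raw = df[name]
                seen = set(self.encoding[name]) | {self._reference[name]}
                bad = set(raw.dropna().unique()) - seen
                if bad:
                    raise ValueError(
                        f"covariate {name!r} has level(s) unseen at fit time: {sorted(map(str, bad))}"
                    )
                for level in self.encoding[name]:
                    cols.append((raw == level).to_numpy(dtype=float))
            else:
                vals = df[name].to_numpy(dtype=float)
                if np.isnan(vals).any():
                    raise ValueError(f"covariate {name!r} contains missing values")
                cols.append(vals)
        if not cols:
            return np.zeros((len(df), 0))
        return np.column_stack(cols)

    @property
    def _reference(self) -> dict:
        return getattr(self, "_reference_levels", {})

    def cumulative_hazard(self, times, X: np.ndarray | None = None) -> np.ndarray:
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if np.any(times <= 0):
            raise ValueError("times must be positive")
        eta = spline_basis(np.log(times), self.knots) @ self.gamma
        if X is not None and X.size:
            eta = eta + X @ self.beta_cov
        return np.exp(eta)

    def predict_risk(self, x, horizon: float) -> float:
        """P(event by ``horizon``) for one covariate row; 1 - exp(-H)."""
        if horizon <= 0:
            raise ValueError("horizon must be positive")
        xrow = self.design_row(x) if self.covariate_names else None
        H = self.cumulative_hazard(
            [horizon], xrow[None, :] if xrow is not None else None
        )[0]
        return float(1.0 - np.exp(-H))

    def predict_risk_frame(self, df: pd.DataFrame, horizon: float) -> np.ndarray:
        """Vectorized event risk by ``horizon`` for every row of ``df``."""
        if horizon <= 0:
            raise ValueError("horizon must be positive")
        X = self.design_matrix(df) if self.covariate_names else None
        H = self.cumulative_hazard(np.full(len(df), float(horizon)),
                                   X if X is not None and X.size else None)
        if X is not None and not X.size:
            H = np.full(len(df), H[0])
        return 1.0 - np.exp(-H)


def predict_risk(model: RPSplineModel, x, horizon: float) -> float:
    return model.predict_risk(x, horizon)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

_DERIV_FLOOR = 1e-8


def _negloglik_and_grad(params, B, dB, X, d, logt):
    """Right-censored negative log-likelihood and gradient.

    log h = eta + log(s'(u)'gamma) - log t with eta = B gamma + X beta.
    The log of the basis slope is extended linearly below a small floor so the
    objective stays finite and C^1 when a line-search step makes the fitted
    cumulative hazard locally decreasing.
    """
    p = B.shape[1]
    gamma, beta = params[:p], params[p:]
    eta = B @ gamma
    if X.size:
        eta = eta + X @ beta
    H = np.exp(np.clip(eta, -700, 700))
    slope = dB @ gamma
    safe = slope > _DERIV_FLOOR
    logslope = np.where(safe, np.log(np.where(safe, slope, 1.0)),
                        np.log(_DERIV_FLOOR) + (slope - _DERIV_FLOOR) / _DERIV_FLOOR)
    dlogslope = np.where(safe, 1.0 / np.where(safe, slope, 1.0), 1.0 / _DERIV_FLOOR)

    ll = np.sum(d * (eta + logslope - logt)) - np.sum(H)
    resid = d - H  # common factor of the eta-gradient
    g_gamma = B.T @ resid + dB.T @ (d * dlogslope)
    g_beta = X.T @ resid if X.size else np.zeros(0)
    return -ll, -np.concatenate([g_gamma, g_beta])


def fit_rp(
    data: CohortTable,
    covariates: list[str] | None = None,
    n_internal_knots: int = 2,
    knots=None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> RPSplineModel:
    """Fit the spline log-cumulative-hazard model to a trial-role cohort.

    Initialization is the exponential fit (``gamma = (log(events / total
    time), 1)``, remaining coefficients 0).  A fitted cumulative hazard that
    decreases anywhere on the observed log-time range is rejected and the
    model is refit with one fewer internal knot (with a warning), since
    monotone H is required for valid risks.
    """
    if data.role != "trial":
        raise ValueError("fit_rp requires a trial-role cohort (needs outcomes)")
    covariates = list(covariates or [])
    times = data.data["time"].to_numpy(dtype=float)
    events = data.data["event"].to_numpy(dtype=float)
    n_events = int(events.sum())
    if n_events == 0:
        raise FitError("no events in the data")
    if n_events < 10:
        raise FitError(f"too few events to fit ({n_events} < 10)")

    X, enc, ref = _encode(data.data, covariates, data.schema)
    if np.isnan(X).any():
        raise ValueError("covariates contain missing values; impute first")

    use_knots = _check_knots(knots) if knots is not None else default_knots(
        times, events, n_internal_knots)

    logt = np.log(times)
    B = spline_basis(logt, use_knots)
    dB = spline_basis_deriv(logt, use_knots)

    rate = n_events / times.sum()
    x0 = np.zeros(B.shape[1] + X.shape[1])
    x0[0] = np.log(rate)
    x0[1] = 1.0

    ll0 = -_negloglik_and_grad(x0, B, dB, X, events, logt)[0]
    res = minimize(
        _negloglik_and_grad, x0, args=(B, dB, X, events, logt),
        jac=True, method="BFGS",
        options={"maxiter": max_iter, "gtol": 1e-6},
    )
    ll = -res.fun
    if not np.isfinite(ll) or ll < ll0 - 1e-6:
        raise FitError(f"optimizer failed: loglike {ll} vs initial {ll0}; {res.message}")

    p = B.shape[1]
    model = RPSplineModel(
        knots=use_knots,
        gamma=res.x[:p],
        beta_cov=res.x[p:],
        covariate_names=covariates,
        encoding=enc,
        loglike=float(ll),
        n_iter=int(res.nit),
        converged=bool(res.success or np.linalg.norm(res.jac) < 1e-3 * max(1, n_events)),
        n_events=n_events,
        n_obs=len(times),
    )
    model._reference_levels = ref

    if not _monotone_on_grid(model):
        n_int = len(use_knots) - 2
        if knots is not None or n_int == 0:
            raise FitError("fitted cumulative hazard is non-monotone")
        warnings.warn(
            f"non-monotone fitted cumulative hazard with {n_int} internal "
            f"knots; refitting with {n_int - 1}", stacklevel=2)
        return fit_rp(data, covariates, n_internal_knots=n_int - 1,
                      max_iter=max_iter, tol=tol)
    return model


def _monotone_on_grid(model: RPSplineModel, n_grid: int = 200) -> bool:
    # H(t|x) = exp(s(u)'gamma) exp(x'beta): monotone in t for every x iff the
    # baseline spline is non-decreasing; covariates cannot change that.
    lo, hi = model.knots[0], model.knots[-1]
    span = hi - lo
    grid = np.linspace(lo - 0.1 * span, hi + 0.1 * span, n_grid)
    return bool(np.all(spline_basis_deriv(grid, model.knots) @ model.gamma >= -1e-10))


def _encode(df: pd.DataFrame, covariates: list[str], schema: dict[str, str]):
    """Design matrix with reference-level one-hot coding for categoricals.

    Reference = most frequent level in the training data.
    """
    cols, enc, ref = [], {}, {}
    for name in covariates:
        if name not in df.columns:
            raise KeyError(f"covariate {name!r} absent from data")
        if schema.get(name) == "categorical" or df[name].dtype == object:
            counts = df[name].value_counts()
            reference = counts.index[0]
            others = [lev for lev in counts.index if lev != reference]
            enc[name] = others
            ref[name] = reference
            for level in others:
                cols.append((df[name] == level).to_numpy(dtype=float))
        else:
            cols.append(df[name].to_numpy(dtype=float))
    X = np.column_stack(cols) if cols else np.zeros((len(df), 0))
    return X, enc, ref


# ---------------------------------------------------------------------------
# Nelson-Aalen
# ---------------------------------------------------------------------------

@dataclass
class HazardPath:
    """Step cumulative-hazard estimate with H(0) = 0."""

    times: np.ndarray           # distinct event times, increasing
    cumhaz: np.ndarray          # H at those times, non-decreasing
    at_subject_times: np.ndarray  # H(T_i) per input subject, imputation predictor

    def __call__(self, t) -> np.ndarray:
        """Evaluate the step function H(t)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        idx = np.searchsorted(self.times, t, side="right")
        padded = np.concatenate([[0.0], self.cumhaz])
        return padded[idx]


def nelson_aalen(times, events) -> HazardPath:
    """Nelson-Aalen cumulative hazard: H(t) = sum_{t_j <= t} d_j / n_j.

    Ties are aggregated at distinct event times (d_j may exceed 1).  Also
    evaluates H at each subject's own time, the predictor used by the
    imputation models.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty input")
    if times.shape != events.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times <= 0):
        raise ValueError("times must be positive")

    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    n = times.size

    event_times = np.unique(t_sorted[events[order] == 1])
    cumhaz = np.empty(event_times.size)
    running = 0.0
    for i, tj in enumerate(event_times):
        d_j = int(np.sum((times == tj) & (events == 1)))
        n_j = int(np.sum(times >= tj))
        running += d_j / n_j
        cumhaz[i] = running

    path = HazardPath(event_times, cumhaz, np.zeros(n))
    path.at_subject_times = path(times)
    return path
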