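"""Spline log-cumulative-hazard model, its Weibull limit, and Nelson-Aalen."""

import numpy as np
import pandas as pd
import pytest
from lifelines import NelsonAalenFitter, WeibullFitter

from trialtransport.cohorts import CohortTable
from trialtransport.simulate import CovariateSpec, DGPConfig, generate_trial
from trialtransport.survival import (FitError, RPSplineModel, fit_rp,
                                     nelson_aalen, spline_basis,
                                     spline_basis_deriv)


# ---------------------------------------------------------------------------
# restricted cubic basis
# ---------------------------------------------------------------------------

def test_zero_internal_knots_reduces_to_linear_basis():
    B = spline_basis([0.0, 1.0, 2.5], [-1.0, 3.0])
    np.testing.assert_allclose(B, [[1, 0], [1, 1], [1, 2.5]])


def test_basis_is_linear_beyond_boundary_knots():
    knots = [0.0, 1.0, 2.0]
    # derivative constant outside the boundaries => zero curvature there
    left = spline_basis_deriv([-5.0, -3.0, -1.0], knots)
    right = spline_basis_deriv([3.0, 4.0, 9.0], knots)
    for D in (left, right):
        assert np.allclose(D - D[0], 0.0)


def test_internal_knot_term_matches_hand_formula():
    kmin, kj, kmax = 0.0, 1.0, 2.0
    u = 1.0  # at the internal knot (midpoint of the boundary interval)
    lam = (kmax - kj) / (kmax - kmin)
    expected = (max(u - kj, 0) ** 3 - lam * max(u - kmin, 0) ** 3
                - (1 - lam) * max(u - kmax, 0) ** 3)
    B = spline_basis([u], [kmin, kj, kmax])
    assert B[0, 2] == pytest.approx(expected, abs=1e-14)
    assert B.shape[1] == 3  # 1 internal knot -> dimension 3


def test_knot_validation():
    with pytest.raises(ValueError):
        spline_basis([0.0], [1.0])
    with pytest.raises(ValueError):
        spline_basis([0.0], [1.0, 1.0, 2.0])


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _weibull_trial(k, lam, n, seed, censor_admin=4.0):
    rng = np.random.default_rng(seed)
    t = (-np.log(rng.uniform(size=n)) / lam) ** (1.0 / k)
    time = np.minimum(t, censor_admin)
    event = (t <= censor_admin).astype(int)
    df = pd.DataFrame({"arm": rng.integers(0, 2, n), "time": time, "event": event})
    return CohortTable(df, role="trial")


def test_weibull_recovery_with_zero_internal_knots():
    k, lam = 1.5, 0.05
    data = _weibull_trial(k, lam, 5000, seed=4)
    model = fit_rp(data, [], n_internal_knots=0)
    # basis [1, u]: gamma = (log lam, k)
    assert model.gamma[1] == pytest.approx(k, abs=0.1)
    truth = 1 - np.exp(-lam * 4 ** k)
    assert model.predict_risk({}, 4.0) == pytest.approx(truth, abs=0.02)


def test_exponential_data_gives_unit_log_time_slope():
    data = _weibull_trial(1.0, 0.08, 5000, seed=5)
    model = fit_rp(data, [], n_internal_knots=0)
    assert model.gamma[1] == pytest.approx(1.0, abs=0.1)


def test_binary_covariate_log_hazard_ratio_recovered():
    rng = np.random.default_rng(6)
    n = 5000
    x = rng.integers(0, 2, n)
    lam = 0.05 * np.exp(np.log(2) * x)
    t = rng.exponential(1 / lam)
    time = np.minimum(t, 4.0)
    event = (t <= 4.0).astype(int)
    df = pd.DataFrame({"arm": rng.integers(0, 2, n), "time": time,
                       "event": event, "x": x})
    model = fit_rp(CohortTable(df, role="trial"), ["x"], n_internal_knots=1)
    assert model.beta_cov[0] == pytest.approx(np.log(2), abs=0.15)


def test_zero_knot_fit_matches_lifelines_weibull_mle():
    """Degenerate-spline oracle equivalence: 4-year risk within 1e-4 of a
    direct Weibull maximum-likelihood fit on the same data."""
    data = _weibull_trial(1.3, 0.06, 3000, seed=7)
    model = fit_rp(data, [], n_internal_knots=0)
    wf = WeibullFitter().fit(data.data["time"], data.data["event"])
    risk_wf = 1 - float(wf.survival_function_at_times(4.0).iloc[0])
    assert model.predict_risk({}, 4.0) == pytest.approx(risk_wf, abs=1e-4)


def test_loglik_not_below_initialization(effect_dgp):
    trial = generate_trial(effect_dgp, 2000)
    model = fit_rp(trial, ["age"], n_internal_knots=2)
    # exponential-fit initialization log-likelihood
    times = trial.data["time"].to_numpy()
    events = trial.data["event"].to_numpy()
    rate = events.sum() / times.sum()
    ll_init = np.sum(events * np.log(rate)) - rate * times.sum()
    assert model.loglike >= ll_init - 1e-9


def test_survival_monotone_and_risk_increasing(effect_dgp):
    trial = generate_trial(effect_dgp, 3000)
    model = fit_rp(trial, ["age", "cvd_history"], n_internal_knots=2)
    x = {"age": 70.0, "cvd_history": 1.0}
    horizons = np.linspace(0.05, 4.0, 60)
    risks = [model.predict_risk(x, h) for h in horizons]
    assert np.all(np.diff(risks) >= -1e-12)
    assert model.predict_risk(x, 1e-9) == pytest.approx(0.0, abs=1e-6)


def test_no_covariate_risk_matches_nelson_aalen(effect_dgp):
    trial = generate_trial(effect_dgp, 20000)
    model = fit_rp(trial, [], n_internal_knots=2)
    na = nelson_aalen(trial.data["time"].to_numpy(), trial.data["event"].to_numpy())
    risk_na = 1 - np.exp(-na(4.0 - 1e-9)[0])
    assert model.predict_risk({}, 4.0) == pytest.approx(risk_na, abs=0.01)


def test_direct_cumulative_hazard_evaluation():
    # basis [1, u], gamma = (log 0.2, 1): H(4) = 0.8, risk = 1 - exp(-0.8)
    m = RPSplineModel(knots=np.array([-2.0, 2.0]),
                      gamma=np.array([np.log(0.2), 1.0]),
                      beta_cov=np.zeros(0), covariate_names=[])
    assert m.predict_risk({}, 4.0) == pytest.approx(1 - np.exp(-0.8), abs=1e-12)


def test_fit_requires_events():
    df = pd.DataFrame({"arm": [0, 1] * 10, "time": np.ones(20),
                       "event": np.zeros(20, dtype=int)})
    with pytest.raises(FitError):
        fit_rp(CohortTable(df, role="trial"), [])


def test_unseen_categorical_level_is_rejected():
    rng = np.random.default_rng(8)
    n = 400
    df = pd.DataFrame({
        "arm": rng.integers(0, 2, n),
        "time": rng.exponential(5, n).clip(0.01, 4.0),
        "event": rng.integers(0, 2, n),
        "race": rng.choice(["a", "b", "c"], n),
    })
    model = fit_rp(CohortTable(df, role="trial"), ["race"], n_internal_knots=0)
    with pytest.raises(ValueError, match="unseen"):
        model.predict_risk({"race": "zzz"}, 4.0)


# ---------------------------------------------------------------------------
# Nelson-Aalen
# ---------------------------------------------------------------------------

def test_nelson_aalen_hand_computed_paths():
    path = nelson_aalen([1.0, 2.0, 3.0], [1, 0, 1])
    assert path(1.0)[0] == pytest.approx(1 / 3)
    assert path(3.0)[0] == pytest.approx(1 / 3 + 1.0)
    np.testing.assert_allclose(path.at_subject_times, [1 / 3, 1 / 3, 4 / 3])

    two = nelson_aalen([1.0, 2.0], [1, 1])
    np.testing.assert_allclose(two.cumhaz, [0.5, 1.5])


def test_nelson_aalen_no_events_is_zero():
    path = nelson_aalen([1.0, 2.0, 3.0], [0, 0, 0])
    assert path.times.size == 0
    assert np.all(path([0.5, 5.0]) == 0.0)


def test_nelson_aalen_empty_and_invalid_inputs():
    with pytest.raises(ValueError):
        nelson_aalen([], [])
    with pytest.raises(ValueError):
        nelson_aalen([1.0, -1.0], [1, 0])


def test_nelson_aalen_agrees_with_lifelines(effect_dgp):
    trial = generate_trial(effect_dgp, 2000)
    t = trial.data["time"].to_numpy()
    e = trial.data["event"].to_numpy()
    ours = nelson_aalen(t, e)
    naf = NelsonAalenFitter(nelson_aalen_smoothing=False).fit(t, e)
    grid = np.array([0.5, 1.0, 2.0, 3.0, 3.9])
    theirs = naf.cumulative_hazard_at_times(grid).to_numpy()
    np.testing.assert_allclose(ours(grid), theirs, atol=1e-10)
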