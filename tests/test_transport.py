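"""Eligibility filtering, standardization, NNT/NNH and estimate agreement."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from trialtransport.cohorts import CohortTable
from trialtransport.simulate import generate_target, generate_trial, oracle_true_effect
from trialtransport.transport import (EligibilityRule, NNTResult,
                                      UndefinedNNTError, apply_eligibility,
                                      estimate_agreement, fit_arm_models,
                                      nnt_from_rd, standardize,
                                      subgroup_transport, transport_effect,
                                      trial_mean_effect)


# ---------------------------------------------------------------------------
# eligibility
# ---------------------------------------------------------------------------

@pytest.fixture
def toy_target():
    df = pd.DataFrame({"egfr": [10.0, 25.0, 50.0, 65.0, 80.0],
                       "age": [70, 71, np.nan, 73, 74]})
    return CohortTable(df, role="target", population_id="toy")


def test_empty_rule_list_is_identity(toy_target):
    out = apply_eligibility(toy_target, [])
    pd.testing.assert_frame_equal(out.data, toy_target.data)


def test_half_open_range_rule(toy_target):
    out, report = apply_eligibility(
        toy_target, [EligibilityRule("egfr", "in-range", (20.0, 60.0))],
        return_report=True)
    assert out.data["egfr"].tolist() == [25.0, 50.0]
    assert report[0][1] == 3


def test_missing_value_excluded_and_counted(toy_target):
    out, report = apply_eligibility(
        toy_target, [EligibilityRule("age", ">=", 70, on_missing="exclude")],
        return_report=True)
    assert out.n == 4
    assert report[0][1] == 1
    kept = apply_eligibility(
        toy_target, [EligibilityRule("age", ">=", 70, on_missing="keep")])
    assert kept.n == 5


def test_malformed_rules_rejected(toy_target):
    with pytest.raises(ValueError):
        EligibilityRule("egfr", "~~", 5)
    with pytest.raises(ValueError):
        EligibilityRule("egfr", "in-range", (60.0, 20.0))
    with pytest.raises(KeyError):
        apply_eligibility(toy_target, [EligibilityRule("ghost", "<", 1)])


# ---------------------------------------------------------------------------
# trial mean effect and transport
# ---------------------------------------------------------------------------

def test_trial_mean_effect_null_truth(null_dgp):
    trial = generate_trial(null_dgp, 10000)
    est = trial_mean_effect(trial, 4.0)
    assert est.rr == pytest.approx(1.0, abs=0.05)


def test_trial_mean_effect_recovers_oracle(effect_dgp):
    trial = generate_trial(effect_dgp, 20000)
    est = trial_mean_effect(trial, 4.0)
    # estimand: oracle evaluated on the trial's own covariates
    truth = oracle_true_effect(
        effect_dgp, CohortTable(trial.covariates, role="target"), 4.0)
    assert est.rr == pytest.approx(truth.rr, abs=0.05)


def test_trial_mean_effect_requires_two_arms(effect_dgp):
    trial = generate_trial(effect_dgp, 1000)
    single = trial.subset(trial.data["arm"] == 1)
    with pytest.raises(ValueError):
        trial_mean_effect(single, 4.0)


def test_transport_to_unshifted_target_matches_trial_effect(effect_dgp):
    cfg = dataclasses.replace(effect_dgp, target_shift={})
    trial = generate_trial(cfg, 10000)
    target = generate_target(cfg, 10000, "same")
    t_est = transport_effect(trial, target, ["age", "cvd_history"], 4.0)
    trial_est = trial_mean_effect(trial, 4.0)
    assert t_est.rr == pytest.approx(trial_est.rr, abs=0.05)


def test_transport_recovers_oracle_under_interaction(interaction_dgp):
    trial = generate_trial(interaction_dgp, 20000)
    target = generate_target(interaction_dgp, 10000, "older")
    truth = oracle_true_effect(interaction_dgp, target, 4.0)
    est = transport_effect(trial, target, ["age"], 4.0)
    # delta_age < 0: protection strengthens with age, so the older target's
    # true RR sits below the trial population's
    assert truth.rr < oracle_true_effect(
        interaction_dgp, CohortTable(trial.covariates, role="target"), 4.0).rr
    assert est.rr == pytest.approx(truth.rr, abs=0.05)
    assert est.rd == pytest.approx(truth.rd, abs=0.01)


def test_single_subject_target_equals_individual_prediction(effect_dgp):
    trial = generate_trial(effect_dgp, 4000)
    target = generate_target(effect_dgp, 1, "one")
    m0, m1 = fit_arm_models(trial, ["age", "cvd_history"])
    est = standardize(m0, m1, target, 4.0)
    row = target.data.iloc[0]
    assert est.risk0 == pytest.approx(m0.predict_risk(row[["age", "cvd_history"]], 4.0), abs=1e-12)
    assert est.risk1 == pytest.approx(m1.predict_risk(row[["age", "cvd_history"]], 4.0), abs=1e-12)


def test_transport_to_self_is_exact_under_shared_models(effect_dgp):
    """Standardizing the trial's own covariate rows through the same pair of
    arm models must equal the transported estimate bit for bit."""
    trial = generate_trial(effect_dgp, 4000)
    self_target = CohortTable(trial.covariates.copy(), role="target",
                              population_id="self")
    m0, m1 = fit_arm_models(trial, ["age", "cvd_history"])
    a = standardize(m0, m1, self_target, 4.0)
    b = transport_effect(trial, self_target, ["age", "cvd_history"], 4.0)
    assert a.risk0 == pytest.approx(b.risk0, abs=1e-12)
    assert a.risk1 == pytest.approx(b.risk1, abs=1e-12)


def test_missing_covariate_is_rejected(effect_dgp):
    trial = generate_trial(effect_dgp, 2000)
    target = generate_target(effect_dgp, 100, "t")
    with pytest.raises(KeyError, match="ghost"):
        transport_effect(trial, target, ["ghost"], 4.0)


# ---------------------------------------------------------------------------
# subgroups
# ---------------------------------------------------------------------------

def test_all_selecting_predicate_equals_full_transport(effect_dgp):
    trial = generate_trial(effect_dgp, 4000)
    target = generate_target(effect_dgp, 2000, "t")
    full = transport_effect(trial, target, ["age"], 4.0)
    sub = subgroup_transport(trial, target, ["age"], 4.0,
                             [EligibilityRule("age", ">", -1e9)])
    assert sub.risk0 == pytest.approx(full.risk0, abs=1e-12)
    assert sub.risk1 == pytest.approx(full.risk1, abs=1e-12)


def test_partition_weighted_mean_equals_full_target(effect_dgp):
    trial = generate_trial(effect_dgp, 4000)
    target = generate_target(effect_dgp, 2000, "t")
    med = float(target.data["age"].median())
    lo = subgroup_transport(trial, target, ["age"], 4.0,
                            [EligibilityRule("age", "<=", med)])
    hi = subgroup_transport(trial, target, ["age"], 4.0,
                            [EligibilityRule("age", ">", med)])
    full = transport_effect(trial, target, ["age"], 4.0)
    for attr in ("risk0", "risk1"):
        combined = (getattr(lo, attr) * lo.n + getattr(hi, attr) * hi.n) / full.n
        assert combined == pytest.approx(getattr(full, attr), abs=1e-12)


def test_low_kidney_function_subgroup_has_higher_baseline_risk():
    """With kidney function protective in the hazard, the low-eGFR subgroup
    of a shifted target must carry higher standardized risk."""
    from trialtransport.simulate import CovariateSpec, DGPConfig
    cfg = DGPConfig(
        covariate_spec={"egfr": CovariateSpec("normal", mean=70.0, sd=18.0)},
        baseline_shape=1.0, baseline_scale=0.4,
        beta={"egfr": -0.03}, theta=float(np.log(0.8)),
        censor_rate=0.05, target_shift={"egfr": -25.0}, seed=13)
    trial = generate_trial(cfg, 8000)
    target = generate_target(cfg, 8000, "ckd")
    full = transport_effect(trial, target, ["egfr"], 4.0)
    low = subgroup_transport(trial, target, ["egfr"], 4.0,
                             [EligibilityRule("egfr", "<", 30.0)])
    assert low.risk0 > full.risk0


def test_empty_subgroup_is_an_error(effect_dgp):
    trial = generate_trial(effect_dgp, 2000)
    target = generate_target(effect_dgp, 200, "t")
    with pytest.raises(ValueError):
        subgroup_transport(trial, target, ["age"], 4.0,
                           [EligibilityRule("age", ">", 1e9)])


# ---------------------------------------------------------------------------
# NNT / NNH and agreement
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("rd, value, label", [
    (-0.051, 20, "NNT"),
    (+0.013, 77, "NNH"),
    (-0.030, 33, "NNT"),
    (-0.5, 2, "NNT"),
])
def test_nnt_nnh_worked_examples(rd, value, label):
    assert nnt_from_rd(rd) == NNTResult(value, label)


def test_nnt_undefined_at_zero_and_nonfinite():
    with pytest.raises(UndefinedNNTError):
        nnt_from_rd(0.0)
    with pytest.raises(ValueError):
        nnt_from_rd(float("nan"))


@pytest.mark.parametrize("point, ci, expected", [
    (0.90, (0.80, 1.00), True),
    (1.05, (0.80, 1.00), False),
    (0.80, (0.80, 1.00), True),  # closed interval at the boundary
])
def test_estimate_agreement(point, ci, expected):
    assert estimate_agreement(point, ci) is expected


def test_estimate_agreement_rejects_bad_inputs():
    with pytest.raises(ValueError):
        estimate_agreement(float("nan"), (0.8, 1.0))
    with pytest.raises(ValueError):
        estimate_agreement(0.9, (1.0, 0.8))


def test_risk_estimate_contrasts_are_internally_consistent(effect_dgp):
    trial = generate_trial(effect_dgp, 3000)
    target = generate_target(effect_dgp, 1000, "t")
    est = transport_effect(trial, target, ["age"], 4.0)
    assert est.rr == pytest.approx(est.risk1 / est.risk0, abs=1e-12)
    assert est.rd == pytest.approx(est.risk1 - est.risk0, abs=1e-12)
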