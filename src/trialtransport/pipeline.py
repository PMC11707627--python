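"""End-to-end pipeline: config file in, tidy result tables out.

The config (YAML or JSON, one mapping) names the inputs and every analysis
choice; a fixed ``seed`` makes the whole run — simulation, imputation,
bootstrap — bit-reproducible.  Cohorts are either loaded from CSV
(``file:``) or simulated from an embedded DGP config (``simulate:``).

Stages: eligibility filtering -> SMD comparison -> trial effect + bootstrap
CI -> transported effect + nested-imputation bootstrap CI per target
population and subgroup -> agreement flags and NNT/NNH.  Outputs one tidy
``results.csv`` (population, outcome, subgroup, scale, estimate, ci_low,
ci_high, agreement, nnt_label, nnt_value), one SMD table per population and
a run log.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .cohorts import CohortTable
from .inference import BootstrapSpec
from .model import TransportAnalysis
from .simulate import DGPConfig, generate_target, generate_trial, inject_missingness
from .transport import EligibilityRule

__all__ = ["run_pipeline", "load_config", "PipelineConfigError"]

log = logging.getLogger("trialtransport")

_REQUIRED = ("trial", "targets", "covariates")


class PipelineConfigError(ValueError):
    pass


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise PipelineConfigError("config must be a mapping")
    return cfg


def _rules(spec_list) -> list[EligibilityRule]:
    rules = []
    for r in spec_list or []:
        bound = r.get("bound")
        if isinstance(bound, list) and r["comparator"] == "in-range":
            bound = tuple(bound)
        rules.append(EligibilityRule(variable=r["variable"],
                                     comparator=r["comparator"], bound=bound,
                                     on_missing=r.get("on_missing", "exclude")))
    return rules


def _load_cohort(entry: dict, role: str, population_id: str,
                 dgp: DGPConfig | None, seed: int) -> CohortTable:
    if "file" in entry:
        return CohortTable.from_csv(entry["file"], role=role,
                                    population_id=population_id)
    if "simulate" in entry:
        if dgp is None:
            raise PipelineConfigError("simulate requested but no 'dgp' block in config")
        n = int(entry["simulate"]["n"])
        if role == "trial":
            cohort = generate_trial(dgp, n, seed=seed)
        else:
            cohort = generate_target(dgp, n, population_id=population_id, seed=seed)
        if dgp.missing_spec is not None:
            cohort = inject_missingness(cohort, dgp, seed=seed)
        return cohort
    raise PipelineConfigError(f"cohort entry needs 'file' or 'simulate': {entry}")


def run_pipeline(config, out_dir=None, seed: int | None = None) -> dict:
    """Run the full analysis described by ``config`` (path or dict).

    Returns a bundle with the per-population results objects and the tidy
    results frame; writes CSVs and a log when ``out_dir`` is given.
    """
    cfg = load_config(config) if not isinstance(config, dict) else dict(config)
    missing = [k for k in _REQUIRED if k not in cfg]
    if missing:
        raise PipelineConfigError(f"config lacks required fields: {missing}")

    seed = int(cfg.get("seed", 0) if seed is None else seed)
    horizon = float(cfg.get("horizon", 4.0))
    covariates = list(cfg["covariates"])
    outcome = cfg.get("outcome", "primary")
    dgp = DGPConfig.from_dict(cfg["dgp"]) if "dgp" in cfg else None

    boot = cfg.get("bootstrap", {})
    trial_boot = BootstrapSpec(B=int(boot.get("trial_B", 1000)), seed=seed)
    transport_boot = BootstrapSpec(
        B=int(boot.get("transport_B", 500)),
        m_within=int(boot.get("m_within", 10)),
        n_cycles=int(boot.get("n_cycles", 10)), seed=seed)

    eligibility = _rules(cfg.get("eligibility"))
    subgroups = {k: _rules(v) for k, v in (cfg.get("subgroups") or {}).items()}

    trial = _load_cohort(cfg["trial"], "trial", "trial", dgp, seed)
    log.info("trial n=%d, events=%d", trial.n, int(trial.data["event"].sum()))
    for name in covariates:
        if name not in trial.data.columns:
            raise PipelineConfigError(f"covariate {name!r} not in trial cohort")

    out_path = Path(out_dir) if out_dir else None
    if out_path:
        out_path.mkdir(parents=True, exist_ok=True)

    bundle, frames = {}, []
    targets = cfg["targets"]
    if isinstance(targets, dict):
        targets = [dict(id=k, **v) for k, v in targets.items()]
    for entry in targets:
        pop = str(entry.get("id", "target"))
        target = _load_cohort(entry, "target", pop, dgp, seed)
        for name in covariates:
            if name not in target.data.columns:
                raise PipelineConfigError(
                    f"covariate {name!r} not in target cohort {pop!r}")
        analysis = TransportAnalysis(
            trial, target, covariates=covariates, horizon=horizon,
            eligibility=eligibility, subgroups=subgroups, outcome=outcome)
        res = analysis.fit(trial_boot=trial_boot, transport_boot=transport_boot,
                           seed=seed)
        log.info("population %s: n=%d after eligibility, transported RR=%.3f "
                 "(skipped replicates: %d)", pop, res.target_used.n,
                 res.transported.rr_point, res.transported.n_boot_skipped)
        bundle[pop] = res
        frame = res.to_frame()
        frames.append(frame[frame["population"] != "trial"] if frames else frame)
        if out_path:
            res.smd_table.to_csv(out_path / f"smd_{pop}.csv", index=False)

    results = pd.concat(frames, ignore_index=True)
    bundle["results"] = results
    if out_path:
        results.to_csv(out_path / "results.csv", index=False)
        with open(out_path / "run.json", "w") as fh:
            json.dump({"seed": seed, "horizon": horizon,
                       "covariates": covariates, "outcome": outcome}, fh, indent=2)
    return bundle
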