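"""Synthetic trial and target cohorts from a fully known generating process.

The generator emulates the structure of a two-arm BP-target trial carried
into external CKD populations: baseline covariates with specified marginals
(optionally correlated through a Gaussian copula), a Weibull
proportional-hazards outcome with a main treatment effect and optional
treatment-covariate interactions, independent exponential censoring plus
administrative censoring at the analysis horizon, covariate-shifted target
populations, and configurable MCAR/MAR missingness.

Because the baseline hazard is Weibull, the transported estimand has a closed
form: for a subject with covariates x under regime a,

    risk_a(x; t) = 1 - exp(-lambda t^k exp(x' beta + a (theta + x' delta))),

and :func:`oracle_true_effect` averages this over a target cohort.  That
truth oracle is what estimator tests are judged against.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit

from .cohorts import BINARY, CATEGORICAL, CONTINUOUS, CohortTable
from .transport import RiskEstimate

__all__ = [
    "CovariateSpec",
    "MissingSpec",
    "DGPConfig",
    "ConfigError",
    "generate_trial",
    "generate_target",
    "oracle_true_effect",
    "inject_missingness",
]


class ConfigError(ValueError):
    """A data-generating-process configuration field is invalid."""


@dataclass(frozen=True)
class CovariateSpec:
    """Marginal distribution of one baseline covariate.

    dist: ``normal`` (mean, sd), ``bernoulli`` (p) or ``categorical``
    (levels, probs). Units follow the clinical convention for the covariate
    (age in years, SBP/DBP in mm Hg, eGFR in mL/min/1.73 m^2, ...).
    """

    dist: str
    mean: float = 0.0
    sd: float = 1.0
    p: float = 0.5
    levels: tuple = ()
    probs: tuple = ()

    def __post_init__(self):
        if self.dist not in ("normal", "bernoulli", "categorical"):
            raise ConfigError(f"covariate dist {self.dist!r} unknown")
        if self.dist == "normal" and self.sd <= 0:
            raise ConfigError(f"normal covariate sd must be > 0, got {self.sd}")
        if self.dist == "bernoulli" and not (0.0 <= self.p <= 1.0):
            raise ConfigError(f"bernoulli p must be in [0,1], got {self.p}")
        if self.dist == "categorical":
            if len(self.levels) != len(self.probs) or not self.levels:
                raise ConfigError("categorical needs matching levels/probs")
            if abs(sum(self.probs) - 1.0) > 1e-9:
                raise ConfigError("categorical probs must sum to 1")

    @property
    def kind(self) -> str:
        return {"normal": CONTINUOUS, "bernoulli": BINARY,
                "categorical": CATEGORICAL}[self.dist]


@dataclass(frozen=True)
class MissingSpec:
    """Missingness mechanism for :func:`inject_missingness`.

    MCAR masks each targeted cell independently at its fraction; MAR makes
    the masking probability a logistic function of one complete driver
    covariate, with the intercept solved so the marginal fraction is honored.
    """

    mechanism: str = "MCAR"
    fractions: dict[str, float] = field(default_factory=dict)
    driver: str | None = None
    slope: float = 1.0

    def __post_init__(self):
        if self.mechanism not in ("MCAR", "MAR"):
            raise ConfigError(f"missing_spec.mechanism must be MCAR or MAR, got {self.mechanism!r}")
        for name, f in self.fractions.items():
            if not (0.0 <= f <= 1.0):
                raise ConfigError(f"missing fraction for {name!r} must be in [0,1], got {f}")
        if self.mechanism == "MAR" and not self.driver:
            raise ConfigError("MAR missingness requires a driver covariate")


@dataclass(frozen=True)
class DGPConfig:
    """Full specification of the synthetic data-generating process."""

    covariate_spec: dict[str, CovariateSpec]
    baseline_shape: float = 1.0        # Weibull k > 0
    baseline_scale: float = 0.02       # Weibull lambda > 0 (per year^k)
    beta: dict[str, float] = field(default_factory=dict)
    theta: float = 0.0                 # main treatment log-hazard effect
    delta: dict[str, float] = field(default_factory=dict)
    censor_rate: float = 0.0           # exponential censoring, per year
    admin_censor_time: float = 4.0     # years
    target_shift: dict[str, float] = field(default_factory=dict)
    missing_spec: MissingSpec | None = None
    correlation: np.ndarray | None = None  # Gaussian-copula correlation, covariate order
    seed: int = 0

    def __post_init__(self):
        if self.baseline_shape <= 0:
            raise ConfigError(f"baseline_shape must be > 0, got {self.baseline_shape}")
        if self.baseline_scale <= 0:
            raise ConfigError(f"baseline_scale must be > 0, got {self.baseline_scale}")
        if self.censor_rate < 0:
            raise ConfigError(f"censor_rate must be >= 0, got {self.censor_rate}")
        if self.admin_censor_time <= 0:
            raise ConfigError(f"admin_censor_time must be > 0, got {self.admin_censor_time}")
        for label, d in (("beta", self.beta), ("delta", self.delta),
                         ("target_shift", self.target_shift)):
            for name in d:
                if name not in self.covariate_spec:
                    raise ConfigError(f"{label} references undeclared covariate {name!r}")
                if self.covariate_spec[name].dist == "categorical":
                    raise ConfigError(f"{label} cannot apply to categorical covariate {name!r}")
        if self.correlation is not None:
            R = np.asarray(self.correlation, dtype=float)
            k = len(self.covariate_spec)
            if R.shape != (k, k):
                raise ConfigError(f"correlation must be {k}x{k}")
            if not np.allclose(R, R.T) or np.any(np.linalg.eigvalsh(R) < -1e-10):
                raise ConfigError("correlation must be symmetric positive semidefinite")
            object.__setattr__(self, "correlation", R)
        if self.missing_spec is not None:
            for name in self.missing_spec.fractions:
                if name not in self.covariate_spec:
                    raise ConfigError(f"missing_spec references undeclared covariate {name!r}")

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "covariate_spec": {k: _spec_to_dict(v) for k, v in self.covariate_spec.items()},
            "baseline_shape": self.baseline_shape,
            "baseline_scale": self.baseline_scale,
            "beta": dict(self.beta),
            "theta": self.theta,
            "delta": dict(self.delta),
            "censor_rate": self.censor_rate,
            "admin_censor_time": self.admin_censor_time,
            "target_shift": dict(self.target_shift),
            "seed": self.seed,
        }
        if self.correlation is not None:
            d["correlation"] = np.asarray(self.correlation).tolist()
        if self.missing_spec is not None:
            d["missing_spec"] = {
                "mechanism": self.missing_spec.mechanism,
                "fractions": dict(self.missing_spec.fractions),
                "driver": self.missing_spec.driver,
                "slope": self.missing_spec.slope,
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DGPConfig":
        d = dict(d)
        d["covariate_spec"] = {k: CovariateSpec(**v) if not isinstance(v, CovariateSpec) else v
                               for k, v in d["covariate_spec"].items()}
        if "missing_spec" in d and d["missing_spec"] is not None \
                and not isinstance(d["missing_spec"], MissingSpec):
            d["missing_spec"] = MissingSpec(**d["missing_spec"])
        if "correlation" in d and d["correlation"] is not None:
            d["correlation"] = np.asarray(d["correlation"], dtype=float)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "DGPConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def with_seed(self, seed: int) -> "DGPConfig":
        return replace(self, seed=seed)


def _spec_to_dict(s: CovariateSpec) -> dict:
    if s.dist == "normal":
        return {"dist": "normal", "mean": s.mean, "sd": s.sd}
    if s.dist == "bernoulli":
        return {"dist": "bernoulli", "p": s.p}
    return {"dist": "categorical", "levels": list(s.levels), "probs": list(s.probs)}


# ---------------------------------------------------------------------------
# covariate and outcome generation
# ---------------------------------------------------------------------------

def _draw_covariates(config: DGPConfig, n: int, rng: np.random.Generator,
                     shifted: bool) -> pd.DataFrame:
    names = list(config.covariate_spec)
    if not names:
        return pd.DataFrame(index=pd.RangeIndex(n))
    if config.correlation is not None:
        z = rng.multivariate_normal(np.zeros(len(names)), config.correlation,
                                    size=n, method="cholesky")
        u = _std_normal_cdf(z)
    else:
        z = rng.standard_normal((n, len(names)))
        u = _std_normal_cdf(z)

    cols = {}
    for j, name in enumerate(names):
        spec = config.covariate_spec[name]
        shift = config.target_shift.get(name, 0.0) if shifted else 0.0
        if spec.dist == "normal":
            cols[name] = spec.mean + shift + spec.sd * z[:, j]
        elif spec.dist == "bernoulli":
            p = min(max(spec.p + shift, 0.0), 1.0)
            cols[name] = (u[:, j] < p).astype(float)
        else:
            cum = np.cumsum(spec.probs)
            idx = np.searchsorted(cum, u[:, j], side="right").clip(0, len(spec.levels) - 1)
            cols[name] = np.asarray(spec.levels, dtype=object)[idx]
    return pd.DataFrame(cols)


def _std_normal_cdf(z):
    from scipy.stats import norm
    return norm.cdf(z)


def _linear_predictor(config: DGPConfig, cov: pd.DataFrame,
                      arm: np.ndarray | int) -> np.ndarray:
    lp = np.zeros(len(cov))
    for name, b in config.beta.items():
        lp += b * cov[name].to_numpy(dtype=float)
    inter = np.zeros(len(cov))
    for name, d in config.delta.items():
        inter += d * cov[name].to_numpy(dtype=float)
    return lp + np.asarray(arm, dtype=float) * (config.theta + inter)


def _schema_from_config(config: DGPConfig) -> dict[str, str]:
    return {name: spec.kind for name, spec in config.covariate_spec.items()}


def generate_trial(config: DGPConfig, n: int, seed: int | None = None) -> CohortTable:
    """Simulate a two-arm randomized trial cohort of size ``n``.

    Arms are assigned 1:1 by randomization.  Event times follow the Weibull
    proportional-hazards model with linear predictor x'beta + a(theta +
    x'delta); the observed time is min(event time, exponential censoring
    time, administrative censoring time).  A pure function of (config, n,
    seed).
    """
    if n < 2:
        raise ConfigError(f"trial size must be >= 2, got {n}")
    rng = np.random.default_rng([_seed_of(config, seed), 0])

    cov = _draw_covariates(config, n, rng, shifted=False)
    arm = np.zeros(n, dtype=int)
    arm[: n // 2] = 1
    arm = rng.permutation(arm)

    lp = _linear_predictor(config, cov, arm)
    k, lam = config.baseline_shape, config.baseline_scale
    u = rng.uniform(size=n)
    t_event = (-np.log(u) / (lam * np.exp(lp))) ** (1.0 / k)
    if config.censor_rate > 0:
        t_cens = rng.exponential(1.0 / config.censor_rate, size=n)
    else:
        t_cens = np.full(n, np.inf)
    t_cens = np.minimum(t_cens, config.admin_censor_time)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)

    df = cov.copy()
    df.insert(0, "id", np.arange(n))
    df["arm"] = arm
    df["time"] = np.maximum(time, 1e-12)
    df["event"] = event
    return CohortTable(df, role="trial", population_id="trial",
                       schema=_schema_from_config(config))


def generate_target(config: DGPConfig, n: int, population_id: str = "target",
                    seed: int | None = None) -> CohortTable:
    """Simulate a covariate-shifted target cohort (no outcomes)."""
    if n < 1:
        raise ConfigError(f"target size must be >= 1, got {n}")
    stream = 1 + (zlib.crc32(population_id.encode()) % 2**16)
    rng = np.random.default_rng([_seed_of(config, seed), stream])
    cov = _draw_covariates(config, n, rng, shifted=True)
    cov.insert(0, "id", np.arange(n))
    return CohortTable(cov, role="target", population_id=population_id,
                       schema=_schema_from_config(config))


def _seed_of(config: DGPConfig, seed: int | None) -> int:
    return config.seed if seed is None else seed


# ---------------------------------------------------------------------------
# the truth oracle
# ---------------------------------------------------------------------------

def oracle_true_risks(config: DGPConfig, cov: pd.DataFrame,
                      horizon: float) -> tuple[float, float]:
    """Closed-form mean counterfactual risks of a covariate table."""
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    if cov[list(config.beta) + list(config.delta)].isna().any().any():
        raise ValueError("oracle requires complete covariates")
    k, lam = config.baseline_shape, config.baseline_scale
    base = lam * horizon ** k
    risks = []
    for a in (0, 1):
        lp = _linear_predictor(config, cov, a)
        risks.append(float(np.mean(1.0 - np.exp(-base * np.exp(lp)))))
    return risks[0], risks[1]


def oracle_true_effect(config: DGPConfig, target: CohortTable,
                       horizon: float = 4.0) -> RiskEstimate:
    """The true transported estimand for a target cohort, in closed form.

    Evaluates risk_a(x) = 1 - exp(-lambda t^k exp(x'beta + a(theta +
    x'delta))) per subject and averages over the target. Deterministic; under
    theta = 0 and delta = 0 the RR is exactly 1 for any target.
    """
    risk0, risk1 = oracle_true_risks(config, target.data, horizon)
    return RiskEstimate(risk1=risk1, risk0=risk0, horizon=horizon,
                        population_id=target.population_id, n=target.n)


# ---------------------------------------------------------------------------
# missingness injection
# ---------------------------------------------------------------------------

def inject_missingness(cohort: CohortTable, config: DGPConfig,
                       seed: int | None = None) -> CohortTable:
    """Mask covariate cells per ``config.missing_spec``; input left unmodified.

    MCAR: each targeted cell masked independently at its fraction.  MAR: the
    masking probability is expit(a + slope * z) with z the standardized
    driver covariate and the intercept a solved so the marginal fraction is
    attained; the driver must itself be complete.
    """
    spec = config.missing_spec
    if spec is None or not spec.fractions:
        return cohort.with_data(cohort.data.copy())
    # stream keyed on the cohort label so trial and target get distinct masks
    rng = np.random.default_rng(
        [_seed_of(config, seed), 2, zlib.crc32(cohort.population_id.encode())])
    df = cohort.data.copy()

    if spec.mechanism == "MAR":
        drv = df[spec.driver]
        if drv.isna().any():
            raise ConfigError(f"MAR driver {spec.driver!r} has missing values")
        z = (drv - drv.mean()) / (drv.std(ddof=0) or 1.0)
        z = z.to_numpy(dtype=float)

    for name, frac in spec.fractions.items():
        if frac == 0.0:
            continue
        if spec.mechanism == "MCAR":
            mask = rng.uniform(size=len(df)) < frac
        else:
            if name == spec.driver:
                raise ConfigError("MAR driver cannot itself be masked")
            a = _solve_mar_intercept(z, spec.slope, frac)
            mask = rng.uniform(size=len(df)) < expit(a + spec.slope * z)
        if df[name].dtype != object:
            df[name] = df[name].astype(float)
        df.loc[mask, name] = np.nan
    return cohort.with_data(df)


def _solve_mar_intercept(z: np.ndarray, slope: float, frac: float) -> float:
    f = lambda a: float(np.mean(expit(a + slope * z))) - frac
    return brentq(f, -40.0, 40.0)
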