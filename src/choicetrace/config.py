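"""Simulation configuration: the generative truths of a synthetic study.

All defaults are the study conditions the generator emulates: 62
participants x 18 foods (153 exhaustive pairwise trials each), a DEBQ-R
restraint distribution with mean 25.0 and SD 8.11, and outcome models
whose coefficients are the winning-model estimates of the four analyses
(binary choice, angle-AUC, x-flips, palatability ratings) plus the
intake-validation slope.  Coefficients for the log-link families are
stored on the link scale (log odds ratios / log incidence rate ratios)
per standardized unit of their predictor.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml
from scipy import optimize, stats

__all__ = ["SimConfig", "ConfigError", "solve_truncnorm_params", "truncnorm_sample"]

_LN = math.log


class ConfigError(ValueError):
    """Raised for inconsistent simulation configurations."""


def _choice_defaults() -> dict:
    # winning binary-choice model: log odds ratios per z-unit
    return {
        "intercept": _LN(1.04),
        "health": _LN(1.23),
        "calories": _LN(2.12),
        "palatability": _LN(9.58),
        "re": _LN(1.01),
        "calories_re": _LN(0.85),
    }


def _auc_defaults() -> dict:
    # winning angle-AUC model: radians per z-unit
    return {
        "intercept": 0.140,
        "re": 0.005,
        "calories": -0.002,
        "palatability": -0.004,
        "health_re": -0.003,
        "calories_re": -0.002,
    }


def _xflip_defaults() -> dict:
    # winning x-flips model: log incidence rate ratios per z-unit
    return {
        "intercept": _LN(1.97),
        "palatability": _LN(0.96),
        "health_re": _LN(0.96),
        "calories_re": _LN(0.97),
    }


def _pal_defaults() -> dict:
    # palatability-shift models (VAS points per z-unit); the health- and
    # calories-channel entries are the targets of the two separate refits
    return {
        "intercept": 62.61,
        "health": 3.51,
        "health_re": 3.80,
        "calories": -0.50,
        "calories_re": -3.36,
    }


@dataclass
class SimConfig:
    """All generator truths; seedable and serializable to YAML."""

    n_participants: int = 62
    n_foods: int = 18
    seed: int = 0

    # person-level moments (moments OF the truncated distributions)
    re_mean: float = 25.0
    re_sd: float = 8.11
    re_range: tuple = (10.0, 50.0)
    age_mean: float = 22.2
    age_sd: float = 3.98
    age_range: tuple = (16.0, 35.0)
    bmi_mean: float = 22.2
    bmi_sd: float = 3.11
    bmi_range: tuple = (16.2, 33.0)

    # binary choice model
    choice_coefs: dict = field(default_factory=_choice_defaults)
    choice_re_var: float = 0.058
    choice_health_slope: float = 0.491
    choice_health_slope_kind: str = "variance"  # or "correlation"
    choice_health_slope_var_if_corr: float = 0.2

    # conflict-metric models
    auc_coefs: dict = field(default_factory=_auc_defaults)
    auc_sigma2: float = 0.002
    auc_tau00: float = 0.001
    xflip_coefs: dict = field(default_factory=_xflip_defaults)
    xflip_tau00: float = 0.060

    # palatability-shift rating model
    pal_coefs: dict = field(default_factory=_pal_defaults)
    pal_sigma2: float = 1036.0
    pal_tau00: float = 6.845

    # intake validation
    intake_log_or: float = _LN(1.10)
    intake_baseline: float = 0.1
    intake_offered: float = 100.0

    # nuisance structure.  The health/calorie anti-correlation of the food
    # set is calibrated so that refitting the winning choice model on a
    # generated study reproduces the printed winning-model standard errors
    # (the rating collinearity is what drives them); the observed-power
    # column only makes sense under those standard errors.
    latent_corr: float = -0.92
    rating_noise_sd: float = 5.0  # within-participant rating noise (VAS points)
    desire_noise_sd: float = 10.0
    timeout_rate: float = 0.0178  # fraction of trials exceeding 4000 ms
    rt_sigma: float = 0.45        # lognormal RT shape (placeholder model)

    def __post_init__(self) -> None:
        if self.n_foods < 2:
            raise ConfigError("n_foods must be >= 2")
        if self.n_participants < 1:
            raise ConfigError("n_participants must be >= 1")
        for name in ("choice_re_var", "auc_sigma2", "auc_tau00", "xflip_tau00",
                     "pal_sigma2", "pal_tau00"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for mean, sd, rng_, label in (
                (self.re_mean, self.re_sd, self.re_range, "re"),
                (self.age_mean, self.age_sd, self.age_range, "age"),
                (self.bmi_mean, self.bmi_sd, self.bmi_range, "bmi")):
            lo, hi = rng_
            if not lo < hi:
                raise ConfigError(f"{label}_range must satisfy min < max")
            if not (lo <= mean <= hi):
                raise ConfigError(f"{label}_range must bracket {label}_mean")
            if sd < 0:
                raise ConfigError(f"{label}_sd must be >= 0")
        if self.choice_health_slope_kind not in ("variance", "correlation"):
            raise ConfigError("choice_health_slope_kind must be "
                              "'variance' or 'correlation'")
        if not -1 < self.latent_corr < 1:
            raise ConfigError("latent_corr must lie in (-1, 1)")
        if not 0 <= self.timeout_rate < 1:
            raise ConfigError("timeout_rate must lie in [0, 1)")

    @property
    def n_trials(self) -> int:
        return self.n_foods * (self.n_foods - 1) // 2

    def choice_cov_re(self) -> np.ndarray:
        """2x2 random intercept/health-slope covariance of the choice model.

        The printed slope quantity is ambiguous between a slope variance
        and an intercept-slope correlation; both readings are supported
        via ``choice_health_slope_kind`` (default: variance, correlation 0).
        """
        v0 = self.choice_re_var
        if self.choice_health_slope_kind == "variance":
            v1, rho = self.choice_health_slope, 0.0
        else:
            v1, rho = self.choice_health_slope_var_if_corr, self.choice_health_slope
        c = rho * math.sqrt(v0 * v1)
        return np.array([[v0, c], [c, v1]])

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path) -> None:
        d = asdict(self)
        for key in ("re_range", "age_range", "bmi_range"):
            d[key] = list(d[key])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("re_range", "age_range", "bmi_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def solve_truncnorm_params(mean: float, sd: float, lo: float, hi: float):
    """Underlying normal (mu, sigma) whose [lo, hi]-truncation has the
    given mean and SD (moment matching).

    The printed sample moments describe the observed (range-restricted)
    scores, so the generator must un-do the truncation bias: sampling a
    naive truncnorm(mean, sd) would overshoot the mean whenever the
    bounds are asymmetric.
    """
    if sd == 0:
        return mean, 0.0

    def moments(p):
        mu, logsig = p
        sig = math.exp(logsig)
        a, b = (lo - mu) / sig, (hi - mu) / sig
        m, v = stats.truncnorm.stats(a, b, loc=mu, scale=sig, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol = optimize.root(moments, [mean, math.log(sd)], method="hybr")
    if not sol.success or max(abs(np.array(moments(sol.x)))) > 1e-6:
        raise ConfigError(
            f"cannot match truncated moments mean={mean}, sd={sd} on [{lo}, {hi}]")
    return float(sol.x[0]), float(math.exp(sol.x[1]))


def truncnorm_sample(rng, n: int, mean: float, sd: float, lo: float, hi: float):
    """Sample n values whose truncated distribution has the given moments."""
    if sd == 0:
        return np.full(n, float(mean))
    mu, sig = solve_truncnorm_params(mean, sd, lo, hi)
    a, b = (lo - mu) / sig, (hi - mu) / sig
    return stats.truncnorm.rvs(a, b, loc=mu, scale=sig, size=n, random_state=rng)
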