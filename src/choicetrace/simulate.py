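"""Synthetic-study generator.

Produces complete studies — participants, four-motive food ratings,
exhaustive pairwise choice trials with outcomes, trajectory conflict
metrics (or raw paths), and post-task intake — with the hierarchical
statistical structure the downstream analyses assume, so that every
stage of the pipeline is testable without any external data.

Two conflict modes exist:

* ``metrics`` draws the angle-AUC (truncated Gaussian) and x-flip counts
  (Poisson) directly from their generative linear predictors, which
  guarantees the model structure for parameter-recovery tests;
* ``paths`` constructs actual (x, y, t) cursor paths (quadratic Bézier
  toward the chosen corner plus a sinusoidal lateral perturbation at a
  10 ms step) whose curvature amplitude and oscillation count are
  monotone in the same linear predictors.  Path mode makes no exact
  metric promise; it is validated by property tests.

Palatability ratings deserve a note: the rating analyses fit TWO
separate two-level models (a health channel and a calories channel) on
the same outcome, while the generator must produce one palatability
value per food.  Because health and calorie ratings are anti-correlated,
generating from either channel's printed coefficients alone would bias
the other channel's refit by the omitted variable.  The generator
therefore inverts the omitted-variable mapping: given the empirical
correlation r between z-health and z-calories it solves

    gamma_h = (a_h - r * a_c) / (1 - r^2),   (and symmetrically)

so that each *separate* refit recovers its printed coefficients
(a_h, a_c, and likewise the interactions) in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import special

from .config import ConfigError, SimConfig, truncnorm_sample
from .design import DesignError, build_model_input, make_pairings, standardize
from .trajectories import ScreenGeometry

__all__ = [
    "SyntheticStudy",
    "gen_population",
    "gen_ratings",
    "gen_choices",
    "gen_conflict",
    "gen_intake",
    "simulate_study",
]


@dataclass
class SyntheticStudy:
    """All tables of one synthetic study."""

    config: SimConfig
    participants: pd.DataFrame
    ratings: pd.DataFrame
    trials: pd.DataFrame
    metrics: pd.DataFrame | None
    trajectories: pd.DataFrame | None
    intake: pd.DataFrame

    def model_input(self, drop_timeouts: bool = True) -> pd.DataFrame:
        """Analysis-ready trial table (difference scores + z-standardization)."""
        return build_model_input(self.trials, self.ratings, self.participants,
                                 drop_timeouts=drop_timeouts)

    def to_dir(self, out: str | Path) -> None:
        out = Path(out)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / "participants.csv", index=False)
        self.ratings.to_csv(out / "ratings.csv", index=False)
        self.trials.to_csv(out / "trials.csv", index=False)
        if self.metrics is not None:
            self.metrics.to_csv(out / "metrics.csv", index=False)
        if self.trajectories is not None:
            self.trajectories.to_csv(out / "trajectories.csv", index=False)
        self.intake.to_csv(out / "intake.csv", index=False)
        self.config.to_yaml(out / "config.yaml")


def gen_population(config: SimConfig, rng=None) -> pd.DataFrame:
    """Draw the participant table.

    Restrained-eating scores come from a truncated normal whose
    *truncated* moments match the configured mean/SD (see
    :func:`choicetrace.config.solve_truncnorm_params`); age and BMI are
    nuisance covariates drawn the same way; the task-order factor
    ``cond_first`` is counterbalanced.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_participants
    re = truncnorm_sample(rng, n, config.re_mean, config.re_sd, *config.re_range)
    age = truncnorm_sample(rng, n, config.age_mean, config.age_sd, *config.age_range)
    bmi = truncnorm_sample(rng, n, config.bmi_mean, config.bmi_sd, *config.bmi_range)
    cond = np.zeros(n, dtype=int)
    cond[: n // 2] = 1
    rng.shuffle(cond)
    return pd.DataFrame({
        "participant_id": np.arange(1, n + 1),
        "re_score": re,
        "age": age,
        "bmi": bmi,
        "cond_first": cond,
    })


def _food_profiles(config: SimConfig, rng) -> pd.DataFrame:
    """Fixed latent health/calorie profiles, anti-correlated across foods."""
    k = config.n_foods
    h = np.linspace(15.0, 85.0, k)
    hz = (h - h.mean()) / h.std()
    # deterministic component orthogonal to the health profile, so the
    # latent anti-correlation is exact for every seed (the realized
    # motive collinearity is a study condition, not noise)
    u = (-1.0) ** np.arange(k)
    u = u - u.mean()
    u -= hz * (u @ hz) / (hz @ hz)
    if u.std() == 0:
        u = np.ones(k)
    u = u / u.std()
    r = config.latent_corr
    cz = r * hz + np.sqrt(1 - r * r) * u
    c = np.clip(50.0 + 18.0 * cz, 5.0, 95.0)
    return pd.DataFrame({"food_id": np.arange(1, k + 1),
                         "latent_health": h, "latent_calories": c})


def gen_ratings(participants: pd.DataFrame, config: SimConfig, rng=None,
                foods: pd.DataFrame | None = None) -> pd.DataFrame:
    """Generate the participant x food x motive rating table (long format).

    Health and calorie ratings are the latent food profiles plus
    within-participant noise; palatability follows the two-channel
    linear structure described in the module docstring (participant
    random intercept, residual SD sqrt(pal_sigma2), clamped to [0, 100]);
    desire is palatability plus noise and enters no winning model.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if foods is None:
        foods = _food_profiles(config, rng)
    n, k = len(participants), config.n_foods
    pid = np.repeat(participants["participant_id"].to_numpy(), k)
    fid = np.tile(foods["food_id"].to_numpy(), n)
    health = np.clip(np.tile(foods["latent_health"].to_numpy(), n)
                     + rng.normal(0, config.rating_noise_sd, n * k), 0, 100)
    calories = np.clip(np.tile(foods["latent_calories"].to_numpy(), n)
                       + rng.normal(0, config.rating_noise_sd, n * k), 0, 100)

    z_h = standardize(health, "person", pid)
    z_c = standardize(calories, "person", pid)
    z_re_p = standardize(participants["re_score"].to_numpy(), "grand")
    z_re = np.repeat(z_re_p, k)

    # invert the omitted-variable mapping at the realized correlation
    r = float(np.corrcoef(z_h, z_c)[0, 1])
    pc = config.pal_coefs
    det = 1.0 - r * r
    g_h = (pc["health"] - r * pc["calories"]) / det
    g_c = (pc["calories"] - r * pc["health"]) / det
    g_hre = (pc["health_re"] - r * pc["calories_re"]) / det
    g_cre = (pc["calories_re"] - r * pc["health_re"]) / det

    b0 = rng.normal(0, np.sqrt(config.pal_tau00), n)
    eta = (pc["intercept"] + g_h * z_h + g_c * z_c
           + (g_hre * z_h + g_cre * z_c) * z_re + np.repeat(b0, k))
    pal = np.clip(eta + rng.normal(0, np.sqrt(config.pal_sigma2), n * k), 0, 100)
    desire = np.clip(pal + rng.normal(0, config.desire_noise_sd, n * k), 0, 100)

    frames = []
    for motive, vals in (("health", health), ("palatability", pal),
                         ("calories", calories), ("desire", desire)):
        frames.append(pd.DataFrame({"participant_id": pid, "food_id": fid,
                                    "motive": motive, "value": vals}))
    return pd.concat(frames, ignore_index=True)


def gen_choices(ratings: pd.DataFrame, participants: pd.DataFrame,
                trials: pd.DataFrame, config: SimConfig, rng=None) -> pd.DataFrame:
    """Attach Bernoulli choice outcomes, RTs and timeout flags to trials.

    The linear predictor applies the configured choice coefficients to
    the person-standardized difference scores and the grand-standardized
    restraint score, plus a participant random intercept and a random
    health slope (covariance per ``SimConfig.choice_cov_re``).  RTs are a
    lognormal placeholder calibrated so that the configured fraction of
    trials exceeds the 4000 ms deadline (timeout -> excluded from the
    analyses, as in the task).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mi = build_model_input(trials, ratings, participants, drop_timeouts=False)
    if len(mi) != len(trials):
        raise DesignError("model input and trials are misaligned")
    co = config.choice_coefs
    eta = (co["intercept"]
           + co["health"] * mi["z_d_health"].to_numpy()
           + co["calories"] * mi["z_d_calories"].to_numpy()
           + co["palatability"] * mi["z_d_palatability"].to_numpy()
           + co["re"] * mi["z_re"].to_numpy()
           + co["calories_re"] * (mi["z_d_calories"] * mi["z_re"]).to_numpy())
    cov = config.choice_cov_re()
    chol = np.linalg.cholesky(cov + 1e-12 * np.eye(2))
    pids = participants["participant_id"].to_numpy()
    b = rng.standard_normal((len(pids), 2)) @ chol.T
    bmap = {p: i for i, p in enumerate(pids)}
    idx = mi["participant_id"].map(bmap).to_numpy()
    eta = eta + b[idx, 0] + b[idx, 1] * mi["z_d_health"].to_numpy()
    chose_ref = rng.random(len(mi)) < special.expit(eta)

    out = trials.copy()
    out["chose_ref"] = chose_ref.astype(int)
    # lognormal RT with P(RT > 4000) = timeout_rate
    from scipy import stats as _st
    sigma = config.rt_sigma
    if config.timeout_rate > 0:
        mu = np.log(4000.0) - _st.norm.ppf(1 - config.timeout_rate) * sigma
    else:
        mu = np.log(1500.0)
    rt = rng.lognormal(mu, sigma, len(out))
    out["rt_ms"] = rt
    out["timeout"] = (rt > 4000.0).astype(int)
    return out


def _conflict_etas(mi: pd.DataFrame, config: SimConfig):
    """Linear predictors of the two conflict models (chosen-relative z's)."""
    a, xf = config.auc_coefs, config.xflip_coefs
    z_h = mi["z_dsel_health"].to_numpy()
    z_c = mi["z_dsel_calories"].to_numpy()
    z_p = mi["z_dsel_palatability"].to_numpy()
    z_re = mi["z_re"].to_numpy()
    eta_auc = (a["intercept"] + a.get("re", 0.0) * z_re
               + a.get("calories", 0.0) * z_c + a.get("palatability", 0.0) * z_p
               + a.get("health", 0.0) * z_h
               + a.get("health_re", 0.0) * z_h * z_re
               + a.get("calories_re", 0.0) * z_c * z_re
               + a.get("palatability_re", 0.0) * z_p * z_re)
    eta_xf = (xf["intercept"] + xf.get("re", 0.0) * z_re
              + xf.get("calories", 0.0) * z_c + xf.get("palatability", 0.0) * z_p
              + xf.get("health", 0.0) * z_h
              + xf.get("health_re", 0.0) * z_h * z_re
              + xf.get("calories_re", 0.0) * z_c * z_re
              + xf.get("palatability_re", 0.0) * z_p * z_re)
    return eta_auc, eta_xf


def gen_conflict(trials: pd.DataFrame, participants: pd.DataFrame,
                 ratings: pd.DataFrame, config: SimConfig, mode: str = "metrics",
                 rng=None, geometry: ScreenGeometry | None = None):
    """Generate conflict metrics (``mode="metrics"``) or raw paths (``"paths"``).

    Metrics mode draws angle-AUC ~ Gaussian(eta_auc + b0, auc_sigma2)
    truncated at 0 and x-flips ~ Poisson(exp(eta_xf + b0)); paths mode
    builds raw-pixel cursor paths whose curvature and lateral
    oscillation are monotone in the same predictors.

    Raises
    ------
    ValueError
        For an unknown mode.
    """
    if mode not in ("metrics", "paths"):
        raise ValueError(f"unknown mode {mode!r}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mi = build_model_input(trials, ratings, participants, drop_timeouts=False)
    eta_auc, eta_xf = _conflict_etas(mi, config)
    pids = participants["participant_id"].to_numpy()
    bmap = {p: i for i, p in enumerate(pids)}
    idx = mi["participant_id"].map(bmap).to_numpy()
    b_auc = rng.normal(0, np.sqrt(config.auc_tau00), len(pids))[idx]
    b_xf = rng.normal(0, np.sqrt(config.xflip_tau00), len(pids))[idx]

    if mode == "metrics":
        auc = np.maximum(
            rng.normal(eta_auc + b_auc, np.sqrt(config.auc_sigma2)), 0.0)
        xflips = rng.poisson(np.exp(eta_xf + b_xf))
        return pd.DataFrame({
            "participant_id": mi["participant_id"],
            "trial_index": mi["trial_index"],
            "auc": auc,
            "xflips": xflips,
            "timeout": trials["timeout"].to_numpy()
            if "timeout" in trials.columns else 0,
        })

    geom = geometry or ScreenGeometry()
    rows = []
    amp = np.maximum(eta_auc + b_auc, 0.0)          # curvature amplitude
    freq = np.exp(eta_xf + b_xf)                    # lateral oscillation rate
    rts = (trials["rt_ms"].to_numpy() if "rt_ms" in trials.columns
           else np.full(len(mi), 1500.0))
    chose_left = (trials["ref_side"].to_numpy() == "left") \
        if "ref_side" in trials.columns else np.zeros(len(mi), bool)
    if "chose_ref" in trials.columns:
        chose_left = np.where(trials["chose_ref"].astype(bool),
                              chose_left, ~chose_left)
    for i in range(len(mi)):
        t_ms, x, y = make_path(amp[i], freq[i], chose_left=bool(chose_left[i]),
                               duration_ms=min(float(rts[i]), 6000.0),
                               geometry=geom)
        rows.append(pd.DataFrame({
            "participant_id": mi["participant_id"].iat[i],
            "trial_index": mi["trial_index"].iat[i],
            "t_ms": t_ms, "x": x, "y": y,
        }))
    return pd.concat(rows, ignore_index=True)


def make_path(amplitude: float, oscillation: float, chose_left: bool = False,
              duration_ms: float = 1500.0, step_ms: float = 10.0,
              geometry: ScreenGeometry | None = None):
    """Construct one raw-pixel cursor path (t_ms, x, y arrays, y-down).

    A quadratic Bézier from the start box to the chosen corner whose
    control point is pulled toward the non-chosen corner in proportion
    to ``amplitude``, plus a lateral sinusoid with ``oscillation``
    cycles whose amplitude also scales with ``amplitude``.  With
    ``amplitude == 0`` the path is an exact straight line (zero
    angle-AUC, zero x-flips); the computed angle-AUC is monotone
    non-decreasing in ``amplitude``.  Deterministic.
    """
    geom = geometry or ScreenGeometry()
    start = np.array(geom.start)
    target = np.array(geom.left_target if chose_left else geom.right_target)
    other = np.array(geom.right_target if chose_left else geom.left_target)
    m = max(int(duration_ms // step_ms) + 1, 8)
    s = np.linspace(0.0, 1.0, m)
    # control point pulled toward the non-chosen corner by the amplitude
    ctrl = (start + target) / 2 + amplitude * 1.2 * (other - target) / 2
    path = ((1 - s)[:, None] ** 2 * start
            + 2 * ((1 - s) * s)[:, None] * ctrl
            + (s ** 2)[:, None] * target)
    path[:, 0] += amplitude * 400.0 * np.sin(2 * np.pi * oscillation * s) * np.sin(np.pi * s)
    return s * duration_ms, path[:, 0], path[:, 1]


def gen_intake(trials: pd.DataFrame, config: SimConfig, rng=None) -> pd.DataFrame:
    """Generate the taste-test intake table from per-food choice counts.

    For each participant x food, ``grams_offered`` is fixed and
    ``grams_consumed`` ~ Binomial(offered, logistic(alpha + log-OR x
    number of times that food was chosen)), with alpha set so the
    zero-choice consumption proportion equals ``intake_baseline``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if "chose_ref" not in trials.columns:
        raise DesignError("trials lack outcomes; generate choices first")
    chosen = np.where(trials["chose_ref"].astype(bool),
                      trials["food_ref"], trials["food_alt"])
    counts = (pd.DataFrame({"participant_id": trials["participant_id"],
                            "food_id": chosen, "n": 1})
              .groupby(["participant_id", "food_id"])["n"].sum())
    foods = np.sort(pd.unique(np.concatenate(
        [trials["food_ref"].to_numpy(), trials["food_alt"].to_numpy()])))
    full = pd.MultiIndex.from_product(
        [np.sort(trials["participant_id"].unique()), foods],
        names=["participant_id", "food_id"])
    counts = counts.reindex(full, fill_value=0).reset_index(name="choice_count")
    alpha = special.logit(config.intake_baseline)
    p = special.expit(alpha + config.intake_log_or * counts["choice_count"].to_numpy())
    offered = int(config.intake_offered)
    consumed = rng.binomial(offered, p)
    counts["grams_offered"] = float(offered)
    counts["grams_consumed"] = consumed.astype(float)
    return counts


def simulate_study(config: SimConfig | None = None, mode: str = "metrics",
                   seed: int | None = None) -> SyntheticStudy:
    """Generate a complete synthetic study (all tables, one seed).

    ``seed`` overrides ``config.seed``.  All randomness flows from one
    generator in a fixed call order, so identical configs give
    byte-identical tables.
    """
    config = config or SimConfig()
    if seed is not None:
        from dataclasses import replace
        config = replace(config, seed=int(seed))
    rng = np.random.default_rng(config.seed)
    participants = gen_population(config, rng)
    ratings = gen_ratings(participants, config, rng)
    plan = make_pairings(np.arange(1, config.n_foods + 1),
                         participants["participant_id"], rng=rng)
    trials = gen_choices(ratings, participants, plan.trials, config, rng)
    metrics = trajectories = None
    if mode == "metrics":
        metrics = gen_conflict(trials, participants, ratings, config, "metrics", rng)
    else:
        trajectories = gen_conflict(trials, participants, ratings, config,
                                    "paths", rng)
    intake = gen_intake(trials, config, rng)
    return SyntheticStudy(config=config, participants=participants,
                          ratings=ratings, trials=trials, metrics=metrics,
                          trajectories=trajectories, intake=intake)
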