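"""Generator contracts: determinism, ranges, calibration, GLM-oracle recovery."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from choicetrace import (ConfigError, SimConfig, compute_auc, compute_xflips,
                         Trajectory, gen_population, gen_ratings,
                         simulate_study)
from choicetrace.simulate import make_path
from conftest import zero_variance_config


def test_identical_seed_identical_tables(small_config):
    s1 = simulate_study(small_config)
    s2 = simulate_study(small_config)
    for name in ("participants", "ratings", "trials", "metrics", "intake"):
        pd.testing.assert_frame_equal(getattr(s1, name), getattr(s2, name))


def test_structural_invariants(small_study):
    cfg = small_study.config
    n_pairs = cfg.n_foods * (cfg.n_foods - 1) // 2
    counts = small_study.trials.groupby("participant_id").size()
    assert (counts == n_pairs).all()
    vals = small_study.ratings["value"]
    assert vals.between(0, 100).all()
    prop = small_study.intake["grams_consumed"] / small_study.intake["grams_offered"]
    assert prop.between(0, 1).all()
    assert (small_study.metrics["auc"] >= 0).all()
    assert (small_study.metrics["xflips"] >= 0).all()


def test_population_moments_and_degenerate_sd():
    pop = gen_population(SimConfig(n_participants=10000, seed=5))
    assert pop["re_score"].mean() == pytest.approx(25.0, abs=0.3)
    assert pop["re_score"].std() == pytest.approx(8.11, abs=0.3)
    assert pop["re_score"].between(10, 50).all()
    # counterbalanced order factor
    assert pop["cond_first"].sum() == 5000
    degenerate = gen_population(replace(SimConfig(), re_sd=0.0, n_participants=50))
    assert (degenerate["re_score"] == 25.0).all()


def test_invalid_truncation_bounds_error():
    with pytest.raises(ConfigError):
        SimConfig(re_range=(30.0, 20.0))
    with pytest.raises(ConfigError):
        SimConfig(re_mean=60.0)  # outside (10, 50)


def test_choice_probability_increases_with_palatability_advantage():
    study = simulate_study(SimConfig(n_participants=40, n_foods=10, seed=9))
    mi = study.model_input(drop_timeouts=False)
    dec = pd.qcut(mi["z_d_palatability"], 10, labels=False)
    rates = mi.groupby(dec)["chose_ref"].mean()
    # monotone response to the dominant motive, up to MC noise
    assert rates.is_monotonic_increasing
    assert rates.iloc[0] < 0.1 and rates.iloc[-1] > 0.9


def test_null_choice_coefficients_give_even_odds():
    cfg = zero_variance_config(
        n_participants=40, n_foods=10, seed=12,
        choice_coefs={k: 0.0 for k in
                      ("intercept", "health", "calories", "palatability",
                       "re", "calories_re")})
    study = simulate_study(cfg)
    p = study.trials["chose_ref"].mean()
    assert p == pytest.approx(0.5, abs=0.02)


def test_single_level_glm_recovers_choice_truths_at_zero_variance():
    """With all random variances 0 the generative model is an ordinary
    logistic regression; a GLM refit must recover every coefficient
    within 3 standard errors (closed-form oracle)."""
    cfg = zero_variance_config(n_participants=150, n_foods=18, seed=21)
    study = simulate_study(cfg)
    mi = study.model_input()
    X = np.column_stack([np.ones(len(mi)), mi["z_re"], mi["z_d_health"],
                         mi["z_d_calories"], mi["z_d_palatability"],
                         mi["z_d_calories:z_re"]])
    fit = sm.GLM(mi["chose_ref"].to_numpy(), X,
                 family=sm.families.Binomial()).fit()
    truth = [cfg.choice_coefs[k] for k in
             ("intercept", "re", "health", "calories", "palatability",
              "calories_re")]
    for est, se, tr in zip(fit.params, fit.bse, truth):
        assert abs(est - tr) < 3 * se


def test_metrics_mode_constant_intercepts_when_noise_free():
    cfg = zero_variance_config(
        n_participants=12, n_foods=6, seed=3, auc_sigma2=0.0,
        auc_coefs={"intercept": 0.140}, xflip_coefs={"intercept": np.log(1.97)})
    study = simulate_study(cfg)
    assert np.allclose(study.metrics["auc"], 0.140)
    # x-flips stay Poisson draws; their mean approaches the intercept rate
    big = simulate_study(replace(cfg, n_participants=60, n_foods=12, seed=4))
    assert big.metrics["xflips"].mean() == pytest.approx(1.97, abs=0.06)


def test_paths_mode_zero_amplitude_is_straight():
    t, x, y = make_path(amplitude=0.0, oscillation=3.0)
    from choicetrace import ScreenGeometry, preprocess
    traj, _ = preprocess(t, x, y, chose_left=False)
    assert compute_auc(traj) == pytest.approx(0.0, abs=1e-6)
    assert compute_xflips(traj) == 0


def test_paths_mode_auc_monotone_in_amplitude():
    from choicetrace import preprocess
    aucs = []
    for amp in np.linspace(0.0, 0.8, 9):
        t, x, y = make_path(amplitude=float(amp), oscillation=1.5)
        traj, _ = preprocess(t, x, y, chose_left=False)
        aucs.append(compute_auc(traj))
    assert all(b >= a - 1e-9 for a, b in zip(aucs, aucs[1:]))
    assert aucs[-1] > aucs[0]


def test_paths_mode_study_round_trip(small_config):
    """Path-mode output feeds the metric pipeline end to end."""
    from choicetrace import metrics_from_samples
    study = simulate_study(replace(small_config, n_participants=3, n_foods=4),
                           mode="paths")
    trials = study.trials
    ref_left = trials["ref_side"].eq("left")
    chose_left = ref_left == trials["chose_ref"].astype(bool)
    side = pd.Series(np.where(chose_left, "left", "right"),
                     index=pd.MultiIndex.from_frame(
                         trials[["participant_id", "trial_index"]]))
    mets = metrics_from_samples(study.trajectories, side)
    assert len(mets) == len(trials)
    assert (mets["auc"] >= 0).all()


def test_ratings_two_channel_structure_ols_oracle():
    """At zero participant variance and small residual noise an OLS fit of
    each separate channel recovers the configured coefficients, and the
    high-restraint palatability slope on health equals main + 2 x
    interaction at z_re = +2."""
    cfg = zero_variance_config(n_participants=400, n_foods=18, seed=31,
                               pal_sigma2=100.0)
    pop = gen_population(cfg)
    ratings = gen_ratings(pop, cfg)
    from choicetrace.pipeline import rating_model_input
    data = rating_model_input(ratings, pop)
    for channel, main_truth, inter_truth in (
            ("health", 3.51, 3.80), ("calories", -0.50, -3.36)):
        X = np.column_stack([np.ones(len(data)), data[f"z_{channel}"],
                             data["z_re"], data[f"z_{channel}"] * data["z_re"]])
        fit = sm.OLS(data["palatability"].to_numpy(), X).fit()
        assert abs(fit.params[1] - main_truth) < 3 * fit.bse[1] + 0.15
        assert abs(fit.params[3] - inter_truth) < 3 * fit.bse[3] + 0.15
        if channel == "health":
            slope_high_re = fit.params[1] + 2 * fit.params[3]
            assert slope_high_re == pytest.approx(3.51 + 2 * 3.80, abs=0.5)


def test_intake_independent_when_slope_zero():
    cfg = replace(SimConfig(), n_participants=40, n_foods=10, seed=17,
                  intake_log_or=0.0)
    study = simulate_study(cfg)
    intake = study.intake
    prop = intake["grams_consumed"] / intake["grams_offered"]
    corr = np.corrcoef(intake["choice_count"], prop)[0, 1]
    assert abs(corr) < 0.1
    assert prop.mean() == pytest.approx(0.1, abs=0.02)


def test_intake_closed_form_odds_ratio():
    """The generative odds of consumption at 17 vs 0 choices differ by a
    factor 1.10^17 by construction."""
    from scipy import special
    cfg = SimConfig()
    a = special.logit(cfg.intake_baseline)
    odds = lambda c: np.exp(a + cfg.intake_log_or * c)
    assert odds(17) / odds(0) == pytest.approx(1.10 ** 17, rel=1e-10)
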