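"""Mixed-model estimation, selection, goodness of fit and power machinery."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import special, stats

from choicetrace.glmm import (MixedGLM, ModelSpec, hosmer_lemeshow,
                              hosmer_lemeshow_from_probs, power_sim, select)


def _grouped_frame(rng, n_groups, per_group, columns):
    n = n_groups * per_group
    df = pd.DataFrame({c: rng.normal(0, 1, n) for c in columns})
    df["participant_id"] = np.repeat(np.arange(n_groups), per_group)
    return df


# -- estimation ------------------------------------------------------------

def test_gaussian_intercept_only_matches_closed_form():
    """Balanced one-way layout: the ML fixed intercept is the grand mean."""
    rng = np.random.default_rng(0)
    df = _grouped_frame(rng, 10, 30, [])
    df["y"] = 2.5 + np.repeat(rng.normal(0, 1, 10), 30) + rng.normal(0, 1, 300)
    spec = ModelSpec("gaussian", "y", fixed=())
    res = MixedGLM.from_spec(spec, df).fit(reml=False)
    assert res.params["(Intercept)"] == pytest.approx(df["y"].mean(), abs=1e-6)
    assert res.tau00 > 0


def test_binomial_laplace_matches_glm_at_zero_variance():
    """Data with no participant heterogeneity: the mixed fit's fixed effects
    must agree with a single-level logistic regression within 3 SEs."""
    rng = np.random.default_rng(1)
    df = _grouped_frame(rng, 40, 500, ["x1", "x2"])
    eta = 0.3 + 0.8 * df["x1"] - 0.5 * df["x2"]
    df["y"] = (rng.random(len(df)) < special.expit(eta)).astype(float)
    spec = ModelSpec("binomial", "y", fixed=("x1", "x2"))
    res = MixedGLM.from_spec(spec, df).fit()
    X = np.column_stack([np.ones(len(df)), df["x1"], df["x2"]])
    glm = sm.GLM(df["y"].to_numpy(), X, family=sm.families.Binomial()).fit()
    for i, name in enumerate(["(Intercept)", "x1", "x2"]):
        assert abs(res.params[name] - glm.params[i]) < 3 * glm.bse[i]
    assert res.tau00 < 0.01  # boundary variance detected


def test_poisson_laplace_recovers_random_intercept_model():
    rng = np.random.default_rng(2)
    df = _grouped_frame(rng, 50, 120, ["x"])
    b = rng.normal(0, np.sqrt(0.3), 50)
    eta = 0.7 - 0.3 * df["x"] + np.repeat(b, 120)
    df["y"] = rng.poisson(np.exp(eta))
    spec = ModelSpec("poisson", "y", fixed=("x",))
    res = MixedGLM.from_spec(spec, df).fit()
    assert res.params["(Intercept)"] == pytest.approx(0.7, abs=0.25)
    assert res.params["x"] == pytest.approx(-0.3, abs=3 * res.bse["x"])
    assert res.tau00 == pytest.approx(0.3, abs=0.15)
    # criteria are consistent with the reported log-likelihood
    assert res.aic == pytest.approx(-2 * res.llf + 2 * res.k_params)
    assert res.bic == pytest.approx(-2 * res.llf
                                    + res.k_params * np.log(res.model.nobs))
    # exponentiated CI equals exp of the link-scale CI exactly
    ci = res.conf_int()
    eci = res.conf_int(exp=True)
    assert np.allclose(np.exp(ci.to_numpy()), eci.to_numpy())


def test_binomial_counts_with_trials_column():
    rng = np.random.default_rng(3)
    df = _grouped_frame(rng, 30, 20, ["x"])
    df["n"] = 50.0
    eta = special.logit(0.2) + 0.15 * df["x"]
    df["y"] = rng.binomial(50, special.expit(eta)).astype(float)
    spec = ModelSpec("binomial", "y", fixed=("x",), trials="n")
    res = MixedGLM.from_spec(spec, df).fit()
    assert res.params["x"] == pytest.approx(0.15, abs=3 * res.bse["x"])
    assert res.params["(Intercept)"] == pytest.approx(special.logit(0.2),
                                                      abs=0.05)


# -- selection -------------------------------------------------------------

def _choice_like_data(rng, n_groups=24, per_group=60, slope_sd=1.2,
                      beta=(0.0, 1.5, 0.4)):
    """Binary outcome with an x1 effect, optional random x1 slope."""
    df = _grouped_frame(rng, n_groups, per_group, ["x1", "x2"])
    b0 = rng.normal(0, 0.3, n_groups)
    b1 = rng.normal(0, slope_sd, n_groups)
    eta = (beta[0] + beta[1] * df["x1"] + beta[2] * df["x2"]
           + np.repeat(b0, per_group) + np.repeat(b1, per_group) * df["x1"])
    df["y"] = (rng.random(len(df)) < special.expit(eta)).astype(float)
    return df


def test_select_finds_strong_random_slope_and_keeps_strong_effects():
    rng = np.random.default_rng(4)
    df = _choice_like_data(rng)
    spec = ModelSpec("binomial", "y", fixed=("x1", "x2"))
    trace = select(spec, candidate_random_slopes=("x1", "x2"), data=df)
    assert trace.winning_spec.random_slopes == ("x1",)
    assert "x1" in trace.winning_spec.fixed  # huge effect never deleted
    steps = trace.to_frame()
    assert (steps["decision"].str.startswith("stage")).any()


def test_select_null_effects_reduce_to_intercept_only():
    """With all true coefficients zero the modal winning fixed structure is
    empty (backward deletion removes everything)."""
    outcomes = []
    for seed in (10, 11, 12):
        rng = np.random.default_rng(seed)
        df = _grouped_frame(rng, 15, 40, ["x1", "x2"])
        b0 = rng.normal(0, 0.3, 15)
        df["y"] = (rng.random(len(df))
                   < special.expit(np.repeat(b0, 40))).astype(float)
        spec = ModelSpec("binomial", "y", fixed=("x1", "x2"))
        trace = select(spec, candidate_random_slopes=(), data=df)
        outcomes.append(len(trace.winning_spec.fixed))
    assert sorted(outcomes)[1] == 0  # modal outcome: intercept-only


def test_select_invariant_to_term_order():
    rng = np.random.default_rng(5)
    df = _choice_like_data(rng)
    s1 = ModelSpec("binomial", "y", fixed=("x1", "x2"))
    s2 = ModelSpec("binomial", "y", fixed=("x2", "x1"))
    t1 = select(s1, ("x1",), df)
    t2 = select(s2, ("x1",), df)
    assert set(t1.winning_spec.fixed) == set(t2.winning_spec.fixed)
    assert t1.winner.aic == pytest.approx(t2.winner.aic, abs=1e-3)


# -- goodness of fit -------------------------------------------------------

def test_hosmer_lemeshow_df_and_null_distribution():
    """For a well-specified logistic model the statistic is ~ chi2(g-2):
    its mean over replicates approaches 8 for deciles."""
    rng = np.random.default_rng(6)
    stats_ = []
    for _ in range(100):
        x = rng.normal(0, 1, 1500)
        p = special.expit(-0.4 + 0.9 * x)
        y = (rng.random(1500) < p).astype(float)
        X = np.column_stack([np.ones(1500), x])
        fit = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        chi2, df, pval = hosmer_lemeshow_from_probs(y, fit.fittedvalues)
        assert df == 8
        stats_.append(chi2)
    assert np.mean(stats_) == pytest.approx(8.0, abs=1.5)


def test_hosmer_lemeshow_on_mixed_fit(small_model_input):
    from choicetrace.pipeline import CHOICE_WINNING
    res = MixedGLM.from_spec(CHOICE_WINNING, small_model_input).fit()
    chi2, df, p = hosmer_lemeshow(res, groups=10)
    assert df == 8
    assert chi2 >= 0 and 0 <= p <= 1


# -- power -----------------------------------------------------------------

def test_power_null_term_rejects_at_alpha_and_monotone_in_effect():
    rng = np.random.default_rng(7)
    df = _grouped_frame(rng, 20, 40, ["x1", "x2"])
    df["y"] = 0.0  # placeholder outcome; simulation overwrites it
    spec = ModelSpec("binomial", "y", fixed=("x1", "x2"))
    cov = np.array([[0.2]])
    powers = []
    for beta_x2 in (0.0, 0.12, 0.35):
        pr = power_sim(spec, df, {"x1": 0.5, "x2": beta_x2}, cov,
                       terms="x2", n_sims=80, seed=8)
        powers.append(pr.power["x2"])
    # size of the test at the null, within Monte-Carlo slack
    assert powers[0] < 0.15
    lo, hi = stats.binom.interval(0.999, 80, 0.05)
    assert lo / 80 <= powers[0] <= hi / 80 + 0.05
    # power grows with the true effect
    assert powers[0] < powers[1] < powers[2]
    assert powers[2] > 0.8


def test_power_rejects_bad_inputs(small_model_input):
    from choicetrace.pipeline import CHOICE_WINNING
    with pytest.raises(ValueError):
        power_sim(CHOICE_WINNING, small_model_input, {}, np.eye(2),
                  terms="z_d_calories:z_re", n_sims=0)
    with pytest.raises(ValueError):
        power_sim(CHOICE_WINNING, small_model_input, {}, np.eye(3),
                  terms="z_d_calories:z_re", n_sims=5)


# -- presentation ----------------------------------------------------------

def test_summary_and_tidy_table(small_model_input):
    from choicetrace.pipeline import CHOICE_WINNING
    res = MixedGLM.from_spec(CHOICE_WINNING, small_model_input).fit()
    tab = res.to_frame()
    assert set(tab.columns) >= {"term", "estimate", "se", "p",
                                "exp_estimate", "exp_ci_lo", "exp_ci_hi"}
    assert np.allclose(tab["exp_estimate"], np.exp(tab["estimate"]))
    text = res.summary()
    assert "OR" in text and "AIC" in text and "tau00" in text
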