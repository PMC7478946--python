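"""Orchestration of the four analyses plus the intake validation.

Each ``run_*`` function takes prepared tables, optionally performs the
stepwise top-down model selection (otherwise fits the known winning
structure directly), and returns an :class:`AnalysisReport` bundling the
winning fit, the selection trace, diagnostics, optional observed-power
estimates, and provenance (input hashes, seed, options).

The winning-model structures of the four analyses are exposed as module
constants so they can be fitted directly, which is how the parameter-
recovery checks exercise them.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignError, standardize
from .glmm import (MixedGLM, MixedGLMResults, ModelSpec, PowerResult,
                   SelectionTrace, hosmer_lemeshow, power_sim, select)

__all__ = [
    "AnalysisReport",
    "run_choice",
    "run_conflict",
    "run_palatability_shift",
    "run_intake_validation",
    "rating_model_input",
    "CHOICE_WINNING", "CHOICE_BEYOND_OPTIMAL",
    "AUC_WINNING", "XFLIPS_WINNING",
    "PAL_HEALTH_MODEL", "PAL_CALORIES_MODEL",
    "INTAKE_MODEL",
]

log = logging.getLogger("choicetrace")

COVARIATES = ("z_age", "z_bmi", "cond_first")

# Binary choice: beyond-optimal (all motives, cross-level interactions,
# covariates) and the winning structure (random health slope; calories x
# restraint is the surviving interaction).
CHOICE_BEYOND_OPTIMAL = ModelSpec(
    family="binomial", outcome="chose_ref",
    fixed=("z_age", "z_bmi", "cond_first", "z_re",
           "z_d_health", "z_d_calories", "z_d_palatability",
           "z_d_health:z_re", "z_d_calories:z_re", "z_d_palatability:z_re"))
CHOICE_WINNING = ModelSpec(
    family="binomial", outcome="chose_ref",
    fixed=("z_re", "z_d_health", "z_d_calories", "z_d_palatability",
           "z_d_calories:z_re"),
    random_slopes=("z_d_health",))
CHOICE_RANDOM_SLOPE_CANDIDATES = ("z_d_health", "z_d_calories", "z_d_palatability")

# Conflict metrics use chosen-relative difference scores.
_CONFLICT_BEYOND = ("z_age", "z_bmi", "cond_first", "z_re",
                    "z_dsel_health", "z_dsel_calories", "z_dsel_palatability",
                    "z_dsel_health:z_re", "z_dsel_calories:z_re",
                    "z_dsel_palatability:z_re")
AUC_BEYOND_OPTIMAL = ModelSpec("gaussian", "auc", fixed=_CONFLICT_BEYOND)
AUC_WINNING = ModelSpec(
    "gaussian", "auc",
    fixed=("z_re", "z_dsel_calories", "z_dsel_palatability",
           "z_dsel_health:z_re", "z_dsel_calories:z_re"),
    random_slopes=("z_dsel_health",), estimation="REML")
XFLIPS_BEYOND_OPTIMAL = ModelSpec("poisson", "xflips", fixed=_CONFLICT_BEYOND)
XFLIPS_WINNING = ModelSpec(
    "poisson", "xflips",
    fixed=("z_dsel_palatability", "z_dsel_health:z_re", "z_dsel_calories:z_re"))
CONFLICT_RANDOM_SLOPE_CANDIDATES = ("z_dsel_health", "z_dsel_calories",
                                    "z_dsel_palatability")

# Palatability shift: two separate two-level models on the rating table.
PAL_HEALTH_MODEL = ModelSpec(
    "gaussian", "palatability",
    fixed=("z_age", "z_bmi", "z_re", "cond_first", "z_health", "z_health:z_re"),
    estimation="REML")
PAL_CALORIES_MODEL = ModelSpec(
    "gaussian", "palatability",
    fixed=("z_age", "z_bmi", "z_re", "cond_first", "z_calories",
           "z_calories:z_re"),
    estimation="REML")

INTAKE_MODEL = ModelSpec(
    "binomial", "grams_consumed", fixed=("choice_count",),
    trials="grams_offered")


@dataclass
class AnalysisReport:
    """One analysis' results bundle."""

    name: str
    winner: MixedGLMResults
    winning_spec: ModelSpec
    trace: SelectionTrace | None = None
    power: PowerResult | None = None
    diagnostics: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    n_excluded: int = 0

    def coef_table(self) -> pd.DataFrame:
        return self.winner.to_frame()

    def summary(self) -> str:
        parts = [f"=== Analysis: {self.name} ===", self.winner.summary()]
        if self.n_excluded:
            parts.append(f"Excluded trials (timeouts): {self.n_excluded}")
        for k, v in self.diagnostics.items():
            parts.append(f"{k}: {v}")
        if self.power is not None:
            for t, pw in self.power.power.items():
                lo, hi = self.power.ci[t]
                parts.append(f"observed power {t}: {100 * pw:.2f}% "
                             f"[{100 * lo:.2f}; {100 * hi:.2f}] "
                             f"({self.power.n_converged} sims)")
        return "\n".join(parts)

    def to_json_dict(self) -> dict:
        d = {
            "analysis": self.name,
            "spec": self.winning_spec.describe(),
            "coefficients": self.coef_table().to_dict(orient="records"),
            "tau00": self.winner.tau00,
            "slope_components": self.winner.slope_components,
            "sigma2": self.winner.scale,
            "llf": self.winner.llf,
            "aic": self.winner.aic,
            "bic": self.winner.bic,
            "n_obs": int(self.winner.model.nobs),
            "n_participants": int(self.winner.model.n_groups),
            "n_excluded": int(self.n_excluded),
            "converged": bool(self.winner.converged),
            "singular": bool(self.winner.singular),
            "diagnostics": {k: v for k, v in self.diagnostics.items()},
            "provenance": self.provenance,
        }
        if self.power is not None:
            d["power"] = {t: {"power_pct": 100 * p,
                              "ci_pct": [100 * c for c in self.power.ci[t]]}
                          for t, p in self.power.power.items()}
        if self.trace is not None:
            d["selection"] = self.trace.steps
        return d

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.coef_table().to_csv(outdir / f"{self.name}_coefficients.csv",
                                 index=False)
        with open(outdir / f"{self.name}_report.json", "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=2, default=float)
        with open(outdir / f"{self.name}_summary.txt", "w") as fh:
            fh.write(self.summary() + "\n")
        if self.trace is not None:
            self.trace.to_frame().to_csv(outdir / f"{self.name}_selection.csv",
                                         index=False)


def _hash_frame(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(df, index=False).to_numpy().tobytes())
    return h.hexdigest()[:16]


def _provenance(seed, **tables) -> dict:
    return {"seed": seed, "input_hashes": {k: _hash_frame(v)
                                           for k, v in tables.items()}}


def _maybe_power(report: AnalysisReport, data, n_power, seed, alpha=0.05):
    """Observed power of the significant fixed effects, simulating from
    the winning fit's own estimates (simr-style)."""
    if not n_power:
        return
    res = report.winner
    if res.model.family == "gaussian":
        log.info("power simulation for gaussian outcomes not enabled; skipped")
        return
    sig = [t for t in res.params.index
           if t != "(Intercept)" and res.pvalues[t] < alpha]
    if not sig:
        return
    truth = dict(zip(res.params.index, res.params.to_numpy()))
    report.power = power_sim(report.winning_spec, data, truth, res.cov_re,
                             terms=sig, n_sims=n_power, seed=seed)


def run_choice(model_input: pd.DataFrame, do_select: bool = True,
               n_power: int = 0, seed: int = 0) -> AnalysisReport:
    """Binary-choice analysis (binomial logit, motives x restraint).

    With ``do_select`` the full top-down strategy runs from the
    beyond-optimal structure; otherwise the winning structure is fitted
    directly.  Diagnostics include the Hosmer–Lemeshow grouped
    chi-square.
    """
    data = model_input
    trace = None
    if do_select:
        trace = select(CHOICE_BEYOND_OPTIMAL, CHOICE_RANDOM_SLOPE_CANDIDATES,
                       data, covariates=COVARIATES)
        winner, spec = trace.winner, trace.winning_spec
    else:
        winner = MixedGLM.from_spec(CHOICE_WINNING, data).fit()
        spec = CHOICE_WINNING
    report = AnalysisReport(
        name="choice", winner=winner, winning_spec=spec, trace=trace,
        provenance=_provenance(seed, model_input=model_input))
    chi2, df, p = hosmer_lemeshow(winner)
    report.diagnostics["hosmer_lemeshow"] = {"chi2": chi2, "df": df, "p": p}
    _maybe_power(report, data, n_power, seed)
    return report


def run_conflict(model_input: pd.DataFrame, metrics: pd.DataFrame, which: str,
                 do_select: bool = False, n_power: int = 0,
                 seed: int = 0) -> AnalysisReport:
    """Conflict-metric analysis: gaussian for the angle-AUC, poisson for
    x-flips, on chosen-relative motive difference scores.

    Raises
    ------
    DesignError
        On negative AUC inputs or non-integer x-flip counts.
    """
    if which not in ("auc", "xflips"):
        raise ValueError("which must be 'auc' or 'xflips'")
    keys = ["participant_id", "trial_index"]
    data = model_input.merge(
        metrics[keys + [which]], on=keys, how="inner", validate="1:1")
    vals = data[which].to_numpy()
    if which == "auc" and np.any(vals < 0):
        raise DesignError("negative AUC values in metrics input")
    if which == "xflips" and np.any(vals != np.round(vals)):
        raise DesignError("x-flip counts must be non-negative integers")
    trace = None
    if do_select:
        beyond = AUC_BEYOND_OPTIMAL if which == "auc" else XFLIPS_BEYOND_OPTIMAL
        trace = select(beyond, CONFLICT_RANDOM_SLOPE_CANDIDATES, data,
                       covariates=COVARIATES)
        winner, spec = trace.winner, trace.winning_spec
    else:
        spec = AUC_WINNING if which == "auc" else XFLIPS_WINNING
        winner = MixedGLM.from_spec(spec, data).fit(
            reml=(spec.estimation == "REML"))
    report = AnalysisReport(
        name=which, winner=winner, winning_spec=spec, trace=trace,
        provenance=_provenance(seed, model_input=model_input, metrics=metrics))
    if which == "auc":
        resid = data["auc"].to_numpy() - winner.fittedvalues
        report.diagnostics["residuals"] = {
            "mean": float(np.mean(resid)), "sd": float(np.std(resid))}
    _maybe_power(report, data, n_power, seed)
    return report


def rating_model_input(ratings: pd.DataFrame,
                       participants: pd.DataFrame) -> pd.DataFrame:
    """One row per participant x food with raw palatability, person-
    standardized health/calorie ratings, and grand-standardized
    person-level covariates."""
    wide = ratings.pivot_table(index=["participant_id", "food_id"],
                               columns="motive", values="value",
                               aggfunc="first").reset_index()
    pp = participants.set_index("participant_id")
    wide["z_health"] = standardize(wide["health"], "person",
                                   wide["participant_id"])
    wide["z_calories"] = standardize(wide["calories"], "person",
                                     wide["participant_id"])
    for src, dst in (("re_score", "z_re"), ("age", "z_age"), ("bmi", "z_bmi")):
        z = standardize(pp[src].to_numpy(), "grand")
        wide[dst] = pd.Series(z, index=pp.index).reindex(
            wide["participant_id"]).to_numpy()
    wide["cond_first"] = pp["cond_first"].reindex(
        wide["participant_id"]).to_numpy()
    wide["z_health:z_re"] = wide["z_health"] * wide["z_re"]
    wide["z_calories:z_re"] = wide["z_calories"] * wide["z_re"]
    return wide


def run_palatability_shift(ratings: pd.DataFrame, participants: pd.DataFrame,
                           seed: int = 0) -> tuple[AnalysisReport, AnalysisReport]:
    """The two palatability-shift analyses (health and calories channels).

    Each is a two-level gaussian model with a participant random
    intercept, REML-refit: palatability ~ z-motive x grand-z restraint +
    covariates.  Returns (health report, calories report).
    """
    data = rating_model_input(ratings, participants)
    reports = []
    for spec, label in ((PAL_HEALTH_MODEL, "palatability_health"),
                        (PAL_CALORIES_MODEL, "palatability_calories")):
        winner = MixedGLM.from_spec(spec, data).fit(reml=True)
        rep = AnalysisReport(
            name=label, winner=winner, winning_spec=spec,
            provenance=_provenance(seed, ratings=ratings,
                                   participants=participants))
        reports.append(rep)
    return tuple(reports)


def run_intake_validation(intake: pd.DataFrame,
                          trials: pd.DataFrame | None = None,
                          random_intercept: bool = True,
                          seed: int = 0) -> AnalysisReport:
    """Predict consumption proportion from per-food choice frequency.

    Binomial-logit on (grams consumed, grams offered) with the number of
    choices for the food as predictor; the exponentiated slope is the
    odds ratio per additional choice.  ``random_intercept`` toggles the
    participant random intercept (the two-level variant is the default).

    Raises
    ------
    DesignError
        If any row has consumed > offered.
    """
    data = intake.copy()
    if "choice_count" not in data.columns:
        if trials is None:
            raise DesignError("intake lacks choice_count and no trials given")
        chosen = np.where(trials["chose_ref"].astype(bool),
                          trials["food_ref"], trials["food_alt"])
        cc = (pd.DataFrame({"participant_id": trials["participant_id"],
                            "food_id": chosen, "n": 1})
              .groupby(["participant_id", "food_id"])["n"].sum())
        data["choice_count"] = [
            int(cc.get((p, f), 0)) for p, f in
            zip(data["participant_id"], data["food_id"])]
    if np.any(data["grams_consumed"].to_numpy()
              > data["grams_offered"].to_numpy()):
        raise DesignError("grams_consumed exceeds grams_offered")
    if random_intercept:
        winner = MixedGLM.from_spec(INTAKE_MODEL, data).fit()
    else:
        import statsmodels.api as sm
        y = np.column_stack([data["grams_consumed"],
                             data["grams_offered"] - data["grams_consumed"]])
        X = np.column_stack([np.ones(len(data)), data["choice_count"]])
        glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
        winner = _wrap_glm(glm, data, INTAKE_MODEL)
    rep = AnalysisReport(name="intake", winner=winner,
                         winning_spec=INTAKE_MODEL,
                         provenance=_provenance(seed, intake=intake))
    rep.diagnostics["or_per_choice"] = float(
        np.exp(winner.params["choice_count"]))
    return rep


def _wrap_glm(glm_res, data, spec) -> MixedGLMResults:
    """Adapt a single-level GLM fit into the MixedGLMResults container."""
    names = ["(Intercept)"] + list(spec.fixed)
    model = MixedGLM(data[spec.outcome].to_numpy(),
                     np.column_stack([np.ones(len(data)),
                                      *[data[t] for t in spec.fixed]]),
                     data[spec.group].to_numpy(), family=spec.family,
                     trials=data[spec.trials].to_numpy() if spec.trials else None,
                     exog_names=names, spec=spec)
    return MixedGLMResults(
        model=model, params=pd.Series(np.asarray(glm_res.params), index=names),
        bse=pd.Series(np.asarray(glm_res.bse), index=names),
        cov_params=np.asarray(glm_res.cov_params()),
        cov_re=np.zeros((1, 1)), scale=None, llf=float(glm_res.llf),
        k_params=len(names), converged=True, singular=False,
        method="GLM (no random effects)", optimizer_message="",
        raw_params=np.concatenate([np.asarray(glm_res.params), [-8.0]]))
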