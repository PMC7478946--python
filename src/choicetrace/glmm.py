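"""Two-level mixed models with participant random effects.

The analyses model trials (Level 1) nested in participants (Level 2)
with three outcome families: binomial-logit for binary choice (odds
ratios), Gaussian-identity for the angle-AUC conflict metric, and
Poisson-log for x-flip counts (incidence rate ratios).  The random
structure is a participant intercept plus optionally one or more
participant slopes on Level-1 predictors.

The public surface follows the statsmodels Model/Results convention:

>>> model = MixedGLM.from_spec(spec, data)     # doctest: +SKIP
>>> res = model.fit()
>>> res.summary()

Estimation
----------
* Gaussian models delegate to :class:`statsmodels.regression.mixed_linear_model.MixedLM`
  (ML, or REML for the refit of a winning model).
* Binomial and Poisson models are fitted by maximum likelihood under a
  Laplace approximation to the marginal likelihood: per participant the
  random-effect mode is found by Newton iterations (penalized IRLS) and
  the integral replaced by the Gaussian approximation at the mode.  The
  random-effect covariance is parameterized by its log-Cholesky factor.
  Fixed-effect standard errors are Wald, from the numerical Hessian of
  the Laplace log-likelihood.

Model selection follows a stepwise top-down strategy: start from the
"beyond optimal" fixed structure, choose the random structure by
AIC/BIC, backward-delete fixed terms whose removal does not worsen AIC
by at least ``aic_threshold`` (default 2), then refit the winner (REML
when Gaussian).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "ModelSpec",
    "MixedGLM",
    "MixedGLMResults",
    "SelectionTrace",
    "ConvergenceError",
    "select",
    "hosmer_lemeshow",
    "hosmer_lemeshow_from_probs",
    "power_sim",
    "PowerResult",
]

FAMILIES = ("binomial", "gaussian", "poisson")


class ConvergenceError(RuntimeError):
    """Raised when every fit of a selection stage fails to converge."""


@dataclass(frozen=True)
class ModelSpec:
    """Declarative description of a two-level model.

    ``fixed`` lists predictor column names; an interaction is written
    ``"a:b"`` and is the elementwise product of the (already
    standardized) columns ``a`` and ``b``.  An intercept is always
    included.  ``random_slopes`` lists Level-1 columns whose slopes vary
    by participant, in addition to the always-present random intercept.
    For binomial data with more than one trial per row (e.g. grams
    consumed out of grams offered), ``trials`` names the column of totals.
    """

    family: str
    outcome: str
    fixed: tuple[str, ...]
    random_slopes: tuple[str, ...] = ()
    group: str = "participant_id"
    trials: str | None = None
    estimation: str = "ML"  # or "REML" (gaussian only)

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.estimation == "REML" and self.family != "gaussian":
            raise ValueError("REML applies to gaussian models only")
        # Note: an interaction may appear without its main effects and a
        # random slope without its fixed slope — the backward-deletion
        # strategy can (and in the winning conflict models does) delete a
        # main effect whose interaction survives.  Column existence is
        # checked when the design is built.

    def drop(self, term: str) -> "ModelSpec":
        return replace(self, fixed=tuple(t for t in self.fixed if t != term))

    def with_slopes(self, slopes) -> "ModelSpec":
        return replace(self, random_slopes=tuple(slopes))

    def describe(self) -> str:
        rnd = " + ".join(("1",) + self.random_slopes)
        fx = " + ".join(("1",) + self.fixed) or "1"
        return f"{self.outcome} ~ {fx} + ({rnd} | {self.group}) [{self.family}, {self.estimation}]"


def _term_column(data: pd.DataFrame, term: str) -> np.ndarray:
    if term in data.columns:
        return data[term].to_numpy(dtype=float)
    parts = term.split(":")
    col = np.ones(len(data))
    for p in parts:
        if p not in data.columns:
            raise KeyError(f"column {p!r} not in data")
        col = col * data[p].to_numpy(dtype=float)
    return col


def build_design(data: pd.DataFrame, spec: ModelSpec):
    """Build (y, X, Z, groups, trials, names) arrays for a spec."""
    y = data[spec.outcome].to_numpy(dtype=float)
    names = ["(Intercept)"] + list(spec.fixed)
    X = np.column_stack([np.ones(len(data))] +
                        [_term_column(data, t) for t in spec.fixed])
    Z = np.column_stack([np.ones(len(data))] +
                        [_term_column(data, s) for s in spec.random_slopes])
    groups = data[spec.group].to_numpy()
    trials = data[spec.trials].to_numpy(dtype=float) if spec.trials else None
    return y, X, Z, groups, trials, names


# ---------------------------------------------------------------------------
# families (canonical links)

class _Binomial:
    name = "binomial"

    @staticmethod
    def loglik(y, eta, n):
        return y * eta - n * np.logaddexp(0.0, eta)

    @staticmethod
    def const(y, n):
        return float(np.sum(special.gammaln(n + 1) - special.gammaln(y + 1)
                            - special.gammaln(n - y + 1)))

    @staticmethod
    def mean(eta, n):
        return n * special.expit(eta)

    @staticmethod
    def weight(eta, n):
        p = special.expit(eta)
        return n * p * (1.0 - p)


class _Poisson:
    name = "poisson"

    @staticmethod
    def loglik(y, eta, n):
        return y * eta - np.exp(eta)

    @staticmethod
    def const(y, n):
        return float(-np.sum(special.gammaln(y + 1)))

    @staticmethod
    def mean(eta, n):
        return np.exp(eta)

    weight = mean


_FAMILY_IMPL = {"binomial": _Binomial, "poisson": _Poisson}


# ---------------------------------------------------------------------------

class MixedGLM:
    """Two-level mixed model for one of the three supported families.

    Parameters
    ----------
    endog : array
        Outcome per row (binary/int counts, or successes when ``trials``
        is given, or a continuous value for gaussian).
    exog : (n, p) array
        Fixed-effects design including the intercept column.
    groups : array
        Participant identifier per row.
    exog_re : (n, q) array, optional
        Random-effects design (default: intercept only).
    """

    def __init__(self, endog, exog, groups, exog_re=None, family="binomial",
                 trials=None, exog_names=None, re_names=None, spec=None):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        order = np.argsort(np.asarray(groups), kind="stable")
        self.family = family
        self.endog = np.asarray(endog, dtype=float)[order]
        self.exog = np.asarray(exog, dtype=float)[order]
        self.groups = np.asarray(groups)[order]
        self.exog_re = (np.ones((len(self.endog), 1)) if exog_re is None
                        else np.asarray(exog_re, dtype=float)[order])
        self.trials = (np.ones_like(self.endog) if trials is None
                       else np.asarray(trials, dtype=float)[order])
        self._has_trials = trials is not None
        uniq, self.group_idx = np.unique(self.groups, return_inverse=True)
        self.group_labels = uniq
        self.n_groups = len(uniq)
        self.nobs = len(self.endog)
        p = self.exog.shape[1]
        self.exog_names = list(exog_names) if exog_names is not None else (
            ["(Intercept)"] + [f"x{i}" for i in range(1, p)])
        q = self.exog_re.shape[1]
        self.re_names = list(re_names) if re_names is not None else (
            ["(Intercept)"] + [f"z{i}" for i in range(1, q)])
        self.spec = spec
        self._b_cache = np.zeros((self.n_groups, q))
        if self.n_groups < 2:
            raise ValueError("need at least 2 participants")

    # -- construction ------------------------------------------------------

    @classmethod
    def from_spec(cls, spec: ModelSpec, data: pd.DataFrame) -> "MixedGLM":
        y, X, Z, groups, trials, names = build_design(data, spec)
        return cls(y, X, groups, exog_re=Z, family=spec.family, trials=trials,
                   exog_names=names,
                   re_names=["(Intercept)"] + list(spec.random_slopes),
                   spec=spec)

    # -- Laplace machinery (binomial / poisson) ----------------------------

    @property
    def _q(self):
        return self.exog_re.shape[1]

    def _theta_to_chol(self, theta):
        q = self._q
        L = np.zeros((q, q))
        L[np.diag_indices(q)] = np.exp(theta[:q])
        if q > 1:
            L[np.tril_indices(q, -1)] = theta[q:]
        return L

    def _sigma_inv_logdet(self, theta):
        L = self._theta_to_chol(theta)
        Linv = np.linalg.inv(L)
        sigma_inv = Linv.T @ Linv
        logdet = 2.0 * float(np.sum(theta[:self._q]))
        return sigma_inv, logdet

    def _eta(self, beta, b):
        eta = self.exog @ beta
        eta += np.einsum("ij,ij->i", self.exog_re, b[self.group_idx])
        return eta

    def _penalized_ll(self, fam, beta, b, sigma_inv):
        eta = self._eta(beta, b)
        ll = float(np.sum(fam.loglik(self.endog, eta, self.trials)))
        pen = 0.5 * float(np.einsum("ij,jk,ik->", b, sigma_inv, b))
        return ll - pen, eta

    def _inner_mode(self, fam, beta, theta, tol=1e-9, maxiter=60):
        """Newton mode-finding for the per-group random effects."""
        q = self._q
        sigma_inv, logdet_sigma = self._sigma_inv_logdet(theta)
        b = self._b_cache.copy()
        f, eta = self._penalized_ll(fam, beta, b, sigma_inv)
        gidx = self.group_idx
        for _ in range(maxiter):
            resid = self.endog - fam.mean(eta, self.trials)
            w = fam.weight(eta, self.trials)
            grad = np.empty((self.n_groups, q))
            H = np.empty((self.n_groups, q, q))
            for j in range(q):
                zj = self.exog_re[:, j]
                grad[:, j] = np.bincount(gidx, zj * resid, self.n_groups)
                for k in range(j + 1):
                    H[:, j, k] = H[:, k, j] = np.bincount(
                        gidx, zj * self.exog_re[:, k] * w, self.n_groups)
            grad -= b @ sigma_inv
            H += sigma_inv[None, :, :]
            step = np.linalg.solve(H, grad[:, :, None])[:, :, 0]
            gmax = np.max(np.abs(grad))
            if gmax < tol:
                break
            # backtracking on the joint penalized log-likelihood
            scale = 1.0
            for _ in range(25):
                b_new = b + scale * step
                f_new, eta_new = self._penalized_ll(fam, beta, b_new, sigma_inv)
                if f_new >= f - 1e-12:
                    break
                scale *= 0.5
            b, f, eta = b_new, f_new, eta_new
        else:
            pass  # gradient tolerance not met; Laplace still evaluated
        # final curvature at the mode
        w = fam.weight(eta, self.trials)
        H = np.empty((self.n_groups, q, q))
        for j in range(q):
            zj = self.exog_re[:, j]
            for k in range(j + 1):
                H[:, j, k] = H[:, k, j] = np.bincount(
                    gidx, zj * self.exog_re[:, k] * w, self.n_groups)
        H += sigma_inv[None, :, :]
        self._b_cache = b
        return b, f, H, logdet_sigma

    def _neg_laplace_ll(self, params, fam):
        p = self.exog.shape[1]
        beta, theta = params[:p], params[p:]
        b, f, H, logdet_sigma = self._inner_mode(fam, beta, theta)
        sign, logdet_H = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            return 1e10
        ll = f - 0.5 * self.n_groups * logdet_sigma - 0.5 * float(np.sum(logdet_H))
        return -ll

    def _start_params(self, fam):
        glm_fam = sm.families.Binomial() if fam.name == "binomial" else sm.families.Poisson()
        endog = (np.column_stack([self.endog, self.trials - self.endog])
                 if self._has_trials else self.endog)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm = sm.GLM(endog, self.exog, family=glm_fam).fit()
        q = self._q
        theta0 = np.full(q, np.log(0.3))
        theta0 = np.concatenate([theta0, np.zeros(q * (q - 1) // 2)])
        return np.concatenate([np.asarray(glm.params), theta0])

    # -- fitting -----------------------------------------------------------

    def fit(self, reml: bool | None = None, start_params=None, maxiter=300,
            _retry=True) -> "MixedGLMResults":
        """Fit the model; returns a :class:`MixedGLMResults`.

        Non-convergence never raises from here: the result carries a
        ``converged`` flag and optimizer diagnostics (one restart from a
        perturbed start is attempted first).
        """
        if self.family == "gaussian":
            return self._fit_gaussian(reml=bool(reml), maxiter=maxiter)
        fam = _FAMILY_IMPL[self.family]
        p, q = self.exog.shape[1], self._q
        x0 = np.asarray(start_params, float) if start_params is not None \
            else self._start_params(fam)
        bounds = ([(None, None)] * p + [(-8.0, 4.0)] * q
                  + [(-4.0, 4.0)] * (q * (q - 1) // 2))
        self._b_cache = np.zeros((self.n_groups, q))
        res = optimize.minimize(self._neg_laplace_ll, x0, args=(fam,),
                                method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": maxiter, "ftol": 1e-11,
                                         "gtol": 1e-7})
        if not res.success and _retry:
            rng = np.random.default_rng(0)
            x1 = res.x + rng.normal(scale=0.05, size=res.x.size)
            res2 = optimize.minimize(self._neg_laplace_ll, x1, args=(fam,),
                                     method="L-BFGS-B", bounds=bounds,
                                     options={"maxiter": maxiter, "ftol": 1e-11,
                                              "gtol": 1e-7})
            if res2.fun < res.fun:
                res = res2
        params = res.x
        llf = -float(res.fun) + fam.const(self.endog, self.trials)
        hess = approx_hess1(params, self._neg_laplace_ll, args=(fam,))
        try:
            cov = np.linalg.inv(hess)
            singular_cov = False
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(hess)
            singular_cov = True
        bad_var = np.diag(cov)[:p] <= 0
        if np.any(bad_var):
            cov = np.linalg.pinv(hess)
            singular_cov = True
        beta, theta = params[:p], params[p:]
        L = self._theta_to_chol(theta)
        cov_re = L @ L.T
        singular_re = bool(np.any(theta[:q] <= -7.9))
        k = p + q + q * (q - 1) // 2
        return MixedGLMResults(
            model=self, params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(np.sqrt(np.abs(np.diag(cov)[:p])), index=self.exog_names),
            cov_params=cov[:p, :p], cov_re=cov_re, scale=None, llf=llf,
            k_params=k, converged=bool(res.success),
            singular=singular_re or singular_cov,
            method="Laplace-ML", optimizer_message=str(res.message),
            raw_params=params)

    def _fit_gaussian(self, reml: bool, maxiter: int) -> "MixedGLMResults":
        exog_re = self.exog_re
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mod = sm.MixedLM(self.endog, self.exog, groups=self.groups,
                             exog_re=exog_re)
            try:
                mres = mod.fit(reml=reml, maxiter=maxiter,
                               method=["bfgs", "powell", "cg"])
                converged = bool(mres.converged)
            except Exception as exc:  # pragma: no cover - statsmodels internal
                raise ConvergenceError(f"MixedLM failed: {exc}") from exc
        p = self.exog.shape[1]
        q = self._q
        k = p + q * (q + 1) // 2 + 1
        cov_re = np.asarray(mres.cov_re)
        # boundary / singular detection mirrors lme4's isSingular
        singular = bool(np.min(np.linalg.eigvalsh(cov_re)) < 1e-8 * max(
            1.0, float(np.max(np.abs(cov_re)))))
        return MixedGLMResults(
            model=self, params=pd.Series(np.asarray(mres.fe_params),
                                         index=self.exog_names),
            bse=pd.Series(np.asarray(mres.bse_fe), index=self.exog_names),
            cov_params=np.asarray(mres.cov_params())[:p, :p],
            cov_re=cov_re, scale=float(mres.scale), llf=float(mres.llf),
            k_params=k, converged=converged, singular=singular,
            method="MixedLM-" + ("REML" if reml else "ML"),
            optimizer_message="", raw_params=None)


@dataclass
class MixedGLMResults:
    """Estimates, uncertainties and criteria of one mixed-model fit.

    ``params``/``bse``/``pvalues`` are on the link scale; ``exp_params``
    and ``conf_int(exp=True)`` give odds ratios (binomial) or incidence
    rate ratios (poisson).  ``cov_re`` is the participant random-effect
    covariance (intercept variance tau00 first); ``scale`` the gaussian
    residual variance sigma2.
    """

    model: MixedGLM
    params: pd.Series
    bse: pd.Series
    cov_params: np.ndarray
    cov_re: np.ndarray
    scale: float | None
    llf: float
    k_params: int
    converged: bool
    singular: bool
    method: str
    optimizer_message: str
    raw_params: np.ndarray | None

    # -- inference ---------------------------------------------------------

    @property
    def zvalues(self) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * stats.norm.sf(np.abs(self.zvalues)),
                         index=self.params.index)

    def conf_int(self, alpha: float = 0.05, exp: bool = False) -> pd.DataFrame:
        zc = stats.norm.ppf(1 - alpha / 2)
        lo = self.params - zc * self.bse
        hi = self.params + zc * self.bse
        if exp:
            lo, hi = np.exp(lo), np.exp(hi)
        return pd.DataFrame({"ci_lo": lo, "ci_hi": hi})

    @property
    def exp_params(self) -> pd.Series:
        return np.exp(self.params)

    # -- criteria ----------------------------------------------------------

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.k_params

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + self.k_params * np.log(self.model.nobs)

    @property
    def deviance(self) -> float:
        return -2.0 * self.llf

    @property
    def tau00(self) -> float:
        return float(self.cov_re[0, 0])

    @property
    def slope_components(self) -> dict:
        """Slope variances and intercept-slope correlations, by slope name."""
        out = {}
        for i, name in enumerate(self.model.re_names[1:], start=1):
            var = float(self.cov_re[i, i])
            denom = np.sqrt(self.cov_re[0, 0] * var)
            corr = float(self.cov_re[0, i] / denom) if denom > 0 else np.nan
            out[name] = {"variance": var, "correlation": corr}
        return out

    @property
    def fittedvalues(self) -> np.ndarray:
        """Conditional fitted means (per observation, including BLUPs)."""
        m = self.model
        if m.family == "gaussian":
            # refit BLUPs not tracked for gaussian; marginal mean suffices
            return m.exog @ self.params.to_numpy()
        fam = _FAMILY_IMPL[m.family]
        p = m.exog.shape[1]
        beta, theta = self.raw_params[:p], self.raw_params[p:]
        b, _, _, _ = m._inner_mode(fam, beta, theta)
        eta = m._eta(beta, b)
        return fam.mean(eta, m.trials)

    # -- presentation ------------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Tidy coefficient table (one row per fixed effect)."""
        ci = self.conf_int()
        eci = self.conf_int(exp=True)
        return pd.DataFrame({
            "term": self.params.index,
            "estimate": self.params.to_numpy(),
            "se": self.bse.to_numpy(),
            "ci_lo": ci["ci_lo"].to_numpy(),
            "ci_hi": ci["ci_hi"].to_numpy(),
            "p": self.pvalues.to_numpy(),
            "exp_estimate": self.exp_params.to_numpy(),
            "exp_ci_lo": eci["ci_lo"].to_numpy(),
            "exp_ci_hi": eci["ci_hi"].to_numpy(),
        }).reset_index(drop=True)

    def summary(self) -> str:
        m = self.model
        label = {"binomial": "OR", "poisson": "IRR", "gaussian": "B"}[m.family]
        tab = self.to_frame()
        lines = []
        desc = m.spec.describe() if m.spec is not None else f"[{m.family}]"
        lines.append(f"Mixed model ({self.method}): {desc}")
        lines.append(f"Observations: {m.nobs}   Participants: {m.n_groups}")
        hdr = f"{'term':<28}{'est':>9}{'SE':>8}{label:>9}{'95% CI':>20}{'p':>9}"
        lines.append(hdr)
        lines.append("-" * len(hdr))
        for _, r in tab.iterrows():
            show = r["exp_estimate"] if m.family != "gaussian" else r["estimate"]
            lo = r["exp_ci_lo"] if m.family != "gaussian" else r["ci_lo"]
            hi = r["exp_ci_hi"] if m.family != "gaussian" else r["ci_hi"]
            lines.append(f"{r['term']:<28}{r['estimate']:>9.3f}{r['se']:>8.3f}"
                         f"{show:>9.3f}{f'[{lo:.3f}; {hi:.3f}]':>20}{r['p']:>9.3g}")
        lines.append(f"tau00 (participant) = {self.tau00:.4g}")
        for name, comp in self.slope_components.items():
            lines.append(f"slope {name}: var = {comp['variance']:.4g}, "
                         f"corr = {comp['correlation']:.3f}")
        if self.scale is not None:
            lines.append(f"sigma2 (residual) = {self.scale:.4g}")
        lines.append(f"logLik = {self.llf:.3f}  AIC = {self.aic:.3f}  "
                     f"BIC = {self.bic:.3f}")
        if not self.converged:
            lines.append(f"WARNING: optimizer did not report convergence "
                         f"({self.optimizer_message})")
        if self.singular:
            lines.append("WARNING: singular / boundary variance component")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# stepwise top-down selection

@dataclass
class SelectionTrace:
    """Record of the top-down selection path."""

    steps: list = field(default_factory=list)
    winner: MixedGLMResults | None = None
    winning_spec: ModelSpec | None = None

    def log(self, spec: ModelSpec, res: MixedGLMResults | None, decision: str):
        self.steps.append({
            "spec": spec.describe(),
            "aic": res.aic if res is not None else np.nan,
            "bic": res.bic if res is not None else np.nan,
            "converged": res.converged if res is not None else False,
            "decision": decision,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.steps)


def _fit_spec(spec: ModelSpec, data: pd.DataFrame, **kw) -> MixedGLMResults:
    return MixedGLM.from_spec(spec, data).fit(
        reml=(spec.estimation == "REML"), **kw)


def _removable(spec: ModelSpec, protected: set) -> list[str]:
    """Interactions first; mains only once no surviving interaction uses them."""
    inters = [t for t in spec.fixed if ":" in t and t not in protected]
    if inters:
        return inters
    used = {p for t in spec.fixed if ":" in t for p in t.split(":")}
    return [t for t in spec.fixed
            if ":" not in t and t not in used and t not in protected]


def select(beyond_optimal: ModelSpec, candidate_random_slopes, data: pd.DataFrame,
           aic_threshold: float = 2.0, protected: tuple = (),
           covariates: tuple = ()) -> SelectionTrace:
    """Stepwise top-down model selection.

    Stage 1 fits the beyond-optimal fixed structure with a random
    intercept; stage 2 compares random structures (intercept-only and
    each single candidate slope) on AIC with BIC as tie-breaker; stage 3
    backward-deletes fixed terms whose removal does not raise AIC by at
    least ``aic_threshold`` (interactions before their main effects,
    highest p first); stage 4 refits the winner, with REML when the
    family is gaussian.  Covariates listed in ``covariates`` get a final
    screen: a non-significant covariate is dropped unless its removal
    changes the significance pattern of the remaining terms.

    Raises
    ------
    ConvergenceError
        If all fits of a stage fail to converge.
    """
    trace = SelectionTrace()
    protected = set(protected)

    spec0 = beyond_optimal.with_slopes(())
    res0 = _fit_spec(spec0, data)
    trace.log(spec0, res0, "stage1: beyond-optimal, random intercept")

    # stage 2: random structure
    candidates = [((), res0)]
    for s in candidate_random_slopes:
        sp = beyond_optimal.with_slopes((s,))
        try:
            r = _fit_spec(sp, data)
        except ConvergenceError:
            trace.log(sp, None, "stage2: fit failed")
            continue
        trace.log(sp, r, f"stage2: candidate random slope {s}")
        if r.converged:
            candidates.append(((s,), r))
    if not any(r.converged for _, r in candidates):
        raise ConvergenceError("no random-structure candidate converged")
    candidates.sort(key=lambda c: (round(c[1].aic, 6), round(c[1].bic, 6)))
    slopes, current = candidates[0]
    spec = beyond_optimal.with_slopes(slopes)
    trace.log(spec, current, f"stage2: selected random structure {slopes or '(intercept only)'}")

    # stage 3: backward deletion
    while True:
        cand = _removable(spec, protected)
        cand = [t for t in cand if t not in spec.random_slopes]
        if not cand:
            break
        cand.sort(key=lambda t: -current.pvalues.get(t, 0.0))
        removed = False
        for term in cand:
            sp = spec.drop(term)
            try:
                r = _fit_spec(sp, data)
            except ConvergenceError:
                continue
            keep_removal = r.aic < current.aic + aic_threshold
            trace.log(sp, r, f"stage3: drop {term} -> "
                             f"{'removed' if keep_removal else 'retained'} "
                             f"(dAIC={r.aic - current.aic:+.2f})")
            if keep_removal:
                spec, current = sp, r
                removed = True
                break
        if not removed:
            break

    # covariate screen: non-significant covariates dropped unless the
    # significance pattern of the other terms changes
    for cov in covariates:
        if cov not in spec.fixed or cov in {p for t in spec.fixed if ":" in t
                                            for p in t.split(":")}:
            continue
        if current.pvalues.get(cov, 1.0) < 0.05:
            trace.log(spec, current, f"covariate {cov}: significant, kept")
            continue
        sp = spec.drop(cov)
        try:
            r = _fit_spec(sp, data)
        except ConvergenceError:
            continue
        before = {t: current.pvalues[t] < 0.05 for t in sp.fixed}
        after = {t: r.pvalues[t] < 0.05 for t in sp.fixed}
        if before == after:
            spec, current = sp, r
            trace.log(sp, r, f"covariate {cov}: dropped (pattern unchanged)")
        else:
            trace.log(sp, r, f"covariate {cov}: kept (pattern would change)")

    # stage 4: refit winner
    if spec.family == "gaussian":
        spec = replace(spec, estimation="REML")
    winner = _fit_spec(spec, data)
    trace.log(spec, winner, "stage4: winning model refit")
    trace.winner = winner
    trace.winning_spec = spec
    return trace


# ---------------------------------------------------------------------------
# goodness of fit

def hosmer_lemeshow(results: MixedGLMResults, groups: int = 10):
    """Hosmer–Lemeshow grouped chi-square for a binomial fit.

    Observations are binned into ``groups`` quantile groups of the
    conditional fitted probability; the statistic sums
    ``(O - E)^2 / (E (1 - E/n_g))`` over groups, with df = groups - 2.

    Returns ``(chi2, df, p)``; if ties reduce the number of distinct
    bins a ``UserWarning`` is issued and df shrinks accordingly.
    """
    if results.model.family != "binomial":
        raise ValueError("Hosmer–Lemeshow applies to binomial fits")
    mu = results.fittedvalues
    n = results.model.trials
    return hosmer_lemeshow_from_probs(results.model.endog, mu / n, trials=n,
                                      groups=groups)


def hosmer_lemeshow_from_probs(y, prob, trials=None, groups: int = 10):
    """Hosmer–Lemeshow from outcomes and fitted probabilities directly."""
    y = np.asarray(y, dtype=float)
    prob = np.asarray(prob, dtype=float)
    n = np.ones_like(y) if trials is None else np.asarray(trials, dtype=float)
    mu = n * prob
    bins = pd.qcut(prob, groups, labels=False, duplicates="drop")
    g = int(bins.max()) + 1
    if g < groups:
        warnings.warn(f"only {g} distinct fitted-probability groups", UserWarning)
    chi2 = 0.0
    for k in range(g):
        sel = bins == k
        O = float(np.sum(y[sel]))
        E = float(np.sum(mu[sel]))
        ng = float(np.sum(n[sel]))
        denom = E * (1.0 - E / ng)
        if denom > 0:
            chi2 += (O - E) ** 2 / denom
    df = g - 2
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# simulation-based power

@dataclass(frozen=True)
class PowerResult:
    """Observed power of fixed effects, with Clopper–Pearson 95% CIs."""

    n_sims: int
    alpha: float
    power: dict          # term -> proportion significant (0..1)
    ci: dict             # term -> (lo, hi) proportions
    n_converged: int

    def percent(self, term: str) -> float:
        return 100.0 * self.power[term]


def power_sim(spec: ModelSpec, data: pd.DataFrame, truth_params: dict,
              truth_cov_re: np.ndarray, terms, n_sims: int = 200,
              alpha: float = 0.05, seed=None, rng=None) -> PowerResult:
    """Monte-Carlo observed power for fixed effects of a mixed model.

    The outcome is simulated ``n_sims`` times from the generative truth
    (``truth_params`` on the link scale, random-effect covariance
    ``truth_cov_re``) at the design held fixed in ``data``; the spec is
    refit to each replicate and the Wald p-value of each term in
    ``terms`` compared with ``alpha``.  Power is the proportion of
    converged replicates that reject; the CI is exact Clopper–Pearson.
    """
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if isinstance(terms, str):
        terms = [terms]
    if rng is None:
        rng = np.random.default_rng(seed)
    if spec.family == "gaussian":
        raise NotImplementedError("power_sim targets the binomial/poisson analyses")
    fam = _FAMILY_IMPL[spec.family]
    model = MixedGLM.from_spec(spec, data)
    p = model.exog.shape[1]
    q = model._q
    beta = np.array([truth_params.get(name, 0.0) for name in model.exog_names])
    cov_re = np.atleast_2d(np.asarray(truth_cov_re, dtype=float))
    if cov_re.shape != (q, q):
        raise ValueError(f"truth_cov_re must be {q}x{q} for this spec")
    chol = np.linalg.cholesky(cov_re + 1e-12 * np.eye(q))
    theta0 = np.concatenate([np.log(np.maximum(np.diag(chol), 1e-4)),
                             chol[np.tril_indices(q, -1)]])
    start = np.concatenate([beta, theta0])
    eta_fixed = model.exog @ beta
    hits = {t: 0 for t in terms}
    n_conv = 0
    for _ in range(n_sims):
        b = rng.standard_normal((model.n_groups, q)) @ chol.T
        eta = eta_fixed + np.einsum("ij,ij->i", model.exog_re, b[model.group_idx])
        if spec.family == "binomial":
            y = rng.binomial(model.trials.astype(int), special.expit(eta))
        else:
            y = rng.poisson(np.exp(eta))
        sim = MixedGLM(y, model.exog, model.groups, exog_re=model.exog_re,
                       family=spec.family,
                       trials=model.trials if model._has_trials else None,
                       exog_names=model.exog_names, re_names=model.re_names,
                       spec=spec)
        res = sim.fit(start_params=start)
        if not np.all(np.isfinite(res.bse.to_numpy())):
            continue
        n_conv += 1
        for t in terms:
            if res.pvalues[t] < alpha:
                hits[t] += 1
    power = {t: hits[t] / max(n_conv, 1) for t in terms}
    ci = {}
    for t in terms:
        lo, hi = _clopper_pearson(hits[t], max(n_conv, 1))
        ci[t] = (lo, hi)
    return PowerResult(n_sims=n_sims, alpha=alpha, power=power, ci=ci,
                       n_converged=n_conv)


def _clopper_pearson(k: int, n: int, conf: float = 0.95):
    a = 1 - conf
    lo = stats.beta.ppf(a / 2, k, n - k + 1) if k > 0 else 0.0
    hi = stats.beta.ppf(1 - a / 2, k + 1, n - k) if k < n else 1.0
    return float(lo), float(hi)
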