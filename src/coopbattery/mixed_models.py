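"""Mixed-effects models for ultimatum-game rejections and fairness ratings.

Two specifications, both with a participant random intercept:

* **Rejection model** (logistic): rejection ~ centered offer * predictor,
  where the predictor is either the group indicator (healthy controls as
  reference, coded 0) or the mean-centered dissociality score.  Offers in
  euro are centered at 3.5 (the mean of the 1-6 menu).  Fit by maximum
  likelihood with the random intercept integrated out by Gauss-Hermite
  quadrature; odds ratios are exponentiated coefficients.

* **Fairness model** (linear): rating ~ group * (centered offer +
  centered offer^2), offers 0-10 centered at 5, fit with a standard
  linear mixed-model routine (statsmodels MixedLM).

Wald inference on the fixed effects uses residual degrees of freedom
n_obs - n_fixed, matching how mixed-model t statistics are commonly
reported for these designs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = [
    "FixedEffectEstimate",
    "GlmmResult",
    "or_from_coef",
    "fit_logistic_random_intercept",
    "fit_ug_glmm",
    "fit_fairness_lmm",
]

UG_OFFER_CENTER = 3.5
FAIRNESS_OFFER_CENTER = 5.0


@dataclass(frozen=True)
class FixedEffectEstimate:
    name: str
    b: float
    se: float
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    odds_ratio: Optional[float] = None


@dataclass(frozen=True)
class GlmmResult:
    fixed_effects: list[FixedEffectEstimate]
    random_intercept_sd: float
    loglik: Optional[float]
    n_obs: int
    n_groups: int
    method: str
    flags: tuple[str, ...] = ()

    def coef(self, name: str) -> FixedEffectEstimate:
        for fe in self.fixed_effects:
            if fe.name == name:
                return fe
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(fe) for fe in self.fixed_effects]).set_index("name")


def or_from_coef(b: float) -> float:
    """Odds ratio from a log-odds coefficient: exp(b)."""
    if not math.isfinite(b):
        raise ValueError("coefficient must be finite")
    return math.exp(b)


def _wald_table(
    names: list[str],
    beta: np.ndarray,
    se: np.ndarray,
    df: float,
    odds_ratios: bool,
) -> list[FixedEffectEstimate]:
    tcrit = stats.t.ppf(0.975, df)
    out = []
    for name, b, s in zip(names, beta, se):
        tval = b / s if s > 0 else np.nan
        p = 2.0 * stats.t.sf(abs(tval), df) if np.isfinite(tval) else np.nan
        out.append(
            FixedEffectEstimate(
                name=name, b=float(b), se=float(s), t=float(tval), df=float(df),
                p=float(p), ci_low=float(b - tcrit * s), ci_high=float(b + tcrit * s),
                odds_ratio=or_from_coef(float(b)) if odds_ratios else None,
            )
        )
    return out


def fit_logistic_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    names: list[str],
    *,
    n_quad: int = 25,
) -> GlmmResult:
    """ML fit of a logistic model with a per-group Gaussian intercept.

    The marginal likelihood integrates the random intercept out with
    ``n_quad``-node Gauss-Hermite quadrature (effectively exact for a
    scalar intercept at 25 nodes), and is maximised over the fixed effects
    and log random-intercept SD by quasi-Newton optimisation.  Standard
    errors come from the numerical Hessian at the optimum.

    Complete separation in the outcome (all 0 or all 1) is flagged and
    returns a degenerate result rather than crashing.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    groups = np.asarray(groups)
    uniq, gidx = np.unique(groups, return_inverse=True)
    n_obs, p = X.shape
    flags: tuple[str, ...] = ()
    if y.min() == y.max():
        return GlmmResult(
            fixed_effects=[
                FixedEffectEstimate(n, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan, np.nan)
                for n in names
            ],
            random_intercept_sd=np.nan, loglik=None, n_obs=n_obs,
            n_groups=len(uniq), method="gauss_hermite_ml",
            flags=("complete_separation: outcome is constant; "
                   "logistic coefficients are not identified",),
        )

    nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
    log_w = np.log(weights / math.sqrt(2.0 * math.pi))

    def negloglik(theta: np.ndarray) -> float:
        beta, log_sd = theta[:p], theta[p]
        sd = math.exp(log_sd)
        eta = X @ beta  # (n_obs,)
        # (n_obs, n_quad) linear predictors at each quadrature node
        z = eta[:, None] + sd * nodes[None, :]
        # log Bernoulli likelihood per obs/node
        ll = y[:, None] * z - np.logaddexp(0.0, z)
        # sum within groups -> (n_groups, n_quad)
        gll = np.zeros((len(uniq), n_quad))
        np.add.at(gll, gidx, ll)
        from scipy.special import logsumexp
        return -float(logsumexp(gll + log_w[None, :], axis=1).sum())

    # start from the pooled GLM solution
    beta0 = np.zeros(p)
    try:
        import statsmodels.api as sm
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            beta0 = sm.GLM(y, X, family=sm.families.Binomial()).fit().params
    except Exception:
        pass
    theta0 = np.concatenate([beta0, [math.log(0.5)]])
    # log-SD bounded below: the boundary is a zero random-intercept variance
    bounds = [(None, None)] * p + [(-6.0, 3.0)]
    res = optimize.minimize(negloglik, theta0, method="L-BFGS-B", bounds=bounds,
                            options={"gtol": 1e-9, "ftol": 1e-12, "maxiter": 1000})
    res2 = optimize.minimize(negloglik, res.x, method="Nelder-Mead",
                             options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 5000})
    if res2.fun < res.fun:
        res = res2
        flags = flags + ("optimizer_refined",)
    theta = res.x
    if theta[p] <= -5.5:
        flags = flags + ("random_intercept_variance_near_zero",)

    at_boundary = theta[p] <= -5.5
    if at_boundary:
        # variance pinned at ~0: profile out the SD, Hessian over beta only
        log_sd_fix = theta[p]
        hess = _numerical_hessian(
            lambda b: negloglik(np.concatenate([b, [log_sd_fix]])), theta[:p]
        )
    else:
        hess = _numerical_hessian(negloglik, theta)[:p + 1, :p + 1]
    try:
        cov = np.linalg.inv(hess)
        se = np.sqrt(np.clip(np.diag(cov)[:p], 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(p, np.nan)
        flags = flags + ("singular_hessian",)

    df = float(n_obs - p)
    return GlmmResult(
        fixed_effects=_wald_table(names, theta[:p], se, df, odds_ratios=True),
        random_intercept_sd=float(math.exp(theta[p])),
        loglik=float(-res.fun),
        n_obs=n_obs,
        n_groups=len(uniq),
        method="gauss_hermite_ml",
        flags=flags,
    )


def _numerical_hessian(f, x: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    n = len(x)
    h = eps * np.maximum(1.0, np.abs(x))
    H = np.zeros((n, n))
    f0 = f(x)
    for i in range(n):
        for j in range(i, n):
            if i == j:
                xp = x.copy(); xp[i] += h[i]
                xm = x.copy(); xm[i] -= h[i]
                H[i, i] = (f(xp) - 2 * f0 + f(xm)) / h[i] ** 2
            else:
                xpp = x.copy(); xpp[[i, j]] += [h[i], h[j]]
                xpm = x.copy(); xpm[i] += h[i]; xpm[j] -= h[j]
                xmp = x.copy(); xmp[i] -= h[i]; xmp[j] += h[j]
                xmm = x.copy(); xmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (f(xpp) - f(xpm) - f(xmp) + f(xmm)) / (4 * h[i] * h[j])
    return H


def _check_ug_trials(trials: pd.DataFrame) -> None:
    required = {"participant_id", "group", "offer", "rejected"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"UG trials table missing columns: {sorted(missing)}")
    offers = trials["offer"].to_numpy()
    if offers.min() < 0 or offers.max() > 10:
        raise ValueError("offers must lie in 0..10 euro")


def fit_ug_glmm(
    trials: pd.DataFrame,
    predictor: str = "group",
    *,
    reference_group: str = "HC",
    n_quad: int = 25,
) -> GlmmResult:
    """Logistic random-intercept model of ultimatum-game rejections.

    Fixed effects: centered offer (offer - 3.5), the predictor (group
    indicator with ``reference_group`` = 0, or mean-centered dissociality),
    and their interaction.  One row per participant x offer is expected.
    """
    _check_ug_trials(trials)
    offer_c = trials["offer"].to_numpy(dtype=float) - UG_OFFER_CENTER
    if predictor == "group":
        pred = (trials["group"].to_numpy() != reference_group).astype(float)
        pred_name = "group"
    elif predictor == "dissociality":
        if "dissociality" not in trials.columns:
            raise ValueError("trials table has no dissociality column")
        raw = trials["dissociality"].to_numpy(dtype=float)
        pred = raw - raw.mean()
        pred_name = "dissociality"
    else:
        raise ValueError(f"unknown predictor {predictor!r}")
    X = np.column_stack([np.ones(len(trials)), offer_c, pred, offer_c * pred])
    names = ["(Intercept)", "offer", pred_name, f"{pred_name}_x_offer"]
    y = trials["rejected"].to_numpy(dtype=float)
    return fit_logistic_random_intercept(
        y, X, trials["participant_id"].to_numpy(), names, n_quad=n_quad
    )


def fit_fairness_lmm(trials: pd.DataFrame, *, reference_group: str = "HC") -> GlmmResult:
    """Linear random-intercept model of fairness ratings.

    Fixed effects: group, centered offer, centered offer^2 and the group
    interactions with both offer terms; offers 0-10 are centered at 5.
    Needs at least three distinct offers for the quadratic term.
    """
    required = {"participant_id", "group", "offer", "rating"}
    missing = required - set(trials.columns)
    if missing:
        raise ValueError(f"fairness trials table missing columns: {sorted(missing)}")
    if trials["offer"].nunique() < 3:
        raise ValueError("quadratic offer term needs at least 3 distinct offers")

    import statsmodels.api as sm

    df = trials.copy()
    df["offer_c"] = df["offer"].astype(float) - FAIRNESS_OFFER_CENTER
    df["offer_c2"] = df["offer_c"] ** 2
    df["bpd"] = (df["group"] != reference_group).astype(float)
    df["bpd_x_offer"] = df["bpd"] * df["offer_c"]
    df["bpd_x_offer2"] = df["bpd"] * df["offer_c2"]
    # exog column order fixes the report row order
    names = ["(Intercept)", "group", "offer", "group_x_offer", "offer2", "group_x_offer2"]
    exog = sm.add_constant(
        df[["bpd", "offer_c", "bpd_x_offer", "offer_c2", "bpd_x_offer2"]].to_numpy()
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(
            df["rating"].to_numpy(dtype=float), exog, groups=df["participant_id"].to_numpy()
        )
        fit = model.fit(reml=True)
    beta = np.asarray(fit.fe_params)
    se = np.asarray(fit.bse_fe)
    dfres = float(len(df) - len(beta))
    ri_var = float(fit.cov_re.iloc[0, 0]) if hasattr(fit.cov_re, "iloc") else float(fit.cov_re[0][0])
    return GlmmResult(
        fixed_effects=_wald_table(names, beta, se, dfres, odds_ratios=True),
        random_intercept_sd=math.sqrt(max(ri_var, 0.0)),
        loglik=float(fit.llf),
        n_obs=len(df),
        n_groups=df["participant_id"].nunique(),
        method="mixedlm_reml",
    )
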