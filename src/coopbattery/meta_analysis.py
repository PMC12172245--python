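"""Random-effects mini meta-analysis of standardized mean differences.

Per study, Cohen's d (pooled-SD standardiser, no small-sample correction)
with the usual large-sample variance

    var(d) = (n1 + n2) / (n1 n2) + d^2 / (2 (n1 + n2)).

Studies are pooled by inverse-variance weighting under a random-effects
model; the between-study variance tau^2 is estimated by REML (default) or
DerSimonian-Laird.  Heterogeneity is summarised by Cochran's Q,
I^2 = max(0, (Q - df)/Q) * 100%, and Q-profile confidence intervals for
tau^2 (transformed to I^2 via the typical within-study variance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "StudyEffect",
    "MetaResult",
    "smd_from_summary",
    "aggregate_summaries",
    "dichotomize_by_cutoff",
    "pool_random_effects",
]


@dataclass(frozen=True)
class StudyEffect:
    label: str
    d: float
    n1: int
    n2: int
    var_d: float

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("group sizes must be >= 2")
        if self.var_d <= 0:
            raise ValueError("sampling variance must be positive")


@dataclass(frozen=True)
class MetaResult:
    pooled_d: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    q: float
    q_df: int
    i2: float
    i2_ci: tuple[float, float]
    tau2: float
    tau2_ci: tuple[float, float]
    weights: dict[str, float]
    tau2_method: str

    def as_dict(self) -> dict:
        out = {k: getattr(self, k) for k in (
            "pooled_d", "ci_low", "ci_high", "z", "p", "q", "q_df",
            "i2", "tau2", "tau2_method")}
        out["i2_ci"] = list(self.i2_ci)
        out["tau2_ci"] = list(self.tau2_ci)
        out["weights"] = self.weights
        return out


def smd_from_summary(
    label: str, m1: float, s1: float, n1: int, m2: float, s2: float, n2: int
) -> StudyEffect:
    """Cohen's d between two groups from their (M, SD, N) summaries."""
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    if sp2 == 0:
        raise ValueError("zero pooled SD: d undefined")
    d = (m1 - m2) / math.sqrt(sp2)
    var_d = (n1 + n2) / (n1 * n2) + d**2 / (2.0 * (n1 + n2))
    return StudyEffect(label, d, n1, n2, var_d)


def aggregate_summaries(
    summaries: Sequence[tuple[float, float, int]]
) -> tuple[float, float, int]:
    """Combine condition-level (mean, SD, n) into one exact group summary.

    Uses total sums and sums of squares, so aggregating sub-conditions and
    then computing an effect size is identical to computing it on the
    pooled sample.
    """
    if not summaries:
        raise ValueError("no summaries to aggregate")
    n_tot = sum(n for _, _, n in summaries)
    sum_x = sum(m * n for m, _, n in summaries)
    sum_x2 = sum((n - 1) * s**2 + n * m**2 for m, s, n in summaries)
    mean = sum_x / n_tot
    var = (sum_x2 - n_tot * mean**2) / (n_tot - 1)
    return mean, math.sqrt(max(var, 0.0)), n_tot


def dichotomize_by_cutoff(
    values: Sequence[float], cutoff: float
) -> tuple[np.ndarray, np.ndarray]:
    """Split feature scores into (>= cutoff, < cutoff) groups.

    Input-preparation helper for studies that report a continuous severity
    score rather than diagnosed groups; not an inference step.
    """
    arr = np.asarray(values, dtype=float)
    return arr[arr >= cutoff], arr[arr < cutoff]


def _dl_tau2(y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / v
    mu = (w * y).sum() / w.sum()
    q = float((w * (y - mu) ** 2).sum())
    df = len(y) - 1
    c = w.sum() - (w**2).sum() / w.sum()
    return max(0.0, (q - df) / c) if c > 0 else 0.0


def _reml_nll(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = (w * y).sum() / w.sum()
    return 0.5 * (
        np.log(v + tau2).sum()
        + math.log(w.sum())
        + float((w * (y - mu) ** 2).sum())
    )


def _reml_tau2(y: np.ndarray, v: np.ndarray) -> float:
    upper = max(10.0 * y.var() if len(y) > 1 else 1.0, 10.0 * float(v.max()), 1.0)
    res = optimize.minimize_scalar(
        _reml_nll, args=(y, v), bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x) if res.x > 1e-9 else 0.0


def _generalized_q(tau2: float, y: np.ndarray, v: np.ndarray) -> float:
    w = 1.0 / (v + tau2)
    mu = (w * y).sum() / w.sum()
    return float((w * (y - mu) ** 2).sum())


def _q_profile_tau2_ci(
    y: np.ndarray, v: np.ndarray, level: float = 0.95
) -> tuple[float, float]:
    """Q-profile confidence interval for tau^2 (monotone root search)."""
    df = len(y) - 1
    lo_target = stats.chi2.ppf(1 - (1 - level) / 2, df)  # Q large -> lower bound
    hi_target = stats.chi2.ppf((1 - level) / 2, df)

    def bound(target: float) -> float:
        f0 = _generalized_q(0.0, y, v) - target
        if f0 <= 0:
            return 0.0
        hi = 1.0
        while _generalized_q(hi, y, v) - target > 0 and hi < 1e6:
            hi *= 10.0
        return float(optimize.brentq(
            lambda t: _generalized_q(t, y, v) - target, 0.0, hi, xtol=1e-10
        ))

    return bound(lo_target), bound(hi_target)


def pool_random_effects(
    studies: Sequence[StudyEffect],
    tau2_method: str = "REML",
    *,
    level: float = 0.95,
) -> MetaResult:
    """Inverse-variance random-effects pooling of study effect sizes.

    A single study passes through unchanged with tau^2 = 0 and
    heterogeneity reported as zero (undefined-as-zero convention).
    Setting ``tau2_method="FE"`` forces tau^2 = 0 (fixed-effect pooling).
    """
    if len(studies) == 0:
        raise ValueError("need at least one study")
    y = np.array([s.d for s in studies], dtype=float)
    v = np.array([s.var_d for s in studies], dtype=float)
    k = len(studies)

    method = tau2_method.upper()
    if k == 1 or method == "FE":
        tau2 = 0.0
    elif method == "REML":
        tau2 = _reml_tau2(y, v)
    elif method in ("DL", "DERSIMONIAN-LAIRD"):
        tau2 = _dl_tau2(y, v)
    else:
        raise ValueError(f"unknown tau2 method {tau2_method!r}")

    w = 1.0 / (v + tau2)
    pooled = float((w * y).sum() / w.sum())
    se = math.sqrt(1.0 / w.sum())
    zcrit = stats.norm.ppf(1 - (1 - level) / 2)
    z = pooled / se
    p = 2.0 * stats.norm.sf(abs(z))

    # heterogeneity on fixed-effect weights
    wf = 1.0 / v
    mu_f = (wf * y).sum() / wf.sum()
    q = float((wf * (y - mu_f) ** 2).sum())
    q_df = k - 1
    i2 = max(0.0, (q - q_df) / q) * 100.0 if q > 0 and k > 1 else 0.0

    if k > 1:
        tau2_ci = _q_profile_tau2_ci(y, v, level)
        # typical within-study variance (Higgins-Thompson)
        s2_typ = q_df * wf.sum() / (wf.sum() ** 2 - (wf**2).sum())
        i2_ci = tuple(100.0 * t / (t + s2_typ) for t in tau2_ci)
    else:
        tau2_ci = (0.0, 0.0)
        i2_ci = (0.0, 0.0)

    weights = {s.label: float(wi / w.sum()) for s, wi in zip(studies, w)}
    return MetaResult(
        pooled_d=pooled, ci_low=pooled - zcrit * se, ci_high=pooled + zcrit * se,
        z=float(z), p=float(p), q=q, q_df=q_df, i2=float(i2),
        i2_ci=i2_ci, tau2=float(tau2), tau2_ci=tau2_ci,  # type: ignore[arg-type]
        weights=weights, tau2_method=method,
    )
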