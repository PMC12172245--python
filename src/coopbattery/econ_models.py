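"""Utility models for joint-payoff evaluation and per-subject fitting.

Each candidate model maps a payoff pair (x_self, x_other) to a feature
vector; a subject's ratings of the payoff grid are regressed on those
features by ordinary least squares.  Model evidence is approximated per
subject as -BIC/2 from the Gaussian likelihood at the OLS solution, which
puts all models on a common scale for the fixed- and random-effects model
comparison downstream.

The central model is the Fehr-Schmidt inequality-aversion utility

    U(x_s, x_o) = x_s - alpha * max(x_o - x_s, 0) - beta * max(x_s - x_o, 0)

where alpha weighs disadvantageous and beta advantageous inequality.
Because a rating scale is an (unknown) affine transform of utility, the
structural alpha and beta are recovered as ratios of regression
coefficients: alpha_hat = -b_disadvantageous / b_self.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PayoffPair",
    "ModelSpec",
    "SubjectFit",
    "fs_utility",
    "jpe_grid",
    "build_design",
    "fit_subject",
    "model_registry",
    "evidence_matrix",
]

GRID_LEVELS = tuple(range(-50, 51, 10))


@dataclass(frozen=True)
class PayoffPair:
    x_self: float
    x_other: float


def jpe_grid() -> pd.DataFrame:
    """The standard 11 x 11 payoff lattice, {-50..50 step 10}^2, 121 cells.

    Ordered row-major by (x_self, x_other); deterministic.
    """
    cells = [(s, o) for s in GRID_LEVELS for o in GRID_LEVELS]
    return pd.DataFrame(cells, columns=["x_self", "x_other"])


def fs_utility(x_self, x_other, alpha: float, beta: float):
    """Fehr-Schmidt utility; vectorised over payoff arrays."""
    x_self = np.asarray(x_self, dtype=float)
    x_other = np.asarray(x_other, dtype=float)
    out = (
        x_self
        - alpha * np.maximum(x_other - x_self, 0.0)
        - beta * np.maximum(x_self - x_other, 0.0)
    )
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class ModelSpec:
    """A candidate utility model: named feature map over payoff pairs."""

    name: str
    param_names: tuple[str, ...]
    features: Callable[[np.ndarray, np.ndarray], np.ndarray] = field(repr=False)

    @property
    def k(self) -> int:
        return len(self.param_names)


def _F(*cols):
    return np.column_stack(cols)


def _registry_entries() -> list[ModelSpec]:
    return [
        ModelSpec("selfish", ("x_self",), lambda s, o: _F(s)),
        ModelSpec("other_regarding", ("x_other",), lambda s, o: _F(o)),
        ModelSpec("joint_gain", ("joint",), lambda s, o: _F(s + o)),
        ModelSpec("total_inequality", ("abs_ineq",), lambda s, o: _F(np.abs(s - o))),
        ModelSpec(
            "inequality_joint_gain",
            ("abs_ineq", "joint"),
            lambda s, o: _F(np.abs(s - o), s + o),
        ),
        ModelSpec(
            "fehr_schmidt",
            ("x_self", "disadv_ineq", "adv_ineq"),
            lambda s, o: _F(s, np.maximum(o - s, 0.0), np.maximum(s - o, 0.0)),
        ),
        ModelSpec(
            "charness_rabin",
            ("x_self", "other_when_ahead", "other_when_behind"),
            lambda s, o: _F(s, o * (s >= o), o * (s < o)),
        ),
        ModelSpec("max_min", ("min_payoff",), lambda s, o: _F(np.minimum(s, o))),
        ModelSpec(
            "envy",
            ("x_self", "disadv_ineq"),
            lambda s, o: _F(s, np.maximum(o - s, 0.0)),
        ),
    ]


def model_registry(
    extra: Optional[Sequence[ModelSpec]] = None,
    replace: Optional[Sequence[ModelSpec]] = None,
) -> dict[str, ModelSpec]:
    """The candidate-model set: nine utility models keyed by name.

    ``replace`` swaps in a caller-supplied set entirely; ``extra`` appends.
    Duplicate names are rejected.
    """
    specs = list(replace) if replace is not None else _registry_entries()
    if extra:
        specs = specs + list(extra)
    names = [m.name for m in specs]
    if len(set(names)) != len(names):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValueError(f"duplicate model names: {dup}")
    return {m.name: m for m in specs}


def build_design(
    model: ModelSpec, grid: pd.DataFrame, add_intercept: bool = True
) -> np.ndarray:
    """Design matrix for a model over a payoff grid (intercept first).

    Raises on an empty grid and on rank deficiency, naming the model so
    degenerate sub-grids (e.g. the equal-payoff diagonal under an
    inequality model) fail loudly rather than silently.
    """
    if len(grid) == 0:
        raise ValueError("empty payoff grid")
    s = grid["x_self"].to_numpy(dtype=float)
    o = grid["x_other"].to_numpy(dtype=float)
    X = model.features(s, o).astype(float)
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient design for model '{model.name}' on this grid; "
            f"columns: intercept, {', '.join(model.param_names)}"
        )
    return X


@dataclass(frozen=True)
class SubjectFit:
    model: str
    intercept: float
    coefs: Mapping[str, float]
    sigma2: float
    r2: float
    n_obs: int
    k_params: int
    loglik: float
    log_evidence: float
    degenerate: bool = False
    alpha_hat: Optional[float] = None
    beta_hat: Optional[float] = None


def fit_subject(
    model: ModelSpec,
    grid: pd.DataFrame,
    ratings: np.ndarray,
    *,
    standardize: bool = True,
) -> SubjectFit:
    """OLS fit of one model to one subject's grid ratings.

    Ratings are z-scored per subject by default so evidences are
    comparable across subjects regardless of scale use; the Gaussian
    log-likelihood is evaluated at the MLE residual variance and the log
    evidence approximated as -BIC/2 with k = predictors + intercept + 1
    (residual variance).

    Constant ratings are not an error: the fit is flagged degenerate with
    zero slopes and R^2 = 0.

    For the Fehr-Schmidt model the structural inequality weights are
    exposed as coefficient ratios (invariant to the affine rating map):
    ``alpha_hat = -b_disadv / b_self``, ``beta_hat = -b_adv / b_self``.
    """
    y = np.asarray(ratings, dtype=float)
    if len(y) != len(grid):
        raise ValueError("ratings length does not match grid")
    X = build_design(model, grid)
    n, p = X.shape
    if n < p + 2:
        raise ValueError(f"need at least {p + 2} observations, got {n}")

    sd = float(np.std(y))
    degenerate = sd == 0.0
    if standardize and not degenerate:
        y = (y - y.mean()) / sd
    elif degenerate:
        y = y - y.mean()  # all zeros

    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 0.0 if tss == 0.0 else 1.0 - rss / tss
    sigma2 = max(rss / n, 1e-12)  # floor keeps the evidence finite
    loglik = -0.5 * n * (np.log(2 * np.pi * sigma2) + rss / (n * sigma2))
    k_total = p + 1
    bic = k_total * np.log(n) - 2.0 * loglik
    coefs = dict(zip(model.param_names, beta[1:]))

    alpha_hat = beta_hat = None
    if model.name == "fehr_schmidt" and not degenerate:
        b_self = coefs["x_self"]
        if b_self > 0:
            alpha_hat = -coefs["disadv_ineq"] / b_self
            beta_hat = -coefs["adv_ineq"] / b_self
    return SubjectFit(
        model=model.name,
        intercept=float(beta[0]),
        coefs={k: float(v) for k, v in coefs.items()},
        sigma2=sigma2,
        r2=float(r2),
        n_obs=n,
        k_params=k_total,
        loglik=float(loglik),
        log_evidence=float(-bic / 2.0),
        degenerate=degenerate,
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
    )


def evidence_matrix(
    responses: Mapping[str, tuple[pd.DataFrame, np.ndarray]],
    registry: Optional[Mapping[str, ModelSpec]] = None,
    *,
    standardize: bool = True,
) -> pd.DataFrame:
    """Subjects x models table of log evidences.

    ``responses`` maps subject id to (grid, ratings).  Row order follows
    the mapping; column order follows the registry.
    """
    registry = registry if registry is not None else model_registry()
    rows = {}
    for sid, (grid, ratings) in responses.items():
        rows[sid] = {
            name: fit_subject(spec, grid, ratings, standardize=standardize).log_evidence
            for name, spec in registry.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(registry))
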