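"""Synthetic cohorts of social-preference agents for the task battery.

Each simulated participant carries latent Fehr-Schmidt inequality weights
(alpha for disadvantageous, beta for advantageous inequality), a response
noise SD on the rating scales, and a softmax/logistic choice temperature.
All task behaviour is generated from those latents:

* SVO slider: softmax over the nine option utilities of each item.
* Dictator game: softmax over the 11 possible allocations of 10 euro.
* Ultimatum game: accept offer o with probability
  logistic(U(o, 10 - o) / temperature); rejection pays (0, 0), which
  carries no inequality penalty.
* Minimum acceptance: smallest offer with non-negative utility, plus
  rounded Gaussian noise.
* Fairness ratings: utility of each split mapped affinely onto the 1-9
  scale, plus noise, rounded and clamped.
* Joint payoff evaluation: utility over the 121-cell payoff grid mapped
  affinely onto the 1-8 scale (anchored at the grid's noiseless utility
  extremes, larger = better, i.e. already reverse-coded relative to raw
  instruments where 1 = very good), plus noise, rounded half-up, clamped.

Defaults emulate a two-group design of 35 patients and 50 controls with
identical social-preference distributions (the study-scale null) and a
group difference only in the dissociality trait score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .econ_models import fs_utility, jpe_grid
from .svo_items import SliderItem, default_items

__all__ = [
    "UtilityParams",
    "GroupSpec",
    "CohortConfig",
    "Participant",
    "generate_cohort",
    "simulate_svo_choices",
    "simulate_dg_allocation",
    "simulate_ug_decisions",
    "simulate_min_acceptance",
    "simulate_fairness_ratings",
    "simulate_jpe_ratings",
    "simulate_dissociality",
    "participants_frame",
    "trials_frame",
    "DEFAULT_CONFIG",
]

UG_OFFERS = tuple(range(1, 7))
FAIRNESS_OFFERS = tuple(range(0, 11))
JPE_RATING_MIN, JPE_RATING_MAX = 1, 8
FAIRNESS_RATING_MIN, FAIRNESS_RATING_MAX = 1, 9


@dataclass(frozen=True)
class UtilityParams:
    """Latent social-preference parameters of one agent."""

    alpha: float  # disadvantageous-inequality weight (>= 0 typical)
    beta: float   # advantageous-inequality weight
    noise_sd: float = 0.5   # rating/choice noise, response-scale units
    temperature: float = 1.0  # softmax/logistic temperature, utility units

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")


@dataclass(frozen=True)
class GroupSpec:
    """Latent-parameter distribution of one group (normal per parameter)."""

    label: str
    n: int
    alpha_mean: float = 0.8
    alpha_sd: float = 0.3
    beta_mean: float = 0.45
    beta_sd: float = 0.15
    noise_mean: float = 0.5
    noise_sd: float = 0.0
    temperature_mean: float = 1.0
    temperature_sd: float = 0.0
    dissociality_mean: float = 20.0
    dissociality_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"group {self.label}: n must be >= 1")
        for name in ("alpha_sd", "beta_sd", "noise_sd", "temperature_sd", "dissociality_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"group {self.label}: {name} must be >= 0")


@dataclass(frozen=True)
class CohortConfig:
    """Two-group cohort configuration; identical seeds give identical cohorts."""

    group_a: GroupSpec
    group_b: GroupSpec
    seed: int = 0
    include_secondary_svo: bool = True


DEFAULT_CONFIG = CohortConfig(
    group_a=GroupSpec(label="BPD", n=35, dissociality_mean=27.0, dissociality_sd=7.0),
    group_b=GroupSpec(label="HC", n=50, dissociality_mean=20.0, dissociality_sd=6.0),
    seed=0,
)


@dataclass(frozen=True)
class Participant:
    id: str
    group: str
    params: UtilityParams
    dissociality: int
    svo_choices: dict[int, int]
    dg_allocation: int
    ug_offers: tuple[int, ...]
    ug_rejected: tuple[int, ...]
    min_acceptance: int
    fairness_offers: tuple[int, ...]
    fairness_ratings: tuple[int, ...]
    jpe_grid: pd.DataFrame = field(repr=False)
    jpe_ratings: np.ndarray = field(repr=False)


def _round_half_up(x: np.ndarray) -> np.ndarray:
    return np.floor(x + 0.5)


def _softmax_choice(utilities: np.ndarray, temperature: float, rng: np.random.Generator) -> int:
    """0-based index drawn from softmax(U / temperature); argmax at tiny T."""
    u = np.asarray(utilities, dtype=float)
    z = (u - u.max()) / temperature
    # below ~1e-8 the softmax is numerically an argmax anyway
    w = np.exp(z)
    p = w / w.sum()
    return int(rng.choice(len(u), p=p))


def simulate_svo_choices(
    params: UtilityParams,
    items: Sequence[SliderItem],
    rng: Optional[np.random.Generator] = None,
) -> dict[int, int]:
    """Chosen option (1-based) per slider item via softmax over utilities."""
    rng = rng if rng is not None else np.random.default_rng(0)
    choices = {}
    for item in items:
        if len(item.options) != 9:
            raise ValueError(f"item {item.item_id} malformed: needs 9 options")
        s = np.array([opt[0] for opt in item.options], dtype=float)
        o = np.array([opt[1] for opt in item.options], dtype=float)
        u = fs_utility(s, o, params.alpha, params.beta)
        choices[item.item_id] = _softmax_choice(u, params.temperature, rng) + 1
    return choices


def simulate_dg_allocation(
    params: UtilityParams, rng: Optional[np.random.Generator] = None, pot: int = 10
) -> int:
    """Euro given to the other in a one-shot dictator game (0..pot)."""
    rng = rng if rng is not None else np.random.default_rng(0)
    give = np.arange(pot + 1, dtype=float)
    u = fs_utility(pot - give, give, params.alpha, params.beta)
    return int(_softmax_choice(u, params.temperature, rng))


def simulate_ug_decisions(
    params: UtilityParams,
    offers: Sequence[int] = UG_OFFERS,
    rng: Optional[np.random.Generator] = None,
    pot: int = 10,
) -> list[int]:
    """Per-offer rejection indicators (1 = rejected) for ultimatum offers.

    P(accept) = logistic(U_accept / temperature); the rejection outcome
    (0, 0) is equal for both parties, so its Fehr-Schmidt utility is 0.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    out = []
    for offer in offers:
        if not 0 <= offer <= pot:
            raise ValueError(f"offer {offer} outside 0..{pot}")
        u_accept = fs_utility(float(offer), float(pot - offer), params.alpha, params.beta)
        p_accept = float(expit(u_accept / params.temperature))
        out.append(int(rng.random() >= p_accept))
    return out


def simulate_min_acceptance(
    params: UtilityParams, rng: Optional[np.random.Generator] = None, pot: int = 10
) -> int:
    """Smallest acceptable offer: utility threshold plus rounded noise."""
    rng = rng if rng is not None else np.random.default_rng(0)
    offers = np.arange(pot + 1, dtype=float)
    u = fs_utility(offers, pot - offers, params.alpha, params.beta)
    acceptable = np.nonzero(u >= 0)[0]
    base = int(acceptable[0]) if len(acceptable) else pot
    noisy = base + rng.normal(0.0, params.noise_sd)
    return int(np.clip(_round_half_up(np.array([noisy]))[0], 0, pot))


def _affine_ratings(
    u: np.ndarray,
    lo: int,
    hi: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Map utilities affinely onto [lo, hi], add noise, round half-up, clamp.

    The map is anchored at the noiseless utility extremes of the stimulus
    set; a flat utility profile maps to the scale midpoint.
    """
    span = u.max() - u.min()
    if span == 0:
        mapped = np.full_like(u, (lo + hi) / 2.0)
    else:
        mapped = lo + (u - u.min()) / span * (hi - lo)
    noisy = mapped + rng.normal(0.0, noise_sd, size=len(u))
    return np.clip(_round_half_up(noisy), lo, hi).astype(int)


def simulate_fairness_ratings(
    params: UtilityParams,
    offers: Sequence[int] = FAIRNESS_OFFERS,
    rng: Optional[np.random.Generator] = None,
    pot: int = 10,
) -> list[int]:
    """Fairness ratings (1-9) of hypothetical splits, inverted-U in offer."""
    rng = rng if rng is not None else np.random.default_rng(0)
    o = np.asarray(offers, dtype=float)
    u = fs_utility(o, pot - o, params.alpha, params.beta)
    return _affine_ratings(
        u, FAIRNESS_RATING_MIN, FAIRNESS_RATING_MAX, params.noise_sd, rng
    ).tolist()


def simulate_jpe_ratings(
    params: UtilityParams,
    grid: Optional[pd.DataFrame] = None,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Analysis-ready joint-payoff ratings on the 1-8 scale (8 = best).

    Ratings are produced already reverse-coded relative to raw instruments
    that anchor 1 = very good, so larger ratings mean better evaluations
    and regression weights on utility features come out positive.
    """
    grid = grid if grid is not None else jpe_grid()
    if len(grid) == 0:
        raise ValueError("empty payoff grid")
    rng = rng if rng is not None else np.random.default_rng(0)
    s = grid["x_self"].to_numpy(dtype=float)
    o = grid["x_other"].to_numpy(dtype=float)
    u = np.asarray(fs_utility(s, o, params.alpha, params.beta))
    return _affine_ratings(u, JPE_RATING_MIN, JPE_RATING_MAX, params.noise_sd, rng)


def simulate_dissociality(
    mean: float, sd: float, rng: np.random.Generator, n_items: int = 12
) -> int:
    """Trait score as a sum of 12 Likert items (1-5 each, range 12-60)."""
    item_scores = rng.normal(mean / n_items, sd / np.sqrt(n_items), size=n_items)
    item_scores = np.clip(_round_half_up(item_scores), 1, 5)
    return int(item_scores.sum())


def _draw_params(spec: GroupSpec, rng: np.random.Generator) -> UtilityParams:
    alpha = max(0.0, rng.normal(spec.alpha_mean, spec.alpha_sd))
    beta = rng.normal(spec.beta_mean, spec.beta_sd)
    noise = max(0.0, rng.normal(spec.noise_mean, spec.noise_sd))
    temp = max(1e-3, rng.normal(spec.temperature_mean, spec.temperature_sd))
    return UtilityParams(alpha=alpha, beta=beta, noise_sd=noise, temperature=temp)


def generate_cohort(config: CohortConfig = DEFAULT_CONFIG) -> list[Participant]:
    """Generate the full two-group cohort with every task record populated."""
    rng = np.random.default_rng(config.seed)
    items = default_items()
    if not config.include_secondary_svo:
        items = [it for it in items if it.role == "primary"]
    grid = jpe_grid()
    cohort: list[Participant] = []
    pid = 0
    for spec in (config.group_a, config.group_b):
        for _ in range(spec.n):
            pid += 1
            params = _draw_params(spec, rng)
            cohort.append(
                Participant(
                    id=f"p{pid:03d}",
                    group=spec.label,
                    params=params,
                    dissociality=simulate_dissociality(
                        spec.dissociality_mean, spec.dissociality_sd, rng
                    ),
                    svo_choices=simulate_svo_choices(params, items, rng),
                    dg_allocation=simulate_dg_allocation(params, rng),
                    ug_offers=UG_OFFERS,
                    ug_rejected=tuple(simulate_ug_decisions(params, UG_OFFERS, rng)),
                    min_acceptance=simulate_min_acceptance(params, rng),
                    fairness_offers=FAIRNESS_OFFERS,
                    fairness_ratings=tuple(
                        simulate_fairness_ratings(params, FAIRNESS_OFFERS, rng)
                    ),
                    jpe_grid=grid,
                    jpe_ratings=simulate_jpe_ratings(params, grid, rng),
                )
            )
    return cohort


def participants_frame(cohort: Sequence[Participant]) -> pd.DataFrame:
    """Wide per-participant table: latents, trait score, scalar task outcomes."""
    rows = []
    for p in cohort:
        rows.append({
            "participant_id": p.id,
            "group": p.group,
            "alpha": p.params.alpha,
            "beta": p.params.beta,
            "noise_sd": p.params.noise_sd,
            "temperature": p.params.temperature,
            "dissociality": p.dissociality,
            "dg_allocation": p.dg_allocation,
            "min_acceptance": p.min_acceptance,
            "ug_rejection_rate": float(np.mean(p.ug_rejected)) * 100.0,
        })
    return pd.DataFrame(rows)


def trials_frame(cohort: Sequence[Participant]) -> pd.DataFrame:
    """Long-format trials table covering every task, one row per response."""
    rows = []
    for p in cohort:
        base = {"participant_id": p.id, "group": p.group, "dissociality": p.dissociality}
        for i, (item_id, choice) in enumerate(sorted(p.svo_choices.items())):
            rows.append({**base, "task": "svo", "trial_index": i,
                         "item_id": item_id, "option_index": choice})
        rows.append({**base, "task": "dg", "trial_index": 0, "allocation": p.dg_allocation})
        for i, (offer, rej) in enumerate(zip(p.ug_offers, p.ug_rejected)):
            rows.append({**base, "task": "ug", "trial_index": i,
                         "offer": offer, "rejected": rej})
        rows.append({**base, "task": "minacc", "trial_index": 0,
                     "min_acceptance": p.min_acceptance})
        for i, (offer, rating) in enumerate(zip(p.fairness_offers, p.fairness_ratings)):
            rows.append({**base, "task": "fairness", "trial_index": i,
                         "offer": offer, "rating": rating})
        for i, ((_, cell), rating) in enumerate(zip(p.jpe_grid.iterrows(), p.jpe_ratings)):
            rows.append({**base, "task": "jpe", "trial_index": i,
                         "x_self": int(cell["x_self"]), "x_other": int(cell["x_other"]),
                         "rating": int(rating)})
    return pd.DataFrame(rows)
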