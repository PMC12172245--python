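"""Scoring of the SVO Slider Measure.

The continuous social-value-orientation angle is computed from the six
primary items: average the chosen (self, other) allocations, subtract the
instrument's 50-point origin from each coordinate, and take the arctangent
of other over self.  Larger angles mean more weight on the other person's
payoff.  Angles map onto four categories (altruistic, prosocial,
individualistic, competitive) at the instrument's published boundaries.

The nine secondary items locate a prosocial respondent between two ideal
motivations: minimising payoff inequality versus maximising the joint
payoff.  The prosocial-motivation index is the normalised Euclidean
distance of the chosen allocations to the inequality-averse ideals,
so 0 = perfectly inequality-averse and 1 = perfectly joint-gain-maximising.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .svo_items import SliderItem, primary_items, secondary_items

__all__ = [
    "SvoResult",
    "svo_angle",
    "svo_category",
    "prosocial_motivation_index",
    "check_consistency",
    "score_participant",
    "item_ideals",
    "ALTRUISTIC_BOUNDARY",
    "PROSOCIAL_BOUNDARY",
    "COMPETITIVE_BOUNDARY",
]

# Published category boundaries of the slider instrument, in degrees.
ALTRUISTIC_BOUNDARY = 57.15
PROSOCIAL_BOUNDARY = 22.45
COMPETITIVE_BOUNDARY = -12.04


@dataclass(frozen=True)
class SvoResult:
    angle: float
    category: str
    pm_index: Optional[float]
    pm_category: Optional[str]
    consistent_primary: bool
    consistent_secondary: Optional[bool]


def _mean_allocation(
    choices: Mapping[int, int], items: Sequence[SliderItem]
) -> tuple[float, float]:
    selfs, others = [], []
    for item in items:
        if item.item_id not in choices:
            raise ValueError(f"missing choice for item {item.item_id}")
        s, o = item.allocation(choices[item.item_id])
        selfs.append(s)
        others.append(o)
    return sum(selfs) / len(selfs), sum(others) / len(others)


def svo_angle(
    choices: Mapping[int, int], items: Optional[Sequence[SliderItem]] = None
) -> float:
    """SVO angle in degrees from the six primary-item choices.

    angle = atan((mean_other - 50) / (mean_self - 50)).

    Raises
    ------
    ValueError
        If a primary item is unanswered, or mean self-allocation equals 50
        (degenerate denominator; such response sets cannot be scored on the
        angular scale -- inspect the raw choices instead).
    """
    items = list(items) if items is not None else primary_items()
    items = [it for it in items if it.role == "primary"]
    if len(items) != 6:
        raise ValueError(f"expected 6 primary items, got {len(items)}")
    mean_self, mean_other = _mean_allocation(choices, items)
    if math.isclose(mean_self, 50.0):
        raise ValueError(
            "mean self-allocation equals 50: angle undefined "
            "(denominator zero); the response set cannot be scored"
        )
    return math.degrees(math.atan2(mean_other - 50.0, mean_self - 50.0))


def svo_category(angle: float) -> str:
    """Four-way orientation category for an SVO angle.

    Boundaries are closed on the prosocial side: 57.15 is prosocial,
    22.45 is prosocial, -12.04 is competitive.
    """
    if not math.isfinite(angle):
        raise ValueError("angle must be finite")
    if angle > ALTRUISTIC_BOUNDARY:
        return "altruistic"
    if angle >= PROSOCIAL_BOUNDARY:
        return "prosocial"
    if angle > COMPETITIVE_BOUNDARY:
        return "individualistic"
    return "competitive"


def item_ideals(item: SliderItem) -> tuple[int, int]:
    """1-based option indices of an item's two prosocial ideal points.

    Returns (inequality-averse ideal, joint-gain ideal).  The
    inequality-averse ideal minimises |self - other| (ties broken toward
    the higher joint payoff); the joint-gain ideal maximises self + other
    (ties broken toward lower inequality).
    """
    best_ia, best_jg = None, None
    for idx, (s, o) in enumerate(item.options, start=1):
        ineq, joint = abs(s - o), s + o
        if best_ia is None or (ineq, -joint) < (best_ia[0], -best_ia[1]):
            best_ia = (ineq, joint, idx)
        if best_jg is None or (-joint, ineq) < (-best_jg[0], best_jg[1]):
            best_jg = (joint, ineq, idx)
    assert best_ia is not None and best_jg is not None
    return best_ia[2], best_jg[2]


def prosocial_motivation_index(
    choices: Mapping[int, int], items: Optional[Sequence[SliderItem]] = None
) -> tuple[float, str]:
    """Prosocial-motivation index over the nine secondary items.

    index = sum(dist to inequality-averse ideal)
            / [sum(dist to IA ideal) + sum(dist to joint-gain ideal)]

    with Euclidean distances in (self, other) payoff space.  Index < 0.5
    (ties included) is categorised inequality-averse, otherwise
    joint-gain-maximising.
    """
    items = list(items) if items is not None else secondary_items()
    items = [it for it in items if it.role == "secondary"]
    if len(items) != 9:
        raise ValueError(f"expected 9 secondary items, got {len(items)}")
    d_ia = d_jg = 0.0
    for item in items:
        if item.item_id not in choices:
            raise ValueError(f"missing choice for secondary item {item.item_id}")
        s, o = item.allocation(choices[item.item_id])
        ia_idx, jg_idx = item_ideals(item)
        ia_s, ia_o = item.allocation(ia_idx)
        jg_s, jg_o = item.allocation(jg_idx)
        d_ia += math.hypot(s - ia_s, o - ia_o)
        d_jg += math.hypot(s - jg_s, o - jg_o)
    total = d_ia + d_jg
    index = 0.5 if total == 0 else d_ia / total
    category = "inequality_averse" if index <= 0.5 else "joint_gain_maximizing"
    return index, category


def check_consistency(
    choices: Mapping[int, int],
    items: Optional[Sequence[SliderItem]] = None,
    *,
    prosocial_categories: Iterable[str] = ("prosocial",),
    max_offset: int = 1,
) -> tuple[bool, Optional[bool]]:
    """Screen for consistently prosocial responding.

    Primary flag: the angle-based category falls in ``prosocial_categories``.
    Secondary flag: on every secondary item the chosen option lies within
    ``max_offset`` option positions of one of the item's two prosocial
    ideals (inequality-averse or joint-gain); ``None`` if the secondary
    block is absent.  Downstream prosocial-motivation comparisons keep only
    participants with both flags true, mirroring the reduced sample sizes
    such screens produce.
    """
    all_items = list(items) if items is not None else (primary_items() + secondary_items())
    prim = [it for it in all_items if it.role == "primary"]
    sec = [it for it in all_items if it.role == "secondary"]

    consistent_primary = svo_category(svo_angle(choices, prim)) in set(prosocial_categories)

    if not sec or any(it.item_id not in choices for it in sec):
        return consistent_primary, None
    consistent_secondary = True
    for item in sec:
        ia_idx, jg_idx = item_ideals(item)
        chosen = choices[item.item_id]
        if min(abs(chosen - ia_idx), abs(chosen - jg_idx)) > max_offset:
            consistent_secondary = False
            break
    return consistent_primary, consistent_secondary


def score_participant(
    choices: Mapping[int, int], items: Optional[Sequence[SliderItem]] = None
) -> SvoResult:
    """Full slider scoring: angle, category, PM index, consistency flags."""
    all_items = list(items) if items is not None else (primary_items() + secondary_items())
    prim = [it for it in all_items if it.role == "primary"]
    sec = [it for it in all_items if it.role == "secondary"]
    angle = svo_angle(choices, prim)
    category = svo_category(angle)
    has_secondary = bool(sec) and all(it.item_id in choices for it in sec)
    if has_secondary:
        pm_index, pm_category = prosocial_motivation_index(choices, sec)
    else:
        pm_index, pm_category = None, None
    cons_p, cons_s = check_consistency(choices, all_items)
    return SvoResult(angle, category, pm_index, pm_category, cons_p, cons_s)
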