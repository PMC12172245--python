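"""Payoff menus of the SVO Slider Measure.

The slider instrument presents 15 items; on each, the respondent picks one
of nine prespecified (self, other) point allocations.  The six *primary*
items span the angular space used for the continuous social-value
orientation score; the nine *secondary* items lie along the prosocial edge
and separate inequality aversion from joint-gain maximisation.

The menus below are the published instrument's allocation tables
(points, 0-100 range).  Two of them are independently checkable against
task descriptions in the literature: primary item 6 runs from (100, 50)
to (85, 85), secondary item 9 from (100, 70) to (50, 100) with option 4
at (81, 81).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

__all__ = ["SliderItem", "default_items", "primary_items", "secondary_items"]


@dataclass(frozen=True)
class SliderItem:
    """One slider item: nine (self, other) payoff options.

    Option indices are 1-based throughout, matching the instrument.
    """

    item_id: int
    role: Literal["primary", "secondary"]
    options: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(self.options) != 9:
            raise ValueError(
                f"item {self.item_id}: expected 9 options, got {len(self.options)}"
            )
        for s, o in self.options:
            if not (0 <= s <= 100 and 0 <= o <= 100):
                raise ValueError(
                    f"item {self.item_id}: payoff ({s}, {o}) outside 0-100"
                )

    def allocation(self, option_index: int) -> tuple[int, int]:
        """Return the (self, other) allocation for a 1-based option index."""
        if not 1 <= option_index <= 9:
            raise ValueError(f"option index {option_index} not in 1..9")
        return self.options[option_index - 1]


def _item(item_id: int, role: str, selfs: Sequence[int], others: Sequence[int]) -> SliderItem:
    return SliderItem(item_id, role, tuple(zip(selfs, others)))  # type: ignore[arg-type]


_PRIMARY = [
    _item(1, "primary", (85, 85, 85, 85, 85, 85, 85, 85, 85),
          (85, 76, 68, 59, 50, 41, 33, 24, 15)),
    _item(2, "primary", (85, 87, 89, 91, 93, 94, 96, 98, 100),
          (15, 19, 24, 28, 33, 37, 41, 46, 50)),
    _item(3, "primary", (50, 54, 59, 63, 68, 72, 76, 81, 85),
          (100, 98, 96, 94, 93, 91, 89, 87, 85)),
    _item(4, "primary", (50, 54, 59, 63, 68, 72, 76, 81, 85),
          (100, 89, 79, 68, 58, 47, 36, 26, 15)),
    _item(5, "primary", (100, 94, 88, 81, 75, 69, 63, 56, 50),
          (50, 56, 63, 69, 75, 81, 88, 94, 100)),
    _item(6, "primary", (100, 98, 96, 94, 93, 91, 89, 87, 85),
          (50, 54, 59, 63, 68, 72, 76, 81, 85)),
]

_SECONDARY = [
    _item(7, "secondary", (100, 96, 93, 89, 85, 81, 78, 74, 70),
          (50, 56, 63, 69, 75, 81, 88, 94, 100)),
    _item(8, "secondary", (90, 91, 93, 94, 95, 96, 98, 99, 100),
          (100, 99, 98, 96, 95, 94, 93, 91, 90)),
    _item(9, "secondary", (100, 94, 88, 81, 75, 69, 63, 56, 50),
          (70, 74, 78, 81, 85, 89, 93, 96, 100)),
    _item(10, "secondary", (100, 99, 98, 96, 95, 94, 93, 91, 90),
          (70, 74, 78, 81, 85, 89, 93, 96, 100)),
    _item(11, "secondary", (70, 74, 78, 81, 85, 89, 93, 96, 100),
          (100, 96, 93, 89, 85, 81, 78, 74, 70)),
    _item(12, "secondary", (50, 56, 63, 69, 75, 81, 88, 94, 100),
          (100, 99, 98, 96, 95, 94, 93, 91, 90)),
    _item(13, "secondary", (50, 56, 63, 69, 75, 81, 88, 94, 100),
          (100, 94, 88, 81, 75, 69, 63, 56, 50)),
    _item(14, "secondary", (100, 96, 93, 89, 85, 81, 78, 74, 70),
          (90, 91, 93, 94, 95, 96, 98, 99, 100)),
    _item(15, "secondary", (90, 91, 93, 94, 95, 96, 98, 99, 100),
          (50, 56, 63, 69, 75, 81, 88, 94, 100)),
]


def primary_items() -> list[SliderItem]:
    """The six primary slider items (general SVO score)."""
    return list(_PRIMARY)


def secondary_items() -> list[SliderItem]:
    """The nine secondary slider items (prosocial-motivation score)."""
    return list(_SECONDARY)


def default_items() -> list[SliderItem]:
    """All 15 items of the slider instrument, in published order."""
    return list(_PRIMARY) + list(_SECONDARY)
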