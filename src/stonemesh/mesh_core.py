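"""Mesh-model arithmetic for the amount-of-stone index Q.

The mesh model treats lithotripsy as crack-making: a calculus is overlaid
with a 5-mm grid in x, y and z, and Q counts the theoretical minimum number
of 5 mm x 5 mm cross-sections ("cracks") needed to reduce the stone to
target-size units.  Q is a dimensionless count reported in "u".

Per CT level the stone is measured orthogonally (x = maximum in-plane
diameter, y = maximum diameter perpendicular to x), each millimetre value is
graded onto the 5-mm grid (half-open bins, an exact bin edge rounds up), and

* within a level the cracks parallel to the slice axis number
  ``x*(y-1) + y*(x-1)``;
* between two adjacent levels the cracks perpendicular to the slice axis
  number ``min(x_up, x_lo) * min(y_up, y_lo)`` (the shared column of units).

Q for a stone is the alternating sum n1 + n12 + n2 + n23 + ...; for multiple
stones the per-stone values add.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

__all__ = [
    "GridSpec",
    "UnitizedLevel",
    "QResult",
    "unitize",
    "unitize_level",
    "within_level_cracks",
    "between_level_cracks",
    "stone_q",
    "total_q",
    "average_directions",
]


@dataclass(frozen=True)
class GridSpec:
    """Mesh geometry: target fragment size and slice-sampling step, in mm.

    ``target_size`` is the edge of the target stone unit (5 mm for an 18F
    percutaneous channel; smaller channels need smaller targets).
    ``level_step`` is the z-distance between sampled CT levels (4.9 mm, i.e.
    every 7th slice at the 0.7-mm reference slice distance).
    """

    target_size: float = 5.0
    level_step: float = 4.9

    def __post_init__(self) -> None:
        if not (self.target_size > 0):
            raise ValueError("target_size must be positive")
        if not (self.level_step > 0):
            raise ValueError("level_step must be positive")
        if self.level_step > self.target_size:
            raise ValueError(
                "level_step must not exceed target_size "
                f"({self.level_step} > {self.target_size})"
            )


@dataclass(frozen=True)
class UnitizedLevel:
    """One level's graded (x, y) pair: counts of 5-mm grid cells per axis."""

    x_units: int
    y_units: int

    def __post_init__(self) -> None:
        if self.x_units < 1 or self.y_units < 1:
            raise ValueError("unit grades must be >= 1")


@dataclass(frozen=True)
class QResult:
    """Amount of stone in u, split into within- and between-level cracks.

    For a single scan direction ``q_total == within_level + between_level``
    holds exactly; after averaging top-down and bottom-up runs q_total may be
    half-integral.
    """

    q_total: float
    within_level: int
    between_level: int


def unitize(measurement_mm: float, target_size: float = 5.0) -> int:
    """Grade a millimetre measurement onto the target-size grid.

    Half-open binning with the bin edge rounding up: on a 5-mm grid,
    (0, 5) -> 1, [5, 10) -> 2, [10, 15) -> 3, ...  Equivalent to
    ``floor(mm / target) + 1``.

    Raises
    ------
    ValueError
        If the measurement or target size is not strictly positive.
    """
    if not (measurement_mm > 0):
        raise ValueError(f"measurement must be positive, got {measurement_mm}")
    if not (target_size > 0):
        raise ValueError(f"target_size must be positive, got {target_size}")
    return int(math.floor(measurement_mm / target_size)) + 1


def unitize_level(x_mm: float, y_mm: float, target_size: float = 5.0) -> UnitizedLevel:
    """Grade an orthogonal (x, y) millimetre pair into a :class:`UnitizedLevel`."""
    return UnitizedLevel(unitize(x_mm, target_size), unitize(y_mm, target_size))


def within_level_cracks(level: UnitizedLevel) -> int:
    """Cracks parallel to the slice axis on one level: ``x(y-1) + y(x-1)``.

    A level already at target size, (1, 1), needs none.
    """
    x, y = level.x_units, level.y_units
    return x * (y - 1) + y * (x - 1)


def between_level_cracks(upper: UnitizedLevel, lower: UnitizedLevel) -> int:
    """Cracks perpendicular to the slice axis between two adjacent levels.

    Counted as the product of the per-axis minima of the two graded pairs —
    the cross-section both levels share.
    """
    return min(upper.x_units, lower.x_units) * min(upper.y_units, lower.y_units)


def stone_q(levels: Sequence[UnitizedLevel]) -> QResult:
    """Amount of stone for one calculus from its ordered graded levels.

    ``Q = n_1 + n_{1-2} + n_2 + n_{2-3} + ... `` — the sum of every level's
    within-level cracks plus the between-level cracks of each adjacent pair.
    """
    if len(levels) == 0:
        raise ValueError("stone_q requires at least one level")
    within = sum(within_level_cracks(lv) for lv in levels)
    between = sum(
        between_level_cracks(a, b) for a, b in zip(levels[:-1], levels[1:])
    )
    return QResult(q_total=float(within + between), within_level=within,
                   between_level=between)


def total_q(per_stone: Iterable[QResult | float]) -> float:
    """Sum Q over multiple stones (each stone graded and counted separately)."""
    total = 0.0
    for item in per_stone:
        total += item.q_total if isinstance(item, QResult) else float(item)
    return total


def average_directions(q_topdown: QResult | float, q_bottomup: QResult | float) -> float:
    """Average the top-down and bottom-up runs of the same stone set.

    The mean may be half-integral; no re-rounding is applied.
    """
    a = q_topdown.q_total if isinstance(q_topdown, QResult) else float(q_topdown)
    b = q_bottomup.q_total if isinstance(q_bottomup, QResult) else float(q_bottomup)
    return (a + b) / 2.0
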