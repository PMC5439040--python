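"""Age-interval arithmetic shared by every stage of the pipeline.

All demographic quantities are held on a fixed grid of 5-year age groups
(0--4, 5--9, ..., 95--99, 100+).  Disease rates additionally use the coarse
adult grouping of the source burden-of-disease study (30--44, 45--59,
60--69, 70--79, 80+).  Intervals are closed on both ends; a ``None`` upper
bound marks an open-ended terminal group.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "AgeInterval",
    "fine_intervals",
    "adult_fine_intervals",
    "coarse_intervals",
    "group_midpoint",
    "interval_from_bounds",
]


@dataclass(frozen=True, order=True)
class AgeInterval:
    """A closed age interval ``[lower, upper]`` in whole years.

    ``upper is None`` denotes an open-ended group such as 80+ or 100+.
    """

    lower: int
    upper: int | None = None

    def __post_init__(self) -> None:
        if self.lower < 0:
            raise ValueError(f"age lower bound must be >= 0, got {self.lower}")
        if self.upper is not None and self.upper < self.lower:
            raise ValueError(f"invalid interval [{self.lower}, {self.upper}]")

    @property
    def is_open(self) -> bool:
        return self.upper is None

    @property
    def label(self) -> str:
        return f"{self.lower}+" if self.is_open else f"{self.lower}-{self.upper}"

    def contains(self, age: float) -> bool:
        if self.is_open:
            return age >= self.lower
        return self.lower <= age <= self.upper

    def distance(self, age: float) -> float:
        """Distance from ``age`` to the nearest point of the interval (0 if inside)."""
        if age < self.lower:
            return self.lower - age
        if self.upper is not None and age > self.upper:
            return age - self.upper
        return 0.0


def group_midpoint(interval: AgeInterval, open_offset: float = 5.0) -> float:
    """Representative age of a group, used as the regression abscissa.

    Closed intervals use the arithmetic midpoint ((lo+hi)/2).  Open-ended
    groups are closed conventionally ``open_offset`` years above the lower
    bound (80+ -> 85), except the terminal 100+ group which is pinned at
    100 so the oldest stratum is never extrapolated past the grid.
    """
    if interval.is_open:
        if interval.lower >= 100:
            return float(interval.lower)
        return interval.lower + open_offset
    return (interval.lower + interval.upper) / 2.0


def fine_intervals() -> tuple[AgeInterval, ...]:
    """The full population grid: 0--4 through 95--99 plus 100+."""
    closed = tuple(AgeInterval(lo, lo + 4) for lo in range(0, 100, 5))
    return closed + (AgeInterval(100, None),)


def adult_fine_intervals() -> tuple[AgeInterval, ...]:
    """The adult burden grid: 30--34 through 95--99 plus 100+."""
    return tuple(iv for iv in fine_intervals() if iv.lower >= 30)


def coarse_intervals() -> tuple[AgeInterval, ...]:
    """The coarse adult strata of the source burden-of-disease inputs."""
    return (
        AgeInterval(30, 44),
        AgeInterval(45, 59),
        AgeInterval(60, 69),
        AgeInterval(70, 79),
        AgeInterval(80, None),
    )


def interval_from_bounds(age_lo: int, age_hi: int | None) -> AgeInterval:
    """Build an interval from CSV-style bounds (``age_hi`` None/NaN = open)."""
    return AgeInterval(int(age_lo), None if age_hi is None else int(age_hi))
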