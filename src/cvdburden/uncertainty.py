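"""Sensitivity scenarios and Monte Carlo confidence intervals.

Two sources of uncertainty are propagated onto a projected DALY total:

* **population-estimate error** ``e`` — the projected population may be off
  by up to ±``pop_error`` (2% or 5% in the standard grid), acting as a
  symmetric multiplicative factor ``(1 + e)``;
* **death undercounting** ``u`` — registered CVD deaths are a ``(1 - u)``
  fraction of true deaths (5%, 10% or 20% in the standard grid), so the
  recorded burden scales up by ``1 / (1 - u)``.  Undercounting is one-sided:
  it can only raise the true burden above the recorded value.

``scenario_bounds`` propagates the two ranges deterministically;
``monte_carlo_ci`` samples ``e ~ Uniform(-pop_error, +pop_error)`` and
``u ~ Uniform(0, undercount)`` and reports empirical percentiles.  Uniform
sampling is the maximum-entropy choice given only the ranges, and is
recorded in the interval metadata.  Monte Carlo intervals always lie inside
the corresponding deterministic bounds, which are the support of the
sampled distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScenarioSpec",
    "UncertaintyInterval",
    "STANDARD_GRID",
    "undercount_correct",
    "scenario_bounds",
    "scenario_grid",
    "monte_carlo_ci",
]

DEFAULT_DRAWS = 100_000
DEFAULT_SEED = 20050101


@dataclass(frozen=True)
class ScenarioSpec:
    """One sensitivity cell: population-error fraction × undercount fraction."""

    pop_error: float
    undercount: float

    def __post_init__(self) -> None:
        if not 0 <= self.pop_error < 1:
            raise ValueError(f"pop_error must lie in [0, 1), got {self.pop_error}")
        if not 0 <= self.undercount < 1:
            raise ValueError(f"undercount must lie in [0, 1), got {self.undercount}")


#: the standard six-cell grid, ordered error-major:
#: (2%, 5%), (2%, 10%), (2%, 20%), (5%, 5%), (5%, 10%), (5%, 20%)
STANDARD_GRID: tuple[ScenarioSpec, ...] = tuple(
    ScenarioSpec(e, u) for e in (0.02, 0.05) for u in (0.05, 0.10, 0.20)
)


@dataclass(frozen=True)
class UncertaintyInterval:
    """A point estimate with a lower/upper uncertainty range."""

    point: float
    lower: float
    upper: float
    level: float = 95.0
    method: str = "bounds"
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.lower > self.upper:
            raise ValueError(f"lower {self.lower} exceeds upper {self.upper}")
        if not 0 < self.level < 100:
            raise ValueError(f"level must lie in (0, 100), got {self.level}")

    @property
    def width(self) -> float:
        return self.upper - self.lower


def undercount_correct(daly: float, u: float) -> float:
    """Scale a recorded burden up for death undercounting: ``daly / (1 - u)``."""
    if not 0 <= u < 1:
        raise ValueError(f"undercount fraction must lie in [0, 1), got {u}")
    return daly / (1.0 - u)


def scenario_bounds(point: float, spec: ScenarioSpec) -> UncertaintyInterval:
    """Deterministic interval propagation of one sensitivity cell.

    Lower bound: population overestimated by the full error and no
    undercounting — ``point * (1 - pop_error)``.  Upper bound: population
    underestimated and deaths undercounted at the full rate —
    ``point * (1 + pop_error) / (1 - undercount)``.
    """
    if point < 0:
        raise ValueError(f"point estimate must be non-negative, got {point}")
    lower = point * (1.0 - spec.pop_error)
    upper = undercount_correct(point * (1.0 + spec.pop_error), spec.undercount)
    return UncertaintyInterval(point=point, lower=lower, upper=upper, method="bounds")


def scenario_grid(
    point: float,
    specs: tuple[ScenarioSpec, ...] = STANDARD_GRID,
) -> list[tuple[ScenarioSpec, UncertaintyInterval]]:
    """Deterministic bounds for every cell of a sensitivity grid, in order."""
    return [(spec, scenario_bounds(point, spec)) for spec in specs]


def monte_carlo_ci(
    point: float,
    spec: ScenarioSpec,
    draws: int = DEFAULT_DRAWS,
    level: float = 95.0,
    seed: int = DEFAULT_SEED,
) -> UncertaintyInterval:
    """Percentile Monte Carlo interval for one sensitivity cell.

    Samples ``draws`` realizations of ``point * (1 + e) / (1 - u)`` with
    ``e ~ U(-pop_error, pop_error)`` and ``u ~ U(0, undercount)`` and
    returns the central ``level``% empirical percentile interval.
    Deterministic given ``seed``.
    """
    if draws < 100:
        raise ValueError(f"draws must be >= 100, got {draws}")
    if not 0 < level < 100:
        raise ValueError(f"level must lie in (0, 100), got {level}")
    if point < 0:
        raise ValueError(f"point estimate must be non-negative, got {point}")
    rng = np.random.default_rng(seed)
    e = rng.uniform(-spec.pop_error, spec.pop_error, size=draws)
    u = rng.uniform(0.0, spec.undercount, size=draws)
    samples = point * (1.0 + e) / (1.0 - u)
    lo, hi = np.percentile(samples, [(100.0 - level) / 2.0, (100.0 + level) / 2.0])
    return UncertaintyInterval(
        point=point,
        lower=float(lo),
        upper=float(hi),
        level=level,
        method="monte_carlo",
        seed=seed,
    )
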