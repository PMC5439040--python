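"""Cohort-component population projection in 5-year steps.

Each step ages every cohort with its survivorship ratio, adds births from
the age-specific fertility schedule (scaled each period to a scenario's
total-fertility-rate target), and assumes zero migration.  Five named TFR
scenarios — medium, high, low, constant and instant replacement — carry the
2015-revision fertility trajectories for Iran over 2000--2025.

A pyramid labelled year ``Y`` describes mid-year ``Y``; the step from ``Y``
to ``Y+5`` uses the TFR of the period labelled ``"Y–Y+5"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .synthetic import (
    PopulationPyramid,
    MortalitySchedule,
    FertilitySchedule,
    REPRODUCTIVE_LOWER,
)

__all__ = [
    "ScenarioTFRPath",
    "PopulationSeries",
    "PyramidSummary",
    "SCENARIO_NAMES",
    "scenario_path",
    "scale_to_tfr",
    "project_step",
    "project_series",
    "summarize",
    "interpolate_years",
]

PERIODS = ("2000–2005", "2005–2010", "2010–2015", "2015–2020", "2020–2025")

# Scenario TFR trajectories (children per woman), 2015-revision projections
# for Iran: one value per 5-year period of PERIODS.
_TFR_TABLE = {
    "medium": (1.96, 1.77, 1.59, 1.45, 1.36),
    "high": (1.96, 1.77, 1.84, 1.85, 1.86),
    "low": (1.96, 1.77, 1.34, 1.05, 0.86),
    "constant": (1.96, 1.77, 1.77, 1.77, 1.77),
    "instant_replacement": (2.1, 2.1, 2.1, 2.1, 2.1),
}

SCENARIO_NAMES = tuple(_TFR_TABLE)

_ALIASES = {"instant": "instant_replacement"}


def _norm_period(label: str) -> str:
    return label.replace("-", "–")


@dataclass(frozen=True)
class ScenarioTFRPath:
    """A named total-fertility-rate trajectory by 5-year period."""

    name: str
    tfr_by_period: dict[str, float]

    def __post_init__(self) -> None:
        for period, tfr in self.tfr_by_period.items():
            if tfr <= 0:
                raise ValueError(f"TFR must be positive ({period}: {tfr})")

    def tfr_for(self, period: str) -> float:
        key = _norm_period(period)
        if key not in self.tfr_by_period:
            raise KeyError(
                f"period {period!r} missing from scenario {self.name!r} "
                f"(has {sorted(self.tfr_by_period)})"
            )
        return self.tfr_by_period[key]


def scenario_path(name: str) -> ScenarioTFRPath:
    """Return one of the five built-in TFR scenarios by name."""
    key = _ALIASES.get(name, name)
    if key not in _TFR_TABLE:
        raise KeyError(f"unknown scenario {name!r}; choose from {SCENARIO_NAMES}")
    return ScenarioTFRPath(key, dict(zip(PERIODS, _TFR_TABLE[key])))


@dataclass
class PopulationSeries:
    """Quinquennial pyramids (2005, 2010, ...) under one fertility scenario."""

    scenario: str
    pyramids: dict[int, PopulationPyramid]

    def __post_init__(self) -> None:
        years = sorted(self.pyramids)
        for a, b in zip(years, years[1:]):
            if b - a != 5:
                raise ValueError(f"pyramids must be 5 years apart, got {a} and {b}")

    @property
    def years(self) -> list[int]:
        return sorted(self.pyramids)


@dataclass(frozen=True)
class PyramidSummary:
    """Headline structure indicators of one pyramid."""

    total: float
    share_30plus: float  # percent of total aged >= 30
    share_over65: float  # percent of total aged >= 65
    sex_gap_30plus: float  # male minus female count in ages >= 30, signed


def scale_to_tfr(schedule: FertilitySchedule, tfr_target: float) -> FertilitySchedule:
    """Rescale a fertility schedule by one scalar to hit a TFR target.

    The age pattern (ratios between groups) is unchanged; only the level
    moves.
    """
    if tfr_target <= 0:
        raise ValueError(f"tfr_target must be positive, got {tfr_target}")
    current = schedule.implied_tfr
    if current <= 0:
        raise ValueError("cannot rescale a schedule with zero implied TFR")
    return FertilitySchedule(asfr=schedule.asfr * (tfr_target / current), srb=schedule.srb)


def project_step(
    pyramid: PopulationPyramid,
    mortality: MortalitySchedule,
    fertility: FertilitySchedule,
    exposure: str = "start",
) -> PopulationPyramid:
    """Advance a pyramid one 5-year step by the cohort-component method.

    For each sex, the cohort in group [a, a+4] survives into [a+5, a+9]
    with its survivorship ratio; the open 100+ group retains its own
    survivors plus entrants from 95--99.  Births over the period are
    ``5 * sum(asfr * female exposure)`` across reproductive groups, split
    by the sex ratio at birth and survived into 0--4.  Migration is zero.

    ``exposure`` selects the female counts used for births: ``"start"``
    (start-of-period, the default) or ``"mid"`` (average of start-of-period
    and survived end-of-period counts).
    """
    if exposure not in ("start", "mid"):
        raise ValueError(f"exposure must be 'start' or 'mid', got {exposure!r}")
    counts = pyramid.counts
    surv = mortality.survival
    missing = counts.index.difference(surv.index)
    if len(missing):
        raise KeyError(f"mortality schedule missing age groups {list(missing)}")

    new = pd.DataFrame(0.0, index=counts.index, columns=counts.columns)
    lows = [lo for lo in counts.index if lo < 100]
    for sex in counts.columns:
        for lo in lows[:-1]:
            new.loc[lo + 5, sex] = counts.loc[lo, sex] * surv.loc[lo, sex]
        # terminal group: entrants from 95--99 plus its own survivors
        new.loc[100, sex] = (
            counts.loc[95, sex] * surv.loc[95, sex]
            + counts.loc[100, sex] * surv.loc[100, sex]
        )

    repro = list(REPRODUCTIVE_LOWER)
    fem_start = counts.loc[repro, "female"]
    if exposure == "mid":
        fem_exposure = (fem_start + new.loc[repro, "female"]) / 2.0
    else:
        fem_exposure = fem_start
    asfr = fertility.asfr.reindex(fem_exposure.index)
    if asfr.isna().any():
        raise KeyError("fertility schedule missing reproductive age groups")
    births = float(5.0 * (asfr * fem_exposure).sum())
    male_share = fertility.srb / (1.0 + fertility.srb)
    new.loc[0, "male"] = births * male_share * mortality.birth_survival["male"]
    new.loc[0, "female"] = births * (1.0 - male_share) * mortality.birth_survival["female"]

    return PopulationPyramid(reference_year=pyramid.reference_year + 5, counts=new)


def project_series(
    base: PopulationPyramid,
    mortality: MortalitySchedule,
    base_fertility: FertilitySchedule,
    path: ScenarioTFRPath,
    horizon_year: int,
    exposure: str = "start",
) -> PopulationSeries:
    """Iterate ``project_step`` from the base year to ``horizon_year``.

    Fertility is rescaled to the scenario's TFR for each period; the
    returned series includes both endpoints.  Fully deterministic.
    """
    if horizon_year < base.reference_year or (horizon_year - base.reference_year) % 5:
        raise ValueError(
            f"horizon_year must be >= base year and a multiple of 5 apart, "
            f"got {base.reference_year} -> {horizon_year}"
        )
    pyramids = {base.reference_year: base.copy()}
    current = base
    for year in range(base.reference_year, horizon_year, 5):
        period = f"{year}–{year + 5}"
        fert = scale_to_tfr(base_fertility, path.tfr_for(period))
        current = project_step(current, mortality, fert, exposure=exposure)
        pyramids[current.reference_year] = current
    return PopulationSeries(scenario=path.name, pyramids=pyramids)


def summarize(pyramid: PopulationPyramid) -> PyramidSummary:
    """Total population, 30+ and 65+ shares (percent), and the 30+ sex gap."""
    total = pyramid.total
    if total <= 0:
        raise ValueError("cannot summarize a pyramid with zero total population")
    adult = pyramid.counts.index >= 30
    old = pyramid.counts.index >= 65
    adult_total = float(pyramid.counts.loc[adult].to_numpy().sum())
    old_total = float(pyramid.counts.loc[old].to_numpy().sum())
    gap = float(
        pyramid.counts.loc[adult, "male"].sum() - pyramid.counts.loc[adult, "female"].sum()
    )
    return PyramidSummary(
        total=total,
        share_30plus=100.0 * adult_total / total,
        share_over65=100.0 * old_total / total,
        sex_gap_30plus=gap,
    )


def interpolate_years(series: PopulationSeries) -> dict[int, PopulationPyramid]:
    """Cell-wise linear interpolation to annual pyramids.

    Quinquennial pyramids are returned unchanged; intermediate years are
    convex combinations of the bracketing pyramids, so every interpolated
    cell lies between its bracketing values.
    """
    years = series.years
    if len(years) < 2:
        raise ValueError("need at least two pyramids to interpolate")
    out: dict[int, PopulationPyramid] = {}
    for y0, y1 in zip(years, years[1:]):
        p0, p1 = series.pyramids[y0], series.pyramids[y1]
        for year in range(y0, y1):
            frac = (year - y0) / (y1 - y0)
            counts = p0.counts * (1.0 - frac) + p1.counts * frac
            out[year] = PopulationPyramid(reference_year=year, counts=counts)
    out[years[-1]] = series.pyramids[years[-1]].copy()
    return out
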