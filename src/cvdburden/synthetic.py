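"""Synthetic demographic and burden inputs.

The projection pipeline needs four external ingredients: a base-year
population pyramid, 5-year survivorship ratios, an age-specific fertility
schedule, and a coarse-age-group table of cardiovascular DALY rates.  This
module generates all four with the statistical structure the downstream
analysis assumes, so the full pipeline runs and is testable without any
external demographic database.

Generators are pure functions of their arguments (including ``seed``):
calling one twice with identical arguments returns identical objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ages import AgeInterval, fine_intervals, coarse_intervals, group_midpoint
from .rates import RateLine

__all__ = [
    "PopulationPyramid",
    "MortalitySchedule",
    "FertilitySchedule",
    "CoarseBurdenTable",
    "make_base_population",
    "make_mortality_schedule",
    "make_fertility_schedule",
    "make_coarse_daly_table",
]

SEXES = ("male", "female")

#: lower bounds of the reproductive 5-year age groups (15--19 ... 45--49)
REPRODUCTIVE_LOWER = tuple(range(15, 50, 5))

#: default sex ratio at birth (male births per female birth), demographic convention
DEFAULT_SRB = 1.05


def _fine_index() -> pd.Index:
    return pd.Index([iv.lower for iv in fine_intervals()], name="age_lo")


@dataclass
class PopulationPyramid:
    """Person counts by sex and 5-year age group for one mid-year reference date.

    ``counts`` is indexed by the age-group lower bound (0, 5, ..., 100 where
    100 is the open-ended 100+ group) with one column per sex.
    """

    reference_year: int
    counts: pd.DataFrame

    def __post_init__(self) -> None:
        expected = _fine_index()
        if not self.counts.index.equals(expected):
            self.counts = self.counts.reindex(expected)
        missing = [s for s in SEXES if s not in self.counts.columns]
        if missing:
            raise ValueError(f"pyramid missing sex columns: {missing}")
        if self.counts.isna().any().any():
            raise ValueError("pyramid has missing cells")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("pyramid counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.to_numpy().sum())

    def sex_total(self, sex: str, min_age: int = 0) -> float:
        return float(self.counts.loc[self.counts.index >= min_age, sex].sum())

    def both_sexes(self) -> pd.Series:
        return self.counts["male"] + self.counts["female"]

    def copy(self) -> "PopulationPyramid":
        return PopulationPyramid(self.reference_year, self.counts.copy())

    def intervals(self) -> tuple[AgeInterval, ...]:
        return fine_intervals()


@dataclass
class MortalitySchedule:
    """5-year survivorship proportions by sex and age group.

    ``survival.loc[a, sex]`` is the proportion of the cohort aged [a, a+4]
    surviving into [a+5, a+9] over one projection step; the terminal 100+
    entry is the proportion surviving within 100+.  ``birth_survival`` maps
    sex to the proportion of births alive in the 0--4 group at period end.
    """

    survival: pd.DataFrame
    birth_survival: dict[str, float] = field(default_factory=lambda: {s: 0.99 for s in SEXES})

    def __post_init__(self) -> None:
        vals = self.survival.to_numpy()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("survivorship proportions must lie in [0, 1]")
        for s, v in self.birth_survival.items():
            if not 0 <= v <= 1:
                raise ValueError(f"birth survival for {s} out of [0, 1]: {v}")


@dataclass
class FertilitySchedule:
    """Age-specific fertility rates (births per woman per year) over 15--49.

    The implied total fertility rate is ``5 * sum(asfr)`` — the expected
    completed family size if current rates persisted through a reproductive
    lifetime.  ``srb`` is the sex ratio at birth (males per female birth).
    """

    asfr: pd.Series
    srb: float = DEFAULT_SRB

    def __post_init__(self) -> None:
        if (self.asfr < 0).any():
            raise ValueError("ASFR values must be non-negative")
        if self.srb <= 0:
            raise ValueError(f"sex ratio at birth must be positive, got {self.srb}")

    @property
    def implied_tfr(self) -> float:
        return float(5.0 * self.asfr.sum())


@dataclass
class CoarseBurdenTable:
    """DALY rates per 100,000 person-years on the coarse adult age grouping.

    Long-format frame with columns ``sex`` (both/male/female), ``age_lo``,
    ``age_hi`` (NaN for the open 80+ group) and ``rate_per_100k``.
    """

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sex", "age_lo", "age_hi", "rate_per_100k"}
        if not required.issubset(self.rows.columns):
            raise ValueError(f"coarse table needs columns {sorted(required)}")
        if (self.rows["rate_per_100k"] < 0).any():
            raise ValueError("DALY rates must be non-negative")

    def stratum(self, sex: str) -> pd.DataFrame:
        sub = self.rows[self.rows["sex"] == sex]
        if sub.empty:
            raise KeyError(f"no rows for stratum {sex!r}")
        return sub.reset_index(drop=True)


def make_base_population(
    total_size: float,
    bulge_age: float,
    spread: float,
    sex_gap_30plus: float = 0.0,
    seed: int = 0,
    floor_frac: float = 1e-4,
) -> PopulationPyramid:
    """Generate a base-year pyramid with a young-adult bulge.

    The age profile is a discretized Gaussian bump (scale ``spread`` years)
    centred on ``bulge_age`` over a small flat floor; each group's weight
    uses its distance to ``bulge_age`` (zero inside the containing group),
    so the 5-year group containing ``bulge_age`` is always modal.  The grand
    total equals ``total_size`` exactly and males aged 30+ exceed females
    aged 30+ by exactly ``sex_gap_30plus`` (a signed count).  The seed only
    perturbs the within-group sex split (~0.5% sd).

    Parameters
    ----------
    total_size : total person count of the pyramid (must be > 0).
    bulge_age : age (years, 0--100) at which the profile peaks.
    spread : Gaussian scale of the bump in years (must be > 0).
    sex_gap_30plus : male-minus-female count in ages 30+, imposed exactly.
    seed : RNG seed for the sex-split perturbation.
    """
    if total_size <= 0:
        raise ValueError(f"total_size must be positive, got {total_size}")
    if spread <= 0:
        raise ValueError(f"spread must be positive, got {spread}")
    if not 0 <= bulge_age <= 100:
        raise ValueError(f"bulge_age must lie in [0, 100], got {bulge_age}")

    rng = np.random.default_rng(seed)
    ivs = fine_intervals()
    dist = np.array([iv.distance(bulge_age) for iv in ivs])
    w = np.exp(-0.5 * (dist / spread) ** 2)
    w = w + floor_frac * w.max()
    age_counts = w / w.sum() * total_size

    # seeded sex split around 50/50; age totals stay exact
    male_share = np.clip(0.5 + rng.normal(0.0, 0.005, size=len(ivs)), 0.0, 1.0)
    male = age_counts * male_share
    female = age_counts - male

    counts = pd.DataFrame({"male": male, "female": female}, index=_fine_index())

    # impose the 30+ sex gap by an exact compensating transfer
    adult = counts.index >= 30
    m30 = counts.loc[adult, "male"].sum()
    f30 = counts.loc[adult, "female"].sum()
    delta = (sex_gap_30plus - (m30 - f30)) / 2.0
    if m30 + delta < 0 or f30 - delta < 0:
        raise ValueError("sex_gap_30plus infeasible for this pyramid shape")
    if m30 > 0:
        counts.loc[adult, "male"] *= (m30 + delta) / m30
    if f30 > 0:
        counts.loc[adult, "female"] *= (f30 - delta) / f30

    # restore the exact grand total (transfer conserves it; guard roundoff)
    counts *= total_size / counts.to_numpy().sum()
    return PopulationPyramid(reference_year=2005, counts=counts)


def make_mortality_schedule(adult_level: float = 1.0, seed: int = 0) -> MortalitySchedule:
    """Build a Gompertz-type survivorship schedule anchored at ages 30--34.

    The underlying force of mortality grows exponentially with age, giving
    5-year survivorship ``exp(-5 * m0 * exp(b * (age - 32)))``; female
    mortality rises slightly more slowly than male (b = 0.088 vs 0.092 per
    year).  The whole schedule is scaled so the 30--34 survivorship equals
    ``adult_level * 0.995`` in each sex, so ``adult_level`` moves overall
    adult survival without changing the age pattern.  The curve is fully
    deterministic; ``seed`` is accepted for interface symmetry with the
    other generators.
    """
    del seed
    if not 0 < adult_level <= 1:
        raise ValueError(f"adult_level must lie in (0, 1], got {adult_level}")

    m0 = -np.log(0.995) / 5.0  # anchors 30--34 survivorship at 0.995
    slopes = {"male": 0.092, "female": 0.088}
    mids = np.array([group_midpoint(iv) for iv in fine_intervals()])
    cols = {}
    for sex, b in slopes.items():
        s = np.exp(-5.0 * m0 * np.exp(b * (mids - 32.0)))
        cols[sex] = adult_level * s
    survival = pd.DataFrame(cols, index=_fine_index())
    birth_survival = {"male": 0.988 * adult_level, "female": 0.990 * adult_level}
    return MortalitySchedule(survival=survival, birth_survival=birth_survival)


#: relative age pattern of fertility over 15--19 ... 45--49 (late-transition
#: profile concentrated in the 20s, as in contemporary Iranian schedules)
_ASFR_PATTERN = np.array([0.08, 0.24, 0.28, 0.21, 0.12, 0.055, 0.015])


def make_fertility_schedule(tfr_target: float, srb: float = DEFAULT_SRB) -> FertilitySchedule:
    """Build a hump-shaped ASFR schedule with an exact implied TFR.

    The fixed relative age pattern is scaled by one constant so that
    ``5 * sum(asfr) == tfr_target``; doubling the target doubles every rate.
    """
    if tfr_target <= 0:
        raise ValueError(f"tfr_target must be positive, got {tfr_target}")
    asfr = pd.Series(
        _ASFR_PATTERN / _ASFR_PATTERN.sum() * (tfr_target / 5.0),
        index=pd.Index(REPRODUCTIVE_LOWER, name="age_lo"),
    )
    return FertilitySchedule(asfr=asfr, srb=srb)


def make_coarse_daly_table(
    lines: dict[str, RateLine],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> CoarseBurdenTable:
    """Generate a coarse-age-group DALY-rate table around given rate lines.

    For each stratum the rate of a coarse group is the line evaluated at the
    group midpoint plus additive Gaussian noise (sd ``noise_sd``, on the
    per-100,000 rate scale), truncated at zero.  With ``noise_sd=0`` the
    generating line is exactly recoverable by OLS on the midpoints.
    """
    if noise_sd < 0:
        raise ValueError(f"noise_sd must be non-negative, got {noise_sd}")
    rng = np.random.default_rng(seed)
    records = []
    for sex, line in lines.items():
        for iv in coarse_intervals():
            mid = group_midpoint(iv)
            rate = line.intercept + line.slope * mid
            if noise_sd > 0:
                rate += rng.normal(0.0, noise_sd)
            records.append(
                {
                    "sex": sex,
                    "age_lo": iv.lower,
                    "age_hi": np.nan if iv.is_open else iv.upper,
                    "rate_per_100k": max(0.0, rate),
                }
            )
    return CoarseBurdenTable(rows=pd.DataFrame.from_records(records))
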