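"""Linear age-interpolation of DALY rates.

The source burden-of-disease inputs report cardiovascular DALY rates only
on coarse adult age groups (30--44, 45--59, 60--69, 70--79, 80+).  The
analysis fits a straight line of rate against the coarse-group midpoint,
one line per stratum (both sexes, male, female), and reads 5-year-group
rates off the fitted line.  The three fitted lines of the 2003 Iranian
national burden-of-disease CVD data are shipped as immutable reference
fixtures.

Rates are expressed per 100,000 population per year throughout; the
reference equations carry no explicit scale in their source, and the
per-100,000 reading is the one consistent with the magnitude of the
published burden projections (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from types import MappingProxyType

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .ages import AgeInterval, adult_fine_intervals, group_midpoint

__all__ = [
    "RateLine",
    "FineRateTable",
    "fit_rate_line",
    "predict_rate",
    "expand_to_fine",
    "reference_lines",
]

STRATA = ("both", "male", "female")


@dataclass(frozen=True)
class RateLine:
    """Straight line of DALY rate (per 100,000) against age in years."""

    stratum: str
    intercept: float
    slope: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.intercept) and np.isfinite(self.slope)):
            raise ValueError("rate-line coefficients must be finite")


@dataclass
class FineRateTable:
    """DALY rates per 100,000 on the fine adult grid (30--34 ... 95--99, 100+)."""

    stratum: str
    rates: pd.Series

    def __post_init__(self) -> None:
        if (self.rates < 0).any():
            raise ValueError("fine rates must be non-negative")

    def rate_at(self, age_lo: int) -> float:
        return float(self.rates.loc[age_lo])


def fit_rate_line(table, stratum: str) -> RateLine:
    """Ordinary least squares of coarse-group DALY rate on group midpoint.

    Requires at least two groups with distinct midpoints for the stratum.
    Returns the exact OLS solution (a straight line through the points when
    they are collinear).
    """
    sub = table.stratum(stratum)
    from .ages import interval_from_bounds  # local import avoids cycle at module load

    mids = np.array(
        [
            group_midpoint(
                interval_from_bounds(lo, None if pd.isna(hi) else int(hi))
            )
            for lo, hi in zip(sub["age_lo"], sub["age_hi"])
        ]
    )
    rates = sub["rate_per_100k"].to_numpy(dtype=float)
    if len(mids) < 2 or np.ptp(mids) == 0:
        raise ValueError(
            f"degenerate fit for stratum {stratum!r}: need >= 2 distinct midpoints"
        )
    model = sm.OLS(rates, sm.add_constant(mids)).fit()
    intercept, slope = model.params
    return RateLine(stratum=stratum, intercept=float(intercept), slope=float(slope))


def predict_rate(line: RateLine, age: float) -> float:
    """Rate per 100,000 at ``age``; negative extrapolations clamp to zero."""
    if age < 0:
        raise ValueError(f"age must be non-negative, got {age}")
    return max(0.0, line.intercept + line.slope * age)


def expand_to_fine(
    line: RateLine,
    groups: tuple[AgeInterval, ...] | None = None,
) -> FineRateTable:
    """Read 5-year-group rates off a fitted line at each group midpoint.

    The terminal 100+ group is assigned a rate of zero: the published
    projections carry no burden in that stratum, and the linear
    extrapolation is not trusted past the oldest coarse midpoint.
    """
    if groups is None:
        groups = adult_fine_intervals()
    los = [iv.lower for iv in groups]
    if len(set(los)) != len(los) or los != sorted(los):
        raise ValueError("fine groups must be ordered and disjoint")
    values = {}
    for iv in groups:
        if iv.is_open and iv.lower >= 100:
            values[iv.lower] = 0.0
        else:
            values[iv.lower] = predict_rate(line, group_midpoint(iv))
    rates = pd.Series(values, name="rate_per_100k")
    rates.index.name = "age_lo"
    return FineRateTable(stratum=line.stratum, rates=rates)


#: Fitted rate lines of the 2003 Iranian national CVD burden data,
#: rate per 100,000 = intercept + slope * age.
_REFERENCE_LINES = MappingProxyType(
    {
        "both": RateLine("both", intercept=-5047.25, slope=173.71),
        "male": RateLine("male", intercept=-4896.54, slope=171.17),
        "female": RateLine("female", intercept=-5190.07, slope=176.11),
    }
)


def reference_lines() -> dict[str, RateLine]:
    """Fresh copies of the three reference rate lines (both, male, female)."""
    return {k: RateLine(v.stratum, v.intercept, v.slope) for k, v in _REFERENCE_LINES.items()}
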