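"""DALY burden projection under constant age-specific rates.

The core assumption of the analysis: cardiovascular DALY rates per 100,000
by 5-year age group and sex stay fixed at their base-year level, and all
change in burden comes from the size and age structure of the projected
population.  Burden for a group is then simply

    DALYs = rate_per_100k / 100,000 * group population.

Both-sex results are computed from the both-sex rate line applied to the
sex-summed pyramid, not by adding the male and female results; the three
lines are fitted independently, so both-sex totals differ from male+female
by a small amount (~0.05% in the reference projection).  This module never
enforces cross-stratum additivity.

The published 2005/2025 projection table for Iran is shipped as a packaged
fixture (``data/iran_cvd_daly_reference.csv``) and serves as in-package
ground truth for the summary operations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

from .ages import AgeInterval, adult_fine_intervals
from .cohort import PopulationSeries
from .rates import RateLine, FineRateTable, expand_to_fine, STRATA
from .synthetic import PopulationPyramid

__all__ = [
    "BurdenTable",
    "BurdenProjection",
    "compute_burden",
    "project_burden",
    "total_daly",
    "fold_change",
    "sex_difference",
    "share_under",
    "age_standardized_rate",
    "write_wide_table",
    "load_reference_projection",
]

REFERENCE_FIXTURE = "iran_cvd_daly_reference.csv"

#: slack allowed between a stored Total row and the recomputed column sum;
#: absorbs the rounding of published two-decimal tables
TOTAL_SLACK = 0.05


def _adult_index() -> pd.Index:
    return pd.Index([iv.lower for iv in adult_fine_intervals()], name="age_lo")


@dataclass
class BurdenTable:
    """DALYs by stratum and fine adult age group for one calendar year.

    ``cells`` is indexed by age-group lower bound (30, 35, ..., 100) with
    one column per stratum present.  ``stored_totals`` optionally carries
    externally supplied Total-row values (e.g. from a published table);
    they must agree with the column sums within ``TOTAL_SLACK``.
    """

    reference_year: int
    cells: pd.DataFrame
    stored_totals: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.cells.to_numpy() < 0).any():
            raise ValueError("burden cells must be non-negative")
        for stratum, total in self.stored_totals.items():
            col_sum = float(self.cells[stratum].sum())
            if abs(col_sum - total) > TOTAL_SLACK:
                raise ValueError(
                    f"stored total for {stratum!r} ({total}) differs from column "
                    f"sum ({col_sum}) by more than {TOTAL_SLACK}"
                )

    @property
    def strata(self) -> tuple[str, ...]:
        return tuple(self.cells.columns)

    def total(self, stratum: str) -> float:
        return float(self.cells[stratum].sum())


@dataclass
class BurdenProjection:
    """A year-indexed family of burden tables under one population scenario."""

    scenario: str
    tables: dict[int, BurdenTable]

    @property
    def years(self) -> list[int]:
        return sorted(self.tables)


def compute_burden(
    rates: FineRateTable,
    pyramid: PopulationPyramid,
    stratum: str | None = None,
) -> pd.Series:
    """DALYs per fine adult age group for one stratum.

    For ``stratum="both"`` the pyramid is summed over sexes before
    multiplying; otherwise the named sex column is used.  Linear in the
    pyramid: doubling every population cell doubles every burden cell.
    """
    stratum = stratum or rates.stratum
    if stratum == "both":
        pop = pyramid.both_sexes()
    elif stratum in pyramid.counts.columns:
        pop = pyramid.counts[stratum]
    else:
        raise KeyError(f"stratum {stratum!r} not present in pyramid")
    pop = pop.reindex(rates.rates.index)
    if pop.isna().any():
        raise KeyError("pyramid does not cover every fine age group of the rate table")
    out = rates.rates * pop / 100_000.0
    out.name = stratum
    return out


def project_burden(
    series: PopulationSeries,
    lines: dict[str, RateLine],
) -> BurdenProjection:
    """Apply base-year rate lines to every pyramid of a population series.

    Each line is expanded to the fine grid once; rates never vary with
    year.  Returns one burden table per projected year with one column per
    stratum in ``lines``.
    """
    fine = {stratum: expand_to_fine(line) for stratum, line in lines.items()}
    tables = {}
    for year in series.years:
        pyramid = series.pyramids[year]
        cols = {
            stratum: compute_burden(table, pyramid, stratum)
            for stratum, table in fine.items()
        }
        tables[year] = BurdenTable(reference_year=year, cells=pd.DataFrame(cols))
    return BurdenProjection(scenario=series.scenario, tables=tables)


def total_daly(
    table: BurdenTable,
    stratum: str,
    age_filter=None,
) -> float:
    """Sum of burden cells for a stratum, optionally filtered by age group.

    ``age_filter`` is a predicate over :class:`AgeInterval`; ``None`` sums
    everything.  No rounding is applied.
    """
    col = table.cells[stratum]
    if age_filter is None:
        return float(col.sum())
    keep = [iv.lower for iv in adult_fine_intervals() if age_filter(iv)]
    return float(col.loc[col.index.intersection(keep)].sum())


def fold_change(proj: BurdenProjection, year0: int, year1: int, stratum: str) -> float:
    """Ratio of stratum totals ``total(year1) / total(year0)``."""
    denom = proj.tables[year0].total(stratum)
    if denom == 0:
        raise ZeroDivisionError(f"zero total burden in {year0} for stratum {stratum!r}")
    return proj.tables[year1].total(stratum) / denom


def sex_difference(table: BurdenTable) -> float:
    """Male total minus female total (signed DALYs)."""
    for s in ("male", "female"):
        if s not in table.cells.columns:
            raise KeyError(f"stratum {s!r} missing from burden table")
    return table.total("male") - table.total("female")


def share_under(table: BurdenTable, cutoff_age: float, stratum: str) -> float:
    """Percent of a stratum's burden in groups entirely below ``cutoff_age``.

    A group counts when its upper bound is below the cutoff; open-ended
    groups never do.
    """
    total = table.total(stratum)
    if total <= 0:
        raise ZeroDivisionError(f"zero total burden for stratum {stratum!r}")
    young = total_daly(
        table,
        stratum,
        age_filter=lambda iv: (not iv.is_open) and iv.upper < cutoff_age,
    )
    return 100.0 * young / total


def age_standardized_rate(
    rates: FineRateTable,
    standard: PopulationPyramid,
    stratum: str | None = None,
) -> float:
    """Directly age-standardized DALY rate per 100,000 against a standard pyramid.

    Weights each fine-group rate by the standard population's share of that
    group.  Not used by the default pipeline — the projection's totals are
    crude sums under constant rates — but provided for comparisons against
    an external standard age structure.
    """
    stratum = stratum or rates.stratum
    if stratum == "both":
        pop = standard.both_sexes()
    else:
        pop = standard.counts[stratum]
    pop = pop.reindex(rates.rates.index)
    if pop.isna().any():
        raise KeyError("standard pyramid does not cover the rate table's age groups")
    total = float(pop.sum())
    if total <= 0:
        raise ZeroDivisionError("standard population has zero mass on the adult grid")
    return float((rates.rates * pop).sum() / total)


def _fmt(x: float) -> str:
    return f"{x:.2f}"


def write_wide_table(proj: BurdenProjection, years: list[int], path) -> None:
    """Write a wide CSV with one column per year and stratum.

    Layout: one row per fine adult age group plus a ``Total`` row; values
    formatted with two decimals.  The Total row uses stored totals where a
    table carries them (published tables) and recomputed column sums
    otherwise; either way it agrees with the column sums within
    ``TOTAL_SLACK``.
    """
    strata = [s for s in STRATA if all(s in proj.tables[y].strata for y in years)]
    header = ["age_group"] + [f"{y}_{s}" for y in years for s in strata]
    lines = [",".join(header)]
    for iv in adult_fine_intervals():
        row = [iv.label]
        for y in years:
            for s in strata:
                row.append(_fmt(float(proj.tables[y].cells.loc[iv.lower, s])))
        lines.append(",".join(row))
    total_row = ["Total"]
    for y in years:
        table = proj.tables[y]
        for s in strata:
            total = table.stored_totals.get(s, table.total(s))
            total_row.append(_fmt(total))
    lines.append(",".join(total_row))
    with open(path, "w", newline="") as fh:
        fh.write("\n".join(lines) + "\n")


def _parse_wide(text: str) -> BurdenProjection:
    rows = [line.split(",") for line in text.strip().splitlines()]
    header = rows[0]
    year_strata = [col.split("_", 1) for col in header[1:]]
    years = sorted({int(y) for y, _ in year_strata})
    cells: dict[int, dict[str, dict[int, float]]] = {
        y: {s: {} for _, s in year_strata} for y in years
    }
    totals: dict[int, dict[str, float]] = {y: {} for y in years}
    for row in rows[1:]:
        label, values = row[0], [float(v) for v in row[1:]]
        for (y, s), v in zip(year_strata, values):
            if label == "Total":
                totals[int(y)][s] = v
            else:
                lo = int(label.rstrip("+").split("-")[0])
                cells[int(y)][s][lo] = v
    tables = {}
    for y in years:
        frame = pd.DataFrame(cells[y]).sort_index()
        frame.index.name = "age_lo"
        tables[y] = BurdenTable(reference_year=y, cells=frame, stored_totals=totals[y])
    return BurdenProjection(scenario="reference", tables=tables)


def load_reference_projection() -> BurdenProjection:
    """Load the packaged published 2005/2025 CVD DALY projection for Iran."""
    ref = resources.files("cvdburden.data").joinpath(REFERENCE_FIXTURE)
    return _parse_wide(ref.read_text())
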