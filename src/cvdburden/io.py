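"""Plain-CSV dialects for the pipeline's inputs and outputs.

Pyramids travel as long CSV ``year,sex,age_lo,age_hi,count`` (empty
``age_hi`` for the open-ended terminal group); rate tables as
``sex,age_lo,age_hi,rate_per_100k``; burden projections as
``year,sex,age_lo,age_hi,daly`` with ``TOTAL`` rows; sensitivity results
as one row per scenario cell.  Any externally produced file in the pyramid
dialect can be ingested in place of the synthetic generator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ages import fine_intervals, adult_fine_intervals
from .burden import BurdenProjection
from .synthetic import PopulationPyramid, CoarseBurdenTable, SEXES
from .rates import FineRateTable
from .uncertainty import ScenarioSpec, UncertaintyInterval

__all__ = [
    "write_pyramid_csv",
    "read_pyramid_csv",
    "write_coarse_table_csv",
    "read_coarse_table_csv",
    "write_fine_rates_csv",
    "write_burden_csv",
    "write_sensitivity_csv",
]


def write_pyramid_csv(pyramid: PopulationPyramid, path, header_comment: str | None = None) -> None:
    ivs = fine_intervals()
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("year,sex,age_lo,age_hi,count\n")
        for sex in SEXES:
            for iv in ivs:
                hi = "" if iv.is_open else iv.upper
                count = float(pyramid.counts.loc[iv.lower, sex])
                fh.write(f"{pyramid.reference_year},{sex},{iv.lower},{hi},{count!r}\n")


def read_pyramid_csv(path) -> PopulationPyramid:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    years = df["year"].unique()
    if len(years) != 1:
        raise ValueError(f"pyramid CSV must hold a single year, found {sorted(years)}")
    counts = df.pivot(index="age_lo", columns="sex", values="count")
    counts.columns.name = None
    return PopulationPyramid(reference_year=int(years[0]), counts=counts[list(SEXES)])


def _rate_frame_to_csv(df: pd.DataFrame, path, header_comment: str | None) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("sex,age_lo,age_hi,rate_per_100k\n")
        for _, row in df.iterrows():
            hi = "" if pd.isna(row["age_hi"]) else int(row["age_hi"])
            fh.write(
                f"{row['sex']},{int(row['age_lo'])},{hi},{float(row['rate_per_100k'])!r}\n"
            )


def write_coarse_table_csv(table: CoarseBurdenTable, path, header_comment: str | None = None) -> None:
    _rate_frame_to_csv(table.rows, path, header_comment)


def read_coarse_table_csv(path) -> CoarseBurdenTable:
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return CoarseBurdenTable(rows=df)


def write_fine_rates_csv(table: FineRateTable, path, header_comment: str | None = None) -> None:
    rows = []
    for iv in adult_fine_intervals():
        rows.append(
            {
                "sex": table.stratum,
                "age_lo": iv.lower,
                "age_hi": np.nan if iv.is_open else iv.upper,
                "rate_per_100k": table.rates.loc[iv.lower],
            }
        )
    _rate_frame_to_csv(pd.DataFrame(rows), path, header_comment)


def write_burden_csv(proj: BurdenProjection, path, header_comment: str | None = None) -> None:
    ivs = adult_fine_intervals()
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("year,sex,age_lo,age_hi,daly\n")
        for year in proj.years:
            table = proj.tables[year]
            for stratum in table.strata:
                for iv in ivs:
                    hi = "" if iv.is_open else iv.upper
                    v = float(table.cells.loc[iv.lower, stratum])
                    fh.write(f"{year},{stratum},{iv.lower},{hi},{v!r}\n")
                fh.write(f"{year},{stratum},TOTAL,,{table.total(stratum)!r}\n")


def write_sensitivity_csv(
    rows: list[tuple[ScenarioSpec, UncertaintyInterval]],
    path,
    draws: int | None = None,
    header_comment: str | None = None,
) -> None:
    with open(path, "w", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("scenario,pop_error,undercount,point,lower,upper,method,level,draws,seed\n")
        for i, (spec, iv) in enumerate(rows, start=1):
            fh.write(
                f"{i},{spec.pop_error!r},{spec.undercount!r},{iv.point!r},"
                f"{iv.lower!r},{iv.upper!r},{iv.method},{iv.level!r},"
                f"{'' if draws is None else draws},{'' if iv.seed is None else iv.seed}\n"
            )
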