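"""Burden tables: constant-rate arithmetic and published-table summaries."""

import numpy as np
import pandas as pd
import pytest

import cvdburden as cb
from cvdburden.ages import adult_fine_intervals, fine_intervals
from cvdburden.burden import BurdenTable, BurdenProjection, REFERENCE_FIXTURE
from cvdburden.synthetic import PopulationPyramid


def _uniform_pyramid(value=1e5, year=2005):
    idx = pd.Index([iv.lower for iv in fine_intervals()], name="age_lo")
    counts = pd.DataFrame(value, index=idx, columns=["male", "female"])
    return PopulationPyramid(year, counts)


class TestComputeBurden:
    def test_rate_times_population(self):
        fine = cb.expand_to_fine(cb.reference_lines()["both"])
        p = _uniform_pyramid(3_000_000)  # both sexes: 6M per group
        out = cb.compute_burden(fine, p, "both")
        assert out.loc[30] == pytest.approx(511.47e-5 * 6e6)  # 30,688.2 DALYs
        assert out.loc[100] == 0.0

    def test_zero_population_gives_zero_burden(self):
        fine = cb.expand_to_fine(cb.reference_lines()["male"])
        out = cb.compute_burden(fine, _uniform_pyramid(0.0), "male")
        assert (out == 0).all()

    def test_homogeneous_of_degree_one(self):
        fine = cb.expand_to_fine(cb.reference_lines()["female"])
        p1 = _uniform_pyramid(1e5)
        p2 = _uniform_pyramid(2e5)
        out1 = cb.compute_burden(fine, p1, "female")
        out2 = cb.compute_burden(fine, p2, "female")
        assert np.allclose(out2, 2 * out1)

    def test_unknown_stratum_rejected(self):
        fine = cb.expand_to_fine(cb.reference_lines()["both"])
        with pytest.raises(KeyError):
            cb.compute_burden(fine, _uniform_pyramid(), "other")


class TestProjectBurden:
    def test_constant_population_gives_identical_tables(self, mortality):
        p = _uniform_pyramid()
        series = cb.PopulationSeries(
            "constant", {2005: p, 2010: _uniform_pyramid(year=2010)}
        )
        proj = cb.project_burden(series, cb.reference_lines())
        pd.testing.assert_frame_equal(proj.tables[2005].cells, proj.tables[2010].cells)

    def test_growing_group_grows_burden_cell(self):
        p0 = _uniform_pyramid()
        p1 = _uniform_pyramid(year=2010)
        p1.counts.loc[55] *= 1.5
        p1.counts.loc[60] *= 1.5
        series = cb.PopulationSeries("x", {2005: p0, 2010: p1})
        proj = cb.project_burden(series, cb.reference_lines())
        for lo in (55, 60):
            assert proj.tables[2010].cells.loc[lo, "both"] > proj.tables[2005].cells.loc[lo, "both"]

    def test_synthetic_aging_run_more_than_halves_again(self, base_pyramid, mortality, fertility):
        """End-to-end qualitative aging effect: 2025 burden > 1.5x the 2005 burden."""
        series = cb.project_series(
            base_pyramid, mortality, fertility, cb.scenario_path("medium"), 2025
        )
        proj = cb.project_burden(series, cb.reference_lines())
        assert cb.fold_change(proj, 2005, 2025, "both") > 1.5


class TestPublishedTableSummaries:
    def test_column_sums_match_stored_totals(self, reference_projection):
        for year in (2005, 2025):
            table = reference_projection.tables[year]
            for stratum in ("both", "male", "female"):
                assert table.total(stratum) == pytest.approx(
                    table.stored_totals[stratum], abs=0.05
                )

    def test_total_daly_with_age_filter(self, reference_projection):
        table = reference_projection.tables[2025]
        under65 = cb.total_daly(
            table, "both", age_filter=lambda iv: not iv.is_open and iv.upper < 65
        )
        assert under65 == pytest.approx(1_215_778.88, abs=0.05)
        assert cb.total_daly(table, "both", age_filter=lambda iv: False) == 0.0

    def test_fold_change_and_telescoping(self, reference_projection):
        assert cb.fold_change(reference_projection, 2005, 2025, "both") == pytest.approx(
            2.0404, abs=0.0005
        )
        assert cb.fold_change(reference_projection, 2005, 2005, "both") == 1.0
        ab = cb.fold_change(reference_projection, 2005, 2025, "male")
        ba = cb.fold_change(reference_projection, 2025, 2005, "male")
        assert ab * ba == pytest.approx(1.0)

    def test_sex_difference_both_years(self, reference_projection):
        assert cb.sex_difference(reference_projection.tables[2025]) == pytest.approx(
            6320.12, abs=0.05
        )
        assert cb.sex_difference(reference_projection.tables[2005]) == pytest.approx(
            38_696.65, abs=0.05
        )

    def test_share_under_cutoffs(self, reference_projection):
        table = reference_projection.tables[2025]
        assert cb.share_under(table, 65, "both") == pytest.approx(70.32, abs=0.01)
        assert cb.share_under(table, 101, "both") == pytest.approx(100.0)
        assert cb.share_under(table, 30, "both") == 0.0

    def test_cross_stratum_totals_independent(self, reference_projection):
        """Male + female totals need not equal the both-sex total (separate fits)."""
        table = reference_projection.tables[2005]
        summed = table.stored_totals["male"] + table.stored_totals["female"]
        both = table.stored_totals["both"]
        assert summed != both
        assert abs(summed - both) / both < 0.001  # ~0.05% discrepancy


class TestAgeStandardizedRate:
    def test_uniform_standard_recovers_mean_rate(self):
        fine = cb.expand_to_fine(cb.reference_lines()["both"])
        std = _uniform_pyramid(1e4)
        rate = cb.age_standardized_rate(fine, std, "both")
        assert rate == pytest.approx(fine.rates.mean())

    def test_weights_follow_standard_structure(self, base_pyramid):
        fine = cb.expand_to_fine(cb.reference_lines()["both"])
        young_heavy = cb.age_standardized_rate(fine, base_pyramid, "both")
        # shifting standard mass to old ages raises the standardized rate
        old = base_pyramid.copy()
        old.counts.loc[old.counts.index >= 70] *= 10
        assert cb.age_standardized_rate(fine, old, "both") > young_heavy


class TestAdditivity:
    def test_partition_sums_to_total(self, reference_projection):
        table = reference_projection.tables[2025]
        young = cb.total_daly(table, "both", lambda iv: iv.lower < 60)
        old = cb.total_daly(table, "both", lambda iv: iv.lower >= 60)
        assert young + old == pytest.approx(table.total("both"), rel=1e-9)


class TestWideTableRoundTrip:
    def test_fixture_round_trips_byte_for_byte(self, reference_projection, tmp_path):
        out = tmp_path / "ref.csv"
        cb.write_wide_table(reference_projection, [2005, 2025], out)
        from importlib import resources

        original = resources.files("cvdburden.data").joinpath(REFERENCE_FIXTURE).read_text()
        assert out.read_text() == original

    def test_written_totals_match_column_sums(self, tmp_path, base_pyramid, mortality, fertility):
        series = cb.project_series(
            base_pyramid, mortality, fertility, cb.scenario_path("medium"), 2015
        )
        proj = cb.project_burden(series, cb.reference_lines())
        out = tmp_path / "wide.csv"
        cb.write_wide_table(proj, proj.years, out)
        lines = out.read_text().strip().splitlines()
        header = lines[0].split(",")[1:]
        body = [l.split(",") for l in lines[1:-1]]
        totals = [float(v) for v in lines[-1].split(",")[1:]]
        for j, _col in enumerate(header):
            col_sum = sum(float(r[j + 1]) for r in body)
            assert col_sum == pytest.approx(totals[j], abs=0.05)

    def test_stored_total_inconsistency_rejected(self):
        idx = pd.Index([iv.lower for iv in adult_fine_intervals()], name="age_lo")
        cells = pd.DataFrame({"both": 1.0}, index=idx)
        with pytest.raises(ValueError):
            BurdenTable(2005, cells, stored_totals={"both": 99.0})
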