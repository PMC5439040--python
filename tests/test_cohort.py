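"""Cohort-component projection: survivorship arithmetic, births, scenarios."""

import numpy as np
import pandas as pd
import pytest

import cvdburden as cb
from cvdburden.ages import fine_intervals
from cvdburden.synthetic import PopulationPyramid, MortalitySchedule, FertilitySchedule


def _index():
    return pd.Index([iv.lower for iv in fine_intervals()], name="age_lo")


def _pyramid(cells=None, year=2005):
    """Pyramid with cells given as {(sex, age_lo): count}, zero elsewhere."""
    counts = pd.DataFrame(0.0, index=_index(), columns=["male", "female"])
    for (sex, lo), v in (cells or {}).items():
        counts.loc[lo, sex] = v
    return PopulationPyramid(year, counts)


def _flat_mortality(s=1.0, birth=1.0):
    surv = pd.DataFrame(s, index=_index(), columns=["male", "female"])
    return MortalitySchedule(surv, {"male": birth, "female": birth})


def _zero_fertility(srb=1.05):
    asfr = pd.Series(0.0, index=pd.Index(range(15, 50, 5), name="age_lo"))
    return FertilitySchedule(asfr, srb=srb)


class TestScenarioPaths:
    def test_tfr_grid_values(self):
        expect = {
            "medium": [1.96, 1.77, 1.59, 1.45, 1.36],
            "high": [1.96, 1.77, 1.84, 1.85, 1.86],
            "low": [1.96, 1.77, 1.34, 1.05, 0.86],
            "constant": [1.96, 1.77, 1.77, 1.77, 1.77],
            "instant_replacement": [2.1] * 5,
        }
        for name, values in expect.items():
            path = cb.scenario_path(name)
            assert list(path.tfr_by_period.values()) == values

    def test_alias_and_unknown_names(self):
        assert cb.scenario_path("instant").name == "instant_replacement"
        with pytest.raises(KeyError):
            cb.scenario_path("boom")

    def test_hyphen_period_labels_accepted(self):
        assert cb.scenario_path("low").tfr_for("2020-2025") == 0.86


class TestScaleToTFR:
    def test_halving(self):
        sched = cb.make_fertility_schedule(2.0)
        scaled = cb.scale_to_tfr(sched, 1.0)
        assert np.allclose(scaled.asfr, sched.asfr / 2)

    def test_identity_and_exact_target(self):
        sched = cb.make_fertility_schedule(1.77)
        same = cb.scale_to_tfr(sched, 1.77)
        pd.testing.assert_series_equal(same.asfr, sched.asfr)
        assert cb.scale_to_tfr(sched, 1.86).implied_tfr == pytest.approx(1.86, abs=1e-9)

    def test_age_pattern_preserved(self):
        sched = cb.make_fertility_schedule(1.5)
        scaled = cb.scale_to_tfr(sched, 3.3)
        ratio = scaled.asfr / sched.asfr
        assert np.allclose(ratio, ratio.iloc[0])

    def test_zero_schedule_rejected(self):
        with pytest.raises(ValueError):
            cb.scale_to_tfr(_zero_fertility(), 2.0)


class TestProjectStep:
    def test_pure_survivorship_moves_one_cohort(self):
        p = _pyramid({("male", 30): 100.0})
        out = cb.project_step(p, _flat_mortality(0.9), _zero_fertility())
        assert out.counts.loc[35, "male"] == pytest.approx(90.0)
        assert out.reference_year == 2010
        assert out.total == pytest.approx(90.0)

    def test_unit_survivorship_conserves_total(self, base_pyramid):
        out = cb.project_step(base_pyramid, _flat_mortality(1.0), _zero_fertility())
        assert out.total == pytest.approx(base_pyramid.total, rel=1e-12)
        # every cohort shifted up one group
        assert out.counts.loc[25, "female"] == pytest.approx(
            base_pyramid.counts.loc[20, "female"]
        )

    def test_terminal_group_receives_entrants_plus_own_survivors(self):
        p = _pyramid({("female", 95): 50.0, ("female", 100): 20.0})
        out = cb.project_step(p, _flat_mortality(0.5), _zero_fertility())
        assert out.counts.loc[100, "female"] == pytest.approx(0.5 * 50 + 0.5 * 20)

    def test_birth_arithmetic_closed_form(self):
        p = _pyramid({("female", 25): 1000.0})
        asfr = pd.Series(0.0, index=pd.Index(range(15, 50, 5), name="age_lo"))
        asfr.loc[25] = 0.04
        fert = FertilitySchedule(asfr, srb=1.05)
        out = cb.project_step(p, _flat_mortality(1.0, birth=1.0), fert)
        births = out.counts.loc[0].sum()
        assert births == pytest.approx(200.0)  # 5 * 1000 * 0.04
        assert out.counts.loc[0, "male"] == pytest.approx(200 * 1.05 / 2.05)

    def test_mid_period_exposure_averages_start_and_end(self):
        # women age out of 25-29 with survivorship 0.8 into 30-34; mid
        # exposure for 25-29 averages start count with survivors entering
        # from 20-24 (here zero), halving the start-based births
        p = _pyramid({("female", 25): 1000.0})
        asfr = pd.Series(0.0, index=pd.Index(range(15, 50, 5), name="age_lo"))
        asfr.loc[25] = 0.04
        fert = FertilitySchedule(asfr, srb=1.0)
        out = cb.project_step(p, _flat_mortality(0.8), fert, exposure="mid")
        assert out.counts.loc[0].sum() == pytest.approx(5 * 500.0 * 0.04)
        with pytest.raises(ValueError):
            cb.project_step(p, _flat_mortality(), fert, exposure="end")

    def test_cohorts_never_grow_without_migration(self, base_pyramid, mortality, fertility):
        out = cb.project_step(base_pyramid, mortality, fertility)
        for lo in range(0, 95, 5):
            for sex in ("male", "female"):
                assert out.counts.loc[lo + 5, sex] <= base_pyramid.counts.loc[lo, sex] + 1e-9


class TestProjectSeries:
    def test_zero_steps_returns_base_only(self, base_pyramid, mortality, fertility):
        series = cb.project_series(
            base_pyramid, mortality, fertility, cb.scenario_path("medium"), 2005
        )
        assert series.years == [2005]
        pd.testing.assert_frame_equal(series.pyramids[2005].counts, base_pyramid.counts)

    def test_scenario_totals_ordered_by_tfr_path(self, base_pyramid, mortality, fertility):
        totals = {}
        for name in ("low", "medium", "high"):
            series = cb.project_series(
                base_pyramid, mortality, fertility, cb.scenario_path(name), 2025
            )
            totals[name] = {y: series.pyramids[y].total for y in series.years}
        for year in (2010, 2015, 2020, 2025):
            assert totals["low"][year] <= totals["medium"][year] <= totals["high"][year]

    def test_deterministic(self, base_pyramid, mortality, fertility):
        kw = dict(path=cb.scenario_path("medium"), horizon_year=2025)
        a = cb.project_series(base_pyramid, mortality, fertility, **kw)
        b = cb.project_series(base_pyramid, mortality, fertility, **kw)
        for y in a.years:
            pd.testing.assert_frame_equal(a.pyramids[y].counts, b.pyramids[y].counts)

    def test_missing_period_raises(self, base_pyramid, mortality, fertility):
        path = cb.ScenarioTFRPath("custom", {"2005–2010": 1.8})
        with pytest.raises(KeyError):
            cb.project_series(base_pyramid, mortality, fertility, path, 2025)


class TestSummarize:
    def test_all_mass_in_oldest_group(self):
        p = _pyramid({("male", 100): 10.0, ("female", 100): 10.0})
        s = cb.summarize(p)
        assert s.share_30plus == 100.0
        assert s.share_over65 == 100.0

    def test_symmetric_pyramid_has_zero_gap(self):
        p = _pyramid({("male", 40): 7.0, ("female", 40): 7.0})
        assert cb.summarize(p).sex_gap_30plus == 0.0

    def test_synthetic_2005_calibration_near_published_share(self, base_pyramid):
        s = cb.summarize(base_pyramid)
        assert s.share_30plus == pytest.approx(38.01, abs=2.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            cb.summarize(_pyramid())


class TestInterpolateYears:
    def test_linear_formula_and_endpoints(self, base_pyramid, mortality, fertility):
        series = cb.project_series(
            base_pyramid, mortality, fertility, cb.scenario_path("medium"), 2010
        )
        annual = cb.interpolate_years(series)
        assert sorted(annual) == list(range(2005, 2011))
        c05 = series.pyramids[2005].counts
        c10 = series.pyramids[2010].counts
        expected = c05 * 0.6 + c10 * 0.4
        pd.testing.assert_frame_equal(annual[2007].counts, expected)
        pd.testing.assert_frame_equal(annual[2010].counts, c10)

    def test_interpolated_cells_bracketed(self, base_pyramid, mortality, fertility):
        series = cb.project_series(
            base_pyramid, mortality, fertility, cb.scenario_path("medium"), 2015
        )
        annual = cb.interpolate_years(series)
        for y0 in (2005, 2010):
            lo = np.minimum(series.pyramids[y0].counts, series.pyramids[y0 + 5].counts)
            hi = np.maximum(series.pyramids[y0].counts, series.pyramids[y0 + 5].counts)
            for year in range(y0, y0 + 5):
                c = annual[year].counts
                assert ((c >= lo - 1e-9) & (c <= hi + 1e-9)).all().all()

    def test_single_pyramid_rejected(self, base_pyramid):
        series = cb.PopulationSeries("medium", {2005: base_pyramid})
        with pytest.raises(ValueError):
            cb.interpolate_years(series)
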