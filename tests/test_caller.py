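"""Pregnancy caller: run detection, classification, dating, intervals."""

import datetime as dt
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import baleendo as b
from baleendo.caller import (
    add_months,
    birth_from_calf_sighting,
    classify_runs,
    estimate_calling_baseline,
)
from baleendo.chronology import Chronology
from baleendo.errors import BaleendoError
from baleendo.model import BaleenPregnancyModel


@pytest.fixture
def timeline():
    return Chronology.from_constant_rate(20.0, dt.date(2001, 7, 14))


class TestFindRuns:
    def test_flat_series_no_runs(self, timeline):
        pos = np.arange(0, 40, 2.0)
        runs = b.find_runs(np.full(pos.size, 100.0), pos, timeline, baseline=100.0)
        assert runs == []

    def test_isolated_qualifying_sample_is_single_sample_run(self, timeline):
        pos = np.arange(0, 40, 2.0)
        x = np.full(pos.size, 100.0)
        x[10] = 250.0
        runs = b.find_runs(x, pos, timeline, baseline=100.0)
        assert len(runs) == 1
        assert runs[0].n_samples == 1
        assert classify_runs(runs)[0].classification == "spike"

    def test_twelve_month_elevation_spans_about_20cm(self, timeline):
        pos = np.arange(0, 64, 2.0)
        x = np.full(pos.size, 100.0)
        x[(pos >= 20) & (pos <= 40)] = 300.0  # 20 cm at 20 cm/yr = 12 months
        (run,) = b.find_runs(x, pos, timeline, baseline=100.0)
        assert run.end_cm - run.start_cm == pytest.approx(20.0)
        assert run.duration_months == pytest.approx(12 + 1.2, abs=0.2)  # + half spacings

    def test_one_interior_dip_tolerated_two_not(self, timeline):
        pos = np.arange(0, 40, 2.0)
        x = np.full(pos.size, 300.0)
        x[0] = x[-1] = 100.0
        one_dip = x.copy()
        one_dip[8] = 100.0
        assert len(b.find_runs(one_dip, pos, timeline, baseline=100.0)) == 1
        two_dips = x.copy()
        two_dips[8] = two_dips[9] = 100.0
        assert len(b.find_runs(two_dips, pos, timeline, baseline=100.0)) == 2
        assert len(b.find_runs(one_dip, pos, timeline, 100.0, dip_tolerance=False)) == 2

    @given(seed=st.integers(0, 30))
    def test_runs_disjoint_and_ordered(self, seed):
        timeline = Chronology.from_constant_rate(20.0, dt.date(2001, 7, 14))
        rng = np.random.default_rng(seed)
        pos = np.arange(0, 64, 2.0)
        x = rng.lognormal(np.log(120), 0.6, pos.size)
        runs = b.find_runs(x, pos, timeline, baseline=120.0)
        for r1, r2 in zip(runs, runs[1:]):
            assert r1.end_cm < r2.start_cm

    def test_nonpositive_baseline_rejected(self, timeline):
        with pytest.raises(BaleendoError):
            b.find_runs(np.array([1.0]), np.array([0.0]), timeline, baseline=0.0)


class TestClassifyRun:
    def _run(self, months, n=8, peak_pct=266.0):
        return b.ElevationRun(
            start_cm=0, end_cm=10, start_date=dt.date(1999, 1, 1),
            end_date=dt.date(2000, 1, 1), duration_months=months,
            peak_value_ng_g=500.0, peak_percent_above_baseline=peak_pct, n_samples=n,
        )

    def test_twelve_months_is_full_term(self):
        assert b.classify_run(self._run(12.0)) == "full_term_pregnancy"

    def test_three_months_is_short_elevation(self):
        assert b.classify_run(self._run(3.0, peak_pct=133.0)) == "short_elevation"

    def test_boundary_ten_months_is_short(self):
        assert b.classify_run(self._run(10.0)) == "short_elevation"

    def test_single_sample_is_spike_regardless_of_duration(self):
        assert b.classify_run(self._run(12.0, n=1)) == "spike"

    @given(months=st.lists(st.floats(0.1, 30, allow_nan=False), min_size=2, max_size=10))
    def test_monotone_in_duration(self, months):
        order = {"spike": 0, "short_elevation": 0, "full_term_pregnancy": 1}
        ranks = [order[b.classify_run(self._run(m))] for m in sorted(months)]
        assert ranks == sorted(ranks)


class TestFoetalDating:
    def test_seak1473_conception_february(self):
        call = b.conception_from_foetus(168.0, dt.date(2009, 10, 1))
        assert (call.conception_date.year, call.conception_date.month) == (2009, 2)

    def test_seak68_conception_march(self):
        call = b.conception_from_foetus(39.2, dt.date(2001, 7, 14))
        assert (call.conception_date.year, call.conception_date.month) == (2001, 3)

    def test_calibration_knot_identity(self):
        model = b.FoetalGrowthModel()
        assert model.age_months(39.2) == 4.0
        assert model.age_months(168.0) == 8.0

    def test_length_out_of_range_is_error(self):
        with pytest.raises(BaleendoError):
            b.FoetalGrowthModel().age_months(900.0)


class TestBirthProjectionAndIntervals:
    def test_january_plus_12_is_next_january(self):
        assert b.project_birth(dt.date(1999, 1, 15)) == dt.date(2000, 1, 15)

    def test_feb_2009_plus_12_is_feb_2010(self):
        assert b.project_birth(dt.date(2009, 2, 1)) == dt.date(2010, 2, 1)

    def test_gestation_10_vs_12_shifts_two_months(self):
        d10 = b.project_birth(dt.date(1999, 1, 15), 10)
        d12 = b.project_birth(dt.date(1999, 1, 15), 12)
        assert (d12.year - d10.year) * 12 + d12.month - d10.month == 2

    def test_month_arithmetic_rollover_and_day_clamp(self):
        assert add_months(dt.date(1999, 11, 30), 3) == dt.date(2000, 2, 29)
        assert add_months(dt.date(2000, 3, 31), -1) == dt.date(2000, 2, 29)

    def test_interval_2yr_and_3yr(self):
        iv1 = b.calving_intervals([dt.date(1999, 12, 15), dt.date(2002, 1, 15)])
        assert iv1[0].years == 2
        iv2 = b.calving_intervals([dt.date(2007, 1, 15), dt.date(2010, 2, 1)])
        assert iv2[0].years == 3
        assert iv2[0].exact_years == pytest.approx(3.05, abs=0.01)

    def test_single_birth_no_interval(self):
        assert b.calving_intervals([dt.date(2000, 1, 1)]) == []

    def test_birth_from_calf_sighting_maps_to_prior_anchor(self):
        assert birth_from_calf_sighting(dt.date(2000, 7, 2), 1) == dt.date(2000, 1, 15)
        # sighting before the calving month belongs to the prior winter
        assert birth_from_calf_sighting(dt.date(2000, 1, 2), 2) == dt.date(1999, 2, 15)


class TestLabelStatus:
    def test_no_calls_all_not_pregnant(self, timeline):
        labels = b.label_status(np.arange(0, 20, 2.0), timeline, [])
        assert set(labels) == {"not_pregnant"}

    def test_labels_match_simulator_truth(self, noise_free_scenario):
        plate, truth = b.deposit_plate(noise_free_scenario)
        scen = truth.scenario
        timeline = Chronology.from_constant_rate(18.0, scen.death_date)
        conception, birth = truth.term_windows[0]
        calls = [b.PregnancyCall(conception, birth, source="sighting")]
        labels = b.label_status(plate.positions_cm, timeline, calls)
        mismatches = (labels != truth.table["status"].to_numpy()).sum()
        assert mismatches <= 2  # at most one sample per boundary

    def test_seak68_like_label_counts(self):
        """A 30-sample plate with two pregnancy periods labels roughly
        11 pregnant / 19 not, matching the published group sizes."""
        death = dt.date(2001, 7, 14)
        timeline = Chronology.from_constant_rate(17.0, death)
        pos = np.arange(0, 60, 2.0)  # 30 samples
        calls = [
            b.PregnancyCall(dt.date(1999, 1, 15), dt.date(1999, 12, 15), source="sighting"),
            b.PregnancyCall(dt.date(2001, 3, 15), dt.date(2002, 3, 15), source="foetus_at_necropsy"),
        ]
        labels = b.label_status(pos, timeline, calls)
        n_preg = int((labels == "pregnant").sum())
        assert abs(n_preg - 11) <= 2
        assert n_preg + int((labels == "not_pregnant").sum()) == 30


class TestCallingBaseline:
    def test_converges_to_nonpregnant_level_despite_elevated_majority(self):
        """With >half the plate pregnancy-elevated the plate mean is far
        above the non-pregnant level; iterative run exclusion recovers it."""
        death = dt.date(2002, 7, 5)
        timeline = Chronology.from_constant_rate(18.0, death)
        scen = b.SimScenario(
            seed=5, assay_cv=0.0, spike_rate_per_cm=0.0, d15N_noise_sd=0.0,
            years_covered=4.5, bgr_per_year=(18.0,) * 5, death_date=death,
            pregnancy_windows=(
                b.PregnancyWindow(dt.date(1998, 3, 15)),
                b.PregnancyWindow(dt.date(2000, 1, 15)),
                b.PregnancyWindow(dt.date(2001, 9, 15)),
            ),
        )
        plate, truth = b.deposit_plate(scen)
        pos, p4 = plate.series("progesterone_ng_g")
        assert np.mean(truth.table["status"] == "pregnant") > 0.5
        base = estimate_calling_baseline(p4, pos, timeline)
        assert base == pytest.approx(scen.baseline_p4_ng_g, rel=0.05)
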