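"""Forward simulator: life history, latent hormone kernel, deposition."""

import datetime as dt

import numpy as np
import pytest

import baleendo as b
from baleendo.config import DAYS_PER_MONTH
from baleendo.errors import ScenarioError
from baleendo.simulate import LifeEvent, sample_scenario


def _scenario(**kw):
    defaults = dict(
        seed=0,
        assay_cv=0.0,
        spike_rate_per_cm=0.0,
        d15N_noise_sd=0.0,
        pregnancy_windows=(b.PregnancyWindow(dt.date(1999, 1, 15)),),
    )
    defaults.update(kw)
    return b.SimScenario(**defaults)


class TestLifeHistory:
    def test_two_term_pregnancies_resting_year_interval_2yr(self):
        scen = _scenario(
            years_covered=4.5,
            bgr_per_year=(18.0,) * 5,
            death_date=dt.date(2002, 7, 5),
            pregnancy_windows=(
                b.PregnancyWindow(dt.date(1998, 1, 15)),
                b.PregnancyWindow(dt.date(2000, 1, 15)),
            ),
        )
        events = b.simulate_life_history(scen)
        births = sorted(e.date for e in events if e.kind == "birth")
        assert len(births) == 2
        assert (births[1] - births[0]).days / 365.25 == pytest.approx(2.0, abs=0.05)

    def test_conception_jan_1999_birth_in_dec_jan_window(self):
        events = b.simulate_life_history(_scenario())
        birth = next(e.date for e in events if e.kind == "birth")
        assert dt.date(1999, 12, 1) <= birth <= dt.date(2000, 1, 31)

    def test_failed_pregnancy_truncates_at_month(self):
        scen = _scenario(
            pregnancy_windows=(
                b.PregnancyWindow(dt.date(1999, 1, 15), outcome="failed", failed_at_month=3.0),
            )
        )
        events = b.simulate_life_history(scen)
        fail = next(e for e in events if e.kind == "failure")
        assert (fail.date - dt.date(1999, 1, 15)).days == pytest.approx(
            3 * DAYS_PER_MONTH, abs=1
        )

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ScenarioError):
            _scenario(
                pregnancy_windows=(
                    b.PregnancyWindow(dt.date(1999, 1, 15)),
                    b.PregnancyWindow(dt.date(1999, 9, 15)),
                )
            )

    def test_bgr_outside_plausible_band_rejected(self):
        with pytest.raises(ScenarioError):
            _scenario(bgr_per_year=(8.0, 18.0, 18.0, 18.0))


class TestLatentKernel:
    def test_baseline_outside_pregnancy_exactly(self):
        scen = _scenario()
        latent = b.latent_progesterone(b.simulate_life_history(scen), scen)
        assert latent(dt.date(1998, 6, 1)) == scen.baseline_p4_ng_g
        assert latent(dt.date(2000, 6, 1)) == scen.baseline_p4_ng_g

    def test_maximum_at_three_quarters_gestation(self):
        scen = _scenario()
        latent = b.latent_progesterone(b.simulate_life_history(scen), scen)
        conception = dt.date(1999, 1, 15)
        t_peak = conception + dt.timedelta(days=round(0.75 * 12 * DAYS_PER_MONTH))
        peak_val = latent(t_peak)
        grid = [conception + dt.timedelta(days=i) for i in range(0, 430)]
        assert peak_val == max(latent(d) for d in grid)

    def test_peak_equals_baseline_times_multiplier(self):
        scen = _scenario(baseline_p4_ng_g=132.44, pregnancy_multiplier=3.66)
        latent = b.latent_progesterone(b.simulate_life_history(scen), scen)
        conception = dt.date(1999, 1, 15)
        t_peak = conception + dt.timedelta(days=round(0.75 * 12 * DAYS_PER_MONTH))
        assert latent(t_peak) == pytest.approx(484.8, rel=0.01)

    def test_continuity_at_piece_boundaries(self):
        scen = _scenario()
        latent = b.latent_progesterone(b.simulate_life_history(scen), scen)
        conception = dt.date(1999, 1, 15)
        for months in (0.0, scen.onset_rise_months, 9.0, 13.0):
            t = conception + dt.timedelta(days=round(months * DAYS_PER_MONTH))
            before = latent(t - dt.timedelta(days=1))
            after = latent(t + dt.timedelta(days=1))
            step = scen.baseline_p4_ng_g * scen.pregnancy_multiplier / 8
            assert abs(after - before) < step  # no jumps larger than a day's slope


class TestDepositPlate:
    def test_sample_count_3p5yr_at_18(self):
        plate, _ = b.deposit_plate(_scenario())
        assert plate.n_samples in (31, 32)

    def test_noise_free_plate_equals_latent(self):
        scen = _scenario()
        plate, truth = b.deposit_plate(scen)
        assert np.allclose(
            plate.data["progesterone_ng_g"].to_numpy(),
            truth.table["latent_p4_ng_g"].to_numpy(),
        )

    def test_d15n_range_twice_amplitude(self):
        scen = _scenario(d15N_amplitude=1.2)
        plate, _ = b.deposit_plate(scen)
        d15n = plate.data["d15N_permil"].to_numpy()
        assert np.ptp(d15n) == pytest.approx(2 * 1.2, abs=0.1)

    def test_truth_dates_strictly_decrease_with_position(self):
        _, truth = b.deposit_plate(_scenario())
        dates = [dt.date.fromisoformat(d) for d in truth.table["true_date"]]
        assert all(a > b_ for a, b_ in zip(dates, dates[1:]))

    def test_status_transitions_only_at_events(self):
        scen = _scenario()
        _, truth = b.deposit_plate(scen)
        status = truth.table["status"].to_numpy()
        changes = (status[:-1] != status[1:]).sum()
        assert changes == 2  # one pregnancy fully inside the plate

    def test_peak_count_matches_years_covered(self):
        for seed in range(5):
            plate, truth = b.deposit_plate(b.SimScenario(seed=seed))
            pos, d15n = plate.series("d15N_permil")
            sm = b.smooth_d15n(d15n)
            peaks = b.detect_peaks(pos, sm, 5.0)
            years = truth.scenario.years_covered
            assert int(years) - 1 <= len(peaks) <= int(years) + 1

    def test_seed_reproducibility(self):
        p1, _ = b.deposit_plate(b.SimScenario(seed=9))
        p2, _ = b.deposit_plate(b.SimScenario(seed=9))
        assert p1.data.equals(p2.data)


def test_sample_scenario_draws_valid_study_conditions(rng):
    for _ in range(20):
        scen = sample_scenario(rng)
        assert all(16.0 <= r <= 24.0 for r in scen.bgr_per_year)
        terms = [w for w in scen.pregnancy_windows if w.outcome == "term"]
        assert len(terms) == 1
        events = b.simulate_life_history(scen)
        assert any(isinstance(e, LifeEvent) and e.kind == "birth" for e in events)
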