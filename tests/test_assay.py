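"""Immunoassay reduction: 4PL curve, percent bound, triage, mass balance."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import baleendo as b
from baleendo.assay import (
    MANUFACTURER_SENSITIVITY_PG_ML,
    duplicate_cv_percent,
    serial_dilution_concentrations,
)
from baleendo.config import ExtractionParams
from baleendo.errors import AssayQCError, CurveFitError, ExtrapolationError

TRUE = dict(lower=0.1, upper=2.0, ec50=400.0, slope=1.1)


def _standards(noise=0.0, rng=None, concs=None):
    concs = serial_dilution_concentrations() if concs is None else concs
    curve = b.StandardCurve(TRUE["lower"], TRUE["upper"], TRUE["ec50"], TRUE["slope"])
    wells = []
    for c in concs:
        for rep in (0, 1):
            od = float(curve.response(c))
            if noise:
                od += rng.normal(0, noise)
            wells.append(
                b.AssayWell(f"std{c:g}", rep, od, role="standard", concentration_pg_ml=c)
            )
    return wells


class TestStandardCurve:
    def test_serial_dilution_spans_25_to_3200(self):
        concs = serial_dilution_concentrations(3200.0, 8)
        assert concs[0] == 3200.0
        assert concs[-1] == pytest.approx(25.0)

    def test_noise_free_parameters_recovered(self):
        fit = b.fit_standard_curve(_standards())
        assert fit.lower_asymptote == pytest.approx(TRUE["lower"], rel=1e-6)
        assert fit.upper_asymptote == pytest.approx(TRUE["upper"], rel=1e-6)
        assert fit.ec50_pg_ml == pytest.approx(TRUE["ec50"], rel=1e-6)
        assert fit.slope == pytest.approx(TRUE["slope"], rel=1e-6)

    def test_od_at_midpoint_returns_ec50(self):
        fit = b.fit_standard_curve(_standards())
        mid_od = (fit.lower_asymptote + fit.upper_asymptote) / 2
        assert fit.od_to_concentration(mid_od) == pytest.approx(fit.ec50_pg_ml, rel=1e-9)

    @given(conc=st.floats(25.0, 3200.0, allow_nan=False))
    def test_inverse_property_within_valid_range(self, conc):
        curve = b.StandardCurve(**{
            "lower_asymptote": TRUE["lower"],
            "upper_asymptote": TRUE["upper"],
            "ec50_pg_ml": TRUE["ec50"],
            "slope": TRUE["slope"],
        })
        assert curve.od_to_concentration(float(curve.response(conc))) == pytest.approx(
            conc, rel=1e-9
        )

    def test_refuses_extrapolation(self):
        fit = b.fit_standard_curve(_standards())
        low_od = float(fit.response(10.0))  # below 25 pg/ml
        with pytest.raises(ExtrapolationError):
            fit.od_to_concentration(low_od)

    def test_too_few_levels_is_error(self):
        with pytest.raises(CurveFitError):
            b.fit_standard_curve(_standards(concs=np.array([3200.0, 800, 200, 50])))

    def test_non_monotone_standards_is_error(self):
        wells = _standards()
        bad = b.AssayWell("std800", 0, 1.9, role="standard", concentration_pg_ml=800.0)
        with pytest.raises(CurveFitError):
            b.fit_standard_curve(wells + [bad, bad])


class TestPercentBound:
    def test_b0_is_100(self):
        assert b.percent_bound(2.0, b0=2.0, nsb=0.1) == 100.0

    def test_nsb_is_0(self):
        assert b.percent_bound(0.1, b0=2.0, nsb=0.1) == 0.0

    def test_midway_is_50(self):
        assert b.percent_bound(1.05, b0=2.0, nsb=0.1) == pytest.approx(50.0)

    def test_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            assert b.percent_bound(2.5, b0=2.0, nsb=0.1) == 100.0

    def test_b0_not_above_nsb_is_error(self):
        with pytest.raises(AssayQCError):
            b.percent_bound(1.0, b0=0.1, nsb=0.2)


class TestTriage:
    @pytest.fixture
    def curve(self):
        return b.fit_standard_curve(_standards())

    def _wells(self, ods, dilution=4):
        return [
            b.AssayWell("s", i, od, role="sample", dilution_factor=dilution)
            for i, od in enumerate(ods)
        ]

    def test_low_percent_bound_redilutes_one_step(self, curve):
        od = 0.1 + 0.03 * 1.9  # 3% bound
        assert b.triage_sample(self._wells([od, od]), curve, 2.0, 0.1) == "redilute_16"
        assert (
            b.triage_sample(self._wells([od, od], dilution=16), curve, 2.0, 0.1)
            == "redilute_64"
        )

    def test_high_duplicate_cv_reassays(self, curve):
        # duplicates reading 100 and 125 pg/ml: CV 15.7% > 10%
        ods = [float(curve.response(100.0)), float(curve.response(125.0))]
        assert duplicate_cv_percent([100.0, 125.0]) == pytest.approx(15.71, abs=0.01)
        assert b.triage_sample(self._wells(ods), curve, 2.0, 0.1) == "reassay"

    def test_equal_duplicates_accepted_and_idempotent(self, curve):
        ods = [float(curve.response(400.0))] * 2
        wells = self._wells(ods)
        assert b.triage_sample(wells, curve, 2.0, 0.1) == "accept"
        assert b.triage_sample(wells, curve, 2.0, 0.1) == "accept"

    def test_single_replicate_reassays(self, curve):
        assert b.triage_sample(self._wells([1.0]), curve, 2.0, 0.1) == "reassay"


class TestMassBalance:
    def test_worked_example_35_56(self):
        assert b.to_ng_per_g(1000.0, 4) == pytest.approx(35.56, abs=0.01)

    def test_zero_is_zero(self):
        assert b.to_ng_per_g(0.0, 4) == 0.0

    @given(
        conc=st.floats(1, 3000, allow_nan=False),
        dilution=st.sampled_from([1, 4, 16, 64]),
        scale=st.floats(0.5, 3.0, allow_nan=False),
    )
    def test_linearity_and_volume_scaling_invariance(self, conc, dilution, scale):
        base = b.to_ng_per_g(conc, dilution)
        assert b.to_ng_per_g(2 * conc, dilution) == pytest.approx(2 * base, rel=1e-12)
        assert b.to_ng_per_g(conc, 2 * dilution) == pytest.approx(2 * base, rel=1e-12)
        scaled = ExtractionParams(
            solvent_volume_ml=4.0 * scale, aliquot_volume_ml=3.0 * scale
        )
        assert b.to_ng_per_g(conc, dilution, scaled) == pytest.approx(base, rel=1e-12)

    def test_sensitivity_recorded_not_enforced(self):
        # the curve's low standard (25) sits below the kit sensitivity
        assert serial_dilution_concentrations()[-1] < MANUFACTURER_SENSITIVITY_PG_ML
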