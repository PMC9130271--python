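import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phryno import ecophys
from phryno.ecophys import (MetabolicConstants, ThermoregSample, band_deviations,
                            effectiveness, fit_allometry, mass_corrected_mr,
                            metabolic_B, metabolic_I, predict_mass, production,
                            temp_corrected_mr)

REFERENCE_ALLOMETRY = (3.355, -5.065)


class TestThermoregulation:
    def test_hand_enumerated_deviations(self):
        db = band_deviations([30, 32, 36], 31, 34)
        np.testing.assert_allclose(db, [1, 0, 2])
        s = ThermoregSample(np.array([30.0, 32, 36]), np.array([31.0]), 31, 34)
        assert s.deviations()[0] == pytest.approx(1.0)

    def test_inside_range_and_boundary_are_zero(self):
        assert band_deviations([31, 32, 34], 31, 34).sum() == 0.0
        s = ThermoregSample(np.array([32.0]), np.array([31.0, 31.0]), 31, 34)
        assert s.deviations()[1] == 0.0

    def test_effectiveness_values(self):
        assert effectiveness(0.0, 5.0) == 1.0
        assert effectiveness(2.0, 2.0) == 0.0
        assert effectiveness(1.0, 6.0) == pytest.approx(0.8333, abs=1e-4)

    def test_effectiveness_undefined_on_perfect_habitat(self):
        with pytest.raises(ZeroDivisionError):
            effectiveness(0.5, 0.0)

    def test_invalid_band_and_empty_sample(self):
        with pytest.raises(ValueError):
            band_deviations([30.0], 34, 31)
        with pytest.raises(ValueError):
            band_deviations([], 31, 34)

    def test_deviations_invariant_to_order_and_duplication(self):
        tb = np.array([29.0, 33.5, 36.0, 31.2])
        s1 = ThermoregSample(tb, tb, 31, 34)
        s2 = ThermoregSample(tb[::-1], np.tile(tb, 3), 31, 34)
        assert s1.deviations()[0] == pytest.approx(s2.deviations()[0])
        assert s1.deviations()[1] == pytest.approx(s2.deviations()[1])


class TestMetabolicRate:
    def test_normalization_constant_recovered_at_zero_activation(self):
        c = MetabolicConstants(E_act=0.0)
        assert metabolic_I(1.0, 35.0, c) == pytest.approx(math.log(20.3))

    def test_three_quarter_power_scaling(self):
        r = metabolic_I(2.0, 30.0) / metabolic_I(1.0, 30.0)
        assert r == pytest.approx(2 ** 0.75, rel=1e-12)

    def test_reference_point(self):
        # frozen from exact arithmetic: ln(20.3) 10^{3/4} e^{-0.63/(k 308.15 K)}
        assert metabolic_I(10.0, 35.0) == pytest.approx(8.4147e-10, rel=1e-4)
        assert metabolic_B(10.0, 35.0) == pytest.approx(8.4147e-11, rel=1e-4)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.floats(0.1, 500.0), st.floats(0.0, 45.0))
    def test_mass_specific_identity(self, M, T):
        assert metabolic_B(M, T) * M == pytest.approx(metabolic_I(M, T), rel=1e-12)

    def test_log_scale_variant_is_log_of_multiplicative_form(self):
        assert metabolic_I(7.0, 28.0, log_scale=True) == pytest.approx(
            math.log(metabolic_I(7.0, 28.0)), rel=1e-12)

    def test_B_monotone_decreasing_in_mass(self):
        masses = np.geomspace(0.5, 200, 30)
        b = metabolic_B(masses, 30.0)
        assert np.all(np.diff(b) < 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            metabolic_I(0.0, 30.0)
        with pytest.raises(ValueError):
            metabolic_I(1.0, -300.0)


class TestCorrectedRates:
    def test_temp_corrected_at_unit_mass(self):
        assert temp_corrected_mr(1.0) == 18.02

    def test_temp_corrected_log_linearity(self):
        assert temp_corrected_mr(math.e) == pytest.approx(18.73)
        assert temp_corrected_mr(5 * math.e) - temp_corrected_mr(5.0) \
            == pytest.approx(0.71, rel=1e-9)

    def test_mass_corrected_value_and_monotonicity(self):
        assert mass_corrected_mr(30.0) == pytest.approx(-6.113, abs=1e-3)
        temps = np.linspace(5, 45, 20)
        assert np.all(np.diff(mass_corrected_mr(temps)) > 0)


class TestAllometry:
    def test_exact_power_law_recovered(self):
        svl = np.array([40, 55, 62, 80, 95.0])
        mass = 10 ** (-5.0) * svl ** 3.2
        fit = fit_allometry(svl, mass)
        assert fit.slope == pytest.approx(3.2, abs=1e-10)
        assert fit.intercept == pytest.approx(-5.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_slope_matches_closed_form_ols(self, rng):
        svl = rng.uniform(30, 120, 10)
        mass = rng.uniform(1, 60, 10)
        fit = fit_allometry(svl, mass)
        x, y = np.log10(svl), np.log10(mass)
        want = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert fit.slope == pytest.approx(want, rel=1e-12)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            fit_allometry([50, 50, 50], [5, 6, 7])

    def test_mass_prediction(self):
        assert predict_mass(100.0, REFERENCE_ALLOMETRY) == pytest.approx(44.16, abs=0.01)
        slope, inter = REFERENCE_ALLOMETRY
        unit_svl = 10 ** (-inter / slope)
        assert predict_mass(unit_svl, REFERENCE_ALLOMETRY) == pytest.approx(1.0)
        svls = np.linspace(30, 140, 25)
        assert np.all(np.diff(predict_mass(svls, REFERENCE_ALLOMETRY)) > 0)


class TestProduction:
    def test_arithmetic(self):
        assert production(0.5, 10, 10.0) == pytest.approx(0.5)
        assert production(0.5, 0, 10.0) == 0.0

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.floats(0.01, 5), st.floats(0, 40), st.floats(0.5, 100))
    def test_linear_in_numerator(self, om, af, fm):
        assert production(2 * om, af, fm) == pytest.approx(2 * production(om, af, fm))

    def test_nonpositive_female_mass_rejected(self):
        with pytest.raises(ValueError):
            production(0.5, 3, 0.0)


def test_species_energetics_identities(study):
    tr = study.traits
    ok = tr[["I", "B", "mass"]].dropna()
    np.testing.assert_allclose(ok["B"] * ok["mass"], ok["I"], rtol=1e-12)
    ok = tr[["db_bar", "de_bar", "E"]].dropna()
    np.testing.assert_allclose(1 - ok["db_bar"] / ok["de_bar"], ok["E"], rtol=1e-12)
    af = tr[["clutch_size", "clutches_per_year", "annual_fecundity"]].dropna()
    np.testing.assert_allclose(af["clutch_size"] * af["clutches_per_year"],
                               af["annual_fecundity"], rtol=1e-12)
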