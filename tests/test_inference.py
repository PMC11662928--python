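"""Condition-level model fits: isotherm, saturating rate, Bell, oligo time."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from npkinetics.inference import (
    bell_rate,
    fit_bell,
    fit_langmuir,
    fit_oligo_time,
    fit_saturating_rate,
    occupancy_from_extension,
)


class TestOccupancy:
    def test_endpoints_and_midpoint(self):
        assert occupancy_from_extension(0.30, 0.30, 0.10) == 0.0
        assert occupancy_from_extension(0.10, 0.30, 0.10) == 1.0
        assert occupancy_from_extension(0.20, 0.30, 0.10) == pytest.approx(0.5)

    def test_degenerate_bounds_rejected(self):
        with pytest.raises(ValueError):
            occupancy_from_extension(0.2, 0.1, 0.1)

    def test_out_of_range_clipped_with_warning(self):
        with pytest.warns(UserWarning):
            theta = occupancy_from_extension(0.05, 0.30, 0.10)
        assert theta == 1.0


class TestLangmuir:
    def test_exact_self_consistency(self):
        c = np.array([0.5, 1, 3, 10, 30, 90.0])
        pts = list(zip(c, c / (c + 3.0)))
        fit = fit_langmuir(pts)
        assert fit.K_half == pytest.approx(3.0, rel=1e-6)
        assert fit.residual_rms < 1e-7

    def test_all_zero_occupancy_rejected(self):
        with pytest.raises(ValueError, match="no information"):
            fit_langmuir([(1, 0.0), (3, 0.0), (10, 0.0)])

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_langmuir([(1, 0.2), (1, 0.21), (3, 0.5)])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 20.0), K=st.floats(0.5, 10.0))
    def test_scale_equivariance(self, scale, K):
        c = np.array([0.5, 1, 3, 10, 30, 90.0])
        pts = list(zip(c, c / (c + K)))
        pts_scaled = [(s * scale, th) for s, th in pts]
        K1 = fit_langmuir(pts).K_half
        K2 = fit_langmuir(pts_scaled).K_half
        assert K2 == pytest.approx(K1 * scale, rel=1e-4)


class TestSaturatingRate:
    @staticmethod
    def model(c, a, b):
        return a * c * b / (a * c + b)

    def test_exact_self_consistency(self):
        c = np.array([1, 3, 10, 30, 90.0])
        pts = list(zip(c, self.model(c, 0.042, 0.45)))
        fit = fit_saturating_rate(pts)
        assert fit.bimolecular == pytest.approx(0.042, rel=1e-7)
        assert fit.asymptote == pytest.approx(0.45, rel=1e-7)

    def test_low_concentration_slope_is_bimolecular(self):
        fit = fit_saturating_rate(
            [(c, self.model(c, 0.042, 0.45)) for c in (1, 3, 10, 30, 90)])
        eps = 1e-6
        slope = fit.predict(eps) / eps
        assert slope == pytest.approx(fit.bimolecular, rel=1e-4)

    def test_recompaction_term_subtraction(self):
        c = np.array([1, 3, 10, 30, 90.0])
        k = self.model(c, 0.029, 0.15) + 0.11 * 3.0 / (3.0 + c)
        fit = fit_saturating_rate(list(zip(c, k)), recompaction_k0=0.11,
                                  recompaction_Kr=3.0)
        assert fit.bimolecular == pytest.approx(0.029, rel=1e-6)
        assert fit.asymptote == pytest.approx(0.15, rel=1e-6)

    def test_degenerate_design_rejected(self):
        with pytest.raises(ValueError):
            fit_saturating_rate([(3, 0.1), (3, 0.11), (3, 0.12)])
        with pytest.raises(ValueError):
            fit_saturating_rate([(1, 0.1), (3, 0.2), (10, 0.3)],
                                recompaction_k0=0.1)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(scale=st.floats(0.1, 20.0))
    def test_scale_equivariance(self, scale):
        c = np.array([1, 3, 10, 30, 90.0])
        pts = list(zip(c, self.model(c, 0.042, 0.45)))
        scaled = [(s * scale, k) for s, k in pts]
        f1 = fit_saturating_rate(pts)
        f2 = fit_saturating_rate(scaled)
        assert f2.bimolecular == pytest.approx(f1.bimolecular / scale,
                                               rel=1e-5)
        assert f2.asymptote == pytest.approx(f1.asymptote, rel=1e-5)


class TestBell:
    def test_zero_length_is_force_independent(self):
        F = np.array([10.0, 30.0, 50.0])
        np.testing.assert_allclose(bell_rate(0.01, 0.0, F, 4.06), 0.01)

    def test_unit_exponent(self):
        # F*dx = kBT  =>  k = e * k_0
        assert bell_rate(0.01, 4.06 / 10.0, 10.0, 4.06) \
            == pytest.approx(0.01 * np.e, rel=1e-12)

    def test_two_point_closed_form(self):
        """(10 pN, 0.01) and (50 pN, 0.1) give dx = kBT ln(10)/40."""
        fit = fit_bell([(10.0, 0.01), (50.0, 0.1)], kBT=4.06)
        assert fit.delta_x == pytest.approx(4.06 * np.log(10) / 40.0,
                                            rel=1e-9)
        assert fit.delta_x == pytest.approx(0.2337, abs=2e-4)

    def test_roundtrip_recovery(self):
        F = np.array([5.0, 15.0, 30.0, 45.0])
        k = bell_rate(0.004, -0.31, F, 4.0615)
        fit = fit_bell(list(zip(F, k)), kBT=4.0615)
        assert fit.k_0 == pytest.approx(0.004, rel=1e-9)
        assert fit.delta_x == pytest.approx(-0.31, rel=1e-9)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            fit_bell([(10.0, 0.0), (50.0, 0.1)])


class TestOligoTime:
    def test_exact_self_consistency(self):
        t = np.array([5, 25, 50, 100, 200, 400, 800.0])
        k = 0.010 + (0.11 - 0.010) * np.exp(-t / 100.0)
        fit = fit_oligo_time(list(zip(t, k)))
        assert fit.k_0 == pytest.approx(0.11, rel=1e-7)
        assert fit.k_inf == pytest.approx(0.010, rel=1e-7)
        assert fit.tau == pytest.approx(100.0, rel=1e-7)
        assert fit.predict(0) == pytest.approx(0.11, rel=1e-7)
        assert fit.predict(1e9) == pytest.approx(0.010, rel=1e-7)

    def test_too_few_times_rejected(self):
        with pytest.raises(ValueError):
            fit_oligo_time([(5, 0.1), (100, 0.05), (800, 0.01)])

    def test_non_monotone_warns_but_fits(self):
        t = np.array([5, 50, 100, 200, 800.0])
        k = 0.010 + 0.1 * np.exp(-t / 100.0)
        k[2] *= 2.5  # gross outlier upward
        with pytest.warns(UserWarning, match="monotone"):
            fit = fit_oligo_time(list(zip(t, k)))
        assert fit.tau > 0
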