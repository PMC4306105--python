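"""Dean-number utilities and the curved-pipe secondary-flow solver."""

import math

import numpy as np
import pytest

from stentflow import (
    classify_dean_regime,
    dean_number,
    dean_series_oracle,
    solve_dean_cross_section,
)

CR = 0.15            # curvature ratio a/R of the study geometry


class TestDeanNumber:
    @pytest.mark.parametrize("Re,expected", [(200, 77.5), (400, 155.0),
                                             (600, 232.0), (800, 310.0)])
    def test_study_values_3sf(self, Re, expected):
        dn = dean_number(Re, 0.0015, 0.010)
        # round to 3 significant figures
        from math import floor, log10
        k = 2 - int(floor(log10(abs(dn))))
        assert round(dn, k) == pytest.approx(expected)

    def test_zero_reynolds(self):
        assert dean_number(0.0, 0.0015, 0.010) == 0.0

    def test_validation(self):
        with pytest.raises(ValueError):
            dean_number(100, 0.02, 0.01)     # r >= R
        with pytest.raises(ValueError):
            dean_number(-1, 0.0015, 0.01)


class TestRegime:
    def test_threshold_exclusive(self):
        assert classify_dean_regime(36.0) == "stable"
        assert classify_dean_regime(36.0001) == "unstable"
        assert classify_dean_regime(0.0) == "stable"

    def test_study_cases_unstable(self):
        for Re in (200, 400, 600, 800):
            assert classify_dean_regime(dean_number(Re, 0.0015, 0.010)) == "unstable"

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_dean_regime(-1.0)


class TestSeriesOracle:
    def test_zero_dean_is_poiseuille(self):
        sol = dean_series_oracle(0.0)
        rr = sol.r[:, None]
        assert np.allclose(sol.w, 2 * (1 - rr**2) * np.ones_like(sol.w))
        assert np.all(sol.psi == 0.0)
        assert not sol.series_warning

    def test_stream_function_antisymmetric(self):
        sol = dean_series_oracle(10.0)
        mirrored = np.roll(sol.psi[:, ::-1], 1, axis=1)   # theta -> -theta
        assert np.abs(sol.psi + mirrored).max() < 1e-12

    def test_validity_warning(self):
        assert dean_series_oracle(25.0).series_warning
        assert not dean_series_oracle(15.0).series_warning


class TestCrossSectionSolver:
    def test_straight_pipe_limit(self):
        sol = solve_dean_cross_section(0.0, CR, n_r=32, n_theta=64)
        rr = sol.r[:, None]
        hp = 2 * (1 - rr**2) * np.ones_like(sol.w)
        err = np.linalg.norm(sol.w - hp) / np.linalg.norm(hp)
        assert err < 0.005
        assert np.abs(sol.psi).max() == 0.0

    def test_matches_series_at_small_dean(self):
        Re = 10.0 / math.sqrt(CR)
        sol = solve_dean_cross_section(Re, CR)
        oracle = dean_series_oracle(sol.Dn_pressure)
        amp = np.abs(sol.psi).max() / np.abs(oracle.psi).max()
        assert amp == pytest.approx(1.0, abs=0.05)
        rel = np.linalg.norm(sol.psi - oracle.psi) / np.linalg.norm(oracle.psi)
        assert rel < 0.05

    def test_high_dean_trends(self, dean_sweep):
        sols = dean_sweep
        # axial-velocity maximum displaced toward the outer bend, more with Re
        xmax = [s.axial_max_location for s in sols]
        assert all(x > 0 for x in xmax)
        assert xmax[-1] > xmax[0]
        # secondary kinetic energy grows monotonically with Dn
        ke = [s.secondary_kinetic_energy for s in sols]
        assert all(b > a for a, b in zip(ke, ke[1:]))

    def test_peak_velocity_linear_in_reynolds(self, dean_sweep):
        sols = dean_sweep
        re_arr = np.array([s.Re for s in sols])
        # dimensional peak ~ peak_axial (mean-velocity units) * v_mean ~ Re
        peak = np.array([s.peak_axial for s in sols]) * re_arr
        fit = np.polyfit(re_arr, peak, 1)
        resid = peak - np.polyval(fit, re_arr)
        r2 = 1 - resid @ resid / np.sum((peak - peak.mean())**2)
        assert r2 > 0.99

    def test_symmetry_at_high_dean(self, dean_sweep):
        sol = dean_sweep[-1]
        anti = sol.psi + np.roll(sol.psi[:, ::-1], 1, axis=1)
        assert np.abs(anti).max() / np.abs(sol.psi).max() < 1e-6
        sym = sol.w - np.roll(sol.w[:, ::-1], 1, axis=1)
        assert np.abs(sym).max() / sol.w.max() < 1e-6

    def test_validation(self):
        with pytest.raises(ValueError):
            solve_dean_cross_section(200.0, 1.5)
        with pytest.raises(ValueError):
            solve_dean_cross_section(200.0, CR, n_theta=33)
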