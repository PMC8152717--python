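import math

import numpy as np
import pytest

from conftest import poiseuille_dp_mmHg
from coroflow.geometry import synth_stenosis_geometry
from coroflow.solver import (FluidProperties, FlowModel, PressureWaveform,
                             SolverSettings, mesh_convergence_check,
                             reduced_order_dp, reynolds_number,
                             reynolds_regime, solve_pulsatile_quasi_steady)


class TestForward:
    def test_poiseuille_limit(self, tube_model, analogue):
        """Straight tube at low Re reproduces the closed-form laminar drop."""
        sol = tube_model.forward(60.0)
        expect = poiseuille_dp_mmHg(analogue, 1.5e-3, 0.08, 60.0)
        assert sol.dP_mmHg == pytest.approx(expect, rel=0.02)
        assert sol.converged and sol.residual <= 1e-6

    def test_zero_flow_is_hydrostatic(self, tube_model):
        sol = tube_model.forward(0.0)
        assert sol.dP_mmHg == 0.0
        assert np.all(sol.u_z_m_s == 0.0)

    def test_negative_flow_rejected(self, tube_model):
        with pytest.raises(ValueError):
            tube_model.forward(-1.0)

    def test_mass_conserved_along_vessel(self, sten60_model):
        """Velocity-quadrature flux agrees between every pair of stations."""
        sol = sten60_model.forward(100.0)
        flux = sol.flux_profile_mL_min()
        # inlet and outlet fluxes agree to < 0.1%; interior stations (where
        # the narrow jet strains the quadrature) stay within 0.5%
        assert abs(flux[-1] - flux[0]) / flux[0] < 1e-3
        assert np.ptp(flux) / flux.mean() < 5e-3

    def test_deterministic(self, sten60, analogue):
        a = FlowModel(sten60, analogue).forward(80.0, resolution="coarse")
        b = FlowModel(sten60, analogue).forward(80.0, resolution="coarse")
        assert a.dP_mmHg == b.dP_mmHg
        assert np.array_equal(a.u_z_m_s, b.u_z_m_s)

    def test_pressure_drop_monotone_in_flow(self, sten72_model):
        dps = [sten72_model.forward(q).dP_mmHg for q in (50.0, 90.0, 130.0, 180.0)]
        assert all(b > a for a, b in zip(dps, dps[1:]))

    def test_stenotic_loss_between_linear_and_quadratic(self, sten72_model):
        """Doubling flow raises the drop by x2..x4 (viscous vs inertial bounds)."""
        dp1 = sten72_model.forward(90.0).dP_mmHg
        dp2 = sten72_model.forward(180.0).dP_mmHg
        assert 2.0 < dp2 / dp1 < 4.0
        slope = math.log(dp2 / dp1) / math.log(2.0)
        assert 1.0 < slope <= 2.0


class TestInverse:
    def test_recovers_poiseuille_flow(self, tube_model, analogue):
        dp = poiseuille_dp_mmHg(analogue, 1.5e-3, 0.08, 60.0)
        sol = tube_model.invert(dp)
        assert sol.Q_mL_min == pytest.approx(60.0, rel=0.01)

    def test_zero_gradient_zero_flow(self, tube_model):
        assert tube_model.invert(0.0).Q_mL_min == 0.0

    def test_negative_gradient_rejected(self, tube_model):
        with pytest.raises(ValueError):
            tube_model.invert(-2.0)

    def test_round_trip(self, sten60_model):
        dp = sten60_model.forward(75.0).dP_mmHg
        assert sten60_model.invert(dp).Q_mL_min == pytest.approx(75.0, rel=0.005)


class TestReducedOrder:
    def test_straight_tube_is_exact_poiseuille(self, tube, analogue):
        expect = poiseuille_dp_mmHg(analogue, 1.5e-3, 0.08, 60.0)
        assert reduced_order_dp(tube, analogue, 60.0) == pytest.approx(
            expect, rel=1e-3)

    def test_zero_flow(self, tube, analogue):
        assert reduced_order_dp(tube, analogue, 0.0) == 0.0

    def test_within_factor_two_of_solver(self, sten72_model, sten72, analogue):
        for q in (50.0, 90.0, 130.0, 180.0):
            full = sten72_model.forward(q).dP_mmHg  # cached from earlier tests
            approx = reduced_order_dp(sten72, analogue, q)
            assert 0.5 < approx / full < 2.0


class TestReynolds:
    def test_zero_flow(self, sten60, analogue):
        assert reynolds_number(sten60, analogue, 0.0) == 0.0

    def test_hand_value_at_throat(self, analogue):
        # 50% DS of a 3 mm vessel: throat D = 1.5 mm; V = Q/A = 1.132 m/s
        g = synth_stenosis_geometry(3.0, 80.0, 50.0)
        re = reynolds_number(g, analogue, 120.0)
        assert re == pytest.approx(525.0, rel=0.01)

    def test_regime_classification(self):
        assert reynolds_regime(499.0) == "physiological"
        assert reynolds_regime(501.0) == "supra-physiological"


class TestPulsatile:
    def test_constant_waveform_equals_steady(self, tube, analogue, tube_model):
        t = np.linspace(0.0, 1.0, 9)
        w = PressureWaveform(t, np.full(9, 90.0), np.full(9, 89.0), period_s=1.0)
        q_mean, _, q_series, flags = solve_pulsatile_quasi_steady(
            tube, analogue, w, model=tube_model)
        steady = tube_model.invert(1.0).Q_mL_min
        assert q_mean == pytest.approx(steady, rel=1e-9)
        assert np.allclose(q_series, steady)
        assert flags == []

    def test_sinusoid_on_viscous_tube_averages_linearly(self, tube, analogue,
                                                        tube_model):
        """Poiseuille response is linear, so mean flow = flow at mean drop."""
        t = np.linspace(0.0, 0.8, 17)
        dp = 1.0 + 0.3 * np.sin(2 * np.pi * t / 0.8)
        w = PressureWaveform(t, np.full(17, 90.0), 90.0 - dp, period_s=0.8)
        q_mean, *_ = solve_pulsatile_quasi_steady(tube, analogue, w,
                                                  model=tube_model)
        dp_mean = np.trapezoid(dp, t) / 0.8
        steady = tube_model.invert(float(dp_mean)).Q_mL_min
        assert q_mean == pytest.approx(steady, rel=0.005)

    def test_negative_gradient_samples_clipped_and_flagged(self, tube, analogue,
                                                           tube_model):
        t = np.linspace(0.0, 1.0, 5)
        pd = np.array([89.0, 91.0, 89.0, 89.0, 89.0])
        w = PressureWaveform(t, np.full(5, 90.0), pd, period_s=1.0)
        q_mean, _, q_series, flags = solve_pulsatile_quasi_steady(
            tube, analogue, w, model=tube_model)
        assert "negative-gradient-samples-clipped" in flags
        assert q_series[1] == 0.0

    def test_waveform_validation(self):
        with pytest.raises(ValueError):
            PressureWaveform(np.array([]), np.array([]), np.array([]))
        with pytest.raises(ValueError):
            PressureWaveform(np.array([0.0, 0.0]), np.array([90.0, 90.0]),
                             np.array([80.0, 80.0]))

    def test_waveform_shorter_than_period_rejected(self, tube, analogue):
        t = np.linspace(0.0, 0.4, 5)
        w = PressureWaveform(t, np.full(5, 90.0), np.full(5, 85.0), period_s=0.8)
        with pytest.raises(ValueError, match="period"):
            solve_pulsatile_quasi_steady(tube, analogue, w)


class TestMeshConvergence:
    def test_tube_inverse_converges_across_levels(self, tube, analogue):
        report = mesh_convergence_check(tube, analogue, 1.06,
                                        levels=("coarse", "standard"))
        assert report.passed
        assert report.rel_delta_fine_standard < 0.005

    def test_single_level_rejected(self, tube, analogue):
        with pytest.raises(ValueError):
            mesh_convergence_check(tube, analogue, 1.0, levels=("standard",))


class TestSettingsValidation:
    def test_bad_settings_rejected(self):
        with pytest.raises(ValueError):
            SolverSettings(residual_target=0.0)
        with pytest.raises(ValueError):
            SolverSettings(max_iterations=0)
        with pytest.raises(ValueError):
            SolverSettings(advection_scheme="quick")

    def test_bad_fluid_rejected(self):
        with pytest.raises(ValueError):
            FluidProperties(0.0, 1000.0)
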