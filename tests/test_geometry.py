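import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coroflow.geometry import (MESH_RESOLUTIONS, ProjectionTrace,
                               VesselGeometry, mesh_generate,
                               percent_diameter_stenosis,
                               reconstruct_axisymmetric,
                               synth_stenosis_geometry)


def _trace(angle, radii=None, n=20, length=40.0):
    s = np.linspace(0.0, length, n)
    r = np.full(n, 1.5) if radii is None else np.asarray(radii, dtype=float)
    return ProjectionTrace(acquisition_angle_deg=angle, arclength_mm=s,
                           projected_radius_mm=r)


class TestReconstruction:
    def test_identical_circular_traces(self):
        g = reconstruct_axisymmetric(_trace(0.0), _trace(90.0))
        assert np.allclose(g.radius_mm, 1.5)

    def test_geometric_mean_of_projected_radii(self):
        # elliptical lumen seen as 1.0 mm and 2.25 mm -> equivalent 1.5 mm
        g = reconstruct_axisymmetric(_trace(0.0, np.full(20, 1.0)),
                                     _trace(45.0, np.full(20, 2.25)))
        assert np.allclose(g.radius_mm, 1.5)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        r1 = 1.5 + 0.3 * rng.random(20)
        r2 = 1.5 + 0.3 * rng.random(20)
        g12 = reconstruct_axisymmetric(_trace(10.0, r1), _trace(55.0, r2))
        g21 = reconstruct_axisymmetric(_trace(55.0, r2), _trace(10.0, r1))
        assert np.array_equal(g12.radius_mm, g21.radius_mm)

    def test_insufficient_angle_rejected(self):
        with pytest.raises(ValueError, match="30 degrees"):
            reconstruct_axisymmetric(_trace(0.0), _trace(20.0))

    def test_angle_separation_wraps(self):
        # 350 and 30 degrees are only 40 degrees apart: accepted
        reconstruct_axisymmetric(_trace(350.0), _trace(30.0))

    def test_non_overlapping_ranges_rejected(self):
        far = ProjectionTrace(90.0, np.linspace(100, 140, 20), np.full(20, 1.5))
        with pytest.raises(ValueError, match="overlap"):
            reconstruct_axisymmetric(_trace(0.0), far)

    def test_resampling_preserves_length(self):
        g = reconstruct_axisymmetric(_trace(0.0, n=11), _trace(60.0, n=37))
        assert g.length_mm == pytest.approx(40.0, rel=1e-3)

    def test_station_spacing_bounded(self):
        g = reconstruct_axisymmetric(_trace(0.0), _trace(60.0))
        assert np.diff(g.arclength_mm).max() <= 0.25 + 1e-12


class TestSynthStenosis:
    def test_minimum_diameter_matches_percent_ds(self):
        g = synth_stenosis_geometry(3.0, 80.0, 50.0)
        assert 2 * g.radius_mm.min() == pytest.approx(1.5, abs=1e-6)

    def test_zero_percent_is_straight_tube(self):
        g = synth_stenosis_geometry(3.0, 80.0, 0.0)
        assert np.allclose(g.radius_mm, 1.5)

    def test_severe_phantom_within_bench_envelope(self):
        g = synth_stenosis_geometry(3.0, 80.0, 72.0)
        assert 2 * g.radius_mm.min() == pytest.approx(0.84, abs=1e-6)

    def test_reproducible_given_seed(self):
        a = synth_stenosis_geometry(3.0, 80.0, 60.0, seed=9, roughness=0.01)
        b = synth_stenosis_geometry(3.0, 80.0, 60.0, seed=9, roughness=0.01)
        assert np.array_equal(a.radius_mm, b.radius_mm)
        c = synth_stenosis_geometry(3.0, 80.0, 60.0, seed=10, roughness=0.01)
        assert not np.array_equal(a.radius_mm, c.radius_mm)

    def test_seed_irrelevant_without_roughness(self):
        a = synth_stenosis_geometry(3.0, 80.0, 60.0, seed=1)
        b = synth_stenosis_geometry(3.0, 80.0, 60.0, seed=2)
        assert np.array_equal(a.radius_mm, b.radius_mm)

    @settings(derandomize=True, max_examples=25)
    @given(st.floats(0.0, 85.0), st.floats(2.0, 4.5), st.floats(60.0, 90.0))
    def test_area_positive_and_continuous(self, ds, dia, length):
        g = synth_stenosis_geometry(dia, length, ds)
        area = g.area_mm2
        assert (area > 0).all()
        jumps = np.abs(np.diff(area)) / area[:-1]
        assert jumps.max() < 0.20

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            synth_stenosis_geometry(3.0, 80.0, 100.0)
        with pytest.raises(ValueError):
            synth_stenosis_geometry(-3.0, 80.0, 50.0)
        with pytest.raises(ValueError):
            synth_stenosis_geometry(3.0, 80.0, 50.0, stenosis_center_mm=2.0)


class TestPercentDS:
    def test_straight_tube_is_zero(self):
        assert percent_diameter_stenosis(
            synth_stenosis_geometry(3.0, 80.0, 0.0)) == 0.0

    def test_definition(self):
        g = synth_stenosis_geometry(3.0, 80.0, 50.0)
        assert percent_diameter_stenosis(g) == pytest.approx(50.0, abs=0.5)

    def test_tapered_vessel_with_proximal_distal_mean_rule(self):
        s = np.linspace(0.0, 60.0, 241)
        r = np.interp(s, [0, 60], [1.6, 1.4])       # taper 3.2 -> 2.8 mm
        dip = np.abs(s - 30.0) <= 5.0
        r[dip] = np.minimum(r[dip], 0.6 + 0.18 * (np.abs(s[dip] - 30.0)))
        g = VesselGeometry(arclength_mm=s, radius_mm=r)
        assert 2 * r.min() == pytest.approx(1.2, abs=0.01)
        assert percent_diameter_stenosis(g) == pytest.approx(60.0, abs=1.0)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            percent_diameter_stenosis(
                synth_stenosis_geometry(3.0, 80.0, 50.0), "median")


class TestMeshing:
    def test_wall_nodes_on_lumen_surface(self):
        g = synth_stenosis_geometry(3.0, 80.0, 0.0)
        mesh = mesh_generate(g, "standard")
        assert np.allclose(mesh.r_mm[:, -1], 1.5)
        assert np.all(mesh.r_mm[:, 0] == 0.0)

    def test_default_resolution_floor(self):
        nz, nr = MESH_RESOLUTIONS["standard"]
        assert nz >= 100 and nr >= 20

    def test_cell_count_scales_quadratically(self):
        g = synth_stenosis_geometry(3.0, 80.0, 0.0)
        m1 = mesh_generate(g, (100, 20))
        m2 = mesh_generate(g, (200, 40))
        ratio = m2.n_cells / m1.n_cells
        assert 3.8 < ratio < 4.2

    def test_throat_region_axially_refined(self):
        g = synth_stenosis_geometry(3.0, 80.0, 72.0, stenosis_length_mm=20.0)
        mesh = mesh_generate(g, "standard")
        s_min, _ = g.min_diameter()
        in_throat = np.abs(mesh.z_mm - s_min) <= 5.0  # central throat window
        assert in_throat.sum() >= 20

    def test_radial_growth_ratio_bounded(self):
        mesh = mesh_generate(synth_stenosis_geometry(3.0, 80.0, 0.0), "standard")
        steps = np.diff(mesh.eta)
        assert (steps[:-1] / steps[1:]).max() <= 1.2

    def test_tiny_lumen_rejected(self):
        g = synth_stenosis_geometry(3.0, 80.0, 97.0)
        with pytest.raises(ValueError, match="mesh tolerance"):
            mesh_generate(g)

    def test_unknown_resolution_rejected(self):
        with pytest.raises(ValueError):
            mesh_generate(synth_stenosis_geometry(3.0, 80.0, 0.0), "ultra")
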