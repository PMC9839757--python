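"""Shape solver: hemisphere limit, volume fidelity, tension monotonicity,
scale invariance and agreement with the variational oracle."""

import numpy as np
import pytest
from scipy.integrate import quad

from nichemech import shape
from nichemech.errors import NumericalValidityError

from oracles import droplet_profile_by_area_minimization

R0 = 8.7
V0 = 2 / 3 * np.pi * R0 ** 3


class TestGeometryParams:
    def test_height_above_radius_rejected(self):
        with pytest.raises(ValueError):
            shape.GeometryParams(r0=8.7, height=9.0)

    @pytest.mark.parametrize("kw", [dict(r0=-1, height=0.5),
                                    dict(r0=1, height=0.0),
                                    dict(r0=1, height=0.5, dtheta=0),
                                    dict(r0=1, height=0.5, volume_tol=-1)])
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            shape.GeometryParams(**kw)

    def test_strain_bookkeeping(self):
        p = shape.GeometryParams(r0=8.7, height=4.0)
        assert 53 <= 100 * p.strain <= 56  # "~55%" lateral compression


class TestComputeVolume:
    def test_hemisphere_closed_form(self):
        theta = np.linspace(0, np.pi / 2, 1001)
        v = shape.compute_volume(theta, np.full_like(theta, R0))
        assert v == pytest.approx(V0, rel=1e-3)

    def test_zero_radius(self):
        theta = np.linspace(0, np.pi / 2, 101)
        assert shape.compute_volume(theta, np.zeros_like(theta)) == 0.0

    def test_against_adaptive_quadrature(self):
        # R(theta) = 1 + 0.1 cos(theta): independent adaptive quadrature
        f = lambda t: (1 + 0.1 * np.cos(t)) ** 2 * np.sin(t) ** 2 * (
            (1 + 0.1 * np.cos(t)) * np.sin(t) + 0.1 * np.sin(t) * np.cos(t))
        expected = np.pi * quad(f, 0, np.pi / 2, epsabs=1e-12)[0]
        theta = np.linspace(0, np.pi / 2, 2001)
        v = shape.compute_volume(theta, 1 + 0.1 * np.cos(theta))
        assert v == pytest.approx(expected, rel=1e-3)

    def test_non_monotone_grid_rejected(self):
        with pytest.raises(ValueError):
            shape.compute_volume(np.array([0.0, 0.5, 0.3]), np.ones(3))


class TestSolver:
    def test_uncompressed_limit_is_exact_hemisphere(self):
        sol = shape.solve_compressed_shape(shape.GeometryParams(r0=R0, height=R0))
        assert np.allclose(sol.radius, R0)
        assert np.allclose(sol.curv_azimuthal, 1 / R0, rtol=5e-3)
        assert np.allclose(sol.curv_axial, 1 / R0, rtol=5e-3)
        assert sol.volume == pytest.approx(V0, rel=1e-6)
        assert sol.contact_radius == 0.0

    def test_apex_boundary_conditions(self):
        sol = shape.solve_compressed_shape(shape.GeometryParams(r0=R0, height=4.0))
        assert sol.radius[0] == pytest.approx(4.0, rel=1e-9)
        dtheta = sol.theta[1] - sol.theta[0]
        slope = (sol.radius[1] - sol.radius[0]) / dtheta
        assert abs(slope) < 0.05  # dR/dtheta(0) = 0 within discretisation error

    @pytest.mark.parametrize("eps", [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.54])
    def test_volume_conservation_along_sweep(self, eps):
        sol = shape.solve_compressed_shape(
            shape.GeometryParams(r0=R0, height=R0 * (1 - eps)))
        assert sol.volume_error <= 0.01

    def test_reported_grid_reproduces_volume(self):
        sol = shape.solve_compressed_shape(shape.GeometryParams(r0=R0, height=4.0))
        v = shape.compute_volume(sol.theta, sol.radius)
        assert v == pytest.approx(sol.volume, rel=1e-2)

    @pytest.mark.parametrize("eps", [0.1, 0.25, 0.54])
    def test_shape_matches_area_minimization_oracle(self, eps):
        """Shooting solution equals the constrained-area-minimum profile."""
        sol = shape.solve_compressed_shape(
            shape.GeometryParams(r0=1.0, height=1 - eps))
        rho_o, z_o = droplet_profile_by_area_minimization(1.0, 1 - eps)
        theta_o = np.arctan2(rho_o, z_o)
        r_o = np.hypot(rho_o, z_o)
        order = np.argsort(theta_o)
        inner = (sol.theta > 0.05) & (sol.theta < np.pi / 2 - 0.02)
        r_pkg = sol.radius[inner]
        r_orc = np.interp(sol.theta[inner], theta_o[order], r_o[order])
        assert np.max(np.abs(r_pkg - r_orc) / r_orc) < 0.01

    def test_example_small_cell(self):
        sol = shape.solve_compressed_shape(shape.GeometryParams(r0=1.0, height=0.8))
        assert sol.volume == pytest.approx(2 * np.pi / 3, rel=0.01)


class TestTension:
    def test_hemisphere_reference_is_unity(self):
        sol = shape.solve_compressed_shape(shape.GeometryParams(r0=R0, height=R0))
        t = shape.surface_average_tension(sol)
        assert t.t_overall_rel == pytest.approx(1.0, rel=1e-2)
        assert t.t_axial_rel == pytest.approx(1.0, rel=1e-2)

    def test_compression_endpoint_prediction(self):
        """~60% drop of overall tension, ~2x axial rise at 54% strain."""
        t = shape.tension_vs_strain(R0, [0.0, 0.54])
        assert t[0].t_overall_rel == pytest.approx(1.0, rel=1e-2)
        assert 0.35 <= t[1].t_overall_rel <= 0.45
        assert 1.8 <= t[1].t_axial_rel <= 2.2

    def test_monotone_in_strain(self):
        strains = [0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        res = shape.tension_vs_strain(R0, strains)
        ov = [t.t_overall_rel for t in res]
        ax = [t.t_axial_rel for t in res]
        assert all(b < a for a, b in zip(ov, ov[1:]))
        assert all(b > a for a, b in zip(ax, ax[1:]))

    @pytest.mark.parametrize("r0", [1.0, 8.7, 20.0])
    def test_tension_ratios_scale_invariant(self, r0):
        t = shape.tension_vs_strain(r0, [0.3])[0]
        ref = shape.tension_vs_strain(8.7, [0.3])[0]
        assert t.t_overall_rel == pytest.approx(ref.t_overall_rel, rel=1e-6)
        assert t.t_axial_rel == pytest.approx(ref.t_axial_rel, rel=1e-6)

    def test_grid_refinement_stability(self):
        """Halving dtheta moves the relative tensions by < 0.5%."""
        for dt in (shape.DEFAULT_DTHETA, shape.DEFAULT_DTHETA / 2):
            p = shape.GeometryParams(r0=R0, height=4.0, dtheta=dt)
            t = shape.surface_average_tension(shape.solve_compressed_shape(p))
            if dt == shape.DEFAULT_DTHETA:
                base = t
        assert t.t_overall_rel == pytest.approx(base.t_overall_rel, rel=5e-3)
        assert t.t_axial_rel == pytest.approx(base.t_axial_rel, rel=5e-3)

    def test_trivial_sweep(self):
        res = shape.tension_vs_strain(R0, [0.0])
        assert res[0].t_overall_rel == pytest.approx(1.0, rel=1e-2)

    def test_unsorted_strains_rejected(self):
        with pytest.raises(ValueError):
            shape.tension_vs_strain(R0, [0.3, 0.1])

    def test_alternative_averages_reported(self):
        t = shape.tension_vs_strain(R0, [0.54])[0]
        assert set(t.alternatives) == {"arithmetic", "harmonic"}
        # the arithmetic mean of the axial component exceeds the geometric
        # (heavy upper tail at the contact line), the harmonic lies below
        assert t.alternatives["arithmetic"][1] > t.t_axial_rel
        assert t.alternatives["harmonic"][1] < t.t_axial_rel
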