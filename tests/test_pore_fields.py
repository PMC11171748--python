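"""Pore geometry and potential/steric lattice behavior."""

import numpy as np
import pytest

from nanoduplex.fields import (PotentialGrid, SolverError,
                               conical_resistance_analytic, effective_force,
                               fill_invalid, solve_potential,
                               solve_potential_slit, solved_resistance,
                               steric_grid)
from nanoduplex.pore import PoreShape, build_pore

SIGMA = 15.1  # 151 mS/cm in nS/nm


class TestGeometry:
    def test_conical_defaults(self):
        geo = build_pore("conical_pipette")
        assert geo.wall_radius(0.0) == pytest.approx(5.0)
        # widening 4.87 deg over the first 50 nm, then 1.2 deg
        assert geo.wall_radius(50.0) == pytest.approx(
            5.0 + 50 * np.tan(np.radians(4.87)), rel=1e-9)
        assert geo.wall_radius(300.0) == pytest.approx(
            5.0 + 50 * np.tan(np.radians(4.87))
            + 250 * np.tan(np.radians(1.2)), rel=1e-9)

    def test_cylinder_constant_radius(self):
        geo = build_pore("cylinder", membrane_thickness_nm=30)
        z = np.linspace(-14, 14, 10)
        assert np.allclose(geo.wall_radius(z), 5.0)

    def test_hourglass_symmetric(self):
        geo = build_pore("hourglass", membrane_thickness_nm=40,
                         taper_angle_deg_near=15)
        z = np.linspace(0.5, 19, 8)
        assert np.allclose(geo.wall_radius(z), geo.wall_radius(-z))
        assert geo.wall_radius(0.0) == pytest.approx(5.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            build_pore("conical_pipette", aperture_radius_nm=200.0)
        with pytest.raises(ValueError):
            build_pore("slit")  # slit has no default dimensions


class TestSolvePotential:
    def test_cylinder_interior_field_linear(self):
        geo = build_pore("cylinder", aperture_radius_nm=5,
                         membrane_thickness_nm=40, chamber_length_nm=60,
                         chamber_radius_nm=60)
        grid = solve_potential(geo, 600.0, dz_A=20, dr_A=10)
        axis = grid.phi_mV[:, 0]
        sel = (grid.z_nm > -15) & (grid.z_nm < 15)
        coef = np.polyfit(grid.z_nm[sel], axis[sel], 1)
        resid = np.max(np.abs(np.polyval(coef, grid.z_nm[sel]) - axis[sel]))
        assert resid < 0.5  # mV; linear within the membrane

    def test_maximum_principle(self, desk_conical_grid):
        vals = desk_conical_grid.phi_mV[desk_conical_grid.valid]
        assert vals.min() >= 0.0
        assert vals.max() <= 600.0 + 1e-9

    def test_conical_resistance_vs_analytic(self):
        # pure single-angle cone so the closed form applies
        geo = build_pore("conical_pipette", taper_near_extent_nm=1000.0,
                         chamber_length_nm=100, chamber_radius_nm=100)
        grid = solve_potential(geo, 600.0, dz_A=20, dr_A=10)
        R_solved = solved_resistance(grid, SIGMA)
        R_ref = conical_resistance_analytic(geo, SIGMA)
        assert R_solved == pytest.approx(R_ref, rel=0.10)

    def test_resistance_monotone_in_aperture(self):
        res = []
        for r_ap in (4.0, 6.0, 9.0):
            geo = build_pore("conical_pipette", aperture_radius_nm=r_ap,
                             chamber_length_nm=80, chamber_radius_nm=80,
                             pipette_length_nm=200)
            grid = solve_potential(geo, 600.0, dz_A=20, dr_A=10)
            res.append(solved_resistance(grid, SIGMA))
        assert res[0] > res[1] > res[2]

    def test_refinement_stability(self):
        geo = build_pore("conical_pipette", chamber_length_nm=60,
                         chamber_radius_nm=60, pipette_length_nm=150)
        g1 = solve_potential(geo, 600.0, dz_A=10, dr_A=10)
        g2 = solve_potential(geo, 600.0, dz_A=5, dr_A=10)
        # compare on the coarse grid's interior axis nodes
        phi1 = g1.phi_mV[1:-1, 0]
        phi2 = g2.phi_mV[2:-2:2, 0]
        denom = np.maximum(np.abs(phi1), 30.0)
        assert np.max(np.abs(phi1 - phi2) / denom) < 0.05


class TestStericGrid:
    def test_values_forced_by_formula(self):
        geo = build_pore("cylinder", aperture_radius_nm=5,
                         membrane_thickness_nm=20, chamber_length_nm=30,
                         chamber_radius_nm=30)
        grid = solve_potential(geo, 600.0, dz_A=10, dr_A=10, fill=False)
        u = grid.steric_kcal_mol
        assert np.all(u[grid.valid] == 0.0)
        wall = ~grid.valid
        assert np.all(u[wall] > 0.0)
        # one voxel into the wall laterally = 10 A -> u = 4 * 10^2
        d_min = np.sqrt(u[wall].min() / 4.0)
        assert d_min == pytest.approx(10.0, abs=1e-9)

    def test_agrees_with_inside_predicate(self, desk_conical_grid):
        g = desk_conical_grid
        assert np.array_equal(g.steric_kcal_mol > 0, ~g.valid)


class TestFillInvalid:
    def _toy_grid(self, phi, valid):
        nz, nr = phi.shape
        return PotentialGrid(z_nm=np.arange(nz, dtype=float),
                             r_nm=np.arange(nr, dtype=float),
                             phi_mV=phi.astype(float),
                             steric_kcal_mol=np.zeros_like(phi, dtype=float),
                             valid=valid, voltage_mV=600.0)

    def test_all_valid_is_noop(self):
        phi = np.arange(20.0).reshape(4, 5)
        g = fill_invalid(self._toy_grid(phi, np.ones((4, 5), bool)))
        assert np.array_equal(g.phi_mV, phi)

    def test_single_hole_gets_neighbor_mean(self):
        phi = np.arange(25.0).reshape(5, 5)
        valid = np.ones((5, 5), bool)
        valid[2, 2] = False
        expect = (phi[1, 2] + phi[3, 2] + phi[2, 1] + phi[2, 3]) / 4
        g = fill_invalid(self._toy_grid(phi, valid))
        assert g.phi_mV[2, 2] == pytest.approx(expect)

    def test_two_deep_slab_layer_order(self):
        # right half invalid; fill proceeds layer by layer from the left
        phi = np.zeros((5, 6))
        phi[:, :3] = np.array([1.0, 2.0, 3.0])[None, :]
        valid = np.zeros((5, 6), bool)
        valid[:, :3] = True
        g = fill_invalid(self._toy_grid(phi, valid))
        # first filled layer is dominated by the last valid column
        assert np.all(np.abs(g.phi_mV[:, 3] - 3.0) < 1e-9 + 1e-9) or \
            np.all(g.phi_mV[:, 3] <= 3.0)
        # all voxels defined, valid untouched
        assert np.all(np.isfinite(g.phi_mV))
        assert np.array_equal(g.phi_mV[:, :3], phi[:, :3])

    def test_idempotent(self, desk_conical_grid):
        g1 = desk_conical_grid  # already filled by solve_potential
        g2 = fill_invalid(g1)
        assert np.array_equal(g1.phi_mV, g2.phi_mV)

    def test_all_invalid_rejected(self):
        with pytest.raises(SolverError):
            fill_invalid(self._toy_grid(np.zeros((3, 3)),
                                        np.zeros((3, 3), bool)))


class TestEffectiveForce:
    def _uniform_field_grid(self, E_mV_nm=2.0):
        nz, nr = 21, 11
        z = np.arange(nz, dtype=float)
        r = np.arange(nr, dtype=float)
        phi = (z[:, None] * E_mV_nm) * np.ones((1, nr))
        g = PotentialGrid(z_nm=z, r_nm=r, phi_mV=phi,
                          steric_kcal_mol=np.zeros((nz, nr)),
                          valid=np.ones((nz, nr), bool), voltage_mV=600.0)
        g.filled = True
        return g

    def test_uniform_axial_field(self):
        g = self._uniform_field_grid(E_mV_nm=2.0)
        # q = -2e bead (duplex charge), 1/32 scaling
        F = effective_force(g, (0.0, 0.0, 10.0), charge_e=-2.0,
                            scale=1.0 / 32.0)
        expect = 2.0 * 2.0 * 0.1602176634 / 32.0
        assert F[2] == pytest.approx(expect, rel=1e-9)
        assert F[0] == F[1] == 0.0

    def test_zero_gradient_region(self):
        g = self._uniform_field_grid(E_mV_nm=0.0)
        F = effective_force(g, (1.0, 1.0, 5.0), charge_e=-2.0, scale=1.0)
        assert np.allclose(F, 0.0)

    def test_outside_grid_far_field(self):
        g = self._uniform_field_grid()
        F = effective_force(g, (0.0, 0.0, 1e4), charge_e=-2.0, scale=1.0)
        assert np.allclose(F, 0.0)
        assert g.n_outside_queries == 1

    def test_form_scaling_per_unit_length(self, dd_spec, rd_spec):
        """The per-unit-length effective force ratio A-like:B is the
        all-atom 19.47/20.98, independent of bead spacing."""
        from nanoduplex.chain import electrophoretic_scale
        per_len_dd = electrophoretic_scale(dd_spec) / dd_spec.rise_nm
        per_len_rd = electrophoretic_scale(rd_spec) / rd_spec.rise_nm
        assert per_len_rd / per_len_dd == pytest.approx(
            19.47 / 20.98, rel=1e-9)


class TestSlit:
    def test_slit_solve_small(self):
        geo = build_pore("slit", slit_width_nm=10, slit_height_nm=4,
                         membrane_thickness_nm=10, chamber_length_nm=15,
                         chamber_radius_nm=15)
        x, y, z, phi, valid = solve_potential_slit(geo, 600.0, spacing_A=20.0)
        vals = phi[valid]
        assert vals.min() >= 0 and vals.max() <= 600 + 1e-9
        # potential increases along z through the slit on the axis
        icx, icy = len(x) // 2, len(y) // 2
        axis = phi[icx, icy, :]
        assert axis[1] < axis[len(z) // 2] < axis[-2]


class TestRoundTrip:
    def test_h5_round_trip(self, tmp_path, desk_conical_grid):
        p = tmp_path / "grid.h5"
        desk_conical_grid.save_h5(p)
        g = PotentialGrid.load_h5(p)
        assert np.array_equal(g.phi_mV, desk_conical_grid.phi_mV)
        assert g.geometry.shape is PoreShape.CONICAL_PIPETTE
        assert g.voltage_mV == 600.0
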