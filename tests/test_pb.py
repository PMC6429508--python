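"""Grid electrostatics: geometry, dielectric maps, LPB solver vs closed
forms."""

import numpy as np
import pytest

from gagesd.pb import (
    SolverParams,
    build_grid,
    coupling_constant,
    debye_huckel,
    dielectric_maps,
    kappa_parameters,
    solve_lpb,
)
from gagesd.types import Atom, ChargedStructure, GagesdError, Structure


def point_charge(q=1.0, radius=1.5, pos=(0.0, 0.0, 0.0)):
    atom = Atom("NZ", "N", "LYS", 1, "A", *pos)
    return ChargedStructure(Structure([atom]), np.array([q]),
                            np.array([radius]))


def uniform_params(**kw):
    defaults = dict(eps_protein=78.0, eps_solvent=78.0, padding=20.0)
    defaults.update(kw)
    return SolverParams(**defaults)


class TestBuildGrid:
    def test_single_atom_padding_ten(self):
        grid = build_grid(point_charge(), SolverParams(padding=10.0))
        assert grid.dims == (21, 21, 21)
        assert np.allclose(grid.origin, (-10, -10, -10))

    def test_zero_padding_degenerate_box(self):
        grid = build_grid(point_charge(), SolverParams(padding=0.0))
        assert grid.dims == (1, 1, 1)

    def test_doubling_padding_grows_dims_linearly(self):
        g1 = build_grid(point_charge(), SolverParams(padding=5.0))
        g2 = build_grid(point_charge(), SolverParams(padding=10.0))
        for d1, d2 in zip(g1.dims, g2.dims):
            assert d2 - d1 == 10  # 2*padding/h extra points

    def test_empty_structure_rejected(self):
        with pytest.raises(GagesdError):
            build_grid(np.zeros((0, 3)), SolverParams())


class TestDielectricMaps:
    def test_far_point_solvent_near_point_protein(self):
        params = SolverParams(padding=12.0)
        charged = point_charge(radius=1.7)
        grid = build_grid(charged, params)
        maps = dielectric_maps(charged, grid, params)
        centre = tuple(d // 2 for d in grid.dims)
        assert maps.protein[centre]
        assert not maps.protein[0, 0, 0]
        # a face deep in solvent carries the solvent dielectric
        assert maps.eps_x[0, 0, 0] == 78.0

    def test_probe_inaccessible_gap_labelled_protein(self):
        """Two atoms with a 2.0 Å surface gap (< probe diameter): the gap
        interior is protein by the sphere-rolling definition."""
        from oracles import two_sphere_ses_interior

        r = 1.7
        gap = 2.0
        centers = np.array([[-(r + gap / 2), 0, 0], [r + gap / 2, 0, 0]])
        atoms = [Atom("C1", "C", "ALA", 1, "A", *centers[0]),
                 Atom("C2", "C", "ALA", 2, "A", *centers[1])]
        charged = ChargedStructure(Structure(atoms), np.zeros(2),
                                   np.full(2, r))
        params = SolverParams(padding=8.0, spacing=0.5)
        grid = build_grid(charged, params)
        maps = dielectric_maps(charged, grid, params)
        centre_idx = tuple(
            int(round((0 - grid.origin[d]) / grid.spacing))
            for d in range(3))
        assert maps.protein[centre_idx]
        assert two_sphere_ses_interior(np.zeros(3), centers, r,
                                       params.probe_radius)
        # and a point well outside is solvent by both routes
        far = np.array([0.0, 0.0, 6.0])
        far_idx = tuple(int(round((far[d] - grid.origin[d]) / grid.spacing))
                        for d in range(3))
        assert not maps.protein[far_idx]
        assert not two_sphere_ses_interior(far, centers, r,
                                           params.probe_radius)

    def test_boundary_faces_harmonic_mean(self):
        params = SolverParams(padding=10.0)
        charged = point_charge(radius=1.7)
        grid = build_grid(charged, params)
        maps = dielectric_maps(charged, grid, params)
        values = np.unique(np.round(maps.eps_x, 6))
        harmonic = 2 * 2.0 * 78.0 / (2.0 + 78.0)
        assert set(values) <= {2.0, round(harmonic, 6), 78.0}

    def test_ions_excluded_from_stern_shell(self):
        params = SolverParams(padding=10.0)
        charged = point_charge(radius=1.7)
        grid = build_grid(charged, params)
        maps = dielectric_maps(charged, grid, params)
        centre = tuple(d // 2 for d in grid.dims)
        # 3 Å from the atom centre: outside protein but inside Stern shell
        assert not maps.ion_accessible[centre[0] + 3, centre[1], centre[2]]
        assert maps.ion_accessible[centre[0] + 8, centre[1], centre[2]]


class TestDebyeHuckel:
    def test_inverse_distance_law(self):
        q = np.array([1.0])
        c = np.zeros((1, 3))
        a = np.array([0.0])
        pts = np.array([[5.0, 0, 0], [10.0, 0, 0]])
        phi = debye_huckel(q, c, a, pts, 78.0, 0.0, 298.15)
        assert phi[0] / phi[1] == pytest.approx(2.0, abs=1e-12)

    def test_superposition_linearity(self):
        c = np.array([[0.0, 0, 0], [4.0, 0, 0]])
        a = np.array([1.5, 1.5])
        pts = np.array([[10.0, 3.0, 2.0]])
        both = debye_huckel(np.array([1.0, -0.5]), c, a, pts, 78.0, 0.1,
                            298.15)
        one = debye_huckel(np.array([1.0, 0.0]), c, a, pts, 78.0, 0.1,
                           298.15)
        two = debye_huckel(np.array([0.0, -0.5]), c, a, pts, 78.0, 0.1,
                           298.15)
        assert both[0] == pytest.approx(one[0] + two[0], abs=1e-12)

    def test_screening_decreases_with_ionic_strength(self):
        q, c, a = np.array([1.0]), np.zeros((1, 3)), np.array([1.5])
        pt = np.array([[8.0, 0, 0]])
        phis = []
        for ionic in (0.01, 0.05, 0.15, 0.5):
            kappa, _ = kappa_parameters(ionic, 78.0, 298.15)
            phis.append(debye_huckel(q, c, a, pt, 78.0, kappa, 298.15)[0])
        assert all(x > y for x, y in zip(phis, phis[1:]))

    def test_coincident_point_rejected(self):
        with pytest.raises(GagesdError):
            debye_huckel(np.array([1.0]), np.zeros((1, 3)),
                         np.array([1.5]), np.zeros((1, 3)), 78.0, 0.0,
                         298.15)


class TestSolver:
    def test_zero_charges_give_zero_potential(self):
        charged = point_charge(q=0.0)
        params = SolverParams(padding=8.0)
        grid = build_grid(charged, params)
        maps = dielectric_maps(charged, grid, params)
        phi, info = solve_lpb(charged, maps, params, grid)
        assert np.all(phi.values == 0.0)

    def test_uniform_dielectric_matches_coulomb_within_3pct(self):
        charged = point_charge()
        params = uniform_params()
        grid = build_grid(charged, params)
        maps = dielectric_maps(charged, grid, params)
        phi, info = solve_lpb(charged, maps, params, grid)
        assert info["residual"] <= params.tolerance
        lam = coupling_constant(params.temperature)
        centre = tuple(d // 2 for d in grid.dims)
        for r in (5, 8, 10, 12, 15):
            value = phi.values[centre[0] + r, centre[1], centre[2]]
            oracle = lam / (78.0 * r)
            assert abs(value - oracle) / oracle < 0.03, r
        # spot value from the closed form: r = 10 Å -> ~0.719 kT/e
        assert phi.values[centre[0] + 10, centre[1], centre[2]] == \
            pytest.approx(0.719, abs=0.03)

    def test_screened_matches_debye_huckel_within_3pct(self):
        radius = 1.5
        charged = point_charge(radius=radius)
        params = uniform_params(ionic_strength=0.15)
        grid = build_grid(charged, params)
        maps = dielectric_maps(charged, grid, params)
        maps.ion_accessible[:] = True  # uniform-medium oracle everywhere
        phi, _info = solve_lpb(charged, maps, params, grid)
        kappa, _ = kappa_parameters(0.15, 78.0, 298.15)
        lam = coupling_constant(params.temperature)
        centre = tuple(d // 2 for d in grid.dims)
        for r in (5, 8, 10, 12, 15):
            value = phi.values[centre[0] + r, centre[1], centre[2]]
            oracle = lam * np.exp(-kappa * (r - radius)) / (
                78.0 * r * (1 + kappa * radius))
            assert abs(value - oracle) / oracle < 0.03, r

    def test_linearity_in_charge(self):
        params = uniform_params(padding=10.0)
        c1 = point_charge(q=1.0)
        c2 = point_charge(q=2.0)
        grid = build_grid(c1, params)
        maps = dielectric_maps(c1, grid, params)
        phi1, _ = solve_lpb(c1, maps, params, grid)
        phi2, _ = solve_lpb(c2, maps, params, grid)
        assert np.allclose(phi2.values, 2.0 * phi1.values, rtol=1e-5,
                           atol=1e-9)

    def test_centrosymmetric_configuration_gives_symmetric_potential(self):
        charged = point_charge(radius=1.6)
        params = SolverParams(padding=9.0)
        grid = build_grid(charged, params)
        maps = dielectric_maps(charged, grid, params)
        phi, _ = solve_lpb(charged, maps, params, grid)
        v = phi.values
        for flipped in (v[::-1, :, :], v[:, ::-1, :], v[:, :, ::-1]):
            assert np.allclose(v, flipped, rtol=1e-4, atol=1e-7)

    def test_grid_refinement_consistency(self):
        """Halving h changes the solvent-shell potential by < 5%."""
        charged = point_charge(radius=1.6)
        coarse = SolverParams(padding=8.0, spacing=1.0)
        fine = SolverParams(padding=8.0, spacing=0.5)
        g1 = build_grid(charged, coarse)
        phi1, _ = solve_lpb(charged,
                            dielectric_maps(charged, g1, coarse), coarse, g1)
        g2 = build_grid(charged, fine)
        phi2, _ = solve_lpb(charged,
                            dielectric_maps(charged, g2, fine), fine, g2)
        c1 = tuple(d // 2 for d in g1.dims)
        c2 = tuple(d // 2 for d in g2.dims)
        for r in (5, 6, 7):
            v1 = phi1.values[c1[0] + r, c1[1], c1[2]]
            v2 = phi2.values[c2[0] + 2 * r, c2[1], c2[2]]
            assert abs(v1 - v2) / abs(v2) < 0.05

    def test_nonconvergence_carries_residual_history(self):
        from gagesd.pb import SolverDiverged

        charged = point_charge()
        params = uniform_params(max_iterations=3, tolerance=1e-14)
        grid = build_grid(charged, params)
        maps = dielectric_maps(charged, grid, params)
        with pytest.raises(SolverDiverged) as err:
            solve_lpb(charged, maps, params, grid)
        assert len(err.value.residuals) >= 1


def test_coupling_constant_thermal_voltage_scale():
    """λ/ε_water at 298.15 K reproduces the familiar ~7.1 Å Bjerrum length
    and the 1/r Coulomb value used throughout."""
    lam = coupling_constant(298.15)
    assert lam / 78.5 == pytest.approx(7.14, abs=0.1)
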