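"""ESD formula properties, site shells, masks and rankings."""

import numpy as np
import pandas as pd
import pytest

from gagesd.conserve import BindingSite, SiteResidue
from gagesd.esd_compare import (
    EsdMatrix,
    build_mask,
    build_shell,
    esd,
    hodgkin_index,
    pairwise_esd,
    rank_species,
    shell_residues,
)
from gagesd.pb import SolverParams, build_grid, dielectric_maps
from gagesd.sites import BINDING_SITES
from gagesd.types import Atom, ChargedStructure, GagesdError, GridField, Structure


def field(values, origin=(0, 0, 0), spacing=1.0):
    return GridField(origin=origin, spacing=spacing,
                     values=np.asarray(values, dtype=float))


def pair_structure(distance, r=1.7):
    atoms = [Atom("CA", "C", "ALA", 1, "A", 0.0, 0.0, 0.0),
             Atom("CA", "C", "ALA", 2, "A", distance, 0.0, 0.0)]
    return Structure(atoms)


class TestEsdFormula:
    def test_identical_potentials_zero(self):
        a = field(np.ones((3, 3, 3)))
        mask = np.ones((3, 3, 3), dtype=bool)
        assert esd(a, a, mask) == 0.0

    def test_sign_flip_is_exactly_two(self):
        v = np.arange(1, 28, dtype=float).reshape(3, 3, 3)
        mask = np.ones((3, 3, 3), dtype=bool)
        assert esd(field(v), field(-v), mask) == 2.0

    def test_hand_evaluated_two_point_mask(self):
        a = np.zeros((1, 1, 2))
        b = np.zeros((1, 1, 2))
        a[0, 0, 0], a[0, 0, 1] = 1.0, 2.0
        b[0, 0, 0], b[0, 0, 1] = 1.0, 1.0
        mask = np.ones((1, 1, 2), dtype=bool)
        assert esd(field(a), field(b), mask) == pytest.approx(0.25)

    def test_zero_zero_terms_contribute_nothing(self):
        a = np.zeros((1, 1, 4))
        b = np.zeros((1, 1, 4))
        a[0, 0, 0], b[0, 0, 0] = 1.0, -1.0
        mask = np.ones((1, 1, 4), dtype=bool)
        assert esd(field(a), field(b), mask) == pytest.approx(0.5)

    def test_bounded_symmetric_nonnegative(self, rng):
        v1 = rng.normal(size=(4, 4, 4))
        v2 = rng.normal(size=(4, 4, 4))
        mask = rng.uniform(size=(4, 4, 4)) > 0.4
        d12 = esd(field(v1), field(v2), mask)
        d21 = esd(field(v2), field(v1), mask)
        assert 0.0 <= d12 <= 2.0
        assert d12 == pytest.approx(d21, abs=1e-15)

    def test_invariant_under_common_rescaling(self, rng):
        v1 = rng.normal(size=(4, 4, 4))
        v2 = rng.normal(size=(4, 4, 4))
        mask = np.ones((4, 4, 4), dtype=bool)
        d = esd(field(v1), field(v2), mask)
        d_scaled = esd(field(7.3 * v1), field(7.3 * v2), mask)
        assert d == pytest.approx(d_scaled, abs=1e-12)

    def test_incongruent_grids_rejected(self):
        a = field(np.zeros((3, 3, 3)))
        b = field(np.zeros((3, 3, 3)), origin=(1, 0, 0))
        with pytest.raises(GagesdError, match="congruent"):
            esd(a, b, np.ones((3, 3, 3), dtype=bool))

    def test_hodgkin_identity_and_sign_flip(self, rng):
        v = rng.normal(size=(3, 3, 3))
        mask = np.ones((3, 3, 3), dtype=bool)
        assert hodgkin_index(field(v), field(v), mask) == pytest.approx(1.0)
        assert hodgkin_index(field(v), field(-v), mask) == \
            pytest.approx(-1.0)


class TestShellResidues:
    def test_at_binding_site_declares_thirteen_residues(self):
        site = BINDING_SITES["antithrombin"]
        assert sorted(site.res_numbers) == [46, 47, 121, 122, 125, 129,
                                            132, 133, 136, 228, 235, 236,
                                            275]

    def test_site_residues_always_in_shell(self):
        from gagesd.synth import make_binding_site, make_template
        structure, _ = make_template(30, {12: "K", 15: "R"})
        site = make_binding_site(structure, [12, 15])
        shell = shell_residues(structure, site, 5.0)
        keys = {(c, n) for c, n, _i in shell}
        assert {("A", 12), ("A", 15)} <= keys

    def test_inclusive_five_angstrom_boundary(self):
        site = BindingSite(protein="x",
                           residues=[SiteResidue("A", 1, "A")])
        inside = shell_residues(pair_structure(4.9), site, 5.0)
        outside = shell_residues(pair_structure(5.1), site, 5.0)
        assert ("A", 2, "") in inside
        assert ("A", 2, "") not in outside
        at_boundary = shell_residues(pair_structure(5.0), site, 5.0)
        assert ("A", 2, "") in at_boundary

    def test_zero_radius_shell_is_the_site(self):
        site = BindingSite(protein="x",
                           residues=[SiteResidue("A", 1, "A")])
        shell = shell_residues(pair_structure(3.0), site, 0.0)
        assert shell == [("A", 1, "")]

    def test_missing_site_residue_errors(self):
        site = BindingSite(protein="x",
                           residues=[SiteResidue("A", 9, "A")])
        with pytest.raises(GagesdError):
            shell_residues(pair_structure(3.0), site, 5.0)


class TestBuildMask:
    def _single_atom_setup(self):
        atom = Atom("CA", "C", "ALA", 1, "A", 0.0, 0.0, 0.0)
        st = Structure([atom])
        charged = ChargedStructure(st, np.array([1.0]), np.array([1.7]))
        params = SolverParams(padding=9.0)
        grid = build_grid(charged, params)
        maps = {"a": dielectric_maps(charged, grid, params)}
        return st, charged, grid, maps

    def test_single_atom_mask_is_spherical_annulus(self):
        st, charged, grid, maps = self._single_atom_setup()
        site = BindingSite(protein="x",
                           residues=[SiteResidue("A", 1, "A")])
        shell = build_shell(st, site, 5.0, 3.0)
        mask = build_mask(grid, maps, st, shell, charged.radii)
        # direct distance scan oracle: solvent points with r <= 1.7 + 3
        ax = [grid.origin[d] + grid.spacing * np.arange(grid.dims[d])
              for d in range(3)]
        X, Y, Z = np.meshgrid(*ax, indexing="ij")
        r = np.sqrt(X ** 2 + Y ** 2 + Z ** 2)
        oracle = (r <= 1.7 + 3.0) & maps["a"].solvent
        assert (mask == oracle).all()
        assert mask.sum() == oracle.sum() > 0

    def test_zero_thickness_empty_mask_errors(self):
        st, charged, grid, maps = self._single_atom_setup()
        site = BindingSite(protein="x",
                           residues=[SiteResidue("A", 1, "A")])
        shell = build_shell(st, site, 5.0, 0.0)
        # thickness 0: every point within the vdW radius is protein,
        # so no solvent point survives
        with pytest.raises(GagesdError, match="empty"):
            build_mask(grid, maps, st, shell, charged.radii)

    def test_entire_structure_mode_ignores_site(self):
        st, charged, grid, maps = self._single_atom_setup()
        mask = build_mask(grid, maps, st, None, charged.radii,
                          mode="entire-structure")
        assert mask.sum() > 0


class TestPairwiseAndRanking:
    def test_two_species_single_off_diagonal(self, rng):
        v = rng.normal(size=(3, 3, 3))
        pots = {"a": field(v), "b": field(v * 0.5)}
        mask = np.ones((3, 3, 3), dtype=bool)
        m = pairwise_esd(pots, mask)
        assert m.values.shape == (2, 2)
        assert m.values[0, 1] == m.values[1, 0] > 0
        assert m.values[0, 0] == m.values[1, 1] == 0.0

    def test_matrix_equals_elementwise_esd(self, rng):
        pots = {k: field(rng.normal(size=(3, 3, 3))) for k in "abc"}
        mask = np.ones((3, 3, 3), dtype=bool)
        m = pairwise_esd(pots, mask)
        for i, ki in enumerate("abc"):
            for j, kj in enumerate("abc"):
                if i != j:
                    assert m.values[i, j] == pytest.approx(
                        esd(pots[ki], pots[kj], mask))

    def test_species_permutation_permutes_matrix(self, rng):
        vals = {k: rng.normal(size=(3, 3, 3)) for k in "abc"}
        mask = np.ones((3, 3, 3), dtype=bool)
        m1 = pairwise_esd({k: field(v) for k, v in vals.items()}, mask)
        order = ["c", "a", "b"]
        m2 = pairwise_esd({k: field(vals[k]) for k in order}, mask)
        perm = [m2.labels.index(k) for k in m1.labels]
        assert np.allclose(m1.values, m2.values[np.ix_(perm, perm)])

    def test_reference_ranked_first_with_zero_esd(self, rng):
        pots = {k: field(rng.normal(size=(3, 3, 3))) for k in "abc"}
        mask = np.ones((3, 3, 3), dtype=bool)
        ranking = rank_species(pairwise_esd(pots, mask), "b")
        assert ranking.iloc[0]["species"] == "b"
        assert ranking.iloc[0]["esd"] == 0.0

    def test_distinct_species_ranked_last(self):
        labels = ["ref", "near", "far"]
        vals = np.array([[0.0, 0.1, 1.5],
                         [0.1, 0.0, 1.0],
                         [1.5, 1.0, 0.0]])
        m = EsdMatrix(values=vals, labels=labels, mask_points=10)
        ranking = rank_species(m, "ref")
        assert list(ranking["species"]) == ["ref", "near", "far"]

    def test_identity_breaks_ties(self):
        labels = ["ref", "a", "b"]
        vals = np.array([[0.0, 0.5, 0.5],
                         [0.5, 0.0, 0.2],
                         [0.5, 0.2, 0.0]])
        m = EsdMatrix(values=vals, labels=labels, mask_points=10)
        identity = pd.Series({"ref": 100.0, "a": 80.0, "b": 95.0})
        ranking = rank_species(m, "ref", identity=identity)
        assert list(ranking["species"]) == ["ref", "b", "a"]

    def test_unknown_reference_rejected(self, rng):
        pots = {k: field(rng.normal(size=(3, 3, 3))) for k in "ab"}
        m = pairwise_esd(pots, np.ones((3, 3, 3), dtype=bool))
        with pytest.raises(GagesdError, match="reference"):
            rank_species(m, "zz")


class TestEsdMatrixInvariants:
    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            EsdMatrix(values=np.array([[0.0, 1.0], [0.5, 0.0]]),
                      labels=["a", "b"], mask_points=1)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            EsdMatrix(values=np.array([[0.0, 2.5], [2.5, 0.0]]),
                      labels=["a", "b"], mask_points=1)
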