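"""Protonation, charge assignment, threading, truncation, superposition."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from gagesd.align import MultipleAlignment, PairwiseAlignment, global_align
from gagesd.prep import (
    ProtonationModel,
    assign_charges_radii,
    kabsch,
    prepare_charged,
    protonation_fractions,
    superpose,
    thread_model,
    truncate_common,
)
from gagesd.synth import make_template, realize_structures
from gagesd.types import GagesdError, SequenceRecord

from oracles import grid_search_rmsd


class TestProtonation:
    def test_histidine_half_protonated_at_ph_6_5(self):
        model = ProtonationModel(ph=6.5, include_termini=False)
        assert model.residue_charge("HIS") == pytest.approx(0.5, abs=1e-12)

    def test_lysine_closed_form_at_ph_7_4(self):
        model = ProtonationModel(ph=7.4, include_termini=False)
        expected = 1.0 / (1.0 + 10 ** (7.4 - 10.53))
        assert model.residue_charge("LYS") == pytest.approx(expected,
                                                            abs=1e-9)
        assert model.residue_charge("LYS") == pytest.approx(0.99926,
                                                            abs=5e-5)

    def test_glutamate_closed_form_at_ph_7_4(self):
        model = ProtonationModel(ph=7.4, include_termini=False)
        expected = -(1.0 - 1.0 / (1.0 + 10 ** (7.4 - 4.45)))
        assert model.residue_charge("GLU") == pytest.approx(expected,
                                                            abs=1e-9)
        assert model.residue_charge("GLU") == pytest.approx(-0.99888,
                                                            abs=5e-5)

    @pytest.mark.parametrize("res", ["LYS", "ARG", "HIS", "ASP", "GLU"])
    def test_charge_monotone_decreasing_in_ph(self, res):
        charges = [ProtonationModel(ph=ph, include_termini=False)
                   .residue_charge(res) for ph in np.linspace(1, 13, 25)]
        assert all(a >= b - 1e-12 for a, b in zip(charges, charges[1:]))

    def test_tripeptide_net_charge_sum_of_closed_forms(self):
        structure, _ = make_template(10, {3: "K", 7: "E"})
        model = ProtonationModel(ph=7.4, include_termini=True)
        charges = protonation_fractions(structure, model)
        f = model.protonated_fraction
        expected = (f(10.53) - (1 - f(4.45))       # K and E side chains
                    + f(8.0) - (1 - f(3.6)))       # termini
        assert sum(charges.values()) == pytest.approx(expected, abs=1e-9)

    def test_ph_range_enforced(self):
        with pytest.raises(ValueError):
            ProtonationModel(ph=15.0)


class TestAssignCharges:
    def test_charge_split_equally_over_carriers(self):
        from gagesd.types import Atom, Structure
        atoms = [
            Atom("CA", "C", "ASP", 1, "A", 0, 0, 0),
            Atom("OD1", "O", "ASP", 1, "A", 1, 0, 0),
            Atom("OD2", "O", "ASP", 1, "A", 0, 1, 0),
        ]
        st = Structure(atoms)
        charged = assign_charges_radii(st, {("A", 1, ""): -1.0})
        assert charged.charges[1] == charged.charges[2] == -0.5
        assert charged.charges[0] == 0.0

    def test_net_charge_conserved(self):
        structure, _ = make_template(30, {5: "K", 9: "R", 14: "D",
                                          20: "E", 25: "H"})
        model = ProtonationModel(ph=7.4)
        residue_charges = protonation_fractions(structure, model)
        charged = assign_charges_radii(structure, residue_charges)
        assert charged.net_charge == pytest.approx(
            sum(residue_charges.values()), abs=1e-9)

    def test_element_radii_assigned(self):
        from gagesd.types import Atom, Structure
        st = Structure([Atom("NZ", "N", "LYS", 1, "A", 0, 0, 0),
                        Atom("O", "O", "ALA", 2, "A", 3, 0, 0),
                        Atom("SG", "S", "CYS", 3, "A", 6, 0, 0)])
        charged = assign_charges_radii(st, {})
        assert list(charged.radii) == [1.55, 1.52, 1.80]

    def test_missing_carrier_falls_back_to_ca(self, caplog):
        from gagesd.types import Atom, Structure
        st = Structure([Atom("CA", "C", "LYS", 1, "A", 0, 0, 0)])
        with caplog.at_level("WARNING"):
            charged = assign_charges_radii(st, {("A", 1, ""): 1.0})
        assert charged.charges[0] == 1.0
        assert any("carrier" in r.message for r in caplog.records)


class TestThreading:
    def test_identical_target_reproduces_template(self):
        template, seq = make_template(20, {5: "K"})
        aln = PairwiseAlignment("t", "t2", seq.residues, seq.residues, 0.0)
        model = thread_model(template, seq,
                             SequenceRecord(id="t2", residues=seq.residues),
                             aln)
        assert model.sequence() == template.sequence()
        assert np.allclose(model.coords, template.coords)

    def test_single_substitution_is_local(self):
        template, seq = make_template(20, {5: "K"})
        mutated = seq.residues[:4] + "E" + seq.residues[5:]
        aln = PairwiseAlignment("t", "m", seq.residues, mutated, 0.0)
        model = thread_model(template, seq,
                             SequenceRecord(id="m", residues=mutated), aln)
        names = [r.name for r in model.residues()]
        assert names[4] == "GLU"
        assert sum(a != b for a, b in zip(model.sequence(),
                                          template.sequence())) == 1
        # backbone coordinates unchanged everywhere
        tmpl_ca = [r.atom("CA").pos for r in template.residues()]
        model_ca = [r.atom("CA").pos for r in model.residues()]
        assert np.allclose(tmpl_ca, model_ca)

    def test_residue_count_equals_aligned_positions(self):
        template, seq = make_template(12, {})
        target = SequenceRecord(id="m", residues="AAAAAAAAA")  # 9 residues
        aln = global_align(seq, target)
        model = thread_model(template, seq, target, aln)
        assert len(model.residues()) == len(aln.matched_positions())

    def test_mismatched_alignment_rejected(self):
        template, seq = make_template(12, {})
        other = SequenceRecord(id="m", residues="KKKK")
        aln = PairwiseAlignment("t", "m", "KKKK", "KKKK", 0.0)
        with pytest.raises(GagesdError, match="row a"):
            thread_model(template, seq, other, aln)


class TestTruncation:
    def test_identical_sequences_nothing_removed(self):
        template, seq = make_template(15, {})
        family = realize_structures(template, seq, {
            "a": SequenceRecord(id="a", residues=seq.residues)})
        msa = MultipleAlignment({"template": seq.residues,
                                 "a": seq.residues})
        out = truncate_common({"template": template, **family}, msa)
        assert all(len(st.residues()) == 15 for st in out.values())

    def test_insertion_removed_and_counts_equalised(self):
        template, seq = make_template(12, {})
        # species "b" has a 3-residue insertion relative to the template
        msa = MultipleAlignment({
            "template": seq.residues[:6] + "---" + seq.residues[6:],
            "b": seq.residues[:6] + "KKK" + seq.residues[6:],
        })
        b_structure, _ = make_template(15, {7: "K", 8: "K", 9: "K"})
        out = truncate_common(
            {"template": template, "b": b_structure}, msa)
        counts = {sid: len(st.residues()) for sid, st in out.items()}
        assert counts == {"template": 12, "b": 12}

    def test_thread_then_truncate_commutes(self):
        """Threading then truncating equals truncating the alignment first
        and threading onto the truncated template."""
        template, seq = make_template(14, {4: "K"})
        target = SequenceRecord(id="m", residues=seq.residues[:5]
                                + seq.residues[7:])
        aln = global_align(seq, target)
        model = thread_model(template, seq, target, aln)
        msa = MultipleAlignment({"template": aln.row_a, "m": aln.row_b})
        out = truncate_common(
            {"template": template, "m": model}, msa,
            positions={"m": [b for _a, b in aln.matched_positions()]})
        # the two routes agree on sequence and coordinates
        assert out["m"].sequence() == model.sequence()
        assert np.allclose(out["m"].coords, model.coords)
        assert len(out["template"].residues()) == len(out["m"].residues())


class TestSuperposition:
    def test_self_superposition_identity(self):
        template, _ = make_template(10, {})
        result, moved = superpose(template, template.copy())
        assert result.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(result.rotation, np.eye(3), atol=1e-9)

    def test_recovers_random_rigid_transform(self, rng):
        template, _ = make_template(25, {})
        R = Rotation.random(random_state=42).as_matrix()
        t = rng.uniform(-20, 20, 3)
        moved = template.transformed(R, t)
        result, back = superpose(template, moved)
        assert result.rmsd < 1e-6
        assert np.allclose(back.coords, template.coords, atol=1e-6)

    def test_matches_euler_grid_search_oracle(self, rng):
        P = rng.normal(scale=5.0, size=(4, 3))
        Q = rng.normal(scale=5.0, size=(4, 3))
        _R, _t, rmsd = kabsch(P, Q)
        oracle = grid_search_rmsd(P, Q)
        assert rmsd == pytest.approx(oracle, abs=1e-3)
        assert rmsd <= oracle + 1e-9  # Kabsch is the true optimum

    def test_rmsd_invariant_under_common_rigid_motion(self, rng):
        P = rng.normal(size=(8, 3))
        Q = rng.normal(size=(8, 3))
        _r1, _t1, rmsd1 = kabsch(P, Q)
        R = Rotation.random(random_state=7).as_matrix()
        shift = np.array([3.0, -4.0, 5.0])
        _r2, _t2, rmsd2 = kabsch(P @ R.T + shift, Q @ R.T + shift)
        assert rmsd1 == pytest.approx(rmsd2, abs=1e-9)

    def test_collinear_points_rejected(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]],
                     dtype=float)
        with pytest.raises(GagesdError, match="collinear"):
            kabsch(P, P)

    def test_too_few_pairs_rejected(self):
        P = np.array([[0, 0, 0], [1, 0, 0]], dtype=float)
        with pytest.raises(GagesdError):
            kabsch(P, P)
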