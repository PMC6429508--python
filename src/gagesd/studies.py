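"""Validation studies run by the analysis scripts and the acceptance suite.

Each function performs one self-contained computation on synthetic inputs
at its stated study conditions and returns plain numbers: solver accuracy
against closed forms, planted-topology recovery, and ESD ranking recovery
of planted charge flips. Problem sizes are chosen so each study runs in
seconds to a few minutes on one CPU (sizes documented in the methods note).
"""

from __future__ import annotations

import numpy as np

from . import esd_compare as _esd
from . import pb as _pb
from . import prep as _prep
from . import synth as _synth
from .align import MultipleAlignment, identity_matrix
from .cluster import identity_to_distance, single_linkage
from .formats import write_newick
from .types import Atom, ChargedStructure, Structure

# Recovery-study conditions. The planted 8-leaf topology study uses long
# sequences: a binomial power calculation (sibling/cousin distance gap
# 2pL vs noise sqrt(0.112 L) at p = 0.02) puts the per-comparison margin
# at ~4.6 sigma for L = 1500, so recovery is expected to be exact; at
# typical single-domain lengths the margin is < 2 sigma and single linkage
# chains stochastically.
RECOVERY_SEQ_LENGTH = 1500
RECOVERY_RATE_BACKGROUND = 0.02
RECOVERY_SITE = tuple(range(90, 115, 3))

FLIP_TEMPLATE_N_RES = 30
FLIP_TEMPLATE_CHARGED = {12: "K", 15: "R", 18: "K", 21: "K",
                         5: "D", 26: "E"}
FLIP_SITE = (12, 15, 18, 21)
FLIP_COUNTS = {"f0": 0, "f1": 1, "f2": 2, "f3": 3}


def histidine_protonation(ph: float = 6.5) -> float:
    """Fractional protonation of a model histidine (pKa 6.5) at ``ph``."""
    return _prep.ProtonationModel(ph=ph).protonated_fraction(6.5)


def _point_charge(q: float = 1.0, radius: float = 1.5) -> ChargedStructure:
    atom = Atom("NZ", "N", "LYS", 1, "A", 0.0, 0.0, 0.0)
    return ChargedStructure(Structure([atom]), np.array([q]),
                            np.array([radius]))


def solver_oracle_error(ionic_strength: float = 0.0,
                        padding: float = 20.0,
                        shell_radii: tuple = (5, 8, 10, 12, 15)
                        ) -> dict[str, float]:
    """Maximum relative error of the FD-LPB solution vs the Coulomb /
    Debye–Hückel closed form, in a uniform dielectric, on the given shell
    of distances (41³ grid at the default spacing)."""
    charged = _point_charge()
    params = _pb.SolverParams(eps_protein=78.0, eps_solvent=78.0,
                              padding=padding,
                              ionic_strength=ionic_strength)
    grid = _pb.build_grid(charged, params)
    maps = _pb.dielectric_maps(charged, grid, params)
    maps.ion_accessible[:] = True   # uniform medium for the closed form
    phi, info = _pb.solve_lpb(charged, maps, params, grid)
    lam = _pb.coupling_constant(params.temperature)
    kappa, _ = _pb.kappa_parameters(ionic_strength, params.eps_solvent,
                                    params.temperature)
    centre = tuple(d // 2 for d in grid.dims)
    a = float(charged.radii[0])
    errors = {}
    for r in shell_radii:
        value = phi.values[centre[0] + r, centre[1], centre[2]]
        oracle = lam * np.exp(-kappa * (r - a)) / (
            params.eps_solvent * r * (1.0 + kappa * a))
        errors[str(r)] = abs(value - oracle) / abs(oracle)
    return {
        "max_rel_error": max(errors.values()),
        "per_radius": errors,
        "iterations": info["iterations"],
        "phi_at_10A_kTe": float(phi.values[centre[0] + 10, centre[1],
                                           centre[2]]),
    }


def _recovery_charged_positions(n_res: int) -> dict[int, str]:
    pos = {}
    for i, p in enumerate(RECOVERY_SITE):
        pos[p] = "KRKRKKRKR"[i % 9]
    pos[20] = "D"
    pos[n_res - 20] = "E"
    return pos


def topology_recovery_rf(seed: int,
                         n_leaves: int = 8,
                         n_res: int = RECOVERY_SEQ_LENGTH,
                         rate_background: float = RECOVERY_RATE_BACKGROUND
                         ) -> int:
    """Robinson–Foulds distance between the planted tree and the
    single-linkage dendrogram of the simulated family's identity matrix.

    Shell rate is zero: only background positions diverge.
    """
    import dendropy
    from dendropy.calculate import treecompare

    _template, seq = _synth.make_template(
        n_res, _recovery_charged_positions(n_res), id="template")
    tree = _synth.balanced_tree(n_leaves)
    leaves, truth = _synth.evolve_family(
        seq, tree, site_positions=list(RECOVERY_SITE), rate_site=0.0,
        rate_background=rate_background, seed=seed)
    msa = MultipleAlignment({k: v.residues for k, v in leaves.items()})
    identity, labels = identity_matrix(msa)
    dend = single_linkage(identity_to_distance(identity), labels)
    tns = dendropy.TaxonNamespace()
    inferred = dendropy.Tree.get(data=write_newick(dend), schema="newick",
                                 taxon_namespace=tns)
    planted = dendropy.Tree.get(data=truth.tree_newick, schema="newick",
                                taxon_namespace=tns)
    inferred.encode_bipartitions()
    planted.encode_bipartitions()
    return int(treecompare.symmetric_difference(inferred, planted))


def flip_ranking_study(seed: int) -> dict:
    """Rank four species with planted charge-flip counts 0..3 by ESD to
    the template; returns the ranking and whether it matches the planted
    order exactly."""
    template, seq = _synth.make_template(
        FLIP_TEMPLATE_N_RES, FLIP_TEMPLATE_CHARGED, id="template")
    seqs, truth = _synth.make_flip_family(seq, list(FLIP_SITE),
                                          dict(FLIP_COUNTS), seed=seed)
    structures = _synth.realize_structures(template, seq, seqs)
    structures["template"] = template
    params = _pb.SolverParams()
    charged = {k: _prep.prepare_charged(st, ph=7.4)
               for k, st in structures.items()}
    coords = np.vstack([c.coords for c in charged.values()])
    grid = _pb.build_grid(coords, params)
    maps = {k: _pb.dielectric_maps(c, grid, params)
            for k, c in charged.items()}
    potentials = {}
    for k, c in charged.items():
        potentials[k], _info = _pb.solve_lpb(c, maps[k], params, grid)
    site = _synth.make_binding_site(template, list(FLIP_SITE))
    shell = _esd.build_shell(template, site, 5.0, 3.0)
    mask = _esd.build_mask(grid, maps, template, shell,
                           charged["template"].radii)
    matrix = _esd.pairwise_esd(potentials, mask)
    ranking = _esd.rank_species(matrix, "template")
    ranked_flips = [truth.charge_flips_site.get(s, 0)
                    for s in ranking["species"] if s != "template"]
    esd_to_template = {s: float(matrix.esd_to("template")[s])
                       for s in matrix.labels}
    return {
        "ranked_species": [s for s in ranking["species"]
                           if s != "template"],
        "ranked_flip_counts": ranked_flips,
        "exact_order": ranked_flips == sorted(ranked_flips),
        "esd_to_template": esd_to_template,
        "mask_points": matrix.mask_points,
    }


def kabsch_recovery_rmsd(seed: int = 1, n_res: int = 25) -> float:
    """RMSD after recovering a random rigid transform of the template."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    template, _ = _synth.make_template(n_res, {})
    R = Rotation.random(random_state=seed).as_matrix()
    t = rng.uniform(-20.0, 20.0, 3)
    moved = template.transformed(R, t)
    result, _back = _prep.superpose(template, moved)
    return float(result.rmsd)
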