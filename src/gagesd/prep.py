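"""Preparation of comparable charged structures per species.

Homolog models are either supplied by the user or produced by backbone
threading: the homolog sequence is placed on the template backbone at
aligned positions, with a single side-chain pseudo-atom per substituted
residue carrying the side-chain charge. All species are truncated to the
alignment's complete columns, rigidly superposed onto the template (Kabsch
over matched Cα), and assigned fractional Henderson–Hasselbalch formal
charges on standard carrier atoms plus per-element radii.

The charge model is deliberately simple continuum-electrostatics input:
model pKa values and fractional (not binary) protonation make the net
charge a smooth function of pH and represent the familiar half-protonated
histidine at pH 6.5 exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

from .align import MultipleAlignment, PairwiseAlignment
from .types import (
    Atom,
    ChargedStructure,
    GagesdError,
    ONE_TO_THREE,
    SequenceRecord,
    Structure,
)

log = logging.getLogger(__name__)

BACKBONE_ATOMS = {"N", "CA", "C", "O", "OXT"}
SIDECHAIN_PSEUDOATOM = "SC"

# model pKa values of the ionizable groups
MODEL_PKA = {
    "ASP": 3.65, "GLU": 4.45, "HIS": 6.5, "CYS": 8.5, "TYR": 10.5,
    "LYS": 10.53, "ARG": 12.5,
}
NTERM_PKA = 8.0
CTERM_PKA = 3.6

BASES = {"LYS", "ARG", "HIS"}
ACIDS = {"ASP", "GLU"}
OPTIONAL_ACIDS = {"CYS", "TYR"}

# heavy atoms that carry the residue's formal charge
CHARGE_CARRIERS = {
    "LYS": ["NZ"],
    "ARG": ["NH1", "NH2"],
    "ASP": ["OD1", "OD2"],
    "GLU": ["OE1", "OE2"],
    "HIS": ["ND1", "NE2"],
    "CYS": ["SG"],
    "TYR": ["OH"],
}
ARG_FALLBACK = ["CZ"]

ELEMENT_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
                 "H": 1.20}
DEFAULT_RADIUS = 1.70


@dataclass
class ProtonationModel:
    """Model-pKa fractional protonation at a fixed pH."""

    ph: float = 7.4
    pka: dict[str, float] = field(default_factory=lambda: dict(MODEL_PKA))
    nterm_pka: float = NTERM_PKA
    cterm_pka: float = CTERM_PKA
    include_termini: bool = True
    ionize_cys_tyr: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.ph <= 14.0:
            raise ValueError("pH must lie in [0, 14]")
        if any(v <= 0 for v in self.pka.values()):
            raise ValueError("pKa values must be positive")

    def protonated_fraction(self, pka: float) -> float:
        return 1.0 / (1.0 + 10.0 ** (self.ph - pka))

    def residue_charge(self, res_name: str) -> float:
        """Formal charge of one residue's side chain at this pH."""
        if res_name in BASES:
            return +self.protonated_fraction(self.pka[res_name])
        if res_name in ACIDS:
            return -(1.0 - self.protonated_fraction(self.pka[res_name]))
        if res_name in OPTIONAL_ACIDS and self.ionize_cys_tyr:
            return -(1.0 - self.protonated_fraction(self.pka[res_name]))
        return 0.0


def protonation_fractions(structure: Structure, model: ProtonationModel
                          ) -> dict[tuple[str, int, str], float]:
    """Per-residue formal charge (e) keyed by (chain, res number, icode).

    Chain termini contribute +f(N-term pKa) and −(1−f(C-term pKa)) to the
    first and last residue of each chain when the model includes termini.
    """
    charges: dict[tuple[str, int, str], float] = {}
    residues = structure.residues()
    for res in residues:
        key = (res.chain, res.res_seq, res.icode)
        charges[key] = model.residue_charge(res.name)
    if model.include_termini:
        by_chain: dict[str, list] = {}
        for res in residues:
            by_chain.setdefault(res.chain, []).append(res)
        for chain_residues in by_chain.values():
            first, last = chain_residues[0], chain_residues[-1]
            charges[(first.chain, first.res_seq, first.icode)] += \
                model.protonated_fraction(model.nterm_pka)
            charges[(last.chain, last.res_seq, last.icode)] -= \
                (1.0 - model.protonated_fraction(model.cterm_pka))
    return charges


def assign_charges_radii(structure: Structure,
                         residue_charges: dict[tuple[str, int, str], float]
                         ) -> ChargedStructure:
    """Split each residue's formal charge equally over its carrier atoms
    and assign per-element radii. Net charge is conserved exactly.

    Carrier atoms are the terminal side-chain heavy atoms (NZ, NH1/NH2,
    OD1/OD2, OE1/OE2, ND1/NE2 ...); threaded or synthetic residues carry a
    single ``SC`` pseudo-atom instead. A residue with a nonzero charge but
    no carrier falls back to its Cα with a logged warning.
    """
    n = len(structure)
    charges = np.zeros(n)
    radii = np.array([ELEMENT_RADII.get(a.element.upper(), DEFAULT_RADIUS)
                      for a in structure])
    index_by_res: dict[tuple[str, int, str], list[int]] = {}
    for i, a in enumerate(structure):
        index_by_res.setdefault(a.residue_key(), []).append(i)

    for res in structure.residues():
        key = (res.chain, res.res_seq, res.icode)
        q = residue_charges.get(key, 0.0)
        if abs(q) < 1e-15:
            continue
        names = {structure.atoms[i].name: i for i in index_by_res[key]}
        carriers = [names[nm] for nm in CHARGE_CARRIERS.get(res.name, [])
                    if nm in names]
        if not carriers and res.name == "ARG":
            carriers = [names[nm] for nm in ARG_FALLBACK if nm in names]
        if not carriers and SIDECHAIN_PSEUDOATOM in names:
            carriers = [names[SIDECHAIN_PSEUDOATOM]]
        if not carriers and "CA" in names:
            log.warning("no charge carrier for %s %s%d; placing charge on CA",
                        res.name, res.chain, res.res_seq)
            carriers = [names["CA"]]
        if not carriers:
            carriers = list(names.values())[:1]
        for i in carriers:
            charges[i] += q / len(carriers)
    return ChargedStructure(structure, charges, radii)


def prepare_charged(structure: Structure, ph: float = 7.4,
                    include_termini: bool = True) -> ChargedStructure:
    """Convenience: protonate at ``ph`` and assign charges and radii."""
    model = ProtonationModel(ph=ph, include_termini=include_termini)
    return assign_charges_radii(structure, protonation_fractions(structure,
                                                                 model))


# ---------------------------------------------------------------------------
# Threading and truncation

def _sidechain_pseudoatom(res, target_name: str) -> Atom:
    """Place the charge-carrier pseudo-atom for a substituted residue along
    the Cα → side-chain-centroid direction (2.5 Å), or 2.5 Å anti-backbone
    when the template residue has no side chain."""
    ca = res.atom("CA")
    if ca is None:
        anchor = res.atoms[0]
        pos = anchor.pos
    else:
        anchor = ca
        side = [a.pos for a in res.atoms
                if a.name not in BACKBONE_ATOMS]
        if side:
            centroid = np.mean(side, axis=0)
            vec = centroid - ca.pos
        else:
            backbone = [a.pos for a in res.atoms if a.name in BACKBONE_ATOMS
                        and a.name != "CA"]
            if backbone:
                vec = ca.pos - np.mean(backbone, axis=0)
            else:
                vec = np.array([1.0, 0.0, 0.0])
        norm = np.linalg.norm(vec)
        vec = vec / norm if norm > 1e-9 else np.array([1.0, 0.0, 0.0])
        pos = ca.pos + 2.5 * vec
    return Atom(name=SIDECHAIN_PSEUDOATOM, element="C",
                res_name=target_name, res_seq=anchor.res_seq,
                chain=anchor.chain, x=float(pos[0]), y=float(pos[1]),
                z=float(pos[2]), icode=anchor.icode)


def thread_model(template: Structure, template_seq: SequenceRecord,
                 target_seq: SequenceRecord,
                 alignment: PairwiseAlignment) -> Structure:
    """Thread a homolog sequence onto the template backbone.

    At aligned positions where the target letter equals the template's the
    residue is copied verbatim; at substitutions the backbone is kept, the
    residue renamed, and the side chain collapsed to a charge-carrier
    pseudo-atom. Template residues unaligned in the target are dropped.
    """
    if alignment.row_a.replace("-", "") != template_seq.residues:
        raise GagesdError("alignment row a does not match template sequence")
    if alignment.row_b.replace("-", "") != target_seq.residues:
        raise GagesdError("alignment row b does not match target sequence")
    tmpl_residues = template.residues()
    if len(tmpl_residues) != len(template_seq):
        raise GagesdError("template structure/sequence length mismatch")

    atoms: list[Atom] = []
    for pos_a, pos_b in alignment.matched_positions():
        res = tmpl_residues[pos_a - 1]
        target_letter = target_seq.residues[pos_b - 1]
        target_name = ONE_TO_THREE.get(target_letter, "UNK")
        if res.one_letter == target_letter:
            atoms.extend(replace(a) for a in res.atoms)
        else:
            for a in res.atoms:
                if a.name in BACKBONE_ATOMS:
                    atoms.append(replace(a, res_name=target_name))
            atoms.append(_sidechain_pseudoatom(res, target_name))
    return Structure(atoms, id=target_seq.id)


def truncate_common(structures: dict[str, Structure],
                    msa: MultipleAlignment,
                    positions: dict[str, list[int]] | None = None
                    ) -> dict[str, Structure]:
    """Keep only residues in complete MSA columns; all outputs end up with
    equal residue counts.

    ``positions`` optionally maps a structure id to the 1-based residue
    positions (in its MSA row's ungapped sequence) that its residues
    represent, in file order — needed for threaded models that only cover
    the aligned positions. By default residues map 1:1 onto the row.
    """
    cols = msa.complete_column_indices()
    if not cols:
        raise GagesdError("alignment has no complete columns")
    out: dict[str, Structure] = {}
    for sid, st in structures.items():
        col2res = msa.column_to_residue(sid)
        keep_pos = {col2res[k] for k in cols}
        residues = st.residues()
        if positions is not None and sid in positions:
            res_positions = positions[sid]
            if len(res_positions) != len(residues):
                raise GagesdError(
                    f"structure {sid!r}: position list does not match "
                    "residue count")
        else:
            if msa.ungapped(sid) != st.sequence():
                raise GagesdError(
                    f"structure {sid!r} sequence does not match its MSA row")
            res_positions = list(range(1, len(residues) + 1))
        atoms: list[Atom] = []
        for pos, res in zip(res_positions, residues):
            if pos in keep_pos:
                atoms.extend(replace(a) for a in res.atoms)
        out[sid] = Structure(atoms, id=st.id)
    counts = {len(st.residues()) for st in out.values()}
    if len(counts) != 1:
        raise GagesdError("truncation failed to equalise residue counts "
                          "(a structure is missing complete-column residues)")
    return out


# ---------------------------------------------------------------------------
# Kabsch superposition

@dataclass
class SuperpositionResult:
    rotation: np.ndarray
    translation: np.ndarray
    rmsd: float
    n_pairs: int

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation is not orthogonal")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation is improper (det < 0)")


def kabsch(fixed: np.ndarray, mobile: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid transform mapping ``mobile`` onto ``fixed``.

    Returns (rotation, translation, rmsd); the optimal proper rotation is
    obtained via scipy's SVD-based solver.
    """
    P = np.asarray(fixed, dtype=float)
    Q = np.asarray(mobile, dtype=float)
    if P.shape != Q.shape or P.shape[0] < 3:
        raise GagesdError("need at least 3 matched pairs")
    # collinearity check: rank of centred coordinates
    Qc = Q - Q.mean(axis=0)
    if np.linalg.matrix_rank(Qc, tol=1e-8) < 2:
        raise GagesdError("matched points are collinear")
    Pc = P - P.mean(axis=0)
    rot, _rssd = Rotation.align_vectors(Pc, Qc)
    R = rot.as_matrix()
    t = P.mean(axis=0) - Q.mean(axis=0) @ R.T
    moved = Q @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - P) ** 2, axis=1))))
    return R, t, rmsd


def superpose(template: Structure, mobile: Structure,
              pairing: list[tuple[int, int]] | None = None
              ) -> tuple[SuperpositionResult, Structure]:
    """Superpose ``mobile`` onto ``template`` over matched Cα pairs.

    ``pairing`` holds (template residue index, mobile residue index) pairs,
    0-based over file-order residues; by default residues are paired
    one-to-one in order (the threaded/truncated case).
    """
    tmpl_res = template.residues()
    mob_res = mobile.residues()
    if pairing is None:
        if len(tmpl_res) != len(mob_res):
            raise GagesdError("cannot pair residues of unequal counts")
        pairing = [(i, i) for i in range(len(tmpl_res))]

    def _ca(res) -> np.ndarray | None:
        a = res.atom("CA")
        return None if a is None else a.pos

    P, Q = [], []
    for it, im in pairing:
        pa, pb = _ca(tmpl_res[it]), _ca(mob_res[im])
        if pa is not None and pb is not None:
            P.append(pa)
            Q.append(pb)
    if len(P) < 3:
        raise GagesdError("fewer than 3 matched Cα pairs")
    R, t, rmsd = kabsch(np.array(P), np.array(Q))
    moved = mobile.transformed(R, t)
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd,
                               n_pairs=len(P)), moved
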