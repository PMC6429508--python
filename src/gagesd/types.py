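"""Core in-memory containers shared across the pipeline.

The pipeline compares homologous glycosaminoglycan (GAG) binding proteins
across species, so everything downstream is phrased in terms of a small set
of containers: a protein sequence (:class:`SequenceRecord`), a heavy-atom
structure with author residue numbering (:class:`Structure`), a structure
decorated with per-atom partial charges and radii (:class:`ChargedStructure`),
and a regular scalar field on a 3-D grid (:class:`GridField`) used for
electrostatic potentials and masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Sequence

import numpy as np

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
VALID_LETTERS = set(AMINO_ACIDS) | {"X"}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "UNK": "X",
}
ONE_TO_THREE = {v: k for k, v in THREE_TO_ONE.items()}


class GagesdError(Exception):
    """Base class for pipeline errors."""


class FileFormatError(GagesdError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """One species' protein sequence.

    ``id`` is typically a database accession (e.g. ``P32261``) or a synthetic
    label; ``species`` is a free-text species tag. ``residues`` is the
    one-letter amino-acid string (canonical 20 letters plus ``X``), with no
    gap characters.
    """

    id: str
    residues: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        bad = set(self.residues) - VALID_LETTERS
        if bad:
            raise ValueError(
                f"record {self.id!r}: non-amino-acid letters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Atom:
    """A heavy atom with author numbering preserved."""

    name: str
    element: str
    res_name: str
    res_seq: int
    chain: str
    x: float
    y: float
    z: float
    icode: str = ""
    occupancy: float = 1.0

    @property
    def pos(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)

    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain, self.res_seq, self.icode)


@dataclass
class Residue:
    """A group of atoms sharing one (chain, residue number, icode)."""

    chain: str
    res_seq: int
    icode: str
    name: str
    atoms: list[Atom]

    @property
    def one_letter(self) -> str:
        return THREE_TO_ONE.get(self.name, "X")

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


class Structure:
    """An ordered heavy-atom structure.

    Atoms keep the author residue numbering of the source coordinates, so
    binding-site declarations given in template numbering can be matched
    directly.
    """

    def __init__(self, atoms: Iterable[Atom], id: str = ""):
        self.atoms: list[Atom] = list(atoms)
        self.id = id
        for a in self.atoms:
            if not np.isfinite([a.x, a.y, a.z]).all():
                raise ValueError(f"atom {a.name} of {a.res_name} {a.res_seq}: "
                                 "non-finite coordinates")

    def __len__(self) -> int:
        return len(self.atoms)

    def __iter__(self) -> Iterator[Atom]:
        return iter(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Å."""
        return np.array([[a.x, a.y, a.z] for a in self.atoms], dtype=float)

    def set_coords(self, xyz: np.ndarray) -> None:
        xyz = np.asarray(xyz, dtype=float)
        if xyz.shape != (len(self.atoms), 3):
            raise ValueError("coordinate array shape mismatch")
        for a, row in zip(self.atoms, xyz):
            a.x, a.y, a.z = map(float, row)

    def residues(self) -> list[Residue]:
        out: list[Residue] = []
        seen: dict[tuple[str, int, str], Residue] = {}
        for a in self.atoms:
            key = a.residue_key()
            if key not in seen:
                res = Residue(a.chain, a.res_seq, a.icode, a.res_name, [])
                seen[key] = res
                out.append(res)
            seen[key].atoms.append(a)
        return out

    def sequence(self, chains: Sequence[str] | None = None) -> str:
        """One-letter sequence over residues in file order.

        Multi-chain structures are concatenated in file order unless a chain
        selection is given.
        """
        return "".join(
            r.one_letter for r in self.residues()
            if chains is None or r.chain in chains
        )

    def select_chains(self, chains: Sequence[str]) -> "Structure":
        keep = set(chains)
        return Structure([replace(a) for a in self.atoms if a.chain in keep],
                         id=self.id)

    def copy(self) -> "Structure":
        return Structure([replace(a) for a in self.atoms], id=self.id)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        out = self.copy()
        out.set_coords(self.coords @ np.asarray(rotation).T + np.asarray(translation))
        return out


@dataclass
class ChargedStructure:
    """A structure plus per-atom partial charge (e) and radius (Å)."""

    structure: Structure
    charges: np.ndarray
    radii: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.structure)
        self.charges = np.asarray(self.charges, dtype=float)
        self.radii = np.asarray(self.radii, dtype=float)
        if self.charges.shape != (n,) or self.radii.shape != (n,):
            raise ValueError("charges/radii must be one value per atom")
        if (self.radii <= 0).any():
            raise ValueError("radii must be positive")

    @property
    def net_charge(self) -> float:
        return float(self.charges.sum())

    @property
    def coords(self) -> np.ndarray:
        return self.structure.coords


@dataclass
class GridField:
    """A regular scalar field: origin (Å), isotropic spacing (Å), values.

    ``values`` is indexed ``[ix, iy, iz]``; the physical position of a grid
    point is ``origin + spacing * (ix, iy, iz)``.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be a 3-D array")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return tuple(
            self.origin[d] + self.spacing * np.arange(self.dims[d])
            for d in range(3)
        )  # type: ignore[return-value]

    def congruent(self, other: "GridField") -> bool:
        return (
            self.dims == other.dims
            and abs(self.spacing - other.spacing) < 1e-9
            and np.allclose(self.origin, other.origin, atol=1e-9)
        )
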