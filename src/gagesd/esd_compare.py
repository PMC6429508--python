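"""Electrostatic similarity distances over the binding-site shell.

Homolog potentials computed on one shared (template-frame) grid are
compared point-by-point over a mask of solvent points near the declared
GAG-binding residues:

    ESD(a, b) = (1/N) Σ_mask |φ_a − φ_b| / max(|φ_a|, |φ_b|)

with 0/0 terms contributing zero, so ESD ∈ [0, 2]: 0 for identical
potentials, exactly 2 when the potentials are sign-flipped everywhere on
the mask. The Hodgkin similarity index (an inner-product measure) is
computed alongside as a robustness check; rankings use ESD.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .conserve import BindingSite
from .pb import DielectricMaps
from .types import GagesdError, GridField, Structure


@dataclass
class SiteShell:
    """Residues within ``site_radius`` of the declared binding residues,
    plus the thickness of the solvent shell the mask extends over."""

    site: BindingSite
    site_radius: float = 5.0
    shell_thickness: float = 3.0
    residues: list[tuple[str, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.site_radius < 0:
            raise ValueError("site radius must be non-negative")


def shell_residues(structure: Structure, site: BindingSite,
                   site_radius: float = 5.0) -> list[tuple[str, int, str]]:
    """Residues with any heavy atom within ``site_radius`` (inclusive) of
    any heavy atom of a declared site residue; site residues included."""
    residues = structure.residues()
    site_keys = {(r.chain, r.res_seq) for r in site.residues}
    site_res = [r for r in residues if (r.chain, r.res_seq) in site_keys]
    if not site_res:
        raise GagesdError(
            f"none of the declared site residues of {site.protein!r} are "
            "present in the structure")
    missing = site_keys - {(r.chain, r.res_seq) for r in site_res}
    if missing:
        raise GagesdError(f"site residues missing from structure: "
                          f"{sorted(missing)}")
    site_coords = np.vstack([[a.pos for a in r.atoms] for r in site_res])
    out: list[tuple[str, int, str]] = []
    for r in residues:
        key = (r.chain, r.res_seq, r.icode)
        if (r.chain, r.res_seq) in site_keys:
            out.append(key)
            continue
        coords = np.array([a.pos for a in r.atoms])
        d2 = ((coords[:, None, :] - site_coords[None, :, :]) ** 2).sum(-1)
        if (d2 <= site_radius ** 2).any():
            out.append(key)
    return out


def build_shell(structure: Structure, site: BindingSite,
                site_radius: float = 5.0, shell_thickness: float = 3.0
                ) -> SiteShell:
    return SiteShell(site=site, site_radius=site_radius,
                     shell_thickness=shell_thickness,
                     residues=shell_residues(structure, site, site_radius))


def build_mask(grid: GridField, maps_by_species: dict[str, DielectricMaps],
               template: Structure, shell: SiteShell | None,
               radii: np.ndarray, mode: str = "site-shell") -> np.ndarray:
    """Boolean comparison mask on the template grid.

    A point is masked when it is solvent-labelled in every species' map and
    lies within (atom radius + shell thickness) of a shell-residue atom of
    the template (``site-shell`` mode) or of any template atom
    (``entire-structure`` mode, for small proteins).
    """
    from .pb import _distance_to_atoms

    if mode not in ("site-shell", "entire-structure"):
        raise GagesdError(f"unknown mask mode {mode!r}")
    thickness = shell.shell_thickness if shell is not None else 3.0
    if mode == "site-shell":
        if shell is None:
            raise GagesdError("site-shell mode requires a SiteShell")
        keep = set(shell.residues)
        sel = [i for i, a in enumerate(template)
               if a.residue_key() in keep]
        if not sel:
            raise GagesdError("no template atoms in the site shell")
        coords = template.coords[sel]
        sel_radii = np.asarray(radii)[sel]
    else:
        coords = template.coords
        sel_radii = np.asarray(radii)
    near = _distance_to_atoms(grid, coords, sel_radii, thickness)
    mask = near
    for m in maps_by_species.values():
        mask = mask & m.solvent
    if not mask.any():
        raise GagesdError("comparison mask is empty")
    return mask


def esd(phi_a: GridField, phi_b: GridField, mask: np.ndarray) -> float:
    """Grid-averaged normalized absolute potential difference on the mask."""
    if not phi_a.congruent(phi_b):
        raise GagesdError("potential grids are not congruent")
    if mask.shape != phi_a.dims:
        raise GagesdError("mask shape does not match the grids")
    if not mask.any():
        raise GagesdError("comparison mask is empty")
    a = phi_a.values[mask]
    b = phi_b.values[mask]
    denom = np.maximum(np.abs(a), np.abs(b))
    num = np.abs(a - b)
    terms = np.zeros_like(num)
    nz = denom > 0
    terms[nz] = num[nz] / denom[nz]
    return float(terms.mean())


def hodgkin_index(phi_a: GridField, phi_b: GridField, mask: np.ndarray
                  ) -> float:
    """Hodgkin similarity 2⟨φ_a φ_b⟩/(⟨φ_a²⟩+⟨φ_b²⟩) ∈ [−1, 1]."""
    if not phi_a.congruent(phi_b):
        raise GagesdError("potential grids are not congruent")
    a = phi_a.values[mask]
    b = phi_b.values[mask]
    denom = np.sum(a * a) + np.sum(b * b)
    if denom == 0:
        return 1.0
    return float(2.0 * np.sum(a * b) / denom)


@dataclass
class EsdMatrix:
    """Symmetric all-pairwise ESD values plus mask provenance."""

    values: np.ndarray
    labels: list[str]
    mask_points: int
    hodgkin: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("ESD matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("ESD diagonal must be zero")
        if v.min() < -1e-12 or v.max() > 2.0 + 1e-12:
            raise ValueError("ESD entries must lie in [0, 2]")
        self.values = v

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels,
                            columns=self.labels)

    def esd_to(self, reference: str) -> pd.Series:
        if reference not in self.labels:
            raise GagesdError(f"unknown reference species {reference!r}")
        return self.to_frame()[reference]


def pairwise_esd(potentials: dict[str, GridField], mask: np.ndarray
                 ) -> EsdMatrix:
    """All-pairwise ESD (and Hodgkin index) over a shared mask."""
    labels = list(potentials)
    if len(labels) < 2:
        raise GagesdError("need at least 2 species for pairwise ESD")
    n = len(labels)
    out = np.zeros((n, n))
    hsi = np.ones((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            out[i, j] = out[j, i] = esd(potentials[labels[i]],
                                        potentials[labels[j]], mask)
            hsi[i, j] = hsi[j, i] = hodgkin_index(
                potentials[labels[i]], potentials[labels[j]], mask)
    return EsdMatrix(values=out, labels=labels,
                     mask_points=int(mask.sum()), hodgkin=hsi)


def rank_species(matrix: EsdMatrix, reference: str,
                 identity: pd.Series | None = None) -> pd.DataFrame:
    """Rank species by ascending ESD to the reference.

    Ties are broken by percent identity to the reference (descending, when
    supplied), then by label.
    """
    esd_col = matrix.esd_to(reference)
    df = pd.DataFrame({"species": matrix.labels,
                       "esd": esd_col.to_numpy()})
    if identity is not None:
        df["identity_pct"] = [identity.get(s, np.nan) for s in matrix.labels]
        df = df.sort_values(["esd", "identity_pct", "species"],
                            ascending=[True, False, True])
    else:
        df = df.sort_values(["esd", "species"])
    df = df.reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    return df
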