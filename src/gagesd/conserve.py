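"""Per-column conservation grading and cross-species binding-site mapping.

Conservation is scored per alignment column as the Jensen–Shannon
divergence between the column's residue frequencies and a background
distribution (uniform over the 20 amino acids by default), normalised by
its maximum ln 2 so the continuous score lies in [0, 1]; columns rich in
gaps are down-weighted by the occupied fraction. Scores are then binned
into the conventional 1..9 grade scale (9 = most conserved) by equal-width
bins between the profile's minimum and maximum score, mirroring how
conservation grades are usually reported relative to the protein at hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import AMINO_ACIDS, GagesdError, Structure
from .align import MultipleAlignment


def _jsd(p: np.ndarray, q: np.ndarray) -> float:
    """Jensen–Shannon divergence (natural log; max ln 2)."""
    m = 0.5 * (p + q)

    def _kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log(a[mask] / b[mask])))

    return 0.5 * _kl(p, m) + 0.5 * _kl(q, m)


@dataclass
class ConservationProfile:
    """Continuous score in [0,1] and integer grade 1..9 per MSA column.

    ``scores``/``grades`` are ``None`` at all-gap columns.
    """

    scores: list[float | None]
    grades: list[int | None]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "column": np.arange(1, len(self.scores) + 1),
            "score": [np.nan if s is None else s for s in self.scores],
            "grade": [np.nan if g is None else g for g in self.grades],
        })

    def to_tsv(self, path_or_sink) -> None:
        self.to_frame().to_csv(path_or_sink, sep="\t", index=False,
                               float_format="%.6g")


def conservation_profile(msa: MultipleAlignment,
                         background: np.ndarray | None = None
                         ) -> ConservationProfile:
    """Grade every MSA column on the 1..9 conservation scale."""
    if len(msa.rows) < 3:
        raise GagesdError("conservation grading needs at least 3 rows")
    letters = AMINO_ACIDS + "X"
    index = {ch: i for i, ch in enumerate(letters)}
    if background is None:
        background = np.zeros(len(letters))
        background[:20] = 1.0 / 20.0
    background = np.asarray(background, dtype=float)
    background = background / background.sum()

    n_rows = len(msa.rows)
    scores: list[float | None] = []
    for k in range(msa.n_columns):
        col = [row[k] for row in msa.rows.values()]
        residues = [c for c in col if c != "-"]
        if not residues:
            scores.append(None)
            continue
        p = np.zeros(len(letters))
        for c in residues:
            p[index[c]] += 1.0
        p /= p.sum()
        occupancy = len(residues) / n_rows
        scores.append(occupancy * _jsd(p, background) / np.log(2.0))

    present = [s for s in scores if s is not None]
    lo, hi = min(present), max(present)
    span = hi - lo
    grades: list[int | None] = []
    for s in scores:
        if s is None:
            grades.append(None)
        elif span < 1e-12:
            grades.append(9)
        else:
            grades.append(min(9, 1 + int(9.0 * (s - lo) / span)))
    return ConservationProfile(scores=scores, grades=grades)


# ---------------------------------------------------------------------------
# Binding sites

@dataclass(frozen=True)
class SiteResidue:
    chain: str
    res_seq: int
    letter: str


@dataclass
class BindingSite:
    """Declared GAG-binding residues of one protein, in template numbering."""

    protein: str
    residues: list[SiteResidue] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"binding site for {self.protein!r} is empty")

    @property
    def res_numbers(self) -> list[int]:
        return [r.res_seq for r in self.residues]

    def validate_against(self, template: Structure) -> list[str]:
        """Return findings for residues absent from, or mismatching, the
        template structure (empty list = consistent)."""
        findings: list[str] = []
        by_key = {(r.chain, r.res_seq): r.one_letter
                  for r in template.residues()}
        for sr in self.residues:
            letter = by_key.get((sr.chain, sr.res_seq))
            if letter is None:
                findings.append(
                    f"{self.protein}: site residue {sr.chain}{sr.res_seq} "
                    "absent from template")
            elif letter != sr.letter:
                findings.append(
                    f"{self.protein}: site residue {sr.chain}{sr.res_seq} "
                    f"declared {sr.letter} but template has {letter}")
        return findings

    def seq_positions(self, template: Structure) -> list[int]:
        """1-based sequence positions of the site residues in the template's
        file-order residue sequence."""
        keys = [(r.chain, r.res_seq, r.icode) for r in template.residues()]
        lookup = {k[:2]: i + 1 for i, k in enumerate(keys)}
        out: list[int] = []
        for sr in self.residues:
            pos = lookup.get((sr.chain, sr.res_seq))
            if pos is None:
                raise GagesdError(
                    f"site residue {sr.chain}{sr.res_seq} not in template")
            out.append(pos)
        return out


def map_binding_site(site_positions: list[int], site_letters: list[str],
                     msa: MultipleAlignment, template_row: str,
                     target_row: str) -> pd.DataFrame:
    """Map declared binding-site positions from the template row of an MSA
    onto a target row.

    ``site_positions`` are 1-based residue indices into the template row's
    ungapped sequence; ``site_letters`` the expected template letters there.
    Returns one row per site residue with the target letter (or gap), the
    target's own 1-based residue number, and a conserved flag.
    """
    tmpl_seq = msa.ungapped(template_row)
    res2col = msa.residue_to_column(template_row)
    target_cols = msa.column_to_residue(target_row)
    target_seq = msa.ungapped(target_row)

    rows = []
    for pos, letter in zip(site_positions, site_letters):
        if pos < 1 or pos > len(tmpl_seq):
            raise GagesdError(f"site position {pos} outside template sequence")
        if tmpl_seq[pos - 1] != letter:
            raise GagesdError(
                f"site position {pos}: template has {tmpl_seq[pos - 1]!r}, "
                f"declaration says {letter!r}")
        col = res2col[pos]
        tgt_res = target_cols[col]
        tgt_letter = "-" if tgt_res is None else target_seq[tgt_res - 1]
        rows.append({
            "template_position": pos,
            "template_letter": letter,
            "target_letter": tgt_letter,
            "target_position": 0 if tgt_res is None else tgt_res,
            "conserved": tgt_letter == letter,
        })
    return pd.DataFrame(rows)
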