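"""Global sequence alignment and multiple alignments of homolog families.

Pairwise alignment is Needleman–Wunsch with affine gaps (Gotoh's three-state
recursion). A gap of length L costs ``gap_open + gap_extend*(L-1)``: the
first gapped column pays the opening penalty, each further column the
extension penalty. Traceback is deterministic, preferring diagonal, then up
(gap in the second sequence), then left.

Multiple alignments are built progressively: pairwise identities give a
single-linkage guide tree, and profiles are merged bottom-up with
sum-of-pairs column scoring. This is deliberately a desk-scale aligner for
closely related orthologs, not a general-purpose MSA engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .types import GagesdError, SequenceRecord

DEFAULT_GAP_OPEN = 10.0
DEFAULT_GAP_EXTEND = 0.5

_NEG = float("-inf")


@lru_cache(maxsize=4)
def load_matrix(name: str = "BLOSUM62") -> dict[tuple[str, str], float]:
    """Load a substitution matrix as a plain dict keyed by letter pairs."""
    arr = substitution_matrices.load(name)
    letters = arr.alphabet
    table: dict[tuple[str, str], float] = {}
    for i, a in enumerate(letters):
        for j, b in enumerate(letters):
            table[(a, b)] = float(arr[i, j])
    return table


@dataclass
class PairwiseAlignment:
    """Two gapped rows with score and column↔residue coordinate maps."""

    id_a: str
    id_b: str
    row_a: str
    row_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.row_a) != len(self.row_b):
            raise ValueError("alignment rows differ in length")
        for ca, cb in zip(self.row_a, self.row_b):
            if ca == "-" and cb == "-":
                raise ValueError("gap-gap column in pairwise alignment")

    @property
    def n_columns(self) -> int:
        return len(self.row_a)

    def column_to_residue(self, which: str) -> list[int | None]:
        """1-based residue index per column, ``None`` at gap columns."""
        row = self.row_a if which == "a" else self.row_b
        out: list[int | None] = []
        pos = 0
        for ch in row:
            if ch == "-":
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return out

    def matched_positions(self) -> list[tuple[int, int]]:
        """1-based (a, b) residue index pairs at co-occupied columns."""
        ca = self.column_to_residue("a")
        cb = self.column_to_residue("b")
        return [(i, j) for i, j in zip(ca, cb) if i is not None and j is not None]

    def percent_identity(self) -> float:
        pairs = [(a, b) for a, b in zip(self.row_a, self.row_b)
                 if a != "-" and b != "-"]
        if not pairs:
            raise GagesdError("no co-occupied columns in alignment")
        same = sum(1 for a, b in pairs if a == b)
        return 100.0 * same / len(pairs)


def _score_fn(matrix: Mapping[tuple[str, str], float]):
    def s(a: str, b: str) -> float:
        try:
            return matrix[(a, b)]
        except KeyError:
            raise GagesdError(
                f"no substitution score for residue pair ({a!r}, {b!r})"
            ) from None
    return s


def global_align(a: SequenceRecord, b: SequenceRecord,
                 matrix: Mapping[tuple[str, str], float] | None = None,
                 gap_open: float = DEFAULT_GAP_OPEN,
                 gap_extend: float = DEFAULT_GAP_EXTEND) -> PairwiseAlignment:
    """Optimal global alignment under the affine-gap model.

    Ties during traceback are broken deterministically: diagonal, then up,
    then left.
    """
    if matrix is None:
        matrix = load_matrix()
    s = _score_fn(matrix)
    sa, sb = a.residues, b.residues
    n, m = len(sa), len(sb)

    # state 0 = M (match), 1 = X (gap in b, consumes a), 2 = Y (gap in a)
    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_extend)
        ptr[1, i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_extend)
        ptr[2, 0, j] = 2

    def _best(cands: tuple[float, float, float]) -> tuple[float, int]:
        # preference order M, X, Y on exact ties
        best_v, best_k = cands[0], 0
        for k in (1, 2):
            if cands[k] > best_v:
                best_v, best_k = cands[k], k
        return best_v, best_k

    for i in range(1, n + 1):
        ai = sa[i - 1]
        for j in range(1, m + 1):
            sub = s(ai, sb[j - 1])
            v, k = _best((M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]))
            M[i, j] = sub + v
            ptr[0, i, j] = k
            v, k = _best((M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                          Y[i - 1, j] - gap_open))
            X[i, j] = v
            ptr[1, i, j] = k
            v, k = _best((M[i, j - 1] - gap_open, X[i, j - 1] - gap_open,
                          Y[i, j - 1] - gap_extend))
            Y[i, j] = v
            ptr[2, i, j] = k

    score, state = _best((M[n, m], X[n, m], Y[n, m]))
    rev_a: list[str] = []
    rev_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        prev = int(ptr[state, i, j])
        if state == 0:
            rev_a.append(sa[i - 1])
            rev_b.append(sb[j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            rev_a.append(sa[i - 1])
            rev_b.append("-")
            i -= 1
        else:
            rev_a.append("-")
            rev_b.append(sb[j - 1])
            j -= 1
        state = prev
    return PairwiseAlignment(a.id, b.id, "".join(reversed(rev_a)),
                             "".join(reversed(rev_b)), float(score))


class MultipleAlignment:
    """Gapped rows of equal length keyed by record id."""

    def __init__(self, rows: Mapping[str, str]):
        self.rows: dict[str, str] = dict(rows)
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows differ in length")
        (self.n_columns,) = lengths

    @property
    def ids(self) -> list[str]:
        return list(self.rows)

    def ungapped(self, row_id: str) -> str:
        return self.rows[row_id].replace("-", "")

    def column(self, k: int) -> dict[str, str]:
        return {rid: row[k] for rid, row in self.rows.items()}

    def column_to_residue(self, row_id: str) -> list[int | None]:
        out: list[int | None] = []
        pos = 0
        for ch in self.rows[row_id]:
            if ch == "-":
                out.append(None)
            else:
                pos += 1
                out.append(pos)
        return out

    def residue_to_column(self, row_id: str) -> dict[int, int]:
        """1-based residue index → 0-based column index."""
        return {res: col for col, res in
                enumerate(self.column_to_residue(row_id)) if res is not None}

    def complete_column_indices(self) -> list[int]:
        return [k for k in range(self.n_columns)
                if all(row[k] != "-" for row in self.rows.values())]

    def subset_columns(self, cols: Sequence[int]) -> "MultipleAlignment":
        return MultipleAlignment(
            {rid: "".join(row[k] for k in cols)
             for rid, row in self.rows.items()})


def percent_identity(msa: MultipleAlignment, id_i: str, id_j: str) -> float:
    """100 × identical columns / columns where both rows hold residues."""
    ri, rj = msa.rows[id_i], msa.rows[id_j]
    both = [(a, b) for a, b in zip(ri, rj) if a != "-" and b != "-"]
    if not both:
        raise GagesdError(
            f"rows {id_i!r} and {id_j!r} share no co-occupied columns")
    same = sum(1 for a, b in both if a == b)
    return 100.0 * same / len(both)


def identity_matrix(msa: MultipleAlignment) -> tuple[np.ndarray, list[str]]:
    """Symmetric percent-identity matrix over all rows (diagonal 100)."""
    ids = msa.ids
    n = len(ids)
    out = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            p = percent_identity(msa, ids[i], ids[j])
            out[i, j] = out[j, i] = p
    return out, ids


def complete_columns(msa: MultipleAlignment) -> MultipleAlignment:
    """Keep exactly the columns where every row has a residue."""
    cols = msa.complete_column_indices()
    if not cols:
        raise GagesdError("alignment has no complete columns")
    return msa.subset_columns(cols)


# ---------------------------------------------------------------------------
# Progressive MSA over a single-linkage guide tree

def _profile_columns(rows: dict[str, str]) -> list[dict[str, int]]:
    ncol = len(next(iter(rows.values())))
    cols: list[dict[str, int]] = [dict() for _ in range(ncol)]
    for row in rows.values():
        for k, ch in enumerate(row):
            if ch != "-":
                cols[k][ch] = cols[k].get(ch, 0) + 1
    return cols


def _align_profiles(rows_a: dict[str, str], rows_b: dict[str, str],
                    matrix: Mapping[tuple[str, str], float],
                    gap_open: float, gap_extend: float) -> dict[str, str]:
    """Merge two profiles by affine-gap DP on sum-of-pairs column scores."""
    cols_a = _profile_columns(rows_a)
    cols_b = _profile_columns(rows_b)
    n, m = len(cols_a), len(cols_b)

    def colscore(ca: dict[str, int], cb: dict[str, int]) -> float:
        tot = 0.0
        cnt = 0
        for x, nx in ca.items():
            for y, ny in cb.items():
                tot += matrix[(x, y)] * nx * ny
                cnt += nx * ny
        return tot / cnt if cnt else 0.0

    M = np.full((n + 1, m + 1), _NEG)
    X = np.full((n + 1, m + 1), _NEG)
    Y = np.full((n + 1, m + 1), _NEG)
    ptr = np.zeros((3, n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = -(gap_open + (i - 1) * gap_extend)
        ptr[1, i, 0] = 1
    for j in range(1, m + 1):
        Y[0, j] = -(gap_open + (j - 1) * gap_extend)
        ptr[2, 0, j] = 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = colscore(cols_a[i - 1], cols_b[j - 1])
            cands = (M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            k = int(np.argmax(cands))
            M[i, j] = sub + cands[k]
            ptr[0, i, j] = k
            cands = (M[i - 1, j] - gap_open, X[i - 1, j] - gap_extend,
                     Y[i - 1, j] - gap_open)
            k = int(np.argmax(cands))
            X[i, j] = cands[k]
            ptr[1, i, j] = k
            cands = (M[i, j - 1] - gap_open, X[i, j - 1] - gap_open,
                     Y[i, j - 1] - gap_extend)
            k = int(np.argmax(cands))
            Y[i, j] = cands[k]
            ptr[2, i, j] = k

    state = int(np.argmax((M[n, m], X[n, m], Y[n, m])))
    ops: list[str] = []  # 'D' both, 'A' column from a only, 'B' from b only
    i, j = n, m
    while i > 0 or j > 0:
        prev = int(ptr[state, i, j])
        if state == 0:
            ops.append("D")
            i, j = i - 1, j - 1
        elif state == 1:
            ops.append("A")
            i -= 1
        else:
            ops.append("B")
            j -= 1
        state = prev
    ops.reverse()

    merged: dict[str, list[str]] = {rid: [] for rid in
                                    list(rows_a) + list(rows_b)}
    ia = ib = 0
    for op in ops:
        if op in ("D", "A"):
            for rid, row in rows_a.items():
                merged[rid].append(row[ia])
            ia += 1
        else:
            for rid in rows_a:
                merged[rid].append("-")
        if op in ("D", "B"):
            for rid, row in rows_b.items():
                merged[rid].append(row[ib])
            ib += 1
        else:
            for rid in rows_b:
                merged[rid].append("-")
    return {rid: "".join(chars) for rid, chars in merged.items()}


def build_msa(records: Sequence[SequenceRecord],
              matrix: Mapping[tuple[str, str], float] | None = None,
              gap_open: float = DEFAULT_GAP_OPEN,
              gap_extend: float = DEFAULT_GAP_EXTEND) -> MultipleAlignment:
    """Progressive multiple alignment guided by single-linkage clustering
    of pairwise Needleman–Wunsch identities."""
    if matrix is None:
        matrix = load_matrix()
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise GagesdError("duplicate record ids in MSA input")
    if len(records) == 1:
        return MultipleAlignment({records[0].id: records[0].residues})

    n = len(records)
    dist = np.zeros((n, n))
    pair_aln: dict[tuple[int, int], PairwiseAlignment] = {}
    for i in range(n):
        for j in range(i + 1, n):
            aln = global_align(records[i], records[j], matrix,
                               gap_open, gap_extend)
            pair_aln[(i, j)] = aln
            dist[i, j] = dist[j, i] = 100.0 - aln.percent_identity()

    from scipy.cluster.hierarchy import linkage
    from scipy.spatial.distance import squareform

    Z = linkage(squareform(dist, checks=False), method="single")
    profiles: dict[int, dict[str, str]] = {
        i: {records[i].id: records[i].residues} for i in range(n)}
    if n == 2:
        aln = pair_aln[(0, 1)]
        return MultipleAlignment({aln.id_a: aln.row_a, aln.id_b: aln.row_b})
    for step, (u, v, _h, _c) in enumerate(Z):
        merged = _align_profiles(profiles.pop(int(u)), profiles.pop(int(v)),
                                 matrix, gap_open, gap_extend)
        profiles[n + step] = merged
    (final,) = profiles.values()
    # preserve the input record order in the output rows
    return MultipleAlignment({rid: final[rid] for rid in ids})
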