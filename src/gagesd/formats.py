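"""Readers and writers for the standard text formats the pipeline touches.

FASTA (plain and gapped), fixed-column PDB, whitespace PQR, OpenDX scalar
grids, CSV matrices, Newick dendrograms and a JSON run report. Readers and
writers are inverse up to 1e-6 on numeric values and exact on identifiers.
"""

from __future__ import annotations

import io as _io
import json
from typing import IO, Iterable, Mapping, Sequence

import gemmi
import numpy as np
import pandas as pd

from .types import (
    Atom,
    FileFormatError,
    GridField,
    SequenceRecord,
    Structure,
    VALID_LETTERS,
)


def _as_text_handle(source: str | IO[str]) -> IO[str]:
    if isinstance(source, str):
        return _io.StringIO(source)
    return source


# ---------------------------------------------------------------------------
# FASTA

def _read_fasta_rows(source: str | IO[str], *, allow_gaps: bool
                     ) -> dict[str, str]:
    handle = _as_text_handle(source)
    rows: dict[str, str] = {}
    current_id: str | None = None
    chunks: list[str] = []

    def _flush() -> None:
        if current_id is None:
            return
        seq = "".join(chunks).upper()
        allowed = VALID_LETTERS | ({"-"} if allow_gaps else set())
        bad = set(seq) - allowed
        if bad:
            raise FileFormatError(
                f"record {current_id!r}: invalid letters {sorted(bad)!r}")
        if not seq.replace("-", ""):
            raise FileFormatError(f"record {current_id!r}: empty sequence")
        rows[current_id] = seq

    for line in handle:
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            _flush()
            header = line[1:].strip()
            current_id = header.split()[0] if header else ""
            if not current_id:
                raise FileFormatError("FASTA header with empty id")
            if current_id in rows:
                raise FileFormatError(f"duplicate FASTA id {current_id!r}")
            chunks = []
        else:
            if current_id is None:
                raise FileFormatError("sequence data before first FASTA header")
            chunks.append(line.replace(" ", ""))
    _flush()
    if not rows:
        raise FileFormatError("empty FASTA input")
    return rows


def read_fasta(source: str | IO[str]) -> list[SequenceRecord]:
    """Parse FASTA into sequence records.

    Headers are ``>id [optional description]``; bodies are uppercased and
    whitespace is stripped. Duplicate ids and letters outside the 20
    canonical amino acids (plus X) are errors.
    """
    rows = _read_fasta_rows(source, allow_gaps=False)
    return [SequenceRecord(id=rid, residues=seq) for rid, seq in rows.items()]


def read_aligned_fasta(source: str | IO[str]) -> dict[str, str]:
    """Read gapped FASTA rows of equal length, keyed by id."""
    rows = _read_fasta_rows(source, allow_gaps=True)
    if len({len(v) for v in rows.values()}) > 1:
        raise FileFormatError("aligned FASTA rows have unequal lengths")
    return rows


def write_fasta(records: Iterable[SequenceRecord] | Mapping[str, str],
                sink: IO[str] | None = None, *, width: int = 60) -> str:
    """Write records (or gapped id→row mapping) as FASTA; returns the text."""
    out = _io.StringIO()
    items: Iterable[tuple[str, str]]
    if isinstance(records, Mapping):
        items = records.items()
    else:
        items = ((r.id, r.residues) for r in records)
    for rid, seq in items:
        out.write(f">{rid}\n")
        for i in range(0, len(seq), width):
            out.write(seq[i:i + width] + "\n")
    text = out.getvalue()
    if sink is not None:
        sink.write(text)
    return text


# ---------------------------------------------------------------------------
# PDB

_WATERS = {"HOH", "WAT", "DOD"}


def _validate_pdb_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")) and len(line.rstrip()) > 6:
            if len(line) < 54:
                raise FileFormatError(
                    f"line {lineno}: truncated coordinate record")
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise FileFormatError(
                        f"line {lineno}: malformed coordinate column "
                        f"{line[lo:hi]!r}") from None


def read_pdb(source: str | IO[str], *, keep_hydrogens: bool = False,
             keep_hetero: bool = False, id: str = "") -> Structure:
    """Read fixed-column PDB coordinates into a :class:`Structure`.

    Only the first model is used. Author residue numbering is preserved.
    For alternate locations the highest-occupancy conformer is kept (ties:
    first in file). HETATM records, waters and hydrogens are dropped by
    default; they carry no formal-charge carriers the downstream charge
    model uses.
    """
    text = source if isinstance(source, str) else source.read()
    text = text.replace("\r\n", "\n").replace("\r", "\n")
    _validate_pdb_lines(text)
    st = gemmi.read_pdb_string(text)
    if len(st) == 0:
        raise FileFormatError("no coordinate records found")
    model = st[0]
    atoms: list[Atom] = []
    for chain in model:
        for res in chain:
            if res.het_flag == "H" and not keep_hetero:
                continue
            if res.name in _WATERS:
                continue
            by_name: dict[str, gemmi.Atom] = {}
            for at in res:
                if at.element.is_hydrogen and not keep_hydrogens:
                    continue
                prev = by_name.get(at.name)
                if prev is None or at.occ > prev.occ:
                    by_name[at.name] = at
            for at in by_name.values():
                atoms.append(Atom(
                    name=at.name,
                    element=at.element.name,
                    res_name=res.name,
                    res_seq=res.seqid.num,
                    chain=chain.name,
                    x=at.pos.x, y=at.pos.y, z=at.pos.z,
                    icode=(res.seqid.icode or "").strip(),
                    occupancy=at.occ,
                ))
    if not atoms:
        raise FileFormatError("no atoms retained from PDB input")
    return Structure(atoms, id=id)


def write_pdb(structure: Structure, sink: IO[str] | None = None) -> str:
    """Write a structure as fixed-column PDB ATOM records."""
    out = _io.StringIO()
    for i, a in enumerate(structure, start=1):
        name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
        out.write(
            f"ATOM  {i:5d} {name:<4s}{'':1s}{a.res_name:>3s} {a.chain:1s}"
            f"{a.res_seq:4d}{a.icode:1s}   "
            f"{a.x:8.3f}{a.y:8.3f}{a.z:8.3f}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2s}\n"
        )
    out.write("END\n")
    text = out.getvalue()
    if sink is not None:
        sink.write(text)
    return text


# ---------------------------------------------------------------------------
# PQR

def write_pqr(charged, sink: IO[str] | None = None) -> str:
    """Write a charged structure as whitespace-separated PQR.

    The final two numeric fields of each ATOM record are the per-atom
    partial charge (e) and radius (Å).
    """
    out = _io.StringIO()
    st = charged.structure
    for i, (a, q, r) in enumerate(zip(st, charged.charges, charged.radii),
                                  start=1):
        out.write(
            f"ATOM {i:6d} {a.name:<4s} {a.res_name:<3s} {a.chain:1s} "
            f"{a.res_seq:5d} {a.x:10.4f} {a.y:10.4f} {a.z:10.4f} "
            f"{q:9.4f} {r:7.4f}\n"
        )
    out.write("END\n")
    text = out.getvalue()
    if sink is not None:
        sink.write(text)
    return text


def read_pqr(source: str | IO[str], id: str = ""):
    """Read the PQR dialect written by :func:`write_pqr`."""
    from .types import ChargedStructure

    handle = _as_text_handle(source)
    atoms: list[Atom] = []
    charges: list[float] = []
    radii: list[float] = []
    for lineno, line in enumerate(handle, start=1):
        tokens = line.split()
        if not tokens or tokens[0] not in ("ATOM", "HETATM"):
            continue
        if len(tokens) < 10:
            raise FileFormatError(f"line {lineno}: short PQR record")
        try:
            x, y, z, q, r = (float(t) for t in tokens[-5:])
        except ValueError:
            raise FileFormatError(
                f"line {lineno}: malformed numeric fields") from None
        atoms.append(Atom(name=tokens[2], element=tokens[2][0],
                          res_name=tokens[3], res_seq=int(tokens[5]),
                          chain=tokens[4], x=x, y=y, z=z))
        charges.append(q)
        radii.append(r)
    if not atoms:
        raise FileFormatError("no PQR atom records found")
    return ChargedStructure(Structure(atoms, id=id), np.array(charges),
                            np.array(radii))


# ---------------------------------------------------------------------------
# OpenDX scalar grids

def write_opendx(field: GridField, sink: IO[str] | None = None,
                 comment: str = "") -> str:
    """Write a grid as an OpenDX general array (z-fastest data order)."""
    nx, ny, nz = field.dims
    n = nx * ny * nz
    out = _io.StringIO()
    if comment:
        for line in comment.splitlines():
            out.write(f"# {line}\n")
    out.write(f"object 1 class gridpositions counts {nx} {ny} {nz}\n")
    ox, oy, oz = field.origin
    h = field.spacing
    out.write(f"origin {ox:.6e} {oy:.6e} {oz:.6e}\n")
    out.write(f"delta {h:.6e} 0.000000e+00 0.000000e+00\n")
    out.write(f"delta 0.000000e+00 {h:.6e} 0.000000e+00\n")
    out.write(f"delta 0.000000e+00 0.000000e+00 {h:.6e}\n")
    out.write(f"object 2 class gridconnections counts {nx} {ny} {nz}\n")
    out.write(f"object 3 class array type double rank 0 items {n} "
              "data follows\n")
    flat = field.values.reshape(-1)  # C order: z fastest
    for i in range(0, n, 3):
        out.write(" ".join(f"{v:.6e}" for v in flat[i:i + 3]) + "\n")
    out.write('attribute "dep" string "positions"\n')
    text = out.getvalue()
    if sink is not None:
        sink.write(text)
    return text


def read_opendx(source: str | IO[str]) -> GridField:
    """Read the OpenDX dialect written by :func:`write_opendx`."""
    handle = _as_text_handle(source)
    dims: tuple[int, int, int] | None = None
    origin: list[float] | None = None
    deltas: list[list[float]] = []
    values: list[float] = []
    n_items = None
    in_data = False
    for line in handle:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if in_data:
            if line.startswith(("attribute", "object", "component", "end")):
                in_data = False
                continue
            values.extend(float(t) for t in line.split())
            continue
        if line.startswith("object 1 class gridpositions"):
            parts = line.split()
            dims = (int(parts[-3]), int(parts[-2]), int(parts[-1]))
        elif line.startswith("origin"):
            origin = [float(t) for t in line.split()[1:4]]
        elif line.startswith("delta"):
            deltas.append([float(t) for t in line.split()[1:4]])
        elif "data follows" in line:
            n_items = int(line.split()[-3])
            in_data = True
    if dims is None or origin is None or len(deltas) != 3:
        raise FileFormatError("incomplete OpenDX header")
    d = np.array(deltas)
    if not np.allclose(d, np.diag(np.diag(d))) or not np.allclose(
            np.diag(d), d[0, 0]):
        raise FileFormatError("only isotropic axis-aligned grids supported")
    n = dims[0] * dims[1] * dims[2]
    if n_items is not None and n_items != n:
        raise FileFormatError("OpenDX item count does not match dims")
    if len(values) != n:
        raise FileFormatError(
            f"OpenDX data has {len(values)} values, expected {n}")
    return GridField(origin=np.array(origin), spacing=float(d[0, 0]),
                     values=np.array(values).reshape(dims))


# ---------------------------------------------------------------------------
# Newick (ultrametric rendering of a single-linkage dendrogram)

def write_newick(dendrogram) -> str:
    """Render a dendrogram as a rooted ultrametric Newick string.

    Each child branch gets length (merge height − child height)/2, so every
    leaf-to-root path equals half the final merge height and leaf-to-leaf
    path lengths reproduce cophenetic distances.
    """
    labels = dendrogram.labels
    n = len(labels)
    if n == 1:
        return f"{labels[0]}:0.0;"
    merge_height = {i: 0.0 for i in range(n)}
    newick = {i: labels[i] for i in range(n)}
    for step, (u, v, h, _size) in enumerate(dendrogram.merges):
        u, v = int(u), int(v)
        bu = (h - merge_height[u]) / 2.0
        bv = (h - merge_height[v]) / 2.0
        node = n + step
        newick[node] = f"({newick[u]}:{bu:g},{newick[v]}:{bv:g})"
        merge_height[node] = float(h)
    return newick[n + len(dendrogram.merges) - 1] + ";"


# ---------------------------------------------------------------------------
# CSV matrices and the JSON report

def write_matrix_csv(matrix: np.ndarray, labels: Sequence[str],
                     path_or_sink) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=list(labels),
                      columns=list(labels))
    df.to_csv(path_or_sink, float_format="%.6g")


def read_matrix_csv(path_or_source) -> tuple[np.ndarray, list[str]]:
    df = pd.read_csv(path_or_source, index_col=0)
    return df.to_numpy(dtype=float), [str(c) for c in df.columns]


def write_report(report: dict, sink: IO[str] | None = None) -> str:
    text = json.dumps(report, indent=2, sort_keys=True, allow_nan=False)
    if sink is not None:
        sink.write(text + "\n")
    return text
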