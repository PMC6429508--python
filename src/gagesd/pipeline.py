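"""End-to-end per-protein workflow: align → cluster → prep → solve → ESD.

A run is described by a :class:`RunConfig` (JSON on disk). Inputs are
either real files (template PDB plus per-species FASTA/model files) or a
synthetic family generated in-process. Every stage writes its artifact
under the output directory and contributes provenance to a single JSON
report; identical config + seed gives byte-identical CSV/JSON outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import align as _align
from . import cluster as _cluster
from . import conserve as _conserve
from . import esd_compare as _esd
from . import formats as _formats
from . import pb as _pb
from . import prep as _prep
from . import synth as _synth
from .sites import BINDING_SITES, DEFAULT_MODE, DEFAULT_PH
from .types import GagesdError, SequenceRecord, Structure

log = logging.getLogger(__name__)

MODES = ("site-shell", "entire-structure")


class ConfigError(GagesdError):
    """Invalid or inconsistent run configuration."""


class StageError(GagesdError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of one per-protein run."""

    protein: str = "synthetic"
    outdir: str = "gagesd_out"
    seed: int = 1
    reference: str = "template"
    mode: str = "site-shell"
    ph: float | None = None
    # real inputs
    template_pdb: str | None = None
    template_chains: list[str] | None = None
    sequences_fasta: str | None = None
    model_pdbs: dict[str, str] = field(default_factory=dict)
    binding_site: list[list] | None = None   # [[chain, resnum, letter], ...]
    # synthetic inputs
    synthetic: bool = True
    n_res: int = _synth.DEFAULT_N_RES
    n_species: int = 4
    rate_site: float = 0.0
    rate_background: float = 0.02
    charge_flip_bias: float = 0.5
    flip_counts: dict[str, int] | None = None
    # comparison parameters
    site_radius: float = 5.0
    shell_thickness: float = 3.0
    solver: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        try:
            data = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        return cls.from_dict(data)

    def resolved_ph(self) -> float:
        if self.ph is not None:
            return self.ph
        return DEFAULT_PH.get(self.protein, 7.4)

    def resolved_mode(self) -> str:
        if self.mode:
            return self.mode
        return DEFAULT_MODE.get(self.protein, "site-shell")

    def solver_params(self) -> _pb.SolverParams:
        return _pb.SolverParams(**self.solver)


def validate_config(config: RunConfig) -> list[str]:
    """Collect findings (missing files, site inconsistencies); never raises
    for content problems — callers decide whether findings are fatal."""
    findings: list[str] = []
    if config.resolved_mode() not in MODES:
        findings.append(f"mode must be one of {MODES}")
    if not 0.0 <= config.resolved_ph() <= 14.0:
        findings.append("pH outside [0, 14]")
    if config.synthetic:
        if config.n_species < 2:
            findings.append("synthetic family needs at least 2 species")
        return findings

    if not config.template_pdb:
        findings.append("template_pdb is required for non-synthetic runs")
    elif not Path(config.template_pdb).exists():
        findings.append(f"template file missing: {config.template_pdb}")
    if not config.sequences_fasta:
        findings.append("sequences_fasta is required for non-synthetic runs")
    elif not Path(config.sequences_fasta).exists():
        findings.append(f"sequence file missing: {config.sequences_fasta}")
    for species, path in config.model_pdbs.items():
        if not Path(path).exists():
            findings.append(f"model file for {species!r} missing: {path}")
    site = _resolve_site(config, findings)
    if site is not None and config.template_pdb and \
            Path(config.template_pdb).exists():
        with open(config.template_pdb) as fh:
            template = _formats.read_pdb(fh, id="template")
        if config.template_chains:
            template = template.select_chains(config.template_chains)
        findings.extend(site.validate_against(template))
    if config.sequences_fasta and Path(config.sequences_fasta).exists():
        with open(config.sequences_fasta) as fh:
            records = _formats.read_fasta(fh)
        if not records:
            findings.append("empty species list")
    return findings


def _resolve_site(config: RunConfig, findings: list[str] | None = None
                  ) -> _conserve.BindingSite | None:
    if config.binding_site:
        try:
            return _conserve.BindingSite(
                protein=config.protein,
                residues=[_conserve.SiteResidue(str(c), int(n), str(l))
                          for c, n, l in config.binding_site])
        except (TypeError, ValueError) as exc:
            if findings is not None:
                findings.append(f"bad binding_site declaration: {exc}")
            return None
    if config.protein in BINDING_SITES:
        return BINDING_SITES[config.protein]
    if findings is not None and config.resolved_mode() == "site-shell":
        findings.append("site-shell mode needs a binding_site declaration "
                        "or a known protein name")
    return None


def _msa_pair_alignment(msa: _align.MultipleAlignment, row_a: str,
                        row_b: str) -> _align.PairwiseAlignment:
    """Project two MSA rows to a pairwise alignment (drop gap-gap columns)."""
    ra, rb = msa.rows[row_a], msa.rows[row_b]
    keep = [(a, b) for a, b in zip(ra, rb) if not (a == "-" and b == "-")]
    return _align.PairwiseAlignment(
        row_a, row_b, "".join(a for a, _ in keep),
        "".join(b for _, b in keep), score=0.0)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full workflow; returns the report dict.

    Artifacts written: aligned FASTA, identity CSV, dendrogram Newick +
    merge CSV, conservation TSV, site-mapping CSV, per-species PQR,
    per-species potential OpenDX, ESD + Hodgkin CSV, ranking CSV/JSON and
    the JSON report.
    """
    findings = validate_config(config)
    if findings:
        raise ConfigError("; ".join(findings))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "protein": config.protein,
        "seed": config.seed,
        "ph": config.resolved_ph(),
        "mode": config.resolved_mode(),
        "reference": config.reference,
        "stages": {},
    }
    stage = "inputs"
    try:
        template, template_seq, records, site, site_positions = \
            _load_inputs(config)
        report["stages"]["inputs"] = {
            "n_species": len(records),
            "template_residues": len(template.residues()),
        }

        stage = "align"
        msa = _align.build_msa([template_seq] + records)
        (outdir / "alignment.fasta").write_text(
            _formats.write_fasta(msa.rows))
        identity, labels = _align.identity_matrix(msa)
        _formats.write_matrix_csv(identity, labels,
                                  outdir / "identity_pct.csv")
        report["stages"]["align"] = {"n_columns": msa.n_columns,
                                     "labels": labels}

        stage = "cluster"
        dend = _cluster.single_linkage(
            _cluster.identity_to_distance(identity), labels)
        (outdir / "dendrogram.nwk").write_text(
            _formats.write_newick(dend) + "\n")
        dend.to_frame().to_csv(outdir / "merges.csv", index=False,
                               float_format="%.10g")
        report["stages"]["cluster"] = {
            "heights": [float(h) for h in dend.heights]}

        stage = "conservation"
        if len(msa.rows) >= 3:
            profile = _conserve.conservation_profile(msa)
            profile.to_tsv(outdir / "conservation.tsv")
            report["stages"]["conservation"] = {
                "n_graded": sum(g is not None for g in profile.grades)}

        stage = "site_mapping"
        site_letters = [template_seq.residues[p - 1] for p in site_positions]
        mapped = []
        for rec in records:
            df = _conserve.map_binding_site(site_positions, site_letters,
                                            msa, template_seq.id, rec.id)
            df.insert(0, "species", rec.id)
            mapped.append(df)
        mapping = pd.concat(mapped, ignore_index=True)
        mapping.to_csv(outdir / "site_mapping.csv", index=False)
        report["stages"]["site_mapping"] = {
            "conserved_fraction": float(mapping["conserved"].mean())}

        stage = "structures"
        structures: dict[str, Structure] = {template_seq.id: template}
        positions: dict[str, list[int]] = {}
        for rec in records:
            if rec.id in config.model_pdbs:
                with open(config.model_pdbs[rec.id]) as fh:
                    structures[rec.id] = _formats.read_pdb(fh, id=rec.id)
            else:
                aln = _msa_pair_alignment(msa, template_seq.id, rec.id)
                structures[rec.id] = _prep.thread_model(
                    template, template_seq, rec, aln)
                positions[rec.id] = [b for _a, b in aln.matched_positions()]
        structures = _prep.truncate_common(structures, msa, positions)
        truncated_template = structures[template_seq.id]

        stage = "superpose"
        superposed: dict[str, Structure] = {}
        rmsds: dict[str, float] = {}
        for sid, st in structures.items():
            if sid == template_seq.id:
                superposed[sid] = st
                rmsds[sid] = 0.0
                continue
            result, moved = _prep.superpose(truncated_template, st)
            superposed[sid] = moved
            rmsds[sid] = result.rmsd
        report["stages"]["superpose"] = {
            "rmsd_A": {k: round(v, 6) for k, v in rmsds.items()}}

        stage = "charges"
        ph = config.resolved_ph()
        charged = {sid: _prep.prepare_charged(st, ph=ph)
                   for sid, st in superposed.items()}
        for sid, ch in charged.items():
            with open(outdir / f"{sid}.pqr", "w") as fh:
                _formats.write_pqr(ch, fh)
        report["stages"]["charges"] = {
            "net_charge_e": {sid: round(ch.net_charge, 6)
                             for sid, ch in charged.items()}}

        stage = "solve"
        params = config.solver_params()
        all_coords = np.vstack([ch.coords for ch in charged.values()])
        grid = _pb.build_grid(all_coords, params)
        maps = {sid: _pb.dielectric_maps(ch, grid, params)
                for sid, ch in charged.items()}
        potentials = {}
        solver_info = {}
        for sid, ch in charged.items():
            phi, info = _pb.solve_lpb(ch, maps[sid], params, grid)
            potentials[sid] = phi
            solver_info[sid] = {k: info[k] for k in
                                ("iterations", "residual", "omega")}
            with open(outdir / f"potential_{sid}.dx", "w") as fh:
                _formats.write_opendx(phi, fh, comment=f"potential {sid} "
                                      f"(kT/e), pH {ph}")
        report["stages"]["solve"] = {
            "grid_dims": list(grid.dims),
            "spacing_A": params.spacing,
            "per_species": solver_info,
        }

        stage = "esd"
        mode = config.resolved_mode()
        shell = None
        if mode == "site-shell":
            # site residues in the truncated template keep author numbering
            shell = _esd.build_shell(truncated_template, site,
                                     config.site_radius,
                                     config.shell_thickness)
        tmpl_radii = charged[template_seq.id].radii
        mask = _esd.build_mask(grid, maps, truncated_template, shell,
                               tmpl_radii, mode=mode)
        matrix = _esd.pairwise_esd(potentials, mask)
        _formats.write_matrix_csv(matrix.values, matrix.labels,
                                  outdir / "esd.csv")
        if matrix.hodgkin is not None:
            _formats.write_matrix_csv(matrix.hodgkin, matrix.labels,
                                      outdir / "hodgkin.csv")
        identity_to_ref = pd.Series(
            {labels[i]: identity[labels.index(config.reference), i]
             for i in range(len(labels))}) \
            if config.reference in labels else None
        ranking = _esd.rank_species(matrix, config.reference,
                                    identity=identity_to_ref)
        ranking.to_csv(outdir / "ranking.csv", index=False,
                       float_format="%.10g")
        report["stages"]["esd"] = {
            "mask_points": matrix.mask_points,
            "ranking": ranking.to_dict(orient="records"),
        }
    except GagesdError as exc:
        if isinstance(exc, (ConfigError, StageError)):
            raise
        raise StageError(stage, exc) from exc

    _check_report(report)
    with open(outdir / "report.json", "w") as fh:
        _formats.write_report(report, fh)
    return report


#: minimal structural schema for the run report: required keys and, for
#: each stage, the fields every downstream consumer relies on.
REPORT_SCHEMA = {
    "top": ("protein", "seed", "ph", "mode", "reference", "stages"),
    "stages": {
        "align": ("n_columns", "labels"),
        "cluster": ("heights",),
        "superpose": ("rmsd_A",),
        "charges": ("net_charge_e",),
        "solve": ("grid_dims", "spacing_A", "per_species"),
        "esd": ("mask_points", "ranking"),
    },
}


def _check_report(report: dict) -> None:
    missing = [k for k in REPORT_SCHEMA["top"] if k not in report]
    for stage, fields in REPORT_SCHEMA["stages"].items():
        if stage not in report["stages"]:
            missing.append(f"stages.{stage}")
            continue
        missing.extend(f"stages.{stage}.{f}" for f in fields
                       if f not in report["stages"][stage])
    if missing:
        raise StageError("report", GagesdError(
            f"run report is missing fields: {missing}"))
    for info in report["stages"]["solve"]["per_species"].values():
        if not np.isfinite(info["residual"]):
            raise StageError("report", GagesdError(
                "non-finite solver residual in report"))


def _load_inputs(config: RunConfig):
    """Produce (template structure, template record, species records,
    binding site, site sequence positions)."""
    if config.synthetic:
        template, template_seq = _synth.make_template(config.n_res,
                                                      id="template")
        site_positions = sorted(_synth.default_site_positions(config.n_res))
        if config.flip_counts:
            seqs, _truth = _synth.make_flip_family(
                template_seq, site_positions, config.flip_counts,
                seed=config.seed)
        else:
            tree = _synth.balanced_tree(config.n_species)
            seqs, _truth = _synth.evolve_family(
                template_seq, tree, site_positions,
                rate_site=config.rate_site,
                rate_background=config.rate_background,
                charge_flip_bias=config.charge_flip_bias, seed=config.seed)
        site = _synth.make_binding_site(template, site_positions,
                                        protein=config.protein)
        return template, template_seq, list(seqs.values()), site, \
            site_positions

    with open(config.template_pdb) as fh:  # type: ignore[arg-type]
        template = _formats.read_pdb(fh, id="template")
    if config.template_chains:
        template = template.select_chains(config.template_chains)
    template_seq = SequenceRecord(id=config.reference or "template",
                                  residues=template.sequence())
    with open(config.sequences_fasta) as fh:  # type: ignore[arg-type]
        records = _formats.read_fasta(fh)
    site = _resolve_site(config)
    if site is None:
        raise ConfigError("no binding site available")
    site_positions = site.seq_positions(template)
    return template, template_seq, records, site, site_positions
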