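#!/usr/bin/env python
"""Sequence-level analysis of the simulated family.

Reads results/family/family.fasta (run 01_simulate_family.py first),
builds the multiple alignment, the percent-identity matrix, the
single-linkage dendrogram, the per-column conservation profile and the
binding-site mapping table, and writes them under results/sequence/.
"""

import json
import sys
from pathlib import Path

import pandas as pd

from gagesd import align, cluster, conserve, formats

ROOT = Path(__file__).resolve().parent.parent
FAMILY = ROOT / "results" / "family"
OUT = ROOT / "results" / "sequence"


def main() -> int:
    fasta = FAMILY / "family.fasta"
    if not fasta.exists():
        print("run analysis/01_simulate_family.py first", file=sys.stderr)
        return 1
    OUT.mkdir(parents=True, exist_ok=True)

    records = formats.read_fasta(fasta.read_text())
    msa = align.build_msa(records)
    (OUT / "alignment.fasta").write_text(formats.write_fasta(msa.rows))

    identity, labels = align.identity_matrix(msa)
    formats.write_matrix_csv(identity, labels, OUT / "identity_pct.csv")

    dend = cluster.single_linkage(cluster.identity_to_distance(identity),
                                  labels)
    (OUT / "dendrogram.nwk").write_text(formats.write_newick(dend) + "\n")

    profile = conserve.conservation_profile(msa)
    profile.to_tsv(OUT / "conservation.tsv")

    site = json.loads((FAMILY / "binding_site.json").read_text())
    positions = [n for _c, n, _l in site]
    letters = [l for _c, _n, l in site]
    tables = []
    template_id = records[0].id
    for rec in records[1:]:
        table = conserve.map_binding_site(positions, letters, msa,
                                          template_id, rec.id)
        table.insert(0, "species", rec.id)
        tables.append(table)
    mapping = pd.concat(tables, ignore_index=True)
    mapping.to_csv(OUT / "site_mapping.csv", index=False)

    print(f"aligned {len(records)} sequences over {msa.n_columns} columns")
    tri = [identity[i, j] for i in range(len(labels))
           for j in range(i + 1, len(labels))]
    print(f"pairwise identity range: {min(tri):.1f}-{max(tri):.1f}%")
    conserved = mapping.groupby("species")["conserved"].mean()
    print("binding-site conservation per species:")
    for species, fraction in conserved.items():
        print(f"  {species}: {100 * fraction:.0f}% of site residues "
              "conserved")
    print(f"tables written to {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
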