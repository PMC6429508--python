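#!/usr/bin/env python
"""Electrostatic comparison of the simulated family.

Runs the full workflow (threading, truncation, superposition, protonation
at pH 7.4, linearized PB on a shared 1 Å grid, binding-site-shell ESD) on
the same family conditions as 01_simulate_family.py and writes potentials,
the ESD/Hodgkin matrices and the species ranking under results/esd/.
"""

import sys
from pathlib import Path

from gagesd.pipeline import RunConfig, run_pipeline

ROOT = Path(__file__).resolve().parent.parent
OUT = ROOT / "results" / "esd"

CONFIG = RunConfig(
    protein="synthetic",
    outdir=str(OUT),
    seed=1,
    n_res=60,
    n_species=6,
    rate_background=0.02,
    rate_site=0.05,
    charge_flip_bias=0.5,
    mode="site-shell",
    reference="template",
)


def main() -> int:
    report = run_pipeline(CONFIG)
    solve = report["stages"]["solve"]
    print(f"grid {'x'.join(map(str, solve['grid_dims']))} at "
          f"{solve['spacing_A']} A spacing; "
          f"{report['stages']['esd']['mask_points']} mask points in the "
          "site shell")
    print("species ranking by ESD to the template (ascending):")
    for row in report["stages"]["esd"]["ranking"]:
        print(f"  {row['rank']}. {row['species']:<10s} "
              f"ESD {row['esd']:.4f}  identity "
              f"{row.get('identity_pct', float('nan')):.1f}%")
    print(f"artifacts written to {OUT}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
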