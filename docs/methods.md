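# Methods

This note documents the models, conventions and numerical choices behind
`gagesd`, and what the synthetic studies do and do not demonstrate.

## Sequence alignment and identity

Pairwise alignment is global Needleman–Wunsch with affine gaps (Gotoh's
three-state recursion) under BLOSUM62 (from Biopython's substitution
matrices), gap open 10, gap extend 0.5. A gap of length L costs
`open + extend·(L−1)`: the first gapped column pays the opening penalty.
Adjacent gaps of opposite type each pay the opening penalty. Traceback
ties are broken deterministically — diagonal, then up, then left — so
identical inputs always give identical alignments. The implementation is
validated against exhaustive enumeration of all monotone alignment paths
(an independent oracle that never builds a DP table) and against
Biopython's `PairwiseAligner` with matching parameters.

Multiple alignments are built progressively: all pairwise identities give
a single-linkage guide tree, and profiles are merged bottom-up with
sum-of-pairs column scoring (gap symbols score zero) under the same gap
penalties. This is a deliberately small, deterministic aligner adequate
for closely related orthologs; it makes no claim to general MSA accuracy.

Percent identity between two MSA rows counts identical columns over
columns where *both* rows hold residues. Identity dialects differ on the
denominator; this one matches the symmetric matrix that is clustered, and
is stated here because the choice changes numbers for gappy pairs.

## Conservation grading

Each MSA column receives a continuous score: the Jensen–Shannon
divergence between the column's residue frequencies and a background
distribution (uniform over the 20 amino acids by default), normalised by
its maximum ln 2, then multiplied by the column's occupied fraction so
gap-rich columns score lower. Higher scores mean more conserved: an
invariant column attains the maximum, a maximally mixed column the
minimum. Scores are binned into the conventional integer grades 1–9
(9 = most conserved) by equal-width bins between the profile's observed
minimum and maximum, i.e. grades are relative to the protein at hand, as
conservation grades are usually reported. This JSD score is a
deliberately simple stand-in for evolutionary-rate methods (Rate4Site
and its relatives): it ignores phylogeny and treats all rows as
independent, which is acceptable for small ortholog panels but
overweights clusters of near-identical sequences.

## Clustering and dendrograms

Identity is converted to dissimilarity as `d = 100 − P` (zero diagonal
enforced) and clustered with the nearest-point (single-linkage)
algorithm via `scipy.cluster.hierarchy.linkage`; a step-by-step
brute-force agglomeration over explicit member sets serves as the test
oracle. Dendrograms are rendered as rooted ultrametric Newick: each child
branch gets `(merge height − child merge height)/2`, so every
leaf-to-root path equals half the final merge height and leaf-to-leaf
path lengths reproduce cophenetic distances exactly.

## Structure preparation

**Threading.** When no model file is supplied, a homolog model is built
by placing the target sequence on the template backbone at aligned
positions: conserved residues are copied verbatim; substituted residues
keep the backbone (N, CA, C, O) and collapse the side chain to a single
`SC` pseudo-atom 2.5 Å along the Cα→side-chain-centroid direction. This
preserves the feature the ESD comparison is sensitive to — where charge
sits on the surface — without side-chain rotamer building or
minimisation. User-supplied model coordinates are used verbatim.

**Truncation.** All species are cut down to the complete columns of the
MSA so every structure has the same residue count, making the potentials
comparable point-by-point on one grid.

**Superposition.** Matched Cα pairs (1:1 after truncation, or an
explicit pairing) are superposed by the Kabsch least-squares rigid
transform (scipy's SVD-based `Rotation.align_vectors`); at least three
non-collinear pairs are required. A fine Euler-angle grid search is the
test oracle.

**Protonation and charges.** Ionisable groups carry fractional
Henderson–Hasselbalch charges at the run pH using fixed model pKa values
(Asp 3.65, Glu 4.45, His 6.5, Cys 8.5, Tyr 10.5, Lys 10.53, Arg 12.5,
N-terminus 8.0, C-terminus 3.6). Fractional (not binary) charges make
the potential a smooth function of pH and represent the half-protonated
histidine at pH 6.5 exactly. Charges are split equally over the
side-chain carrier atoms (NZ; NH1/NH2; OD1/OD2; OE1/OE2; ND1/NE2; the
`SC` pseudo-atom for threaded residues; Cα as a logged fallback) and
radii come from a per-element table (C 1.70, N 1.55, O 1.52, S 1.80 Å).
Cys/Tyr ionisation is off by default (negligible between pH 5.5 and
7.4); there is no pKa-shift prediction and no disulfide detection — this
is the package's main physics simplification relative to structure-based
pKa methods, chosen for determinism and testability.

## Grid electrostatics

The linearized Poisson–Boltzmann equation
`∇·(ε∇φ) − ε_s κ² φ = −4π λ ρ` is discretised with a 7-point
finite-difference stencil. With lengths in Å, charges in e and φ in
thermal-voltage units (kT/e), the coupling constant
`λ = e²/(4πε₀kT)` (≈560.5 Å at 298.15 K) is computed from scipy's
physical constants at run time, never hard-coded.

- **Grid.** Atom-centre bounding box plus 10 Å padding, 1.0 Å spacing,
  odd dims. Defaults: ε_solvent 78.0, ε_protein 2.0, probe 1.4 Å,
  298.15 K. Where both 298 K and 298.15 K would be defensible, 298.15 K
  is used.
- **Dielectric boundary.** Molecular (solvent-excluded) surface by grid
  morphology: points within `r_i + probe` of any atom are marked, then
  eroded by the probe using a Euclidean distance transform, so
  probe-inaccessible crevices stay protein. Boundary faces take the
  harmonic mean of the two dielectrics. This volumetric approximation
  was verified against a direct sphere-rolling construction on a
  two-atom gap case.
- **Ions.** Ionic strength defaults to 0 M (the comparison is of
  potential patterns in water); when I > 0, κ² acts only outside the
  protein plus a 2 Å Stern shell. 0.15 M is exercised in the validation
  studies.
- **Charges** are spread to the 8 surrounding nodes by trilinear
  weights.
- **Boundary condition.** Dirichlet values from the superposition of
  single-atom Debye–Hückel potentials
  `q λ e^{−κ(r−a)} / (ε_s r (1+κa))` — also the analytic oracle for the
  solver in a uniform dielectric.
- **Solver.** Checkerboard (red–black) successive over-relaxation to a
  relative residual of 1e-6. The relaxation factor defaults to the
  near-optimal `ω = 2/(1+sin(π/n_max))` for the grid size (≈1.86 on a
  41³ grid), which converges in ~100 sweeps where a fixed mid-range
  ω (e.g. 1.6) needs several times more; a fixed ω can be set in
  `SolverParams`. Iteration counts and final residuals are recorded in
  the run report. Non-convergence raises an error carrying the residual
  history.

Measured accuracy (41³ grid, uniform dielectric): maximum relative error
1.2% against Coulomb and 1.0% against Debye–Hückel at 0.15 M over the
5–15 Å shell.

## ESD comparison

All species share the template-frame grid. The comparison mask contains
grid points that are (a) solvent in *every* species' dielectric map and
(b) within atom radius + 3 Å of a shell-residue atom of the template.
Shell residues are those with any heavy atom within 5 Å (inclusive) of
any heavy atom of the declared binding-site residues; the declarations
for the six study proteins (antithrombin, heparanase, CCL5, eotaxin-1,
IL-8, PF4, in template author numbering) ship in `gagesd.sites`. Small
proteins can be compared over their entire surface instead
(`entire-structure` mode); the per-protein default follows the
large/small split of the study set. A single shared mask — rather than
per-pair masks — keeps the all-pairwise matrix internally consistent.

    ESD(a,b) = mean over mask of |φ_a − φ_b| / max(|φ_a|, |φ_b|)

with 0/0 terms contributing zero; ESD ∈ [0, 2], is symmetric, vanishes
iff the potentials agree on the mask, and is invariant to common
rescaling. Grid-point averaging over the masked solvent shell is used
(rather than integration over an isopotential surface). The Hodgkin
index `2⟨φ_aφ_b⟩/(⟨φ_a²⟩+⟨φ_b²⟩)` is computed alongside as a robustness
check; rankings use ESD, with percent identity to the reference as the
tie-breaker.

## Synthetic families and what they show

The generator emulates the statistical structure of an ortholog panel:

- an ideal α-helix template (Cα rise 1.5 Å, 100° turn, 2.3 Å radius) with
  one `SC` pseudo-atom per residue and a basic K/R binding patch plus
  scattered acidic residues — defaults: 60 residues, site at positions
  24–39, two Asp/Glu elsewhere;
- divergence along a planted tree with independent per-position
  substitution at class-specific per-branch rates (binding-site vs
  background, default 0.02/branch background — a few percent per branch,
  the divergence scale of mammalian orthologs); site substitutions are
  charge-altering with a configurable bias, background substitutions stay
  within their charge group;
- threaded structures and a truth record of every planted event.

**Study sizes.** The topology-recovery study uses an 8-leaf balanced tree
at background rate 0.02 with 1500-residue sequences. The length is set by
a power calculation, not by trial: with per-branch, per-position rate p,
sibling and cousin leaf pairs differ in expected proportion 2p vs 4p, so
the decision margin per single-linkage comparison is roughly
`2pL/√(0.112·L)` — about 1.7σ at L=200 (recovery fails stochastically)
and 4.6σ at L=1500, where exact recovery across five seeded replicates
has union-bound failure probability ~1e-3. Verified: Robinson–Foulds
distance 0 for seeds 1–5. The ESD-ranking study plants 0/1/2/3
charge-reversing substitutions in the binding site of a 30-residue
template (grid ≈ 31×31×65) and recovers the exact planted order for
seeds 1–5, with ESD to the template increasing ≈0 → 0.73 → 1.35 → 1.65.
The full-pipeline fixture (6 species, 60 residues, grid 31×31×109) runs
in ~10 s.

**What passing does not show.** The synthetic families have gap-free
alignments of equal length, a rigid shared backbone, two-state charge
classes and no rate heterogeneity beyond the two site classes. Passing
therefore validates the machinery — alignment, clustering, threading,
superposition, the solver, masking and the ESD ranking — under known
truth; it does not validate homology-model quality, pKa shifts in real
binding sites, oligomeric-state choices, or alignment accuracy on
distant homologs, all of which affect real cross-species conclusions.

## Reproducibility and degenerate inputs

Everything stochastic takes an explicit seed; identical config + seed
gives byte-identical CSV/JSON artifacts (fixed float formats, sorted
JSON keys). Degenerate inputs fail loudly: empty FASTA, gap-gap columns,
MSAs with no complete columns, fewer than three superposition pairs or
collinear points, charged atoms outside the grid interior, empty
comparison masks, NaN distances. PDB reading keeps author residue
numbering (binding sites are declared in it), keeps the
highest-occupancy altloc (ties: first), first model only, and drops
hydrogens/HETATM/waters by default.

## Known limitations

- The charge model places fractional formal charges on carrier atoms;
  no force-field partial charges, no pKa shifts from the protein
  environment.
- Linear (not nonlinear) PB, single-resolution solve, no focusing; fine
  for comparing potential patterns at moderate charge densities, not for
  absolute energetics.
- The progressive MSA and JSD conservation score are desk-scale
  substitutes for server-grade tools; they are deterministic and
  adequate for close orthologs, and their conventions are stated above
  so results are interpretable.
- Cross-species runs on real proteins require user-supplied template
  structures, sequences and (optionally) homology models; database
  content is not redistributed.
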