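# Methods

This note documents the models, parameters and numerical choices behind
`mirrorbind`, and what the desk-scale validation does and does not
demonstrate.

## Scope and philosophy

The package reproduces the *logic* of an NCAA D-protein affinity-maturation
funnel — ensemble generation, rotamer mutation scanning, curation,
staged-softcore thermodynamic integration, combination design — at a scale
where every step can be verified against an exact reference. Cluster-scale
components (explicit TIP3P solvent, Ewald electrostatics, SHAKE-constrained
MD, production full-atom design score functions, backbone-dependent rotamer
statistics) are
deliberately out of scope; each is replaced by a simpler component honouring
the same contract, so the pipeline's decision structure, bookkeeping and
estimators are exercised exactly as they would be in production. The
published VEGF / D-RFX001 ΔΔG tables ship as checksummed fixtures and drive
the selection/combination logic; they are not re-derived by simulation.

## Structures and chirality

Structures are stored hierarchically (models → residues → atoms) with
author (PDB) residue numbering throughout; PDB parsing and writing go
through biotite, and multi-model PDB doubles as the trajectory format.
Chirality is labelled per residue from the improper dihedral N–CA–C–CB:
values in (−180°, 0°) are L, in (0°, 180°) D; ideal L-alanine measures
≈ −120°. Residues without a CB are achiral; missing backbone atoms give
*unknown*. Mirroring reflects coordinates through the xy-plane (z → −z) —
any single reflection is equivalent up to rotation — and swaps L↔D labels;
it is an exact involution. Interface residues are those with any heavy atom
strictly closer than 5.0 Å (heavy atoms only, the conservative reading) to
any target-chain heavy atom in any ensemble member, with the per-residue
minimum distance recorded.

## Energy model

A united-heavy-atom force field: harmonic bonds (and optional angles /
cosine torsions), 12-6 Lennard-Jones with Lorentz–Berthelot combination,
plain Coulomb with constant dielectric ε = 1 (distance-dependent ε = r
available for scan scoring), Coulomb constant 332.0636 kcal·Å/(mol·e²),
hard 12.0 Å cutoff with no long-range correction. 1-2 and 1-3 pairs are
excluded. Side-chain groups are coarse: aliphatic heavy atoms are single
beads, aromatic and aliphatic rings are single centroid beads (benzene-,
naphthyl/indanyl- and cyclohexyl-sized), charged termini are single ±1 e
beads. Parameters live in a plain-text file (`data/toyff.txt`) alongside
the residue templates.

The `interface_score` used by the scan is E(complex) − Σ E(isolated chains)
at fixed coordinates, which reduces exactly to the cross-chain nonbonded
energy; negative is favourable.

## Residue templates and rotamers

Templates for the 20 canonical amino acids and the 10 NCAAs used in the
design tables (DPP, IGL, 004, D4P, NAL, 26P, HSE, DAB, ALC, ABA) are
internal-coordinate records (bond/angle/dihedral per atom, NeRF
construction) with chi definitions. NCAA geometries follow their structural
descriptions — DPP is a one-carbon lysine, IGL carries its ring directly on
Cα, 004/D4P are shortened Phe/Tyr, 26P is an arginine-sized negative
residue with extended reach — with idealised bond lengths and angles. The
Cβ improper (−120° for L) encodes chirality; building a D residue negates
every side-chain dihedral, producing the exact mirror geometry (verified by
the chirality assignment round trip).

The rotamer library is backbone-independent: chi means and standard
deviations per residue, with an optional ±2σ expansion that turns each base
rotamer into the {−2σ, 0, +2σ} grid per chi (3^k variants). United ring
beads absorb the chi angles beyond the ring attachment, so rotamer counts
are small; this is a deliberate desk-scale simplification and the template
format supports finer representations.

## Repacking and scanning

Repacking is iterated stochastic descent over discrete rotamer assignments:
random restarts (default 4–8) followed by greedy single-position sweeps in
randomised order, ties broken toward the lower rotamer index, so results
are deterministic given the seed. On instances up to 4 positions × 4
rotamers it reproduces exhaustive enumeration (tested).

The scan mutates each interface position to each alphabet code on each
backbone of the ensemble, repacks *all* interface side chains, and records
ΔScore = mutant − native interface score on the same backbone and repeat.
Repeats (default 100, configurable down for toy runs) give a mean ± sd.
Per (position, code) both the mean over backbones and the best (lowest)
per-backbone mean are kept; the best value is the ranking statistic, on the
grounds that a single conducive backbone suffices for design. Logo heights
are |ΔScore| for negative ΔScore only, normalised to a maximum of 1 per
column.

## Curation

Two automated rules stand in for manual structure inspection: (1) mutations
to large hydrophobic residues whose mutated side chain has no heavy atom
within 5.0 Å of the target are removed; (2) glycine and alanine candidates
are flagged/removed, since score functions that reward clash removal are
biased toward them. Hydrogen bonds use donor–acceptor distance ≤ 3.5 Å and
D–H···A angle ≥ 120° (angle check skipped when hydrogens are absent, as in
the united-atom model); salt bridges use opposite formal charges within
4.0 Å. These thresholds are standard structural-biology conventions. Each
removal carries exactly one primary reason code and curation is idempotent.
Observed removal fractions are reported but are not acceptance quantities —
they depend on the candidate mix.

## Thermodynamic integration

Mutations use a dual topology: common atoms (identical parameters in both
states), vanishing atoms (native side chain) and appearing atoms (mutant
side chain, never interacting with the vanishing set). The three stages —
decharge, vdW, recharge — exist because scaling charges while vdW spheres
shrink destabilises sampling; charges therefore change only linearly and
only the vdW stage needs the separation-shifted softcore form (α = 0.5),
which is exactly standard LJ at full coupling and finite at r = 0
otherwise. Per-pair coupling is the product of the two atoms' couplings.
Endpoint identities hold to machine precision: the decharge stage at λ = 0
equals the plain wild-type energy and the recharge stage at λ = 1 equals
the plain mutant energy (dummy atoms contribute nothing in the charge
stages). In the vdW stage both tether sets are bonded; the free energy of a
tethered, non-interacting dummy is environment-independent and cancels
exactly in ΔΔG.

Default λ schedule: 9-point Gauss–Legendre on (0, 1) per stage (weights sum
to 1); a uniform trapezoid schedule is available. One window = one
independent simulation (minimise → equilibrate → sample), 54 in total per
mutation (9 windows × 3 stages × 2 environments). ⟨∂U/∂λ⟩ uses the
analytic derivative (validated against central finite differences to
relative 1e-5); window errors are block-averaged standard errors (10
blocks) and propagate through the quadrature as √(Σ wᵢ² seᵢ²). Window
seeds derive from the master seed by hashing (environment, stage, window),
so legs are independent, order-insensitive and reproducible. The sign
convention is fixed: negative ΔΔG = better binder. Kd fold-change is
exp(−ΔΔG/RT) with R = 1.9872×10⁻³ kcal/(mol·K).

The stability gate computes each frame's RMSD to the trajectory-average
structure after superposition and fails a mutation when any frame exceeds
4.0 Å (strictly); gated mutations are marked rejected and no TI legs run.

## Sampling

Metropolis Monte Carlo with single-atom Gaussian moves replaces MD: for
toy systems it yields identical equilibrium averages without integrator
stability concerns, and a Langevin integrator could be added behind the
same interface. Temperature default 300 K, kB = 1.9872×10⁻³ kcal/(mol·K);
identical seeds give bit-identical trajectories (numpy PCG64). Minimisation
is nonlinear conjugate gradient with numerical gradients; the reported
energy sequence is non-increasing and termination (gradient tolerance vs
iteration cap) is reported. Equilibration applies a schedule of harmonic
positional restraints that must end at weight zero; the convergence flag
requires each successive 10%-block mean structure of the unrestrained tail
to lie within 0.5 Å RMSD of the cumulative mean (the production protocol's
"converged by RMSD" criterion has no published threshold; this plateau rule
is the package's stand-in).

## Clustering

Trajectories are clustered by deterministic leader-radius clustering in
frame order on superposed backbone RMSD (mask N, CA, C, O; default radius
2.0 Å), with medoid refinement: the representative is the medoid when every
member stays within the radius of it, otherwise the leader (which satisfies
the radius by construction). Occupancy is the member fraction in percent.
The published protocol's radius-based clustering tool has a dialect-specific
`maxerr` parameter with no published meaning; it is not emulated.

## Toy systems and oracles

`toyfactory` generates host–guest complexes: a line of host beads, a short
D-chirality guest peptide (alanine scaffold by default, extended strand,
CA–host gap 5.5 Å so the native complex has a genuine sub-5 Å interface),
and planted interactions (salt bridge, hydrogen bond, hydrophobic patch)
placed complementary to a chosen mutation's extended side chain. At
generation time the planted mutation is verified by exhaustive evaluation
to be the global optimum of the interface score at its position, giving
scan tests a known ground truth; unrealisable geometries (bead overlaps,
non-optimal plants) raise errors.

Three oracle families provide exact reference free energies:

* **harmonic spring** (k_A → k_B): ΔG = (k_B T/2) ln(k_B/k_A) per degree of
  freedom;
* **fixed-pair charging** at frozen geometry: ΔG = k_C Δ(q₁q₂)/r;
* **grid quadrature**: ΔG = −kT ln(Z(1)/Z(0)) with Z by dense numerical
  integration over a ≤ 2-D (or radially symmetric) configuration space.

The charge-flip binding toy (a guest bead tethered 3.2 Å from a host bead,
charge +0.3 e → −0.3 e, host −0.5 e in the complex environment and neutral
in the free environment, tether k = 10 kcal/mol/Å²) is fully computable:
identical tethers and LJ parameters for both alchemical beads make the
dummy contributions cancel exactly, reducing the exact ΔΔG to a radial
one-dimensional partition-function ratio. These parameters were calibrated
once so that the TI estimator's statistical error at the suite's sampling
budget (9 windows × 8 000 production steps per window per stage) is
≈ 0.02 kcal/mol, comfortably inside the 0.05 kcal/mol agreement bound the
validation suite asserts; observed |ΔΔG_TI − ΔΔG_exact| ≤ 0.022 kcal/mol
over five independent seeds. The same toy closes the thermodynamic cycle:
the difference of association free energies (mutant − wild type, from
partition functions) matches the TI ΔΔG within statistical error.

## Pipeline and reproducibility

`run_pipeline` chains prepare → sample → cluster → scan → curate → TI →
combine → report on a toy complex. Every stage writes its outputs plus a
manifest (config fingerprint, seed); reruns reuse cached stages, and
deleting one stage's outputs recomputes only that stage with identical
results. All numeric outputs are pure functions of (config, seed). Defaults
mirror the production protocol's stated parameters (300 K, 12 Å cutoff,
2.0 Å cluster radius, 5 Å interface, 9 windows, 4.0 Å gate, 2.0 kcal/mol
combination threshold, 100 scan repeats); run configs scale the simulation
budgets to toy size. The pipeline's vacuum electrostatics with unit
dielectric produce large raw ΔΔG magnitudes on charged toys — internally
consistent, but not comparable to solvated protein values.

## Fixtures

The three published result tables are transcribed as TSV (sparse long
format) with SHA-256 integrity checks and structural invariants (26 filled
NCAA cells over 11 positions; combination members must exist in the
single-mutation table). Signed zeros are preserved as printed (+0.0 and
−0.0) and neither counts as an improvement, which keeps the confirmed-
improvement count at 16 without sign ambiguity. One internal inconsistency
in the source is resolved in favour of the table row label (position 31 is
stored as V31). The published interface list (18 residues) and the manual
curation fractions (≈70% / 59%) are human- and trajectory-dependent and are
not fixture quantities.

## Known limitations

* Vacuum electrostatics and united-atom sterics: toy ΔΔG values are not
  physical binding energies; only their estimator properties are validated.
* Backbone-independent rotamers with coarse ring beads underestimate
  side-chain conformational diversity.
* The single-reflection mirror convention changes coordinate handedness
  globally; structures intended for docking against unmirrored partners
  must be mirrored consistently.
* Leader clustering depends on frame order (documented, deterministic);
  cluster counts are monotone in radius but cluster boundaries are not
  optimised.
* The stability gate samples short apo trajectories; slow conformational
  drift below the RMSD threshold is not detected.
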