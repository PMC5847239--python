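# Methods

This note documents the models and procedures implemented in dimerdyn,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic study systems do and do not show
about real simulation data.

## Structures, trajectories, selections

Residue identity is `(chain_id, residue_index, insertion_code)`
everywhere, preserving author numbering from the PDB.  PDB reading and
writing go through gemmi; multi-MODEL files become one `Structure` per
model.  Binary trajectories (DCD/XTC) are read through mdtraj against the
bound structure; multi-model PDB is the native text trajectory format.
Per-atom energy parameters travel in an 8-column tab-separated table
(serial, name, charge, Rmin/2 in Å, ε in kcal/mol, intrinsic GB radius in
Å, HCT descreening scale, bonded partners), which keeps the test surface
free of heavyweight binary topology formats.  Coordinates are assumed
whole (unwrapped); no minimum-image logic is applied in any analysis.

The selection language is deliberately small — `name`, `chain`, `resid`
(with ranges), `resname`, `element`, `protein`, `water`, `backbone`,
combined with `and`/`or`/`not` — enough to express every selection the
analyses need, deterministic, and order-preserving.

## Flexibility

RMSD uses Kabsch superposition on a fit mask (typically protein Cα) and
evaluates deviation on a separate calculation mask, so core-domain
profiles excluding linkers and loops are just a second mask.  RMSF
concatenates replicas, drops a per-replica initial window (the analysis
convention is to discard early equilibration-like segments; the window is
a parameter in ps), and takes fluctuations about an **iterated mean
structure** (fit → mean → refit until the mean moves < 1e−6 Å).  The mean
reference was chosen because no single-frame reference is canonical and
iteration removes first-frame bias.  PCA frame selection superposes the
interface-Cα coordinates, projects onto the first two principal axes,
bins on a 50×50 grid over the data's bounding box (bin count is a knob;
the grid covers the occupied region), and accumulates bins from most
populated downward — ties broken by flat bin index — until the requested
trajectory coverage (default 15%) is reached.  PCA is unweighted: mass
weighting is immaterial for single-element Cα sets.

## Secondary structure

The Kabsch–Sander rules are implemented in full 8-letter form
(H, G, I, E, B, T, S, C): backbone H-bonds where the electrostatic
pairing energy `0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN)` falls
below −0.5 kcal/mol, helices from consecutive n→n+3/4/5 turns, strands
from parallel/antiparallel bridge ladders (isolated bridges are B),
bends from the 70° Cα virtual angle.  Amide hydrogens are reconstructed
1.0 Å from N along the preceding C=O direction when absent — the
classic DSSP convention — so inputs may carry or lack hydrogens.
Assignment priority is H, E, B, G, I, T, S.  A chain break (C–N distance
> 2.5 Å) suppresses turn and bridge patterns across the gap.  The
implementation is cross-checked in the test suite against mdtraj's
independent DSSP port on ideal fixtures and ensemble models (≥ 95%
agreement on collapsed helix/strand/coil classes; boundary residues may
differ).

"Completely structured" in the strand census reads literally: every
residue of the declared strand region must be labelled E.  Timelines also
report per-residue label fractions and the folded fraction (frames in
which the whole region is E).

## Hydrogen bonds and water bridges

Detection is purely geometric with two presets: distance d(D–A) < 3.5 Å
with angle θ(H–D–A) < 30°, and d < 3.9 Å with θ < 90°.  Both
comparisons are strict, the angle is measured at the donor, and the
second envelope strictly contains the first, so its detections are always
a superset.  Donor/acceptor chemistry is element-based (N/O with an
attached hydrogen donate; N/O accept) from a shipped data file; richer
atom typing is intentionally not reproduced because the presets are used
as threshold sets, not chemistry models.  Water bridges enumerate
protein—w1(—w2)—ligand chains where every consecutive link is an H-bond
in either donation direction (water↔water donation is allowed both
ways); per (protein atom, ligand atom) pair only the minimal-water chain
is kept, and frames are classified exclusively (direct > one-water >
two-water) so the reported percentages are disjoint and additive.

## Conformational clustering

The Daura nearest-neighbour scheme: pairwise RMSD on the calculation
mask after per-pair best fit (batched 3×3 SVDs keep the n² fits cheap),
then repeatedly extract the frame with the most neighbours within the
cutoff.  Ties between equal neighbour counts are broken by the lowest
frame index — the original scheme leaves this open and determinism
matters more than any particular choice.  The cutoff for ligand-pose
clustering defaults to 1.0 Å and is a parameter.

## Dimerization energetics

Single-trajectory MM-GBSA with the entropic term omitted by
construction.  Monomer conformations are the complex frames, so
intra-monomer gas-phase terms cancel exactly and the gas phase reduces to
inter-group Coulomb (k_C = 332.0636 kcal·Å/(mol·e²)) and Lennard-Jones
(Rmin/2 additive, ε geometric).  Polar solvation is GB with
`f_GB = sqrt(r² + R_iR_j·exp(−r²/(4R_iR_j)))` including self terms;
effective radii come from the analytic HCT pairwise-descreening integral
with OBC(II) rescaling
(`R_i⁻¹ = ρ̃_i⁻¹ − ρ_i⁻¹·tanh(αΨ − βΨ² + γΨ³)`, α=1.0, β=0.8, γ=4.85,
offset 0.09 Å), verified against direct numeric quadrature of the
descreening integral in the tests.  Defaults ε_in = 1, ε_out = 78.5,
zero salt, γ_SA = 0.0072 kcal/(mol·Å²), β_SA = 0, probe 1.4 Å — the
conventional constants of the GB-OBC/LCPO toolchain this analysis
mirrors; none is system-specific and all are config-overridable.  No
distance cutoff is applied to GB pair sums at these system sizes.

Surface areas: Shrake–Rupley on a deterministic golden-spiral grid
(default 960 points) is the reference method used by every invariant;
LCPO is provided for fidelity to the approximate analytic workflow, with
a generic overlap-parameter row rather than the full atom-typing table
(its documented few-percent error against the numeric reference is
asserted in the tests).  SASA radii are the intrinsic GB radii.

Per-residue decomposition splits every inter-group pair term half to
each partner residue, attributes GB self-term differences to their own
residue and per-atom SASA differences to the atom's residue; the
per-residue totals therefore sum to ΔG to machine precision, which is
asserted on every run.  Interface membership uses inclusive thresholds:
any atom within 3.5 Å of the partner group in at least 10% of frames.
Apo/holo difference tables flag residues whose total contribution moves
by more than 0.5 kcal/mol (strict).

## Correlation networks

The DCCM uses the isotropic vector-dot convention,
`c_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)`, with deviations taken
about the mean after optional superposition (real trajectories need the
fit; synthetic lab-frame ensembles are analysed without it, since
removing six rigid-body degrees of freedom from planted collective
motion would distort the target).  Zero-variance residues get zero
off-diagonal correlation with a warning.  Edges exist where |c| strictly
exceeds the threshold (0.4 for paths, 0.5 for communities); the path
weight is w = −ln|c|, which maps strong coupling to short distance and
keeps lengths non-negative — the signed correlation is retained as an
edge attribute.  Suboptimal paths are the k shortest simple paths (Yen,
k = 50 by default) with lexicographic tie-breaking; the implementation
is checked against exhaustive simple-path enumeration on small graphs.
Communities default to random-walk agglomeration (walktrap, |c| weights)
with Girvan–Newman betweenness partitioning as the alternative; both must
recover planted block partitions exactly.  DCCMs are computed on the
concatenated trajectory by default (matching the RMSF convention);
per-replica computation is available by subsetting.

## Synthetic study systems

The generators plant the statistical or geometric structure each
analysis is supposed to detect:

- **Correlated Cα ensembles** — displacements drawn per axis from
  N(0, σ²·C_target) via a Cholesky factor (diagonal-jitter fallback for
  semi-definite targets), so the sample DCCM converges to C_target; with
  isotropic axes the vector-dot DCCM recovers the target exactly in
  expectation.  Default σ = 1 Å.
- **Ideal peptides** — NeRF-built backbones at (φ,ψ) = (−57°,−47°) for
  helix and (−139°,135°) for strand; the hairpin refines all dihedrals by
  least squares until the cross-strand N···O/H···O registry reaches ideal
  H-bond geometry (2.95/1.95 Å), deterministically.
- **NMR-like ensemble** — a labelled synthetic stand-in for a deposited
  conformer ensemble: 7 of 20 models keep the intact hairpin (rigid-shift
  jitter only), the rest receive 60–120° dihedral perturbations at the
  turn that break the strand ladder.  The folded count is planted; the
  census machinery must recover it from the H-bond geometry alone.
- **Bridge scenes** — a serine-like hydroxyl, a nitro-like acceptor pair
  and waters placed on 2.8 Å collinear H-bond steps; bridged/unbridged
  frames follow a deterministic seed-derived schedule (a permutation, not
  coin flips) so occupancy targets are exact, and broken frames displace
  the first partner 1.3 Å outward — beyond both distance envelopes by
  more than 0.5 Å.
- **Two-basin ensembles** — exact per-basin frame counts, basin centres a
  prescribed RMSD apart, internal spread well under a quarter of it.
- **Toy dimer** — two net-neutral groups of ten single-atom
  pseudo-residues with a planted salt bridge (±1 e at 3 Å) and one apolar
  contact; group neutrality makes the long-range inter-group terms decay
  as dipole interactions, giving clean separation asymptotics.

What passing these tests shows: the estimators, search algorithms and
energy terms are implemented correctly, conserve what they must conserve
and recover planted ground truth at the stated sample sizes.  What they
do not show: anything about force-field accuracy, sampling convergence of
real simulations, or water models — the generators perform no physical
sampling, and real trajectories carry rotational diffusion, anisotropy
and anharmonicity these Gaussian/scheduled constructions deliberately
omit.

## Problem sizes and numerical choices

The verification runs use 12-residue correlation systems at 10,000
frames (sampling error on c_ij ≈ 1/√n keeps the max error safely under
0.05), 1,000-frame clustering fixtures, 200-frame bridge schedules,
20-atom dimers, and a 2,000-frame end-to-end comparison — sizes chosen so
each planted effect is resolved with a wide margin while the whole chain
runs in minutes on one CPU.  Determinism choices worth knowing:
seed-derived schedules everywhere; clustering and bin-accumulation ties
broken by lowest index; path ties broken lexicographically; CSV output
with fixed float formatting so identical configs reproduce byte-identical
tables.  Degenerate inputs are handled explicitly: collinear point sets
raise a degeneracy error, zero-variance residues are zeroed with a
warning, donors without hydrogens are skipped with a warning, and
disconnected source/sink pairs return an empty path set with a status
flag rather than failing.

## Known limitations

- LCPO uses a generic parameter row, not the published per-type table;
  the numeric Shrake–Rupley method is the reference everywhere it
  matters.
- H-bond chemistry is element-based; sulfur donors/acceptors and
  aromatic acceptors are not modelled.
- The DSSP implementation omits π-helix refinements and β-bulge special
  cases beyond the classic rules; agreement with reference
  implementations is therefore asserted on collapsed classes.
- Mutation predictor scores are consumed as given; no external services
  are queried.
- The pipeline's mutation/interface/path annotation matches residues by
  (chain, position); insertion codes are preserved in the core types but
  not distinguished in annotation.
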