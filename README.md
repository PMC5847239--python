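# dimerdyn

Analysis toolkit for molecular-dynamics studies of PAS-domain transcription
factor dimers — the HIF-2α:ARNT class of systems, where an artificial
ligand bound inside the HIF-2α PAS-B cavity perturbs dimerization through
local folding changes and long-range correlated motions.  The package
implements the complete post-processing chain such a study needs, together
with synthetic-data generators that make every stage verifiable without
multi-hundred-nanosecond trajectories:

- **Flexibility** — RMSD after Cα best-fit (Kabsch), per-residue RMSF over
  replica-concatenated trajectories with an equilibration discard, and
  PCA-based frame selection on interface Cα motions.
- **Secondary structure** — Kabsch–Sander (DSSP) assignment with the
  backbone H-bond energy
  `E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) < −0.5 kcal/mol`,
  folding timelines and ensemble strand censuses.
- **Hydrogen bonds and water bridges** — geometric detection under two
  criteria presets (d(D–A) < 3.5 Å & θ(H–D–A) < 30°, or < 3.9 Å & < 90°),
  protein–water(–water)–ligand chain enumeration with a minimal-water
  rule, and per-frame occupancy accounting.
- **Conformational clustering** — the GROMOS nearest-neighbour (Daura)
  scheme on pairwise best-fit RMSDs.
- **Dimerization energetics** — single-trajectory MM-GBSA:
  `ΔG = G(AB) − G(A) − G(B)` with monomers extracted from the complex
  frames, gas-phase inter-group Coulomb + Lennard-Jones, GB-OBC polar
  solvation (`f_GB = sqrt(r² + R_iR_j·exp(−r²/4R_iR_j))`, HCT
  pairwise-descreening radii with the tanh rescaling), LCPO or
  Shrake–Rupley surface areas, per-residue/per-domain decomposition that
  conserves the total exactly, interface detection (any atom within
  3.5 Å in ≥ 10% of frames) and apo/holo differencing with a
  0.5 kcal/mol highlight.
- **Correlation networks** — the dynamical cross-correlation matrix
  `c_ij = ⟨Δr_i·Δr_j⟩ / sqrt(⟨|Δr_i|²⟩⟨|Δr_j|²⟩)`, thresholded graphs
  (|c| > 0.4, weight −ln|c|), k-shortest suboptimal paths (Yen),
  residue path-frequency, and community detection (walktrap or
  Girvan–Newman) on the |c| > 0.5 graph.
- **Pipeline** — a config-driven apo-vs-holo comparison producing
  byte-reproducible CSV tables, plus mutation classification
  (benign if either predictor says benign; probably damaging when
  Polyphen2 > 0.95, SIFT ∈ [0, 0.01] and MIC ≥ 2.6) and annotation
  against interfaces and communication paths.

## Worked example

The numbered scripts under `analysis/` run each stage on the synthetic
study systems and narrate what they find.  For example:

```sh
$ python analysis/03_secondary_structure.py --seed 1
strand census: 7 of 20 conformers have the resid 8-11 region fully strand
timeline: folded fraction 70.0% (70:30 schedule by construction)

$ python analysis/06_dimer_energetics.py --seed 1
apo: ΔG -8.55 kcal/mol (vdW -2.73, el -42.91, GB +37.73, SA -0.63)
holo: ΔG -6.15 kcal/mol (vdW -0.43, el -42.91, GB +37.74, SA -0.54)
residues changed by > 0.5 kcal/mol: [('A', 2), ('B', 102)]

$ python analysis/07_correlation_networks.py --seed 1
apo: 66 edges at |c|>0.4, 1 communities at |c|>0.5, 50 paths (best length 0.108)
holo: 30 edges at |c|>0.4, 2 communities at |c|>0.5, source and sink disconnected (no path crosses the split)
apo→holo: 36 edges lost, 0 gained, 36 residue pairs split into different communities
```

The census counts NMR-style conformers whose strand region is completely
'E' under DSSP; the energetics run shows the apo/holo difference report
flagging exactly the two residues of the weakened interface contact; and
the network run shows one coherent apo community splitting into two
decoupled holo communities, severing the communication path between the
terminal residues — the planted analogue of ligand-induced domain
decoupling.  `analysis/09_apo_holo_report.py` chains every stage into one
report under `results/compare/`.

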