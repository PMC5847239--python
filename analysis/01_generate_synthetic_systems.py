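#!/usr/bin/env python
"""Generate the synthetic study systems and write them as plain-text fixtures.

Outputs under results/synthetic/: a 20-model NMR-like ensemble (7 conformers
with a fully formed second strand), a one-water bridge scene with a 50%
occupancy schedule, a two-basin conformational ensemble and the toy dimer
with its topology table.
"""

import argparse
from pathlib import Path

from dimerdyn import synthetic_data as sd
from dimerdyn.core_io import write_structure, write_topology


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/synthetic"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    models, region = sd.synthetic_nmr_ensemble(n_models=20, n_folded=7, seed=args.seed)
    write_structure(args.out / "ensemble_synthetic.pdb", models)
    print(f"ensemble: 20 models, strand census region resid {region[0]}-{region[1]}")

    scene, traj = sd.build_bridge_scene(
        sd.BridgeSceneSpec(1, 0.02, 0.5, n_frames=100, seed=args.seed))
    write_structure(args.out / "bridge_scene.pdb", scene)
    write_structure(args.out / "bridge_frames.pdb",
                    [scene.with_coords(traj.coords[f], model_id=f + 1)
                     for f in range(0, traj.n_frames, 10)])
    print(f"bridge scene: {int(traj.bridged_schedule.sum())}/{traj.n_frames} "
          "frames bridged by construction")

    basins = sd.build_two_basin_trajectory(200, 2.0, (0.7, 0.3), seed=args.seed)
    print(f"two-basin ensemble: {int((basins.basin_labels == 0).sum())} + "
          f"{int((basins.basin_labels == 1).sum())} frames, 2.0 Å apart")

    dimer, topology = sd.build_toy_dimer(seed=args.seed)
    write_structure(args.out / "toy_dimer.pdb", dimer)
    write_topology(args.out / "toy_dimer_topology.tsv", topology, dimer)
    print(f"toy dimer: {dimer.n_atoms} pseudo-residues, "
          f"net charges A={topology.charges[dimer.chain_ids == 'A'].sum():+.3f} "
          f"B={topology.charges[dimer.chain_ids == 'B'].sum():+.3f}")


if __name__ == "__main__":
    main()
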