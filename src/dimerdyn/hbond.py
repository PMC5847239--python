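"""Hydrogen-bond and water-bridge detection with occupancy accounting.

Two geometric criteria presets are provided, matching the threshold sets
of common analysis tools: ``gromacs`` (donor–acceptor distance < 3.5 Å and
hydrogen–donor–acceptor angle < 30°) and ``hbplus`` (< 3.9 Å, < 90°).
Both use strict inequalities and measure the angle at the donor.  Water
bridges are donor→water(→water)→acceptor chains in which every consecutive
link is a hydrogen bond in either donation direction; per protein/ligand
atom pair only the chain with the minimal number of waters is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.spatial import cKDTree

from dimerdyn.core_io import SelectionMask, Structure, Trajectory

__all__ = [
    "HBondCriteria",
    "GROMACS_CRITERIA",
    "HBPLUS_CRITERIA",
    "HBond",
    "WaterBridgeRecord",
    "OccupancySeries",
    "detect_hbonds",
    "detect_water_bridges",
    "bridge_occupancy",
]


@dataclass(frozen=True)
class HBondCriteria:
    """Distance/angle envelope for hydrogen-bond detection."""

    max_distance: float
    max_angle: float
    name: str = "custom"

    def __post_init__(self):
        if self.max_distance <= 0:
            raise ValueError("max_distance must be positive")
        if not (0 < self.max_angle <= 180):
            raise ValueError("max_angle must lie in (0, 180]")


GROMACS_CRITERIA = HBondCriteria(3.5, 30.0, "gromacs")
HBPLUS_CRITERIA = HBondCriteria(3.9, 90.0, "hbplus")

PRESETS = {"gromacs": GROMACS_CRITERIA, "hbplus": HBPLUS_CRITERIA}


def _chemistry() -> dict:
    with resources.files("dimerdyn.data").joinpath("hbond_chemistry.yaml").open() as fh:
        return yaml.safe_load(fh)


_CHEM = _chemistry()
_DONOR_ELEMENTS = set(_CHEM["donor_elements"])
_ACCEPTOR_ELEMENTS = set(_CHEM["acceptor_elements"])
_H_ATTACH = float(_CHEM["max_hydrogen_bond_length"])


@dataclass(frozen=True)
class HBond:
    donor: int
    hydrogen: int
    acceptor: int
    distance: float
    angle: float


@dataclass
class WaterBridgeRecord:
    """One detected bridge in one frame."""

    frame: int
    protein_atom: int
    ligand_atom: int
    waters: list[tuple[str, int, str]]
    links: list[HBond] = field(default_factory=list)

    def __post_init__(self):
        if len(self.waters) not in (0, 1, 2):
            raise ValueError("bridges are mediated by at most two waters")


@dataclass
class OccupancySeries:
    """Per-frame bridge state and aggregate percentages."""

    states: np.ndarray  # entries in {none, direct, one-water, two-water}
    direct_pct: float
    one_water_pct: float
    two_water_pct: float

    @property
    def total_bridged_pct(self) -> float:
        return self.direct_pct + self.one_water_pct + self.two_water_pct

    def __post_init__(self):
        for p in (self.direct_pct, self.one_water_pct, self.two_water_pct):
            if not (0.0 <= p <= 100.0):
                raise ValueError("percentages must lie in [0, 100]")


def _attached_hydrogens(structure: Structure, coords: np.ndarray) -> dict[int, list[int]]:
    """Hydrogens covalently attached to each heavy atom (distance rule)."""
    h_idx = np.array([i for i, a in enumerate(structure.atoms) if a.element == "H"], dtype=int)
    heavy = np.array([i for i, a in enumerate(structure.atoms) if a.element != "H"], dtype=int)
    out: dict[int, list[int]] = {int(i): [] for i in heavy}
    if h_idx.size == 0 or heavy.size == 0:
        return out
    tree = cKDTree(coords[heavy])
    for h in h_idx:
        dist, j = tree.query(coords[h], k=1)
        if dist < _H_ATTACH:
            out[int(heavy[j])].append(int(h))
    return out


def detect_hbonds(
    structure: Structure,
    donors: SelectionMask,
    acceptors: SelectionMask,
    criteria: HBondCriteria = GROMACS_CRITERIA,
    coords: np.ndarray | None = None,
) -> list[HBond]:
    """All (donor, hydrogen, acceptor) triplets inside the criteria envelope.

    Donor candidates are N/O atoms of ``donors`` carrying at least one
    attached hydrogen (donors without hydrogens are skipped with a
    warning); acceptors are N/O atoms of ``acceptors``.  Both thresholds
    are strict inequalities; the angle is hydrogen–donor–acceptor,
    measured at the donor.
    """
    coords = structure.coords if coords is None else np.asarray(coords, dtype=float)
    attached = _attached_hydrogens(structure, coords)
    donor_list = [
        int(i) for i in donors.atom_indices
        if structure.atoms[i].element in _DONOR_ELEMENTS
    ]
    acc_list = [
        int(i) for i in acceptors.atom_indices
        if structure.atoms[i].element in _ACCEPTOR_ELEMENTS
    ]
    skipped = [d for d in donor_list if not attached.get(d)]
    if skipped:
        warnings.warn(
            f"{len(skipped)} donor(s) without attached hydrogen skipped",
            stacklevel=2,
        )
    donor_list = [d for d in donor_list if attached.get(d)]
    if not donor_list or not acc_list:
        return []
    acc_arr = np.array(acc_list)
    tree = cKDTree(coords[acc_arr])
    bonds = []
    for d in donor_list:
        for j in tree.query_ball_point(coords[d], criteria.max_distance):
            a = int(acc_arr[j])
            if a == d:
                continue
            dist = float(np.linalg.norm(coords[a] - coords[d]))
            if not (dist < criteria.max_distance):
                continue
            for h in attached[d]:
                if h == a:
                    continue
                u = coords[h] - coords[d]
                v = coords[a] - coords[d]
                denom = np.linalg.norm(u) * np.linalg.norm(v)
                if denom == 0:
                    continue
                ang = float(np.degrees(np.arccos(np.clip(np.dot(u, v) / denom, -1, 1))))
                if ang < criteria.max_angle:
                    bonds.append(HBond(d, h, a, dist, ang))
    return bonds


def _link_map(
    structure: Structure,
    coords: np.ndarray,
    groups: dict[str, SelectionMask],
    criteria: HBondCriteria,
) -> dict[tuple[int, int], HBond]:
    """Symmetric H-bond links between heavy atoms of all listed groups.

    A link (x, y) exists when x donates to y or y donates to x under the
    criteria; the representative HBond is the first detected.
    """
    all_idx = np.unique(np.concatenate([m.atom_indices for m in groups.values()]))
    mask = SelectionMask(all_idx)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # spectator atoms without H are fine here
        bonds = detect_hbonds(structure, mask, mask, criteria, coords)
    links: dict[tuple[int, int], HBond] = {}
    for b in bonds:
        key = (min(b.donor, b.acceptor), max(b.donor, b.acceptor))
        links.setdefault(key, b)
    return links


def _water_molecules(structure: Structure, waters: SelectionMask) -> dict[tuple, list[int]]:
    mols: dict[tuple, list[int]] = {}
    for i in waters.atom_indices:
        mols.setdefault(structure.atoms[i].residue_key, []).append(int(i))
    return mols


def detect_water_bridges(
    structure: Structure,
    protein_atoms: SelectionMask,
    ligand_atoms: SelectionMask,
    waters: SelectionMask,
    criteria: HBondCriteria = GROMACS_CRITERIA,
    max_waters: int = 2,
    coords: np.ndarray | None = None,
    frame: int = 0,
) -> list[WaterBridgeRecord]:
    """Enumerate protein—water(—water)—ligand hydrogen-bond chains.

    Each consecutive link must be a hydrogen bond in either donation
    direction.  For every (protein atom, ligand atom) pair only chains
    with the minimal water count are reported (a direct hydrogen bond,
    water count 0, pre-empts mediated chains).
    """
    coords = structure.coords if coords is None else np.asarray(coords, dtype=float)
    links = _link_map(
        structure, coords,
        {"p": protein_atoms, "l": ligand_atoms, "w": waters},
        criteria,
    )

    def linked(x: int, y: int) -> HBond | None:
        return links.get((min(x, y), max(x, y)))

    mols = _water_molecules(structure, waters)
    water_keys = sorted(mols)
    water_oxygens = {
        k: [i for i in mols[k] if structure.atoms[i].element != "H"] for k in water_keys
    }
    p_idx = [int(i) for i in protein_atoms.atom_indices if structure.atoms[i].element != "H"]
    l_idx = [int(i) for i in ligand_atoms.atom_indices if structure.atoms[i].element != "H"]
    records: list[WaterBridgeRecord] = []
    for p in p_idx:
        for l in l_idx:
            direct = linked(p, l)
            if direct is not None:
                records.append(WaterBridgeRecord(frame, p, l, [], [direct]))
                continue
            found_one = False
            for wk in water_keys:
                for wo in water_oxygens[wk]:
                    b1, b2 = linked(p, wo), linked(wo, l)
                    if b1 and b2:
                        records.append(WaterBridgeRecord(frame, p, l, [wk], [b1, b2]))
                        found_one = True
                        break
                if found_one:
                    break
            if found_one or max_waters < 2:
                continue
            done = False
            for wk1 in water_keys:
                for wk2 in water_keys:
                    if wk1 == wk2 or done:
                        continue
                    for wo1 in water_oxygens[wk1]:
                        for wo2 in water_oxygens[wk2]:
                            b1, b2, b3 = linked(p, wo1), linked(wo1, wo2), linked(wo2, l)
                            if b1 and b2 and b3:
                                records.append(
                                    WaterBridgeRecord(frame, p, l, [wk1, wk2], [b1, b2, b3])
                                )
                                done = True
                                break
                        if done:
                            break
    return records


def bridge_occupancy(
    traj: Trajectory,
    structure: Structure,
    protein_atoms: SelectionMask,
    ligand_atoms: SelectionMask,
    waters: SelectionMask,
    criteria: HBondCriteria = GROMACS_CRITERIA,
    max_waters: int = 2,
) -> OccupancySeries:
    """Per-frame bridge state and aggregate occupancy percentages.

    Frames are classified exclusively — direct contact over a one-water
    bridge over a two-water bridge — so the reported percentages are
    disjoint and additive.
    """
    states = np.full(traj.n_frames, "none", dtype=object)
    for f in range(traj.n_frames):
        recs = detect_water_bridges(
            structure, protein_atoms, ligand_atoms, waters,
            criteria, max_waters, coords=traj.coords[f], frame=f,
        )
        if not recs:
            continue
        n_waters = min(len(r.waters) for r in recs)
        states[f] = {0: "direct", 1: "one-water", 2: "two-water"}[n_waters]
    n = traj.n_frames
    return OccupancySeries(
        states=states,
        direct_pct=100.0 * np.sum(states == "direct") / n,
        one_water_pct=100.0 * np.sum(states == "one-water") / n,
        two_water_pct=100.0 * np.sum(states == "two-water") / n,
    )
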