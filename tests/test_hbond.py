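"""Geometric hydrogen-bond criteria, water bridges and occupancies."""

import numpy as np
import pytest

from dimerdyn import synthetic_data as sd
from dimerdyn.core_io import AtomRecord, SelectionMask, Structure, select
from dimerdyn.hbond import (
    GROMACS_CRITERIA,
    HBPLUS_CRITERIA,
    HBondCriteria,
    bridge_occupancy,
    detect_hbonds,
    detect_water_bridges,
)


def donor_acceptor_pair(distance: float, angle_deg: float) -> Structure:
    """O–H donor plus O acceptor at given D–A distance and H–D–A angle."""
    ang = np.deg2rad(angle_deg)
    atoms = [
        AtomRecord(1, "OG", "O", 1, "SER", "A", np.zeros(3)),
        AtomRecord(2, "HG", "H", 1, "SER", "A",
                   0.97 * np.array([np.cos(ang), np.sin(ang), 0.0])),
        AtomRecord(3, "O1", "O", 2, "LIG", "L", np.array([distance, 0.0, 0.0])),
    ]
    return Structure(atoms)


def _bonds(structure, criteria):
    donors = select(structure, "chain A")
    acceptors = select(structure, "chain L")
    return detect_hbonds(structure, donors, acceptors, criteria)


class TestCriteriaEnvelopes:
    @pytest.mark.parametrize(
        "distance,angle,in_gromacs,in_hbplus",
        [
            (2.8, 5.0, True, True),     # well inside both
            (3.7, 10.0, False, True),   # distance between the two cutoffs
            (3.4, 35.0, False, True),   # angle between the two cutoffs
            (4.1, 5.0, False, False),   # outside both
            (3.5, 5.0, False, True),    # strict inequality at 3.5 Å
            (2.8, 30.0, False, True),   # strict inequality at 30°
        ],
    )
    def test_preset_thresholds(self, distance, angle, in_gromacs, in_hbplus):
        st = donor_acceptor_pair(distance, angle)
        assert bool(_bonds(st, GROMACS_CRITERIA)) is in_gromacs
        assert bool(_bonds(st, HBPLUS_CRITERIA)) is in_hbplus

    def test_donor_without_hydrogen_skipped_with_warning(self):
        atoms = [
            AtomRecord(1, "N", "N", 1, "GLY", "A", np.zeros(3)),
            AtomRecord(2, "O", "O", 2, "LIG", "L", np.array([2.8, 0.0, 0.0])),
        ]
        st = Structure(atoms)
        with pytest.warns(UserWarning, match="without attached hydrogen"):
            bonds = detect_hbonds(st, SelectionMask(np.array([0])),
                                  SelectionMask(np.array([1])), GROMACS_CRITERIA)
        assert bonds == []

    def test_invalid_criteria(self):
        with pytest.raises(ValueError):
            HBondCriteria(-1.0, 30.0)
        with pytest.raises(ValueError):
            HBondCriteria(3.5, 200.0)


def random_scene(seed: int) -> Structure:
    """A random cloud of hydroxyl-like donors/acceptors for property tests."""
    rng = np.random.default_rng(seed)
    atoms = []
    serial = 0
    for i in range(6):
        serial += 1
        o = rng.uniform(0.0, 7.0, 3)
        atoms.append(AtomRecord(serial, "O", "O", i + 1, "MOL",
                                "A" if i < 3 else "L", o))
        serial += 1
        h = o + 0.97 * _unit(rng.normal(size=3))
        atoms.append(AtomRecord(serial, "H", "H", i + 1, "MOL",
                                "A" if i < 3 else "L", h))
    return Structure(atoms)


def _unit(v):
    return v / np.linalg.norm(v)


class TestMonotonicity:
    @pytest.mark.parametrize("seed", range(25))
    def test_looser_thresholds_detect_supersets(self, seed):
        st = random_scene(seed)
        donors = select(st, "chain A")
        acceptors = select(st, "chain L")
        tight = {(b.donor, b.hydrogen, b.acceptor)
                 for b in detect_hbonds(st, donors, acceptors, GROMACS_CRITERIA)}
        loose = {(b.donor, b.hydrogen, b.acceptor)
                 for b in detect_hbonds(st, donors, acceptors, HBPLUS_CRITERIA)}
        assert tight <= loose


class TestWaterBridges:
    def test_one_water_scene_yields_single_water_record(self):
        st, _ = sd.build_bridge_scene(sd.BridgeSceneSpec(1, 0.0, 1.0, 1, 0))
        recs = detect_water_bridges(
            st, select(st, "chain A"), select(st, "chain L"), select(st, "water"))
        assert len(recs) >= 1
        assert all(len(r.waters) == 1 for r in recs)

    def test_minimal_chain_rule_prefers_fewer_waters(self):
        # one-water and two-water chains to the same endpoints: keep 1-water
        atoms = [
            AtomRecord(1, "OG", "O", 1, "SER", "A", np.array([0.0, 0.0, 0.0])),
            AtomRecord(2, "HG", "H", 1, "SER", "A", np.array([0.97, 0.0, 0.0])),
            AtomRecord(3, "O1", "O", 1, "LIG", "L", np.array([5.6, 0.0, 0.0])),
            # direct one-water path
            AtomRecord(4, "O", "O", 1, "HOH", "W", np.array([2.8, 0.0, 0.0])),
            AtomRecord(5, "H1", "H", 1, "HOH", "W", np.array([3.77, 0.0, 0.0])),
            AtomRecord(6, "H2", "H", 1, "HOH", "W", np.array([2.5, 0.9, 0.0])),
            # detour two-water path below the axis
            AtomRecord(7, "O", "O", 2, "HOH", "W", np.array([1.9, -2.0, 0.0])),
            AtomRecord(8, "H1", "H", 2, "HOH", "W",
                       np.array([1.9, -2.0, 0.0]) + 0.97 * _unit(np.array([1.8, 0.0, 0.0]))),
            AtomRecord(9, "H2", "H", 2, "HOH", "W", np.array([1.2, -2.6, 0.0])),
            AtomRecord(10, "O", "O", 3, "HOH", "W", np.array([3.7, -2.0, 0.0])),
            AtomRecord(11, "H1", "H", 3, "HOH", "W",
                       np.array([3.7, -2.0, 0.0]) + 0.97 * _unit(np.array([1.9, 2.0, 0.0]))),
            AtomRecord(12, "H2", "H", 3, "HOH", "W", np.array([4.2, -2.7, 0.0])),
        ]
        st = Structure(atoms)
        recs = detect_water_bridges(
            st, select(st, "chain A"), select(st, "chain L"), select(st, "water"))
        assert len(recs) == 1
        assert len(recs[0].waters) == 1

    def test_water_out_of_reach_gives_no_record(self):
        atoms = [
            AtomRecord(1, "OG", "O", 1, "SER", "A", np.zeros(3)),
            AtomRecord(2, "HG", "H", 1, "SER", "A", np.array([0.97, 0.0, 0.0])),
            AtomRecord(3, "O1", "O", 1, "LIG", "L", np.array([7.4, 0.0, 0.0])),
            AtomRecord(4, "O", "O", 1, "HOH", "W", np.array([3.7, 0.0, 0.0])),
            AtomRecord(5, "H1", "H", 1, "HOH", "W", np.array([4.67, 0.0, 0.0])),
            AtomRecord(6, "H2", "H", 1, "HOH", "W", np.array([3.4, 0.9, 0.0])),
        ]
        st = Structure(atoms)
        recs = detect_water_bridges(
            st, select(st, "chain A"), select(st, "chain L"), select(st, "water"),
            GROMACS_CRITERIA)
        assert recs == []

    def test_exhaustive_enumeration_oracle(self):
        """Bridge search equals brute-force chain enumeration on small scenes."""
        for seed in range(10):
            st = _bridge_property_scene(seed)
            prot = select(st, "chain A")
            lig = select(st, "chain L")
            wat = select(st, "water")
            recs = detect_water_bridges(st, prot, lig, wat, GROMACS_CRITERIA)
            got = {(r.protein_atom, r.ligand_atom, len(r.waters)) for r in recs}
            assert got == _brute_force_bridges(st, GROMACS_CRITERIA)


def _bridge_property_scene(seed: int) -> Structure:
    rng = np.random.default_rng(seed)
    atoms = []
    serial = 0

    def add(name, element, resid, resname, chain, xyz):
        nonlocal serial
        serial += 1
        atoms.append(AtomRecord(serial, name, element, resid, resname, chain,
                                np.asarray(xyz, float)))

    add("OG", "O", 1, "SER", "A", [0.0, 0.0, 0.0])
    add("HG", "H", 1, "SER", "A", 0.97 * _unit(rng.normal(size=3)))
    add("O1", "O", 1, "LIG", "L", rng.uniform(2.0, 8.0, 3))
    for w in range(4):
        o = rng.uniform(-1.0, 8.0, 3)
        add("O", "O", w + 1, "HOH", "W", o)
        add("H1", "H", w + 1, "HOH", "W", o + 0.97 * _unit(rng.normal(size=3)))
        add("H2", "H", w + 1, "HOH", "W", o + 0.97 * _unit(rng.normal(size=3)))
    return Structure(atoms)


def _brute_force_bridges(st: Structure, criteria) -> set:
    """Direct enumeration of all chains with the minimal-water rule."""
    import itertools
    import warnings

    from dimerdyn.hbond import _link_map

    coords = st.coords
    prot = select(st, "chain A")
    lig = select(st, "chain L")
    wat = select(st, "water")
    links = _link_map(st, coords, {"p": prot, "l": lig, "w": wat}, criteria)

    def linked(x, y):
        return (min(x, y), max(x, y)) in links

    water_os = [int(i) for i in wat.atom_indices if st.atoms[i].element != "H"]
    p_idx = [int(i) for i in prot.atom_indices if st.atoms[i].element != "H"]
    l_idx = [int(i) for i in lig.atom_indices if st.atoms[i].element != "H"]
    out = set()
    for p in p_idx:
        for l in l_idx:
            if linked(p, l):
                out.add((p, l, 0))
                continue
            if any(linked(p, w) and linked(w, l) for w in water_os):
                out.add((p, l, 1))
                continue
            for w1, w2 in itertools.permutations(water_os, 2):
                if linked(p, w1) and linked(w1, w2) and linked(w2, l):
                    out.add((p, l, 2))
                    break
    return out


class TestOccupancy:
    def test_scheduled_occupancy_is_exact(self):
        st, traj = sd.build_bridge_scene(sd.BridgeSceneSpec(1, 0.02, 0.5, 60, 1))
        occ = bridge_occupancy(traj, st, select(st, "chain A"),
                               select(st, "chain L"), select(st, "water"))
        assert occ.one_water_pct == 50.0
        assert occ.two_water_pct == 0.0

    def test_all_unbridged_gives_zero(self):
        st, traj = sd.build_bridge_scene(sd.BridgeSceneSpec(1, 0.02, 0.0, 20, 2))
        occ = bridge_occupancy(traj, st, select(st, "chain A"),
                               select(st, "chain L"), select(st, "water"))
        assert occ.total_bridged_pct == 0.0

    def test_hbplus_occupancy_bounds_gromacs(self):
        st, traj = sd.build_bridge_scene(sd.BridgeSceneSpec(2, 0.05, 0.4, 30, 3))
        args = (traj, st, select(st, "chain A"), select(st, "chain L"),
                select(st, "water"))
        occ_g = bridge_occupancy(*args, GROMACS_CRITERIA)
        occ_h = bridge_occupancy(*args, HBPLUS_CRITERIA)
        assert occ_h.total_bridged_pct >= occ_g.total_bridged_pct

    def test_water_relabelling_does_not_change_occupancy(self):
        st, traj = sd.build_bridge_scene(sd.BridgeSceneSpec(2, 0.0, 1.0, 5, 4))
        occ1 = bridge_occupancy(traj, st, select(st, "chain A"),
                                select(st, "chain L"), select(st, "water"))
        # reverse the order of water atoms in the selection mask
        wat = select(st, "water")
        reversed_mask = SelectionMask(wat.atom_indices[::-1].copy())
        occ2 = bridge_occupancy(traj, st, select(st, "chain A"),
                                select(st, "chain L"), reversed_mask)
        assert np.array_equal(occ1.states, occ2.states)
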