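"""MM-GBSA machinery: closed-form limits, quadrature oracles, conservation."""

import numpy as np
import pytest
from scipy.integrate import quad

from dimerdyn import energetics as en
from dimerdyn import synthetic_data as sd
from dimerdyn.core_io import Topology, select
from tests.conftest import random_rotation

PARAMS = en.EnergyParameters()


def single_atom_topology(q=1.0, rho=1.5):
    return Topology(charges=[q], rmin=[1.9], eps=[0.1],
                    gb_radius=[rho], gb_scale=[0.8])


class TestBornRadii:
    def test_isolated_atom_has_descreened_intrinsic_radius(self):
        radii = en.effective_born_radii(single_atom_topology(), np.zeros((1, 3)), PARAMS)
        assert np.isclose(radii.radii[0], 1.5 - PARAMS.born_offset, atol=1e-12)

    def test_distant_pair_approaches_isolated_limit_monotonically(self):
        top = Topology(charges=[0.0, 0.0], rmin=[1.9] * 2, eps=[0.1] * 2,
                       gb_radius=[1.5] * 2, gb_scale=[0.8] * 2)
        prev = None
        for d in (4.0, 8.0, 16.0, 32.0):
            coords = np.array([[0.0, 0.0, 0.0], [d, 0.0, 0.0]])
            r = en.effective_born_radii(top, coords, PARAMS).radii[0]
            assert r >= 1.5 - PARAMS.born_offset - 1e-12
            if prev is not None:
                assert r < prev
            prev = r
        assert np.isclose(prev, 1.5 - PARAMS.born_offset, atol=1e-3)

    def test_hct_integral_matches_quadrature_oracle(self):
        """Analytic pairwise descreening equals direct numeric integration.

        The oracle integrates 1/(4π) ∫ r⁻⁴ dV over the scaled sphere of
        the descreening atom, excluding the region inside the descreened
        atom's own radius, reduced to a 1-D shell integral.
        """
        rng = np.random.default_rng(0)
        coords = rng.uniform(0.0, 4.0, (5, 3))
        rho = rng.uniform(1.2, 2.0, 5)
        scale = rng.uniform(0.7, 0.9, 5)
        top = Topology(charges=np.zeros(5), rmin=np.full(5, 1.9),
                       eps=np.full(5, 0.1), gb_radius=rho, gb_scale=scale)
        rho_t = rho - PARAMS.born_offset
        s = scale * rho_t

        def shell_integral(r_ij, s_j, rho_i):
            # spherical-cap cross-section of the descreening sphere at radius t
            def integrand(t):
                if t >= r_ij + s_j:
                    return 0.0
                if t <= max(rho_i, r_ij - s_j):
                    pass
                cos_theta = (t ** 2 + r_ij ** 2 - s_j ** 2) / (2.0 * t * r_ij)
                cos_theta = np.clip(cos_theta, -1.0, 1.0)
                return 0.5 * (1.0 - cos_theta) / t ** 2

            lo = max(rho_i, abs(r_ij - s_j))
            hi = r_ij + s_j
            if hi <= rho_i:
                return 0.0
            val, _ = quad(integrand, lo, hi, limit=200)
            # fully engulfed shells below |r−s| (atom i inside sphere j)
            if rho_i < s_j - r_ij:
                val += quad(lambda t: 1.0 / t ** 2, rho_i, s_j - r_ij, limit=200)[0]
            return val

        for i in range(5):
            total = 0.0
            for j in range(5):
                if i == j:
                    continue
                r_ij = np.linalg.norm(coords[i] - coords[j])
                total += shell_integral(r_ij, s[j], rho_t[i])
            analytic = en._hct_integral_terms(
                np.array([np.linalg.norm(coords[i] - coords[j]) for j in range(5) if j != i]),
                np.array([s[j] for j in range(5) if j != i]),
                np.full(4, rho_t[i]),
            ).sum()
            assert np.isclose(analytic, total, atol=1e-6)


class TestGBEnergy:
    def test_single_ion_matches_born_formula_exactly(self):
        top = single_atom_topology(q=1.0, rho=1.5)
        coords = np.zeros((1, 3))
        radii = en.effective_born_radii(top, coords, PARAMS)
        gb, _ = en.solvation_energy(top, coords, radii, PARAMS)
        expected = PARAMS.polar_prefactor / (1.5 - PARAMS.born_offset)
        assert abs(gb - expected) < 1e-8

    def test_charge_square_scaling(self, toy_dimer):
        structure, top = toy_dimer
        radii = en.effective_born_radii(top, structure.coords, PARAMS)
        gb1 = en.gb_pair_matrix(top, structure.coords, radii, PARAMS).sum()
        top2 = Topology(charges=2.0 * top.charges, rmin=top.rmin, eps=top.eps,
                        gb_radius=top.gb_radius, gb_scale=top.gb_scale)
        gb2 = en.gb_pair_matrix(top2, structure.coords, radii, PARAMS).sum()
        assert np.isclose(gb2, 4.0 * gb1, rtol=1e-12)

    def test_rotation_translation_invariance(self, toy_dimer):
        structure, top = toy_dimer
        rng = np.random.default_rng(1)
        moved = structure.coords @ random_rotation(rng).T + np.array([3.0, -7.0, 1.0])
        r1 = en.effective_born_radii(top, structure.coords, PARAMS)
        r2 = en.effective_born_radii(top, moved, PARAMS)
        gb1, _ = en.solvation_energy(top, structure.coords, r1, PARAMS)
        gb2, _ = en.solvation_energy(top, moved, r2, PARAMS)
        assert np.isclose(gb1, gb2, atol=1e-8)


class TestSasa:
    def test_isolated_sphere_matches_analytic_area(self):
        area = en.sasa_shrake_rupley(np.zeros((1, 3)), np.array([1.5]), 1.4, 960)[0]
        exact = 4.0 * np.pi * 2.9 ** 2
        assert abs(area - exact) / exact < 0.005

    def test_two_sphere_lcpo_close_to_numeric_reference(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        radii = np.array([1.7, 1.7])
        ref = en.sasa_shrake_rupley(coords, radii, 1.4, 10000).sum()
        approx = en.sasa_lcpo(coords, radii, 1.4).sum()
        assert abs(approx - ref) / ref < 0.05  # documented LCPO approximation

    def test_buried_atom_loses_area(self):
        solo = en.sasa_shrake_rupley(np.zeros((1, 3)), np.array([1.5]), 1.4, 240)[0]
        pair = en.sasa_shrake_rupley(
            np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]), np.array([1.5, 1.5]), 1.4, 240)
        assert pair[0] < solo


class TestDimerizationEnergy:
    def test_matches_three_state_brute_force(self, toy_dimer):
        structure, top = toy_dimer
        a, b = select(structure, "chain A"), select(structure, "chain B")
        dec = en.dimerization_energy(structure.coords, structure, top, a, b, PARAMS)

        def total_g(topol, coords):
            radii = en.effective_born_radii(topol, coords, PARAMS)
            gb, sa = en.solvation_energy(topol, coords, radii, PARAMS)
            coul, lj = en._gas_pair_matrices(topol, coords, PARAMS)
            return coul.sum() + lj.sum() + gb + sa

        ia, ib = a.atom_indices, b.atom_indices
        oracle = (
            total_g(top, structure.coords)
            - total_g(en._subset_topology(top, ia), structure.coords[ia])
            - total_g(en._subset_topology(top, ib), structure.coords[ib])
        )
        assert abs(dec.totals["total"] - oracle) < 1e-6

    def test_per_residue_sum_conserves_total(self, toy_dimer):
        structure, top = toy_dimer
        a, b = select(structure, "chain A"), select(structure, "chain B")
        dec = en.dimerization_energy(structure.coords, structure, top, a, b, PARAMS)
        assert abs(dec.total_per_residue.sum() - dec.totals["total"]) < 1e-6

    def test_separated_groups_leave_negligible_energy(self, toy_dimer):
        structure, top = toy_dimer
        a, b = select(structure, "chain A"), select(structure, "chain B")
        coords = structure.coords.copy()
        coords[b.atom_indices] += np.array([100.0, 0.0, 0.0])
        dec = en.dimerization_energy(coords, structure, top, a, b, PARAMS)
        assert abs(dec.totals["total"]) < 0.05
        assert abs(dec.totals["vdw"]) < 0.01
        assert abs(dec.totals["el"] + dec.totals["gb"]) < 0.05

    def test_zeroed_charges_remove_polar_terms(self, toy_dimer):
        structure, top = toy_dimer
        a, b = select(structure, "chain A"), select(structure, "chain B")
        top0 = Topology(charges=np.zeros_like(top.charges), rmin=top.rmin,
                        eps=top.eps, gb_radius=top.gb_radius, gb_scale=top.gb_scale)
        dec = en.dimerization_energy(structure.coords, structure, top0, a, b, PARAMS)
        assert dec.totals["el"] == 0.0
        assert dec.totals["gb"] == 0.0
        assert dec.totals["vdw"] != 0.0

    def test_overlapping_partition_rejected(self, toy_dimer):
        structure, top = toy_dimer
        a = select(structure, "chain A")
        with pytest.raises(ValueError, match="overlap"):
            en.dimerization_energy(structure.coords, structure, top, a, a, PARAMS)


class TestDomainContributions:
    def test_percentages_sum_to_100(self, toy_dimer):
        structure, top = toy_dimer
        a, b = select(structure, "chain A"), select(structure, "chain B")
        dec = en.dimerization_energy(structure.coords, structure, top, a, b, PARAMS)
        from dimerdyn.core_io import DomainMap

        mapping = {}
        for k in dec.residue_keys:
            mapping[(k[0], k[1])] = "PAS-A" if k[0] == "A" else "PAS-B"
        _, dom = en.per_residue_and_domain_contributions(dec, DomainMap(mapping))
        assert np.isclose(dom["percent"].sum(), 100.0, atol=1e-9)

    def test_unmapped_residue_raises(self, toy_dimer):
        structure, top = toy_dimer
        a, b = select(structure, "chain A"), select(structure, "chain B")
        dec = en.dimerization_energy(structure.coords, structure, top, a, b, PARAMS)
        from dimerdyn.core_io import DomainMap

        with pytest.raises(ValueError, match="not mapped"):
            en.per_residue_and_domain_contributions(dec, DomainMap({("A", 1): "X"}))


class TestInterfaceRule:
    def _contact_trajectory(self, n_contact, n_total):
        """Atom pair in contact for exactly n_contact of n_total frames."""
        base = np.array([[0.0, 0.0, 0.0], [3.2, 0.0, 0.0]])
        frames = []
        for f in range(n_total):
            c = base.copy()
            if f >= n_contact:
                c[1, 0] = 10.0
            frames.append(c)
        return np.array(frames)

    def test_exactly_ten_percent_included(self):
        from dimerdyn.core_io import AtomRecord, SelectionMask, Structure

        st = Structure([
            AtomRecord(1, "CA", "C", 1, "RES", "A", np.zeros(3)),
            AtomRecord(2, "CA", "C", 2, "RES", "B", np.array([3.2, 0.0, 0.0])),
        ])
        ga, gb = SelectionMask(np.array([0])), SelectionMask(np.array([1]))
        coords = self._contact_trajectory(5, 50)   # exactly 10 %
        iset = en.interface_residues(coords, st, ga, gb)
        assert ("A", 1, "") in iset.residues_a
        coords = self._contact_trajectory(4, 50)   # 8 % < threshold
        iset = en.interface_residues(coords, st, ga, gb)
        assert not iset.residues_a

    def test_static_dimer_equals_all_pairs_oracle(self, toy_dimer):
        structure, top = toy_dimer
        a, b = select(structure, "chain A"), select(structure, "chain B")
        cutoff = 4.5
        iset = en.interface_residues(structure.coords, structure, a, b, cutoff=cutoff)
        # O(n²) oracle
        expected_a, expected_b = set(), set()
        for i in a.atom_indices:
            for j in b.atom_indices:
                d = np.linalg.norm(structure.coords[i] - structure.coords[j])
                if d <= cutoff:
                    expected_a.add(structure.atoms[i].residue_key)
                    expected_b.add(structure.atoms[j].residue_key)
        assert set(iset.residues_a) == expected_a
        assert set(iset.residues_b) == expected_b


class TestCompareDecompositions:
    def _decomp(self, values):
        n = len(values)
        keys = [("A", i + 1, "") for i in range(n)]
        z = np.zeros(n)
        return en.EnergyDecomposition(
            residue_keys=keys, vdw=np.asarray(values, float), el=z.copy(),
            gb=z.copy(), sa=z.copy(), n_frames=1, group_labels=["A"] * n)

    def test_identical_inputs_flag_nothing(self):
        d = self._decomp([1.0, -2.0, 0.3])
        diff = en.compare_decompositions(d, d)
        assert not diff["flagged"].any()
        assert np.allclose(diff[["d_vdw", "d_el", "d_gb", "d_sa", "d_total"]], 0.0)

    def test_single_perturbation_flags_one_row(self):
        apo = self._decomp([1.0, -2.0, 0.3])
        holo = self._decomp([1.0, -1.4, 0.3])   # +0.6 on residue 2
        diff = en.compare_decompositions(apo, holo)
        assert diff["flagged"].sum() == 1
        assert diff.loc[diff["flagged"], "resid"].tolist() == [2]

    def test_random_perturbations_match_filter_oracle(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 20)
        delta = rng.normal(0, 0.6, 20)
        apo = self._decomp(base)
        holo = self._decomp(base + delta)
        diff = en.compare_decompositions(apo, holo)
        assert np.array_equal(diff["flagged"].to_numpy(), np.abs(delta) > 0.5)

    def test_key_mismatch_reported(self):
        apo = self._decomp([1.0, 2.0])
        holo = self._decomp([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="keys differ"):
            en.compare_decompositions(apo, holo)
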