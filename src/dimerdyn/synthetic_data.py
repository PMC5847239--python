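"""Generators for inputs with planted statistical and geometric structure.

Every analysis stage in this package is exercised against data whose ground
truth is known by construction: Cα ensembles with a prescribed
cross-correlation matrix, ideal backbone geometries for secondary-structure
assignment, protein–water–ligand bridge scenes that satisfy or violate the
hydrogen-bond criteria on a deterministic frame schedule, two-basin
conformational ensembles for clustering, and small two-group charged
systems for binding-energy tests.  All generators are bit-reproducible
under a fixed seed.  None of them perform physical force-field sampling;
the statistical structure is planted, not emergent (see docs/methods.md
for what this does and does not validate about real simulations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from dimerdyn.core_io import AtomRecord, Structure, Topology, Trajectory

__all__ = [
    "CorrelationSpec",
    "BridgeSceneSpec",
    "SpecError",
    "generate_correlated_trajectory",
    "build_ideal_peptide",
    "build_bridge_scene",
    "build_two_basin_trajectory",
    "build_toy_dimer",
    "synthetic_nmr_ensemble",
    "block_correlation_matrix",
]


class SpecError(ValueError):
    """A generator specification violates its invariants."""


# ---------------------------------------------------------------------------
# Correlated Cα trajectories
# ---------------------------------------------------------------------------

@dataclass
class CorrelationSpec:
    """Target DCCM, displacement amplitude (Å), frame count and seed."""

    c_target: np.ndarray
    sigma: float = 1.0
    n_frames: int = 1000
    seed: int = 0

    def __post_init__(self):
        c = np.asarray(self.c_target, dtype=float)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise SpecError("C_target must be square")
        if not np.allclose(c, c.T, atol=1e-10):
            raise SpecError("C_target must be symmetric")
        if not np.allclose(np.diag(c), 1.0, atol=1e-10):
            raise SpecError("C_target must have unit diagonal")
        if np.min(np.linalg.eigvalsh(c)) < -1e-8:
            raise SpecError("C_target must be positive semi-definite")
        self.c_target = c


def _matrix_sqrt(c: np.ndarray) -> np.ndarray:
    """Cholesky factor of ``c``, with a diagonal-jitter fallback for
    semi-definite targets (e.g. perfectly correlated residue pairs)."""
    for jitter in (0.0, 1e-12, 1e-10, 1e-8):
        try:
            return np.linalg.cholesky(c + jitter * np.eye(len(c)))
        except np.linalg.LinAlgError:
            continue
    raise SpecError("C_target is not positive semi-definite")


def generate_correlated_trajectory(spec: CorrelationSpec, base: Structure) -> Trajectory:
    """Gaussian Cα displacements with covariance σ²·C_target per axis.

    Each frame's displacement along each Cartesian axis is an independent
    draw from N(0, σ²·C_target), added to the base coordinates, so the
    sample DCCM of the output converges to C_target as the number of
    frames grows.
    """
    n_res = spec.c_target.shape[0]
    if base.n_atoms != n_res:
        raise SpecError(
            f"base structure has {base.n_atoms} atoms for a "
            f"{n_res}-residue correlation target"
        )
    rng = np.random.default_rng(spec.seed)
    chol = _matrix_sqrt(spec.c_target)
    z = rng.standard_normal((spec.n_frames, 3, n_res))
    disp = spec.sigma * np.einsum("rk,fak->far", chol, z)
    coords = base.coords[None, :, :] + np.swapaxes(disp, 1, 2)
    return Trajectory(coords, times=np.arange(spec.n_frames, dtype=float))


def block_correlation_matrix(block_sizes: list[int], intra: float = 0.9, inter: float = 0.1) -> np.ndarray:
    """Planted-community correlation matrix: ``intra`` within each block,
    ``inter`` between blocks, unit diagonal.  PSD for the default values."""
    n = sum(block_sizes)
    c = np.full((n, n), inter)
    start = 0
    for b in block_sizes:
        c[start:start + b, start:start + b] = intra
        start += b
    np.fill_diagonal(c, 1.0)
    if np.min(np.linalg.eigvalsh(c)) < -1e-8:
        raise SpecError("requested block structure is not positive semi-definite")
    return c


def ca_chain(n_res: int, spacing: float = 3.8, chain_id: str = "A", first_resid: int = 1) -> Structure:
    """A gently coiled pseudo-Cα chain used as the base of synthetic
    ensembles (non-collinear, so superposition is always well posed)."""
    atoms = [
        AtomRecord(
            serial=i + 1, name="CA", element="C", residue_index=first_resid + i,
            residue_name="GLY", chain_id=chain_id,
            coords=np.array([i * spacing, 3.0 * np.sin(0.6 * i), 3.0 * np.cos(0.6 * i)]),
        )
        for i in range(n_res)
    ]
    return Structure(atoms)


# ---------------------------------------------------------------------------
# Ideal backbone geometries
# ---------------------------------------------------------------------------

_BOND_N_CA = 1.458
_BOND_CA_C = 1.525
_BOND_C_N = 1.329
_BOND_C_O = 1.231
_ANGLE_N_CA_C = 111.2
_ANGLE_CA_C_N = 116.2
_ANGLE_C_N_CA = 121.7
_ANGLE_CA_C_O = 120.8

HELIX_PHI_PSI = (-57.0, -47.0)
STRAND_PHI_PSI = (-139.0, 135.0)


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d bonded to c with ∠(b,c,d) and dihedral ∠(a,b,c,d)."""
    angle = np.deg2rad(angle_deg)
    dihedral = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d2 = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(dihedral),
        bond * np.sin(angle) * np.sin(dihedral),
    ])
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _build_backbone(phi_psi: np.ndarray) -> dict[str, np.ndarray]:
    """Build N/CA/C/O/H backbone coordinates from per-residue (φ, ψ).

    ω is fixed at 180°.  The amide H is placed 1.0 Å from N along the
    C(prev)=O(prev) direction (the classic DSSP reconstruction), so the
    fixture is usable with or without explicit hydrogens.
    """
    n_res = len(phi_psi)
    N = np.zeros((n_res, 3))
    CA = np.zeros((n_res, 3))
    C = np.zeros((n_res, 3))
    O = np.zeros((n_res, 3))
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [_BOND_N_CA, 0.0, 0.0]
    ang = np.deg2rad(_ANGLE_N_CA_C)
    C[0] = CA[0] + _BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res - 1):
        psi = phi_psi[i, 1]
        N[i + 1] = _nerf(N[i], CA[i], C[i], _BOND_C_N, _ANGLE_CA_C_N, psi)
        CA[i + 1] = _nerf(CA[i], C[i], N[i + 1], _BOND_N_CA, _ANGLE_C_N_CA, 180.0)
        C[i + 1] = _nerf(C[i], N[i + 1], CA[i + 1], _BOND_CA_C, _ANGLE_N_CA_C,
                         phi_psi[i + 1, 0])
        O[i] = _nerf(N[i + 1], CA[i], C[i], _BOND_C_O, _ANGLE_CA_C_O, 180.0)
    O[-1] = _nerf(N[-1], CA[-1], C[-1], _BOND_C_O, _ANGLE_CA_C_O,
                  phi_psi[-1, 1] + 180.0)
    H = np.full((n_res, 3), np.nan)
    for i in range(1, n_res):
        d = C[i - 1] - O[i - 1]
        H[i] = N[i] + d / np.linalg.norm(d)
    return {"N": N, "CA": CA, "C": C, "O": O, "H": H}


def _backbone_structure(bb: dict[str, np.ndarray], chain_id: str = "A",
                        first_resid: int = 1, model_id: int | None = None) -> Structure:
    atoms = []
    serial = 0
    n_res = bb["N"].shape[0]
    for i in range(n_res):
        for name, element in [("N", "N"), ("H", "H"), ("CA", "C"), ("C", "C"), ("O", "O")]:
            xyz = bb[name][i]
            if np.any(np.isnan(xyz)):
                continue
            serial += 1
            atoms.append(AtomRecord(
                serial=serial, name=name, element=element,
                residue_index=first_resid + i, residue_name="ALA",
                chain_id=chain_id, coords=xyz,
            ))
    return Structure(atoms, model_id=model_id)


def _hairpin_phi_psi(n_res: int) -> np.ndarray:
    """Dihedrals for a two-stranded antiparallel β-hairpin.

    Strand residues start from ideal β values and a type-II' tight turn at
    the two central residues; all dihedrals are then refined by
    least-squares so the cross-strand N···O / H···O distances reach ideal
    hydrogen-bond geometry.  Deterministic (fixed initial guess, no
    randomness).
    """
    m = n_res // 2
    init = np.tile(STRAND_PHI_PSI, (n_res, 1)).astype(float)
    init[m - 1] = [60.0, -120.0]   # turn i+1 (type II')
    init[m] = [-80.0, 0.0]         # turn i+2
    # antiparallel register: residue i pairs with n_res+1-i (1-based);
    # double H-bonds on pairs stepping outward from the turn by 2
    pairs = []
    i = m - 1
    while i >= 1:
        pairs.append((i - 1, n_res - i))   # 0-based indices
        i -= 2
    x0 = init.ravel()

    def residuals(x: np.ndarray) -> np.ndarray:
        bb = _build_backbone(x.reshape(-1, 2))
        res = []
        for a, b in pairs:
            res.append(np.linalg.norm(bb["O"][a] - bb["N"][b]) - 2.95)
            res.append(np.linalg.norm(bb["N"][a] - bb["O"][b]) - 2.95)
            if not np.any(np.isnan(bb["H"][b])):
                res.append(np.linalg.norm(bb["O"][a] - bb["H"][b]) - 1.95)
            if not np.any(np.isnan(bb["H"][a])):
                res.append(np.linalg.norm(bb["H"][a] - bb["O"][b]) - 1.95)
        res.extend(0.01 * (x - x0))   # stay near ideal dihedrals
        return np.asarray(res)

    fit = least_squares(residuals, x0, method="lm", max_nfev=20000)
    return fit.x.reshape(-1, 2)


def build_ideal_peptide(ss_kind: str, n_res: int) -> Structure:
    """Ideal-geometry backbone fixture for secondary-structure assignment.

    ``helix`` uses (φ, ψ) = (−57°, −47°), ``strand`` (−139°, 135°), and
    ``hairpin`` two antiparallel strands joined by a tight turn with the
    inter-strand H-bond registry refined numerically.
    """
    if ss_kind == "helix":
        if n_res < 4:
            raise SpecError("a helix needs at least 4 residues")
        phi_psi = np.tile(HELIX_PHI_PSI, (n_res, 1))
    elif ss_kind == "strand":
        if n_res < 2:
            raise SpecError("a strand needs at least 2 residues")
        phi_psi = np.tile(STRAND_PHI_PSI, (n_res, 1))
    elif ss_kind == "hairpin":
        if n_res < 6:
            raise SpecError("a hairpin needs at least 6 residues")
        phi_psi = _hairpin_phi_psi(n_res)
    else:
        raise SpecError(f"unknown ss_kind {ss_kind!r}")
    return _backbone_structure(_build_backbone(np.asarray(phi_psi, dtype=float)))


def synthetic_nmr_ensemble(
    n_models: int = 20,
    n_folded: int = 7,
    n_res: int = 12,
    seed: int = 0,
) -> tuple[list[Structure], tuple[int, int]]:
    """SYNTHETIC stand-in for a solution-NMR conformer ensemble.

    Emulates the situation of the isolated HIF-2α PAS-B ensemble, whose
    G-strand is fully formed in only a minority of conformers: ``n_folded``
    of the ``n_models`` conformers are intact β-hairpins (the second
    strand fully hydrogen-bonded), while the rest carry large dihedral
    perturbations around the turn that break the inter-strand ladder.
    This is a constructed object, not deposited coordinates — the folded
    count is planted and the census machinery must recover it.

    Returns the model list and the (first, last) residue indices of the
    second-strand core, i.e. the G-strand-like census region.
    """
    if not (0 <= n_folded <= n_models):
        raise SpecError("n_folded must lie in [0, n_models]")
    rng = np.random.default_rng(seed)
    folded_dihedrals = _hairpin_phi_psi(n_res)
    folded_slots = set(rng.permutation(n_models)[:n_folded].tolist())
    m = n_res // 2
    models = []
    for k in range(n_models):
        if k in folded_slots:
            bb = _build_backbone(folded_dihedrals)
            jitter = rng.normal(0.0, 0.03, size=3)
            for key in bb:
                bb[key] = bb[key] + jitter   # rigid shift: H-bonds intact
        else:
            perturbed = folded_dihedrals.copy()
            # twist the turn and the strand entry: ladder cannot form
            perturbed[m - 1] += rng.uniform(60.0, 120.0, size=2) * rng.choice([-1, 1], 2)
            perturbed[m] += rng.uniform(60.0, 120.0, size=2) * rng.choice([-1, 1], 2)
            perturbed[m + 1, 1] += rng.uniform(40.0, 80.0) * rng.choice([-1, 1])
            bb = _build_backbone(perturbed)
        models.append(_backbone_structure(bb, model_id=k + 1))
    region = (m + 2, n_res - 1)   # second-strand core, author numbering from 1
    return models, region


# ---------------------------------------------------------------------------
# Water-bridge scenes
# ---------------------------------------------------------------------------

@dataclass
class BridgeSceneSpec:
    """Protein–water–ligand bridge scene specification."""

    n_waters_in_bridge: int = 1
    jitter: float = 0.02
    fraction_of_frames_bridged: float = 1.0
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_waters_in_bridge not in (0, 1, 2):
            raise SpecError("n_waters_in_bridge must be 0, 1 or 2")
        if not (0.0 <= self.fraction_of_frames_bridged <= 1.0):
            raise SpecError("fraction_of_frames_bridged must lie in [0, 1]")
        if self.jitter < 0:
            raise SpecError("jitter must be non-negative")


def _bridge_scene_atoms(n_waters: int) -> tuple[list[AtomRecord], int]:
    """Atom list for the canonical bridged geometry.

    A serine-like hydroxyl donor sits at the origin with its hydrogen on
    the +x axis; waters and the nitro-like acceptor pair follow at 2.8 Å
    hydrogen-bond steps, each donor hydrogen collinear with its acceptor
    (well inside both criteria envelopes).  Two spectator waters sit far
    from everything.  Returns the atoms and the index of the mobile atom
    whose displacement breaks the first link in unbridged frames.
    """
    step = 2.8
    atoms: list[AtomRecord] = []
    serial = [0]

    def add(name, element, resid, resname, chain, xyz):
        serial[0] += 1
        atoms.append(AtomRecord(serial[0], name, element, resid, resname, chain,
                                np.asarray(xyz, dtype=float)))

    # serine-like donor
    add("CB", "C", 304, "SER", "A", [-1.43, 0.0, 0.0])
    add("OG", "O", 304, "SER", "A", [0.0, 0.0, 0.0])
    add("HG", "H", 304, "SER", "A", [0.97, 0.0, 0.0])
    x = step
    water_resid = 0
    mobile_index = None
    for w in range(n_waters):
        water_resid += 1
        if mobile_index is None:
            mobile_index = len(atoms)
        add("O", "O", water_resid, "HOH", "W", [x, 0.0, 0.0])
        add("H1", "H", water_resid, "HOH", "W", [x + 0.97, 0.0, 0.0])
        add("H2", "H", water_resid, "HOH", "W", [x - 0.3, 0.9, 0.0])
        x += step
    lig_start = len(atoms)
    if mobile_index is None:
        mobile_index = lig_start
    add("O1", "O", 1, "LIG", "L", [x, 0.0, 0.0])
    add("N1", "N", 1, "LIG", "L", [x + 0.6, 1.05, 0.0])
    add("O2", "O", 1, "LIG", "L", [x + 1.8, 1.1, 0.0])
    # spectator waters, far from every bridge partner
    for k in range(2):
        water_resid += 1
        base = np.array([20.0 + 4.0 * k, 20.0, 20.0])
        add("O", "O", water_resid, "HOH", "W", base)
        add("H1", "H", water_resid, "HOH", "W", base + [0.97, 0.0, 0.0])
        add("H2", "H", water_resid, "HOH", "W", base + [-0.3, 0.9, 0.0])
    return atoms, mobile_index


def build_bridge_scene(spec: BridgeSceneSpec) -> tuple[Structure, Trajectory]:
    """Scene + trajectory with an exact planted bridge-occupancy fraction.

    Bridged/unbridged frames follow a deterministic seed-derived schedule
    (a permutation, not per-frame coin flips) so occupancy targets are
    exact: ``round(fraction · n_frames)`` frames contain the full
    donor→water(→water)→acceptor chain; in the remaining frames the first
    chain partner is displaced 1.3 Å outward, breaking that link by more
    than 0.5 Å beyond both distance thresholds.
    """
    atoms, mobile_index = _bridge_scene_atoms(spec.n_waters_in_bridge)
    structure = Structure(atoms)
    rng = np.random.default_rng(spec.seed)
    n_bridged = int(round(spec.fraction_of_frames_bridged * spec.n_frames))
    bridged = np.zeros(spec.n_frames, dtype=bool)
    bridged[np.sort(rng.permutation(spec.n_frames)[:n_bridged])] = True
    base = structure.coords
    # displace the whole water (or the ligand, for direct contact)
    mobile_res = structure.atoms[mobile_index].residue_key
    mobile_atoms = [i for i, a in enumerate(structure.atoms) if a.residue_key == mobile_res]
    frames = np.empty((spec.n_frames, structure.n_atoms, 3))
    for f in range(spec.n_frames):
        c = base.copy()
        if not bridged[f]:
            c[mobile_atoms, 0] += 1.3
        if spec.jitter > 0:
            c += rng.normal(0.0, spec.jitter, size=c.shape)
        frames[f] = c
    traj = Trajectory(frames)
    traj.bridged_schedule = bridged  # planted ground truth, for tests
    return structure, traj


# ---------------------------------------------------------------------------
# Two-basin ensembles
# ---------------------------------------------------------------------------

def build_two_basin_trajectory(
    n_frames: int,
    basin_rmsd: float,
    weights: tuple[float, float],
    seed: int = 0,
    n_atoms: int = 10,
) -> Trajectory:
    """Frames scattered tightly around two reference conformations.

    The two basins are ``basin_rmsd`` Å apart (RMSD without fitting) and
    each frame deviates from its basin centre by well under
    ``basin_rmsd/4``.  Frame counts per basin are exact:
    ``round(w1 · n_frames)`` frames in basin 1.  The returned trajectory
    carries ``basin_labels`` and ``basin_references`` attributes with the
    planted ground truth.
    """
    if basin_rmsd <= 0:
        raise SpecError("basin_rmsd must be positive")
    if abs(sum(weights) - 1.0) > 1e-9:
        raise SpecError("weights must sum to 1")
    rng = np.random.default_rng(seed)
    ref_a = rng.normal(0.0, 3.0, size=(n_atoms, 3))
    direction = rng.normal(0.0, 1.0, size=(n_atoms, 3))
    direction /= np.sqrt(np.mean(np.sum(direction ** 2, axis=1)))
    ref_b = ref_a + basin_rmsd * direction
    n1 = int(round(weights[0] * n_frames))
    labels = np.zeros(n_frames, dtype=int)
    labels[rng.permutation(n_frames)[n1:]] = 1
    sigma = basin_rmsd / 20.0   # per-coordinate noise; frame RMSD ~ sqrt(3)·σ
    refs = np.stack([ref_a, ref_b])
    frames = refs[labels] + rng.normal(0.0, sigma, size=(n_frames, n_atoms, 3))
    traj = Trajectory(frames)
    traj.basin_labels = labels
    traj.basin_references = refs
    return traj


def two_basin_structure(n_atoms: int = 10) -> Structure:
    """Pseudo-Cα structure matching :func:`build_two_basin_trajectory`."""
    return ca_chain(n_atoms)


# ---------------------------------------------------------------------------
# Toy dimer for binding-energy tests
# ---------------------------------------------------------------------------

def build_toy_dimer(seed: int = 0, n_per_group: int = 10) -> tuple[Structure, Topology]:
    """Two rigid groups of single-atom pseudo-residues for MM-GBSA tests.

    Chain A sits around the origin and chain B ~8 Å away along +x, with a
    planted inter-group salt bridge (+1/−1 at 3.0 Å) and one apolar
    contact pair (zero charge, deep LJ well at ~4 Å).  The remaining atoms
    carry small random charges shifted so each group is net-neutral (the
    long-range inter-group terms then decay as dipole interactions).
    Every atom is its own residue, which
    makes per-residue decompositions exactly checkable by brute force.
    """
    rng = np.random.default_rng(seed)
    atoms, charges = [], []
    serial = 0

    def add(chain, resid, xyz, q, name="C1"):
        nonlocal serial
        serial += 1
        atoms.append(AtomRecord(serial, name, "C", resid, "RES", chain,
                                np.asarray(xyz, dtype=float)))
        charges.append(q)

    # salt bridge pair across the interface
    add("A", 1, [3.5, 0.0, 0.0], +1.0)
    add("B", 101, [6.5, 0.0, 0.0], -1.0)
    # apolar contact pair
    add("A", 2, [3.5, 3.0, 0.0], 0.0)
    add("B", 102, [7.6, 3.0, 0.0], 0.0)
    qa = rng.uniform(-0.2, 0.2, n_per_group - 2)
    qa += (-1.0 - qa.sum()) / len(qa)   # neutralize group A (salt-bridge +1)
    qb = rng.uniform(-0.2, 0.2, n_per_group - 2)
    qb += (1.0 - qb.sum()) / len(qb)    # neutralize group B (salt-bridge −1)
    for i in range(n_per_group - 2):
        add("A", 3 + i, rng.normal(0.0, 1.8, 3) + [0.0, 0.0, 0.0], qa[i])
    for i in range(n_per_group - 2):
        add("B", 103 + i, rng.normal(0.0, 1.8, 3) + [10.0, 0.0, 0.0], qb[i])
    structure = Structure(atoms)
    n = len(atoms)
    eps = np.full(n, 0.109)
    eps[2] = eps[3] = 0.30   # deeper well on the apolar pair
    topology = Topology(
        charges=np.array(charges),
        rmin=np.full(n, 1.908),
        eps=eps,
        gb_radius=np.full(n, 1.7),
        gb_scale=np.full(n, 0.72),
        bonds=[],
    )
    return structure, topology
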