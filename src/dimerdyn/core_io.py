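"""Domain types and readers/writers for structures, topologies and trajectories.

Structures travel as PDB (including multi-MODEL NMR ensembles), trajectories
as multi-model PDB, DCD or XTC, and per-atom energy parameters as a plain
tab-separated topology table.  Residue identity is ``(chain_id,
residue_index, insertion_code)`` everywhere, preserving author numbering
from the PDB.  Coordinates are assumed whole (unwrapped); no minimum-image
logic is applied downstream.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "AtomRecord",
    "Structure",
    "Topology",
    "Trajectory",
    "SelectionMask",
    "DomainMap",
    "ParseError",
    "TopologyError",
    "SelectionError",
    "EmptySelectionError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "read_topology",
    "write_topology",
    "select",
]


class ParseError(ValueError):
    """A file record could not be interpreted."""


class TopologyError(ValueError):
    """Topology/structure mismatch (atom counts, bad bond indices...)."""


class SelectionError(ValueError):
    """Selection expression failed to parse."""


class EmptySelectionError(SelectionError):
    """A syntactically valid selection matched no atoms."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity plus Cartesian coordinates in Å."""

    serial: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    coords: np.ndarray
    insertion_code: str = ""

    def __post_init__(self):
        c = np.asarray(self.coords, dtype=float)
        if c.shape != (3,) or not np.all(np.isfinite(c)):
            raise ParseError(
                f"atom serial {self.serial}: coordinates must be a finite 3-vector"
            )
        object.__setattr__(self, "coords", c)

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_index, self.insertion_code)


class Structure:
    """An ordered set of atoms, optionally one model of an ensemble.

    Parameters
    ----------
    atoms:
        Ordered atom records.  Residue indices must be non-decreasing
        within each chain (PDB author ordering).
    model_id:
        1-based model number for NMR/trajectory ensembles, or ``None``.
    """

    def __init__(self, atoms: Sequence[AtomRecord], model_id: int | None = None):
        atoms = list(atoms)
        if not atoms:
            raise ParseError("a Structure needs at least one atom")
        serials = [a.serial for a in atoms]
        if len(set(serials)) != len(serials):
            raise ParseError("duplicate atom serials in structure")
        last: dict[str, int] = {}
        for a in atoms:
            if a.chain_id in last and a.residue_index < last[a.chain_id]:
                raise ParseError(
                    f"residue_index decreases within chain {a.chain_id!r} "
                    f"at serial {a.serial}"
                )
            last[a.chain_id] = a.residue_index
        self.atoms = atoms
        self.model_id = model_id
        self._coords = np.array([a.coords for a in atoms], dtype=float)

    # -- array views -------------------------------------------------------
    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) float array of positions in Å (a copy-free view)."""
        return self._coords

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def names(self) -> np.ndarray:
        return np.array([a.name for a in self.atoms])

    @property
    def elements(self) -> np.ndarray:
        return np.array([a.element for a in self.atoms])

    @property
    def chain_ids(self) -> np.ndarray:
        return np.array([a.chain_id for a in self.atoms])

    @property
    def residue_indices(self) -> np.ndarray:
        return np.array([a.residue_index for a in self.atoms])

    @property
    def residue_names(self) -> np.ndarray:
        return np.array([a.residue_name for a in self.atoms])

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Per-atom residue keys ``(chain, resid, icode)``."""
        return [a.residue_key for a in self.atoms]

    def unique_residues(self) -> list[tuple[str, int, str]]:
        """Residue keys in order of first appearance."""
        seen, out = set(), []
        for key in self.residue_keys():
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    def with_coords(self, coords: np.ndarray, model_id: int | None = None) -> "Structure":
        """Same atoms, new coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (self.n_atoms, 3):
            raise TopologyError(
                f"coordinate array shape {coords.shape} does not match "
                f"{self.n_atoms} atoms"
            )
        atoms = [
            AtomRecord(
                a.serial, a.name, a.element, a.residue_index, a.residue_name,
                a.chain_id, coords[i], a.insertion_code,
            )
            for i, a in enumerate(self.atoms)
        ]
        return Structure(atoms, model_id=model_id if model_id is not None else self.model_id)


@dataclass
class Topology:
    """Per-atom non-bonded parameters and connectivity.

    Charges are in elementary charge units, ``rmin`` the per-atom Lennard-
    Jones Rmin/2 in Å (combined additively), ``eps`` the LJ well depth in
    kcal/mol (combined geometrically), ``gb_radius`` the intrinsic
    generalized-Born radius in Å and ``gb_scale`` the HCT descreening
    scale factor.  Parameters are consumed, never derived here.
    """

    charges: np.ndarray
    rmin: np.ndarray
    eps: np.ndarray
    gb_radius: np.ndarray
    gb_scale: np.ndarray
    bonds: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self):
        self.charges = np.asarray(self.charges, dtype=float)
        self.rmin = np.asarray(self.rmin, dtype=float)
        self.eps = np.asarray(self.eps, dtype=float)
        self.gb_radius = np.asarray(self.gb_radius, dtype=float)
        self.gb_scale = np.asarray(self.gb_scale, dtype=float)
        n = self.n_atoms
        for arr, label in [
            (self.rmin, "rmin"), (self.eps, "eps"),
            (self.gb_radius, "gb_radius"), (self.gb_scale, "gb_scale"),
        ]:
            if arr.shape != (n,):
                raise TopologyError(f"{label} must have one entry per atom")
        if np.any(self.gb_radius <= 0):
            raise TopologyError("intrinsic GB radii must be positive")
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n) or i == j:
                raise TopologyError(f"bond ({i}, {j}) references invalid atoms")

    @property
    def n_atoms(self) -> int:
        return len(self.charges)


class Trajectory:
    """Ordered coordinate frames over a fixed atom set.

    ``coords`` is (n_frames, n_atoms, 3) in Å, ``times`` in ps (strictly
    increasing within each replica) and ``replica_ids`` a per-frame integer
    label recording concatenation boundaries.
    """

    def __init__(
        self,
        coords: np.ndarray,
        times: np.ndarray | None = None,
        replica_ids: np.ndarray | None = None,
    ):
        coords = np.asarray(coords, dtype=float)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ParseError("trajectory coords must be (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise ParseError("trajectory contains non-finite coordinates")
        n = coords.shape[0]
        if times is None:
            times = np.arange(n, dtype=float)
        times = np.asarray(times, dtype=float)
        if replica_ids is None:
            replica_ids = np.ones(n, dtype=int)
        replica_ids = np.asarray(replica_ids, dtype=int)
        if times.shape != (n,) or replica_ids.shape != (n,):
            raise ParseError("times/replica_ids must have one entry per frame")
        for rep in np.unique(replica_ids):
            t = times[replica_ids == rep]
            if np.any(np.diff(t) <= 0):
                raise ParseError(f"times not strictly increasing in replica {rep}")
        self.coords = coords
        self.times = times
        self.replica_ids = replica_ids

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def __getitem__(self, frame: int) -> np.ndarray:
        return self.coords[frame]

    def subset(self, frame_indices: Sequence[int]) -> "Trajectory":
        idx = np.asarray(frame_indices, dtype=int)
        return Trajectory(self.coords[idx], self.times[idx], self.replica_ids[idx])


@dataclass(frozen=True)
class SelectionMask:
    """Ordered unique atom indices into a bound structure."""

    atom_indices: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.atom_indices, dtype=int)
        if idx.size == 0:
            raise EmptySelectionError("selection mask is empty")
        if len(np.unique(idx)) != len(idx):
            raise SelectionError("selection mask has duplicate indices")
        object.__setattr__(self, "atom_indices", idx)

    def __len__(self) -> int:
        return len(self.atom_indices)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords)[..., self.atom_indices, :]


class DomainMap:
    """Residue → domain-label mapping (e.g. bHLH, PAS-A, PAS-B, linker)."""

    def __init__(self, mapping: dict[tuple[str, int], str], vocabulary: Iterable[str] | None = None):
        self.mapping = dict(mapping)
        self.vocabulary = sorted(set(vocabulary) if vocabulary is not None else set(self.mapping.values()))
        bad = [lab for lab in self.mapping.values() if lab not in self.vocabulary]
        if bad:
            raise ParseError(f"domain labels outside declared vocabulary: {sorted(set(bad))}")

    def label(self, chain_id: str, residue_index: int) -> str | None:
        return self.mapping.get((chain_id, residue_index))

    def residues(self, label: str) -> list[tuple[str, int]]:
        return [k for k, v in self.mapping.items() if v == label]

    def validate_against(self, structure: Structure) -> None:
        present = {(a.chain_id, a.residue_index) for a in structure.atoms}
        missing = [k for k in self.mapping if k not in present]
        if missing:
            raise ParseError(f"domain map names residues absent from structure: {missing[:5]}")

    @classmethod
    def from_csv(cls, path: str | Path) -> "DomainMap":
        df = pd.read_csv(path, dtype={"chain": str, "resid": int, "domain": str})
        return cls({(r.chain, int(r.resid)): r.domain for r in df.itertuples()})

    def to_csv(self, path: str | Path) -> None:
        rows = [
            {"chain": c, "resid": r, "domain": lab}
            for (c, r), lab in sorted(self.mapping.items())
        ]
        pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# PDB I/O (via gemmi)
# ---------------------------------------------------------------------------

def _structure_from_gemmi_model(model: gemmi.Model, model_id: int | None) -> Structure:
    atoms = []
    serial = 0
    for chain in model:
        for res in chain:
            for atom in res:
                serial += 1
                atoms.append(
                    AtomRecord(
                        serial=atom.serial if atom.serial else serial,
                        name=atom.name,
                        element=atom.element.name,
                        residue_index=res.seqid.num,
                        residue_name=res.name,
                        chain_id=chain.name,
                        coords=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                        insertion_code=(res.seqid.icode or "").strip(),
                    )
                )
    if not atoms:
        raise ParseError("model contains no atoms")
    return Structure(atoms, model_id=model_id)


def read_structure(path: str | Path, model: int | None = None) -> Structure | list[Structure]:
    """Read a PDB file into :class:`Structure` objects.

    Multi-MODEL files (NMR ensembles, PDB trajectories) yield one Structure
    per model with ``model_id`` 1..n, unless a specific ``model`` is
    requested.  All ATOM and HETATM records are kept.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:  # gemmi reports the offending line
        raise ParseError(f"{path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models found")
    structures = [
        _structure_from_gemmi_model(m, i + 1) for i, m in enumerate(st)
    ]
    if model is not None:
        for s in structures:
            if s.model_id == model:
                return s
        raise ParseError(f"{path}: model {model} not present")
    return structures[0] if len(structures) == 1 else structures


def write_structure(path: str | Path, structures: Structure | Sequence[Structure]) -> None:
    """Write one Structure (or several, as MODEL blocks) to a PDB file."""
    if isinstance(structures, Structure):
        structures = [structures]
    st = gemmi.Structure()
    st.name = "dimerdyn"
    for k, s in enumerate(structures):
        model = gemmi.Model(k + 1)
        chain_map: dict[str, gemmi.Chain] = {}
        for a in s.atoms:
            if a.chain_id not in chain_map:
                chain_map[a.chain_id] = gemmi.Chain(a.chain_id or "A")
            chain = chain_map[a.chain_id]
            if (
                len(chain) == 0
                or chain[-1].seqid.num != a.residue_index
                or chain[-1].name != a.residue_name
            ):
                res = gemmi.Residue()
                res.name = a.residue_name
                res.seqid = gemmi.SeqId(a.residue_index, a.insertion_code or " ")
                chain.add_residue(res)
            atom = gemmi.Atom()
            atom.name = a.name
            atom.serial = a.serial
            atom.element = gemmi.Element(a.element)
            atom.pos = gemmi.Position(*a.coords)
            chain[-1].add_atom(atom)
        for chain in chain_map.values():
            model.add_chain(chain)
        st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def read_trajectory(paths: str | Path | Sequence[str | Path], structure: Structure) -> Trajectory:
    """Read one or more trajectory files and concatenate them in path order.

    Multi-model PDB is read natively; ``.dcd``/``.xtc`` are read through
    mdtraj using ``structure`` for the atom count.  Each input file becomes
    one replica (ids 1, 2, ...) with its own strictly increasing time axis.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    frames, times, reps = [], [], []
    for rep, p in enumerate(paths, start=1):
        p = Path(p)
        suffix = p.suffix.lower()
        if suffix in {".pdb", ".ent"}:
            models = read_structure(p)
            if isinstance(models, Structure):
                models = [models]
            block = np.array([m.coords for m in models])
        elif suffix in {".dcd", ".xtc"}:
            block = _read_binary_trajectory(p, structure)
        else:
            raise ParseError(f"unsupported trajectory format: {p.suffix}")
        if block.shape[1] != structure.n_atoms:
            raise TopologyError(
                f"{p}: frame atom count {block.shape[1]} does not match "
                f"structure ({structure.n_atoms})"
            )
        frames.append(block)
        times.append(np.arange(block.shape[0], dtype=float))
        reps.append(np.full(block.shape[0], rep, dtype=int))
    return Trajectory(np.concatenate(frames), np.concatenate(times), np.concatenate(reps))


def _read_binary_trajectory(path: Path, structure: Structure) -> np.ndarray:
    import mdtraj  # deferred: only needed for DCD/XTC

    import tempfile

    with tempfile.NamedTemporaryFile(suffix=".pdb", delete=False) as fh:
        tmp = fh.name
    try:
        write_structure(tmp, structure)
        traj = mdtraj.load(str(path), top=tmp)
    finally:
        Path(tmp).unlink(missing_ok=True)
    return np.asarray(traj.xyz, dtype=float) * 10.0  # nm → Å


# ---------------------------------------------------------------------------
# Topology table
# ---------------------------------------------------------------------------

_TOPOLOGY_COLUMNS = [
    "serial", "name", "charge", "rmin", "eps", "gb_radius", "gb_scale", "bonded",
]


def read_topology(path: str | Path, structure: Structure | None = None) -> Topology:
    """Read the 8-column tab-separated topology table.

    Columns: serial, name, charge, rmin, eps, gb_radius, gb_scale, bonded
    (comma-separated partner serials, or ``-``).  If ``structure`` is
    given, row count and serials are validated against it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"bonded": str})
    missing = [c for c in _TOPOLOGY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"topology table missing columns: {missing}")
    serial_to_idx = {int(s): i for i, s in enumerate(df["serial"])}
    if structure is not None:
        if len(df) != structure.n_atoms:
            raise TopologyError(
                f"topology has {len(df)} rows for {structure.n_atoms} atoms"
            )
    bonds = []
    for i, partners in enumerate(df["bonded"].fillna("-")):
        if partners.strip() in {"-", ""}:
            continue
        for tok in partners.split(","):
            j = serial_to_idx.get(int(tok))
            if j is None:
                raise TopologyError(f"bonded partner serial {tok} not in table")
            if i < j:
                bonds.append((i, j))
    return Topology(
        charges=df["charge"].to_numpy(float),
        rmin=df["rmin"].to_numpy(float),
        eps=df["eps"].to_numpy(float),
        gb_radius=df["gb_radius"].to_numpy(float),
        gb_scale=df["gb_scale"].to_numpy(float),
        bonds=bonds,
    )


def write_topology(path: str | Path, topology: Topology, structure: Structure) -> None:
    partners: dict[int, list[int]] = {i: [] for i in range(topology.n_atoms)}
    for i, j in topology.bonds:
        partners[i].append(structure.atoms[j].serial)
        partners[j].append(structure.atoms[i].serial)
    rows = []
    for i, a in enumerate(structure.atoms):
        rows.append({
            "serial": a.serial,
            "name": a.name,
            "charge": topology.charges[i],
            "rmin": topology.rmin[i],
            "eps": topology.eps[i],
            "gb_radius": topology.gb_radius[i],
            "gb_scale": topology.gb_scale[i],
            "bonded": ",".join(str(s) for s in sorted(partners[i])) or "-",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

_WATER_NAMES = {"HOH", "WAT", "SOL", "TIP3"}
_BACKBONE_NAMES = {"N", "CA", "C", "O", "H", "HA", "OXT"}


def _term_mask(structure: Structure, tokens: list[str]) -> np.ndarray:
    """Evaluate one keyword term, e.g. ``name CA CB`` or ``resid 304-306``."""
    key = tokens[0]
    args = tokens[1:]
    n = structure.n_atoms
    if key == "all":
        return np.ones(n, dtype=bool)
    if key == "protein":
        return ~np.isin(structure.residue_names, sorted(_WATER_NAMES))
    if key == "water":
        return np.isin(structure.residue_names, sorted(_WATER_NAMES))
    if key == "backbone":
        return np.isin(structure.names, sorted(_BACKBONE_NAMES))
    if not args:
        raise SelectionError(f"keyword {key!r} needs arguments")
    if key == "name":
        return np.isin(structure.names, args)
    if key == "element":
        return np.isin(structure.elements, [a.upper() for a in args] + args)
    if key == "chain":
        return np.isin(structure.chain_ids, args)
    if key == "resname":
        return np.isin(structure.residue_names, args)
    if key == "resid":
        resids = structure.residue_indices
        mask = np.zeros(n, dtype=bool)
        import re

        for a in args:
            m = re.fullmatch(r"(-?\d+)-(-?\d+)", a)
            if m:
                lo, hi = int(m.group(1)), int(m.group(2))
                mask |= (resids >= lo) & (resids <= hi)
            elif re.fullmatch(r"-?\d+", a):
                mask |= resids == int(a)
            else:
                raise SelectionError(f"bad resid token {a!r}")
        return mask
    raise SelectionError(f"unknown selection keyword {key!r}")


_KEYWORDS = {"all", "protein", "water", "backbone", "name", "element", "chain",
             "resname", "resid"}


def select(structure: Structure, expression: str) -> SelectionMask:
    """Resolve a selection expression to an ordered atom mask.

    Grammar: ``clause (or clause)*`` where each clause is
    ``[not] term (and [not] term)*`` and a term is one of ``all``,
    ``protein``, ``water``, ``backbone``, ``name A B``, ``element O``,
    ``chain B``, ``resname HOH``, ``resid 304-306 310``.
    """
    expr = expression.strip()
    if not expr:
        raise SelectionError("empty selection expression")
    total = np.zeros(structure.n_atoms, dtype=bool)
    for clause in expr.split(" or "):
        clause_mask = np.ones(structure.n_atoms, dtype=bool)
        for raw_term in clause.split(" and "):
            tokens = raw_term.split()
            if not tokens:
                raise SelectionError(f"empty term in expression {expression!r}")
            negate = tokens[0] == "not"
            if negate:
                tokens = tokens[1:]
                if not tokens:
                    raise SelectionError("'not' must be followed by a term")
            if tokens[0] not in _KEYWORDS:
                raise SelectionError(f"unknown selection keyword {tokens[0]!r}")
            m = _term_mask(structure, tokens)
            clause_mask &= ~m if negate else m
        total |= clause_mask
    indices = np.nonzero(total)[0]
    if indices.size == 0:
        raise EmptySelectionError(f"selection {expression!r} matched no atoms")
    return SelectionMask(indices)
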