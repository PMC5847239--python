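"""GROMOS nearest-neighbour conformational clustering (Daura scheme).

Pairwise RMSDs are computed on the calculation mask after best-fit
superposition on the fit mask; the frame with the most neighbours within
the cutoff becomes a cluster centre, it and its neighbours are removed,
and the procedure repeats.  Ties between equal neighbour counts are
broken by the lowest frame index, making the partition deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dimerdyn.core_io import SelectionMask, Trajectory
from dimerdyn.geometry import pairwise_rmsd_matrix

__all__ = ["ClusterResult", "gromos_cluster"]


@dataclass
class Cluster:
    members: np.ndarray   # frame indices, ascending
    centre: int           # representative frame

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ClusterResult:
    """Disjoint, exhaustive partition of frames, largest cluster first."""

    clusters: list[Cluster]
    cutoff: float

    def __post_init__(self):
        sizes = [len(c) for c in self.clusters]
        if any(s2 > s1 for s1, s2 in zip(sizes, sizes[1:])):
            raise ValueError("cluster sizes must be non-increasing")
        all_members = np.concatenate([c.members for c in self.clusters])
        if len(np.unique(all_members)) != len(all_members):
            raise ValueError("clusters overlap")

    @property
    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]

    def membership(self) -> np.ndarray:
        n = sum(self.sizes)
        out = np.empty(n, dtype=int)
        for k, c in enumerate(self.clusters):
            out[c.members] = k
        return out


def gromos_cluster(
    traj: Trajectory,
    cutoff: float,
    fit_mask: SelectionMask | None = None,
    calc_mask: SelectionMask | None = None,
    pairwise_fit: bool = True,
) -> ClusterResult:
    """Daura nearest-neighbour clustering of trajectory frames.

    ``fit_mask`` selects the atoms used for the pairwise best-fit
    superposition, ``calc_mask`` those entering the RMSD (both default to
    all atoms).  When the masks coincide the fit and the metric use the
    same atoms, matching the common usage of fitting on a domain's Cα
    before clustering ligand poses with the same reference frame.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if traj.n_frames == 0:
        raise ValueError("empty trajectory")
    if fit_mask is None and calc_mask is None:
        dmat = pairwise_rmsd_matrix(traj.coords, fit=pairwise_fit)
    elif calc_mask is None or (
        fit_mask is not None and calc_mask is not None
        and np.array_equal(fit_mask.atom_indices, calc_mask.atom_indices)
    ):
        m = fit_mask if fit_mask is not None else calc_mask
        dmat = pairwise_rmsd_matrix(m.apply(traj.coords), fit=pairwise_fit)
    else:
        dmat = _fit_then_calc_rmsd(traj.coords, fit_mask, calc_mask, pairwise_fit)
    n = traj.n_frames
    neighbours = dmat <= cutoff
    np.fill_diagonal(neighbours, True)
    remaining = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while remaining.any():
        counts = (neighbours & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        centre = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.nonzero(neighbours[centre] & remaining)[0]
        clusters.append(Cluster(members=members, centre=centre))
        remaining[members] = False
    clusters.sort(key=lambda c: (-len(c), c.centre))
    return ClusterResult(clusters=clusters, cutoff=cutoff)


def _fit_then_calc_rmsd(
    coords: np.ndarray,
    fit_mask: SelectionMask | None,
    calc_mask: SelectionMask,
    pairwise_fit: bool,
) -> np.ndarray:
    """Pairwise RMSD on ``calc_mask`` after superposing each pair on
    ``fit_mask`` (per-pair Kabsch; quadratic in frames, for modest sets)."""
    from dimerdyn.geometry import apply_transform, superpose

    n = coords.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ci = coords[i]
            if pairwise_fit and fit_mask is not None:
                rot, trans, _ = superpose(fit_mask.apply(coords[i]), fit_mask.apply(coords[j]))
                ci = apply_transform(coords[i], rot, trans)
            diff = calc_mask.apply(ci) - calc_mask.apply(coords[j])
            out[i, j] = out[j, i] = np.sqrt(np.mean(np.sum(diff ** 2, axis=1)))
    return out
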