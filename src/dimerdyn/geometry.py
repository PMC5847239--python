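"""Superposition, RMSD/RMSF flexibility profiles and PCA frame selection.

RMSF follows the replica-concatenation convention: the replicas are joined,
an initial window of each replica is discarded, and fluctuations are taken
about an iteratively refined mean structure.  PCA frame selection picks the
most populated bins of the PC1×PC2 density until a requested coverage
fraction of the trajectory is reached — the scheme used to draw a common
conformational ensemble for energetic post-processing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from dimerdyn.core_io import SelectionMask, Structure, Trajectory

__all__ = [
    "FlexibilityProfile",
    "FrameSubset",
    "superpose",
    "apply_transform",
    "rmsd_series",
    "rmsf",
    "pca_frame_selection",
    "pairwise_rmsd_matrix",
]


class DegeneracyError(ValueError):
    """Superposition is underdetermined (too few or collinear points)."""


@dataclass
class FlexibilityProfile:
    """Per-residue RMSF in Å, keyed by ``(chain, resid, icode)``."""

    residue_keys: list[tuple[str, int, str]]
    rmsf: np.ndarray
    excluded_segments: list[str]

    def __post_init__(self):
        if np.any(self.rmsf < 0):
            raise ValueError("RMSF cannot be negative")
        if len(self.residue_keys) != len(self.rmsf):
            raise ValueError("one RMSF value per residue required")

    def as_dict(self) -> dict[tuple[str, int, str], float]:
        return dict(zip(self.residue_keys, self.rmsf))


@dataclass
class FrameSubset:
    """Frames picked from the PC1×PC2 density, with the histogram used."""

    frame_indices: np.ndarray
    histogram: np.ndarray
    coverage: float

    def __post_init__(self):
        if not (0.0 < self.coverage <= 1.0):
            raise ValueError("coverage must lie in (0, 1]")


def superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    mask: SelectionMask | None = None,
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-fit rigid superposition (Kabsch) of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the mask-atom RMSD.
    The rotation is proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    a = mask.apply(mobile) if mask is not None else mobile
    b = mask.apply(reference) if mask is not None else reference
    if a.shape != b.shape:
        raise ValueError("mobile/reference mask shapes differ")
    if a.shape[0] < 3:
        raise DegeneracyError("need at least 3 points to superpose")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    # collinearity: rank of the centred point cloud must be >= 2
    if np.linalg.matrix_rank(a0, tol=1e-8) < 2 or np.linalg.matrix_rank(b0, tol=1e-8) < 2:
        raise DegeneracyError("points are collinear; rotation underdetermined")
    h = a0.T @ b0
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    trans = cb - rot @ ca
    fitted = a @ rot.T + trans
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - b) ** 2, axis=1))))
    return rot, trans, rmsd


def apply_transform(coords: np.ndarray, rotation: np.ndarray, translation: np.ndarray) -> np.ndarray:
    return np.asarray(coords) @ rotation.T + translation


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    fit_mask: SelectionMask,
    calc_mask: SelectionMask,
) -> np.ndarray:
    """Per-frame RMSD (Å) from ``reference`` after best-fit superposition.

    Each frame is fitted on ``fit_mask`` (typically protein Cα) and the
    deviation evaluated on ``calc_mask``, which may restrict to core
    domains excluding linkers and loops.
    """
    ref = reference.coords
    out = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        rot, trans, _ = superpose(traj.coords[f], ref, fit_mask)
        fitted = apply_transform(traj.coords[f], rot, trans)
        diff = calc_mask.apply(fitted) - calc_mask.apply(ref)
        out[f] = np.sqrt(np.mean(np.sum(diff ** 2, axis=1)))
    return out


def _discard_initial_frames(traj: Trajectory, discard_initial: float) -> np.ndarray:
    """Frame indices surviving the per-replica equilibration discard (ps)."""
    keep = np.zeros(traj.n_frames, dtype=bool)
    for rep in np.unique(traj.replica_ids):
        sel = traj.replica_ids == rep
        t0 = traj.times[sel][0]
        keep |= sel & (traj.times >= t0 + discard_initial)
    return np.nonzero(keep)[0]


def iterative_mean_structure(
    coords: np.ndarray, mask: SelectionMask | None = None, tol: float = 1e-6, max_iter: int = 50
) -> tuple[np.ndarray, np.ndarray]:
    """Fit frames to their mean, recompute the mean, iterate to convergence.

    Returns ``(fitted_coords, mean_coords)``.  Convergence is the maximum
    coordinate shift of the mean between iterations falling below ``tol`` Å.
    """
    fitted = np.array(coords, dtype=float)
    mean = fitted[0].copy()
    for _ in range(max_iter):
        for f in range(fitted.shape[0]):
            rot, trans, _ = superpose(fitted[f], mean, mask)
            fitted[f] = apply_transform(fitted[f], rot, trans)
        new_mean = fitted.mean(axis=0)
        shift = np.max(np.abs(new_mean - mean))
        mean = new_mean
        if shift < tol:
            break
    return fitted, mean


def rmsf(
    traj: Trajectory,
    mask: SelectionMask,
    structure: Structure,
    discard_initial: float = 0.0,
    fit_mask: SelectionMask | None = None,
    excluded_segments: list[str] | None = None,
) -> FlexibilityProfile:
    """Per-residue RMSF over the concatenated replicas.

    Frames earlier than ``discard_initial`` ps into each replica are
    dropped; the rest are superposed on ``fit_mask`` (default: ``mask``)
    onto their iterated mean structure, and RMSF_i =
    sqrt(<|r_i - <r_i>|^2>) is evaluated on the ``mask`` atoms (one value
    per selected residue, typically one Cα each).
    """
    keep = _discard_initial_frames(traj, discard_initial)
    if keep.size == 0:
        raise ValueError("discard window removes every frame")
    fit_mask = fit_mask if fit_mask is not None else mask
    full = np.array(traj.coords[keep], dtype=float)
    mean_fit = fit_mask.apply(full)[0].copy()
    for _ in range(50):
        for f in range(full.shape[0]):
            rot, trans, _ = superpose(fit_mask.apply(full[f]), mean_fit)
            full[f] = apply_transform(full[f], rot, trans)
        new_mean = fit_mask.apply(full).mean(axis=0)
        shift = np.max(np.abs(new_mean - mean_fit))
        mean_fit = new_mean
        if shift < 1e-6:
            break
    sub = mask.apply(full)
    dev = sub - sub.mean(axis=0)
    msf = np.mean(np.sum(dev ** 2, axis=2), axis=0)
    keys = [structure.atoms[i].residue_key for i in mask.atom_indices]
    return FlexibilityProfile(
        residue_keys=keys,
        rmsf=np.sqrt(msf),
        excluded_segments=excluded_segments or [],
    )


def pca_frame_selection(
    traj: Trajectory,
    interface_mask: SelectionMask,
    n_bins: int = 50,
    coverage: float = 0.15,
) -> FrameSubset:
    """Select the frames in the most populated PC1×PC2 density bins.

    PCA is run on the superposed interface-Cα coordinates of the
    concatenated trajectory.  Frames are binned on an ``n_bins`` ×
    ``n_bins`` grid over the (PC1, PC2) bounding box and bins are
    accumulated from most populated downward (ties broken by flat bin
    index) until the cumulative frame fraction reaches ``coverage``.
    """
    if not (0.0 < coverage <= 1.0):
        raise ValueError("coverage must lie in (0, 1]")
    if traj.n_frames < 2:
        raise ValueError("PCA needs at least two frames")
    sub = interface_mask.apply(traj.coords)
    fitted, mean = iterative_mean_structure(sub)
    flat = (fitted - mean).reshape(traj.n_frames, -1)
    # principal axes of the fluctuation covariance via thin SVD
    u, s, vt = np.linalg.svd(flat - flat.mean(axis=0), full_matrices=False)
    proj = (flat - flat.mean(axis=0)) @ vt[:2].T
    edges1 = np.linspace(proj[:, 0].min(), proj[:, 0].max(), n_bins + 1)
    edges2 = np.linspace(proj[:, 1].min(), proj[:, 1].max(), n_bins + 1)
    b1 = np.clip(np.digitize(proj[:, 0], edges1) - 1, 0, n_bins - 1)
    b2 = np.clip(np.digitize(proj[:, 1], edges2) - 1, 0, n_bins - 1)
    flat_bin = b1 * n_bins + b2
    hist = np.bincount(flat_bin, minlength=n_bins * n_bins)
    order = np.lexsort((np.arange(hist.size), -hist))
    target = coverage * traj.n_frames
    chosen, total = [], 0
    for bin_id in order:
        if total >= target or hist[bin_id] == 0:
            break
        chosen.append(bin_id)
        total += hist[bin_id]
    sel = np.nonzero(np.isin(flat_bin, chosen))[0]
    return FrameSubset(
        frame_indices=sel,
        histogram=hist.reshape(n_bins, n_bins),
        coverage=coverage,
    )


def pairwise_rmsd_matrix(
    coords: np.ndarray,
    fit: bool = True,
) -> np.ndarray:
    """All-pairs RMSD (Å) between frames, optionally after pairwise best fit.

    Uses a batched Kabsch evaluation: per-pair cross-covariance matrices
    are SVD-decomposed in one vectorized call, so the n² pair fits stay
    cheap for a few thousand frames of small atom sets.
    """
    x = np.asarray(coords, dtype=float)
    n_frames, n_atoms, _ = x.shape
    centred = x - x.mean(axis=1, keepdims=True)
    if not fit:
        diff = centred[:, None] - centred[None, :]
        return np.sqrt(np.mean(np.sum(diff ** 2, axis=-1), axis=-1))
    sq = np.sum(centred ** 2, axis=(1, 2))
    ii, jj = np.triu_indices(n_frames, k=1)
    # cross-covariances H_ij = A_i^T B_j for every pair above the diagonal
    h = np.einsum("pki,pkj->pij", centred[ii], centred[jj])
    u, s, vt = np.linalg.svd(h)
    det = np.linalg.det(np.einsum("pij,pjk->pik", u, vt))
    s_corr = s.copy()
    s_corr[:, 2] *= np.sign(det)
    msd = (sq[ii] + sq[jj] - 2.0 * s_corr.sum(axis=1)) / n_atoms
    out = np.zeros((n_frames, n_frames))
    vals = np.sqrt(np.clip(msd, 0.0, None))
    out[ii, jj] = vals
    out[jj, ii] = vals
    return out
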