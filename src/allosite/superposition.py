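"""Least-squares superposition and identification of an invariant rigid core.

All frames of a multi-condition "super trajectory" are aligned on a common
rigid core before any geometric analysis.  The core is found iteratively:
frames are superposed on the current candidate residue set, the residue with
the largest positional variance is discarded, and the procedure repeats until
every surviving residue is sufficiently invariant (or a target fraction of
residues remains).  Superposition itself is the Kabsch algorithm with the SVD
sign correction that guarantees a proper rotation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .structure_io import ResidueSelection, Structure, Trajectory

__all__ = [
    "SuperpositionResult",
    "kabsch",
    "superpose",
    "superpose_trajectory",
    "rmsd",
    "rmsd_series",
    "find_invariant_core",
]


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # applied after rotation, Angstrom
    rmsd: float  # on the fitted selection, Angstrom


def kabsch(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation/translation mapping ``mobile`` onto ``reference``.

    Returns ``(R, t)`` such that ``mobile @ R.T + t`` minimises the RMSD to
    ``reference`` over all rigid motions.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.shape[0] < 3:
        raise ValueError("need at least 3 matched points")
    mob_center = mobile.mean(axis=0)
    ref_center = reference.mean(axis=0)
    p = mobile - mob_center
    q = reference - ref_center
    if np.linalg.matrix_rank(p, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear or coincident) selection")
    h = p.T @ q
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = ref_center - rot @ mob_center
    return rot, trans


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    diff = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    return float(np.sqrt((diff ** 2).sum() / diff.shape[0]))


def superpose(
    frame: np.ndarray,
    reference: np.ndarray,
    fit_indices: np.ndarray | None = None,
) -> tuple[SuperpositionResult, np.ndarray]:
    """Fit ``frame`` onto ``reference`` using ``fit_indices`` and transform all atoms.

    ``frame`` and ``reference`` are (n_atoms, 3) arrays sharing one atom
    order; the fit uses only ``fit_indices`` (all atoms when ``None``).
    """
    frame = np.asarray(frame, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if fit_indices is None:
        fit_indices = np.arange(frame.shape[0])
    rot, trans = kabsch(frame[fit_indices], reference[fit_indices])
    transformed = frame @ rot.T + trans
    fitted_rmsd = rmsd(transformed[fit_indices], reference[fit_indices])
    if abs(np.linalg.det(rot) - 1.0) > 1e-6:
        raise RuntimeError("rotation is not proper")  # pragma: no cover
    return SuperpositionResult(rot, trans, fitted_rmsd), transformed


def _fit_atom_indices(
    topology: Structure,
    selection: ResidueSelection | None,
    backbone_only: bool,
) -> np.ndarray:
    idx = topology.select(selection=selection, backbone_only=backbone_only,
                          heavy_only=not backbone_only)
    if idx.size == 0:
        raise ValueError("empty fit selection")
    return idx


def superpose_trajectory(
    traj: Trajectory,
    reference: Structure | np.ndarray | None = None,
    selection: ResidueSelection | None = None,
    backbone_only: bool = True,
) -> tuple[Trajectory, np.ndarray]:
    """Superpose every frame on a reference over ``selection``.

    ``reference=None`` uses the first frame.  Returns the transformed
    trajectory and the per-frame fit RMSD in Angstrom.
    """
    idx = _fit_atom_indices(traj.topology, selection, backbone_only)
    if reference is None:
        ref_coords = traj.coords[0]
    elif isinstance(reference, Structure):
        ref_coords = reference.coords
    else:
        ref_coords = np.asarray(reference, dtype=float)
    out = np.empty_like(traj.coords)
    rmsds = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        result, out[i] = superpose(traj.coords[i], ref_coords, idx)
        rmsds[i] = result.rmsd
    return traj.with_coords(out), rmsds


def rmsd_series(
    traj: Trajectory,
    reference: Structure,
    fit_selection: ResidueSelection | None = None,
    measure_selection: ResidueSelection | None = None,
    fit_backbone_only: bool = True,
    measure_heavy_only: bool = True,
) -> np.ndarray:
    """Per-frame RMSD of ``measure_selection`` after fitting on ``fit_selection``."""
    fit_idx = _fit_atom_indices(traj.topology, fit_selection, fit_backbone_only)
    measure_idx = traj.topology.select(selection=measure_selection,
                                       heavy_only=measure_heavy_only)
    if measure_idx.size == 0:
        raise ValueError("empty measure selection")
    ref = reference.coords
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        _, transformed = superpose(traj.coords[i], ref, fit_idx)
        values[i] = rmsd(transformed[measure_idx], ref[measure_idx])
    return values


def _per_residue_variance(
    coords: np.ndarray, residue_index: np.ndarray, n_residues: int
) -> np.ndarray:
    """Mean (over a residue's atoms) total positional variance, in A^2."""
    mean = coords.mean(axis=0)
    per_atom = ((coords - mean) ** 2).sum(axis=2).mean(axis=0)  # (n_atoms,)
    sums = np.bincount(residue_index, weights=per_atom, minlength=n_residues)
    counts = np.bincount(residue_index, minlength=n_residues)
    return sums / np.maximum(counts, 1)


def find_invariant_core(
    traj: Trajectory,
    backbone_only: bool = True,
    target_fraction: float = 0.5,
    variance_threshold: float | None = 0.1,
    max_mean_iterations: int = 3,
) -> ResidueSelection:
    """Identify the most invariant residues to serve as the alignment frame.

    Starting from all protein residues, the trajectory is iteratively
    superposed on the mean structure of the current candidate set and the
    residue with the largest positional variance is dropped, until either
    every candidate's variance falls below ``variance_threshold`` (A^2, set
    ``None`` to disable) or only ``ceil(target_fraction * n_residues)``
    residues remain.  Ties are broken toward keeping the lower residue number.
    Deterministic for a given trajectory and parameters.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames to measure variance")
    topology = traj.topology
    all_residues = ResidueSelection.all_protein(topology).members
    n_total = len(all_residues)
    floor = max(int(math.ceil(target_fraction * n_total)), 3)
    candidates = list(all_residues)

    while True:
        sel = ResidueSelection(tuple(candidates))
        idx = topology.select(selection=sel, backbone_only=backbone_only,
                              heavy_only=not backbone_only)
        sub = traj.coords[:, idx, :]
        # Iteratively fit all frames to their own mean over the candidate set.
        fitted = sub.copy()
        for _ in range(max_mean_iterations):
            mean = fitted.mean(axis=0)
            for f in range(fitted.shape[0]):
                rot, trans = kabsch(fitted[f], mean)
                fitted[f] = fitted[f] @ rot.T + trans
        res_index_global = topology.residue_index[idx]
        # Compact residue indices local to the candidate set
        uniq, local = np.unique(res_index_global, return_inverse=True)
        variances = _per_residue_variance(fitted, local, uniq.size)

        if variance_threshold is not None and variances.max() < variance_threshold:
            break
        if len(candidates) <= floor:
            break
        if len(candidates) - 1 < 3:
            raise ValueError("invariant core would shrink below 3 residues")
        # Drop the most mobile residue; ties resolve to the lower residue_seq.
        worst = np.flatnonzero(variances == variances.max())
        drop_local = min(worst, key=lambda i: candidates[i])
        del candidates[int(drop_local)]

    ordered = sorted(candidates)
    return ResidueSelection(tuple(ordered))
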