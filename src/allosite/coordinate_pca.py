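"""PCA of the Cartesian coordinates of the binding-site residues.

The covariance matrix C_ij = <(r_i - <r_i>) . (r_j - <r_j>)> is built over
the 3N coordinates of the selected atoms (heavy atoms, including side chains
by default) across all frames of an already core-superposed trajectory, and
diagonalised.  Fitting on the concatenated multi-condition trajectory gives a
single shared component space into which each condition's frames are
projected; the spread of those projections measures how much conformational
freedom the site retains in each condition.

No mass weighting is applied.  Eigenvector signs follow a deterministic
convention (the largest-magnitude component is positive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .structure_io import ResidueSelection, Trajectory

__all__ = ["PCAModel", "fit_pca", "project"]


@dataclass(frozen=True)
class PCAModel:
    mean: np.ndarray  # (3N,) Angstrom
    eigenvectors: np.ndarray  # (3N, 3N), orthonormal columns
    eigenvalues: np.ndarray  # (3N,), A^2, descending, clipped at 0
    selection: ResidueSelection
    atom_indices: np.ndarray  # indices into the fitting topology
    n_atoms: int


def _coordinate_matrix(traj: Trajectory, atom_indices: np.ndarray) -> np.ndarray:
    return traj.coords[:, atom_indices, :].reshape(traj.n_frames, -1)


def fit_pca(
    traj: Trajectory,
    selection: ResidueSelection,
    include_sidechains: bool = True,
) -> PCAModel:
    """Diagonalise the coordinate covariance of the selected residues.

    Uses the sample covariance (ddof=1), so the variance of the fitting set's
    own projections equals the corresponding eigenvalue exactly.
    """
    if traj.n_frames < 2:
        raise ValueError("need at least 2 frames")
    if len(selection) == 0:
        raise ValueError("empty selection")
    if include_sidechains:
        idx = traj.topology.select(selection=selection, heavy_only=True)
    else:
        idx = traj.topology.select(selection=selection, backbone_only=True)
    if idx.size == 0:
        raise ValueError("selection resolves to no atoms")
    x = _coordinate_matrix(traj, idx)
    mean = x.mean(axis=0)
    centered = x - mean
    cov = centered.T @ centered / (x.shape[0] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    # Deterministic sign: largest-|component| entry of each eigenvector positive
    for j in range(evecs.shape[1]):
        k = np.argmax(np.abs(evecs[:, j]))
        if evecs[k, j] < 0:
            evecs[:, j] = -evecs[:, j]
    return PCAModel(mean, evecs, evals, selection, idx, idx.size)


def project(
    traj: Trajectory,
    model: PCAModel,
    n_components: int = 2,
) -> np.ndarray:
    """Scores of each frame in the model's eigenvector basis, (n_frames, k)."""
    if n_components < 1 or n_components > model.eigenvectors.shape[1]:
        raise ValueError("invalid number of components")
    idx = model.atom_indices
    if traj.coords.shape[1] <= idx.max():
        raise ValueError("trajectory atom order does not match the fitted model")
    x = _coordinate_matrix(traj, idx)
    if x.shape[1] != model.mean.shape[0]:
        raise ValueError("atom-order mismatch with fitted model")
    return (x - model.mean) @ model.eigenvectors[:, :n_components]


def project_structure(coords: np.ndarray, model: PCAModel, n_components: int = 2) -> np.ndarray:
    """Project a single conformation (full topology coordinates) into PC space."""
    x = coords[model.atom_indices].reshape(-1)
    return (x - model.mean) @ model.eigenvectors[:, :n_components]
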