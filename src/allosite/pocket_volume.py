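"""Grid-based free-volume estimation of the agonist site.

The region of interest (ROI) is a sphere (default radius 10 A) centred on
the geometric centre of the site residues' heavy atoms.  A cubic grid spans
the ROI bounding box; a cell is free when its centre lies inside the sphere
and farther than the van der Waals radius of every nearby heavy atom.  The
free volume is the number of free cells times the cell volume.  By default
the ROI is re-centred on the site every frame, so the estimate tracks the
pocket as the receptor breathes; a fixed centre can be supplied instead.

Ligand atoms, when present, occlude the grid, so an agonist-bound condition
yields the smallest volumes.

A Monte-Carlo rejection-sampling estimator is provided as an independent
cross-check of the grid method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .structure_io import ResidueSelection, Structure, Trajectory

__all__ = [
    "RegionOfInterest",
    "VolumeSeries",
    "VDW_RADII",
    "site_roi",
    "frame_volume",
    "volume_series",
    "monte_carlo_volume",
    "kde_distribution",
]

#: Bondi-style van der Waals radii in Angstrom; unknown elements fall back to carbon.
VDW_RADII: dict[str, float] = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80}
_DEFAULT_RADIUS = 1.70


@dataclass(frozen=True)
class RegionOfInterest:
    center: np.ndarray  # (3,) Angstrom
    radius: float  # Angstrom

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValueError("ROI radius must be positive")


@dataclass
class VolumeSeries:
    values: np.ndarray  # per-frame free volume, A^3
    condition_label: str
    grid_spacing: float

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)


def site_roi(
    structure: Structure | np.ndarray,
    selection: ResidueSelection,
    radius: float = 10.0,
    topology: Structure | None = None,
) -> RegionOfInterest:
    """Sphere centred on the unweighted mean of the site's heavy-atom coordinates.

    ``structure`` may be a :class:`Structure` or a raw coordinate array (in
    which case ``topology`` supplies the annotations).
    """
    if len(selection) == 0:
        raise ValueError("empty selection")
    if isinstance(structure, Structure):
        coords, top = structure.coords, structure
    else:
        if topology is None:
            raise ValueError("raw coordinates require a topology")
        coords, top = np.asarray(structure, dtype=float), topology
    idx = top.select(selection=selection, heavy_only=True)
    if idx.size == 0:
        raise ValueError("selection resolves to no heavy atoms")
    return RegionOfInterest(coords[idx].mean(axis=0), radius)


def _atom_radii(topology: Structure, radii: dict[str, float] | None) -> np.ndarray:
    table = dict(VDW_RADII)
    if radii:
        table.update({k.upper(): v for k, v in radii.items()})
    return np.array([table.get(el, _DEFAULT_RADIUS) for el in topology.elements])


def _free_mask(
    points: np.ndarray,
    atom_coords: np.ndarray,
    atom_radii: np.ndarray,
) -> np.ndarray:
    """True for probe points farther than each atom's vdW radius from every atom."""
    free = np.ones(points.shape[0], dtype=bool)
    if atom_coords.shape[0] == 0:
        return free
    for r in np.unique(atom_radii):
        tree = cKDTree(atom_coords[atom_radii == r])
        dist, _ = tree.query(points, k=1, distance_upper_bound=r)
        free &= ~(dist <= r)
    return free


def frame_volume(
    coords: np.ndarray,
    topology: Structure,
    roi: RegionOfInterest,
    grid_spacing: float = 0.5,
    radii: dict[str, float] | None = None,
) -> float:
    """Free volume (A^3) of the ROI in one frame.

    Occluding atoms are all heavy atoms of the frame, protein and ligand
    alike; hydrogens are ignored.
    """
    if grid_spacing <= 0:
        raise ValueError("grid spacing must be positive")
    r = roi.radius
    n_cells = int(np.ceil(2.0 * r / grid_spacing))
    offsets = (np.arange(n_cells) + 0.5) * grid_spacing - r
    gx, gy, gz = np.meshgrid(offsets, offsets, offsets, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    points = points[(points ** 2).sum(axis=1) <= r * r]
    points = points + roi.center

    heavy = topology.heavy_mask
    atom_coords = np.asarray(coords, dtype=float)[heavy]
    atom_radii = _atom_radii(topology, radii)[heavy]
    # Only atoms able to reach the ROI matter.
    reach = np.linalg.norm(atom_coords - roi.center, axis=1) <= r + atom_radii
    free = _free_mask(points, atom_coords[reach], atom_radii[reach])
    return float(free.sum()) * grid_spacing ** 3


def volume_series(
    traj: Trajectory,
    selection: ResidueSelection,
    grid_spacing: float = 0.5,
    radii: dict[str, float] | None = None,
    roi_radius: float = 10.0,
    fixed_center: np.ndarray | None = None,
) -> VolumeSeries:
    """Per-frame free volume; the ROI is re-centred on the site each frame
    unless ``fixed_center`` is given."""
    values = np.empty(traj.n_frames)
    for i in range(traj.n_frames):
        if fixed_center is None:
            roi = site_roi(traj.coords[i], selection, roi_radius, topology=traj.topology)
        else:
            roi = RegionOfInterest(fixed_center, roi_radius)
        values[i] = frame_volume(traj.coords[i], traj.topology, roi,
                                 grid_spacing, radii)
    return VolumeSeries(values, traj.condition_label, grid_spacing)


def monte_carlo_volume(
    coords: np.ndarray,
    topology: Structure,
    roi: RegionOfInterest,
    n_samples: int = 1_000_000,
    radii: dict[str, float] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Independent rejection-sampling estimate of the ROI free volume.

    Uniform points are drawn in the ROI sphere and classified free/occupied
    by direct distance computation (no grid, no tree).  Returns the estimate
    and its standard error, both in A^3.
    """
    rng = rng or np.random.default_rng()
    # Uniform points in a ball via normalised Gaussians and a cubic-root radius
    directions = rng.normal(size=(n_samples, 3))
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    radii_sample = roi.radius * rng.random(n_samples) ** (1.0 / 3.0)
    points = roi.center + directions * radii_sample[:, None]

    heavy = topology.heavy_mask
    atom_coords = np.asarray(coords, dtype=float)[heavy]
    atom_r = _atom_radii(topology, radii)[heavy]
    reach = np.linalg.norm(atom_coords - roi.center, axis=1) <= roi.radius + atom_r
    atom_coords, atom_r = atom_coords[reach], atom_r[reach]

    free = np.ones(n_samples, dtype=bool)
    chunk = 100_000
    for start in range(0, n_samples, chunk):
        pts = points[start:start + chunk]
        if atom_coords.shape[0]:
            d2 = ((pts[:, None, :] - atom_coords[None, :, :]) ** 2).sum(axis=2)
            free[start:start + chunk] = np.all(d2 > (atom_r ** 2)[None, :], axis=1)
    p = free.mean()
    ball = 4.0 / 3.0 * np.pi * roi.radius ** 3
    se = ball * np.sqrt(p * (1.0 - p) / n_samples)
    return float(ball * p), float(se)


def kde_distribution(
    series: VolumeSeries | np.ndarray,
    bw_method: str | float = "scott",
    n_grid: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian kernel density estimate of a volume distribution.

    Returns ``(grid, density)`` with the grid spanning the sample range
    extended by four bandwidths on each side; the density integrates to 1.
    """
    values = series.values if isinstance(series, VolumeSeries) else np.asarray(series, float)
    if np.unique(values).size < 2:
        raise ValueError("need at least 2 distinct values for a KDE")
    kde = gaussian_kde(values, bw_method=bw_method)
    bandwidth = np.sqrt(kde.covariance[0, 0])
    grid = np.linspace(values.min() - 4 * bandwidth, values.max() + 4 * bandwidth, n_grid)
    return grid, kde(grid)
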