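"""Distance observables, open/closed state classification and related maps.

The conformational state of the agonist site is summarised by two numbers
per frame: the perimeter of a triangle spanned by three pocket atoms (a Calpha
and two side-chain atoms across the pocket) and one Calpha-Calpha distance
between two site residues.  Fixed thresholds with strict inequalities divide
the (perimeter, distance) plane into closed, open and intermediate states:

* closed:  perimeter < 16 A  and  distance < 8 A
* open:    perimeter > 21 A  and  distance > 13 A
* otherwise intermediate (boundary values included).

The module also provides distance-volume correlation scans over all site
residue pairs, trajectory-averaged Calpha distance matrices and their
differences, contact frequencies for user-supplied residue pairs, and 2-D
densities for state maps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .pocket_volume import VolumeSeries
from .structure_io import ResidueSelection, Trajectory

__all__ = [
    "StateThresholds",
    "DistanceSeries",
    "StateSeries",
    "ca_distance",
    "sidechain_min_distance",
    "triangle_perimeter",
    "classify_state",
    "state_series",
    "correlate_distance_volume",
    "mean_ca_distance_matrix",
    "difference_distance_matrix",
    "contact_frequency",
    "density2d",
]

ResidueId = tuple[str, int]


def _as_residue(res) -> ResidueId:
    """Accept ``(chain, seq)`` or a bare residue number on chain A."""
    if isinstance(res, tuple):
        return (str(res[0]), int(res[1]))
    return ("A", int(res))


@dataclass(frozen=True)
class StateThresholds:
    """Strict-inequality thresholds, in Angstrom."""

    closed_perimeter: float = 16.0
    closed_distance: float = 8.0
    open_perimeter: float = 21.0
    open_distance: float = 13.0

    def __post_init__(self):
        if not (self.closed_perimeter < self.open_perimeter
                and self.closed_distance < self.open_distance):
            raise ValueError("closed-state bounds must lie below open-state bounds")


@dataclass
class DistanceSeries:
    pair: tuple[ResidueId, ResidueId]
    mode: str  # "ca" | "sidechain_min" | "named_atoms"
    values: np.ndarray  # per-frame Angstrom

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)) or np.any(self.values <= 0):
            raise ValueError("distances must be positive and finite")


@dataclass
class StateSeries:
    labels: np.ndarray  # per-frame, in {"closed", "open", "intermediate"}
    perimeter: np.ndarray  # A
    distance: np.ndarray  # A
    thresholds: StateThresholds = field(default_factory=StateThresholds)
    condition_label: str = ""

    def fraction(self, label: str) -> float:
        return float(np.mean(self.labels == label))

    def mask(self, label: str) -> np.ndarray:
        return self.labels == label

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "frame": np.arange(self.labels.size),
            "condition": self.condition_label,
            "state": self.labels,
            "perimeter": self.perimeter,
            "distance": self.distance,
        })


# ------------------------------------------------------------------ distances

def ca_distance(traj: Trajectory, res_a, res_b) -> DistanceSeries:
    a, b = _as_residue(res_a), _as_residue(res_b)
    ia = traj.topology.atom_index(a[0], a[1], "CA")
    ib = traj.topology.atom_index(b[0], b[1], "CA")
    values = np.linalg.norm(traj.coords[:, ia] - traj.coords[:, ib], axis=1)
    return DistanceSeries((a, b), "ca", values)


def _sidechain_indices(traj: Trajectory, res: ResidueId) -> np.ndarray:
    sel = ResidueSelection((res,))
    idx = traj.topology.select(selection=sel, sidechain_only=True)
    if idx.size == 0:
        name = traj.topology.residue_name_of(*res)
        raise ValueError(f"residue {res} ({name}) has no side-chain heavy atom")
    return idx


def sidechain_min_distance(traj: Trajectory, res_a, res_b) -> DistanceSeries:
    """Per-frame minimum heavy-atom distance between two side chains.

    Backbone atoms (N, CA, C, O) are excluded; CB counts as side chain.
    Glycine has no side-chain heavy atom and raises.
    """
    a, b = _as_residue(res_a), _as_residue(res_b)
    ia = _sidechain_indices(traj, a)
    ib = _sidechain_indices(traj, b)
    pa = traj.coords[:, ia, :]  # (F, na, 3)
    pb = traj.coords[:, ib, :]
    d = np.linalg.norm(pa[:, :, None, :] - pb[:, None, :, :], axis=3)
    return DistanceSeries((a, b), "sidechain_min", d.min(axis=(1, 2)))


def triangle_perimeter(
    traj: Trajectory,
    vertex_a: tuple,
    vertex_b: tuple,
    vertex_c: tuple,
) -> np.ndarray:
    """Per-frame perimeter (A) of a triangle given as (residue, atom_name) vertices."""
    idx = []
    for res, atom_name in (vertex_a, vertex_b, vertex_c):
        chain, seq = _as_residue(res)
        idx.append(traj.topology.atom_index(chain, seq, atom_name))
    pa, pb, pc = (traj.coords[:, i] for i in idx)
    return (
        np.linalg.norm(pa - pb, axis=1)
        + np.linalg.norm(pb - pc, axis=1)
        + np.linalg.norm(pc - pa, axis=1)
    )


# --------------------------------------------------------------- state labels

def classify_state(
    perimeter,
    distance,
    thresholds: StateThresholds = StateThresholds(),
) -> np.ndarray:
    """Label frames closed/open/intermediate by strict-inequality thresholds.

    Scalar inputs yield a scalar label.
    """
    p = np.atleast_1d(np.asarray(perimeter, dtype=float))
    d = np.atleast_1d(np.asarray(distance, dtype=float))
    if not (np.all(np.isfinite(p)) and np.all(np.isfinite(d))):
        raise ValueError("non-finite classification inputs")
    labels = np.full(p.shape, "intermediate", dtype=object)
    labels[(p < thresholds.closed_perimeter) & (d < thresholds.closed_distance)] = "closed"
    labels[(p > thresholds.open_perimeter) & (d > thresholds.open_distance)] = "open"
    if np.isscalar(perimeter) or np.asarray(perimeter).ndim == 0:
        return labels[0]
    return labels


def state_series(
    traj: Trajectory,
    triangle: tuple[tuple, tuple, tuple],
    pair: tuple,
    thresholds: StateThresholds = StateThresholds(),
) -> StateSeries:
    """Classify every frame from its triangle perimeter and Calpha pair distance."""
    perim = triangle_perimeter(traj, *triangle)
    dist = ca_distance(traj, pair[0], pair[1]).values
    labels = classify_state(perim, dist, thresholds)
    return StateSeries(np.asarray(labels, dtype=object), perim, dist,
                       thresholds, traj.condition_label)


# -------------------------------------------------------------- correlations

def correlate_distance_volume(
    traj: Trajectory,
    selection: ResidueSelection,
    volume: VolumeSeries,
    modes: tuple[str, ...] = ("ca", "sidechain_min"),
) -> pd.DataFrame:
    """Pearson r between every site residue-pair distance and the pocket volume.

    Returns a table (res_i, res_j, mode, r) sorted by \\|r\\| descending.
    Pairs whose distance has zero variance, and glycine pairs in side-chain
    mode, are skipped.
    """
    v = np.asarray(volume.values, dtype=float)
    if v.size != traj.n_frames:
        raise ValueError("volume series length does not match trajectory")
    if v.size < 3:
        raise ValueError("need at least 3 frames")
    if np.std(v) == 0:
        raise ValueError("volume series has zero variance")
    rows = []
    for res_a, res_b in combinations(selection.members, 2):
        for mode in modes:
            try:
                if mode == "ca":
                    d = ca_distance(traj, res_a, res_b).values
                elif mode == "sidechain_min":
                    d = sidechain_min_distance(traj, res_a, res_b).values
                else:
                    raise ValueError(f"unknown mode {mode!r}")
            except ValueError:
                continue  # e.g. glycine in side-chain mode
            if np.std(d) == 0:
                continue
            r = float(np.corrcoef(d, v)[0, 1])
            rows.append((f"{res_a[0]}:{res_a[1]}", f"{res_b[0]}:{res_b[1]}", mode, r))
    table = pd.DataFrame(rows, columns=["res_i", "res_j", "mode", "r"])
    return table.reindex(table["r"].abs().sort_values(ascending=False).index).reset_index(drop=True)


# ----------------------------------------------------------- distance matrices

def _ca_labels_and_indices(traj: Trajectory) -> tuple[list[str], np.ndarray]:
    top = traj.topology
    idx = np.flatnonzero((top.atom_names == "CA") & ~top.hetero)
    labels = [f"{top.chain_ids[i]}:{top.residue_seqs[i]}" for i in idx]
    return labels, idx


def mean_ca_distance_matrix(traj: Trajectory) -> pd.DataFrame:
    """Trajectory-mean Calpha-Calpha distance matrix (A), labelled chain:seq."""
    labels, idx = _ca_labels_and_indices(traj)
    ca = traj.coords[:, idx, :]
    d = np.linalg.norm(ca[:, :, None, :] - ca[:, None, :, :], axis=3)
    return pd.DataFrame(d.mean(axis=0), index=labels, columns=labels)


def difference_distance_matrix(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Signed element-wise difference ``a - b`` of two mean distance matrices."""
    if list(a.index) != list(b.index) or list(a.columns) != list(b.columns):
        raise ValueError("residue sets of the two matrices do not match")
    return a - b


# ----------------------------------------------------------------- contacts

def contact_frequency(
    traj: Trajectory,
    pairs: list[tuple],
    cutoff: float = 4.5,
) -> pd.DataFrame:
    """Fraction of frames where each residue pair's closest heavy atoms are < cutoff.

    All heavy atoms of each residue count (backbone included), matching the
    consensus-contact convention.
    """
    rows = []
    for res_a, res_b in pairs:
        a, b = _as_residue(res_a), _as_residue(res_b)
        ia = traj.topology.select(selection=ResidueSelection((a,)), heavy_only=True)
        ib = traj.topology.select(selection=ResidueSelection((b,)), heavy_only=True)
        if ia.size == 0 or ib.size == 0:
            raise KeyError(f"cannot resolve pair {res_a}, {res_b}")
        pa = traj.coords[:, ia, :]
        pb = traj.coords[:, ib, :]
        dmin = np.linalg.norm(pa[:, :, None, :] - pb[:, None, :, :], axis=3).min(axis=(1, 2))
        rows.append((f"{a[0]}:{a[1]}", f"{b[0]}:{b[1]}", float(np.mean(dmin < cutoff))))
    return pd.DataFrame(rows, columns=["res_i", "res_j", "frequency"])


def load_pair_list(path) -> list[tuple[int, int]]:
    """Read residue pairs from a plain-text two-column file (``#`` comments)."""
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            a, b = line.split()[:2]
            pairs.append((int(a), int(b)))
    return pairs


# ------------------------------------------------------------------ densities

def density2d(
    x: np.ndarray,
    y: np.ndarray,
    bins: int = 50,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Normalised 2-D histogram (total mass 1); returns (mass, x_edges, y_edges)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size == 0:
        raise ValueError("series must be non-empty and of equal length")
    h, xe, ye = np.histogram2d(x, y, bins=bins)
    return h / h.sum(), xe, ye
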