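"""Protein Structure Networks: residue-interaction strengths and their contrasts.

For residues i and j, the interaction strength is

    I_ij = 100 * n_ij / sqrt(N_i * N_j)

expressed as a percentage, where n_ij counts side-chain heavy-atom pairs
strictly closer than a cutoff (default 4.5 A) and N_i, N_j are residue-type
normalization factors.  Residues separated by three or fewer positions in
the same chain are considered sequence-adjacent and skipped; inter-chain
pairs are never adjacent.  Glycine contributes no side-chain heavy atom and
hence no contacts.

Per-frame matrices are averaged over a trajectory (optionally restricted to
frames in a given conformational state) and contrasted by subtraction, the
difference ranking residue pairs by how much an interaction is strengthened
or weakened between two conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import Structure, Trajectory

__all__ = [
    "NormalizationTable",
    "InteractionMatrix",
    "frame_interaction_strengths",
    "average_psn",
    "psn_difference",
]


@dataclass(frozen=True)
class NormalizationTable:
    """Residue-type normalization values N (> 0), with an optional default."""

    values: dict[str, float]
    default: float | None = None

    def __post_init__(self):
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("normalization values must be positive")
        if self.default is not None and self.default <= 0:
            raise ValueError("default normalization must be positive")

    def __getitem__(self, residue_name: str) -> float:
        try:
            return self.values[residue_name]
        except KeyError:
            if self.default is None:
                raise KeyError(
                    f"no normalization value for residue {residue_name!r} and no default set"
                )
            return self.default

    @classmethod
    def published(cls, default: float | None = None) -> "NormalizationTable":
        """The residue-type values shipped with the package (see data file)."""
        text = resources.files("allosite.data").joinpath("psn_normalization.tsv").read_text()
        values = {}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, value = line.split("\t")
            values[name] = float(value)
        return cls(values, default)

    @classmethod
    def uniform(cls, value: float = 1.0) -> "NormalizationTable":
        """Method-independent mode: every residue type normalised by the same value."""
        return cls({}, default=value)


@dataclass
class InteractionMatrix:
    """Residue-by-residue interaction strengths (percent) with provenance."""

    residue_labels: list[str]  # "chain:seq:resname"
    values: np.ndarray  # symmetric, zero diagonal, >= 0
    condition_label: str = ""
    state_filter: str | None = None
    n_frames: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.residue_labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match residue labels")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.residue_labels,
                            columns=self.residue_labels)


def _psn_context(topology: Structure, norms: NormalizationTable):
    """Precompute side-chain indices, residue mapping and norm products."""
    protein = topology.protein_mask
    res_index = topology.residue_index
    res_ids = topology.residue_ids
    protein_res = sorted({int(res_index[i]) for i in np.flatnonzero(protein)})
    local = {g: k for k, g in enumerate(protein_res)}
    n_res = len(protein_res)

    labels, chains, seqs, norm_values = [], [], [], np.empty(n_res)
    for g in protein_res:
        chain, seq = res_ids[g]
        name = topology.residue_name_of(chain, seq)
        labels.append(f"{chain}:{seq}:{name}")
        chains.append(chain)
        seqs.append(seq)
        norm_values[local[g]] = norms[name]

    sc_idx = np.flatnonzero(topology.sidechain_mask)
    sc_res = np.array([local[int(res_index[i])] for i in sc_idx], dtype=int)
    chains = np.array(chains)
    seqs = np.array(seqs, dtype=int)
    denom = 100.0 / np.sqrt(norm_values[:, None] * norm_values[None, :])
    return labels, chains, seqs, sc_idx, sc_res, denom


def _adjacency_mask(chains: np.ndarray, seqs: np.ndarray, min_separation: int) -> np.ndarray:
    """True where a residue pair is sequence-adjacent (skip) or the diagonal."""
    same_chain = chains[:, None] == chains[None, :]
    close = np.abs(seqs[:, None] - seqs[None, :]) <= min_separation
    return same_chain & close


def frame_interaction_strengths(
    topology: Structure,
    coords: np.ndarray | None = None,
    cutoff: float = 4.5,
    norms: NormalizationTable | None = None,
    min_separation: int = 3,
    condition_label: str = "",
) -> InteractionMatrix:
    """Interaction-strength matrix of one conformation."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if min_separation < 0:
        raise ValueError("min_separation must be >= 0")
    norms = norms or NormalizationTable.published()
    labels, chains, seqs, sc_idx, sc_res, denom = _psn_context(topology, norms)
    xyz = topology.coords if coords is None else np.asarray(coords, dtype=float)
    counts = _contact_counts(xyz, sc_idx, sc_res, len(labels), cutoff)
    counts[_adjacency_mask(chains, seqs, min_separation)] = 0
    return InteractionMatrix(labels, counts * denom, condition_label, None, 1)


def _contact_counts(
    xyz: np.ndarray,
    sc_idx: np.ndarray,
    sc_res: np.ndarray,
    n_res: int,
    cutoff: float,
) -> np.ndarray:
    """n_ij: side-chain heavy-atom pairs strictly closer than the cutoff."""
    counts = np.zeros((n_res, n_res))
    if sc_idx.size == 0:
        return counts
    pts = xyz[sc_idx]
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if pairs.size:
        d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
        pairs = pairs[d < cutoff]  # strict inequality at the boundary
    for a, b in pairs:
        ra, rb = sc_res[a], sc_res[b]
        if ra == rb:
            continue
        counts[ra, rb] += 1
        counts[rb, ra] += 1
    return counts


def average_psn(
    traj: Trajectory,
    cutoff: float = 4.5,
    norms: NormalizationTable | None = None,
    min_separation: int = 3,
    frame_mask: np.ndarray | None = None,
    state_filter: str | None = None,
) -> InteractionMatrix:
    """Element-wise mean interaction-strength matrix over (a subset of) frames.

    ``frame_mask`` selects frames (boolean or index array); ``state_filter``
    is recorded as provenance only.
    """
    norms = norms or NormalizationTable.published()
    labels, chains, seqs, sc_idx, sc_res, denom = _psn_context(traj.topology, norms)
    frames = np.arange(traj.n_frames)
    if frame_mask is not None:
        frames = frames[np.asarray(frame_mask)]
    if frames.size == 0:
        raise ValueError("no frames left after filtering")
    adjacency = _adjacency_mask(chains, seqs, min_separation)
    total = np.zeros((len(labels), len(labels)))
    for f in frames:
        counts = _contact_counts(traj.coords[f], sc_idx, sc_res, len(labels), cutoff)
        total += counts
    total /= frames.size
    total[adjacency] = 0
    return InteractionMatrix(labels, total * denom, traj.condition_label,
                             state_filter, int(frames.size))


def psn_difference(
    a: InteractionMatrix,
    b: InteractionMatrix,
) -> tuple[InteractionMatrix, pd.DataFrame]:
    """Signed difference ``a - b`` plus the edge list ranked by \\|delta\\|.

    Positive entries mark interactions stronger in ``a``.  The edge list has
    columns (res_i, res_j, delta, sign) and drops exactly-zero edges.
    """
    if a.residue_labels != b.residue_labels:
        raise ValueError("residue sets of the two matrices do not match")
    diff = a.values - b.values
    out = InteractionMatrix(
        list(a.residue_labels), diff,
        condition_label=f"{a.condition_label} - {b.condition_label}",
        state_filter=a.state_filter, n_frames=min(a.n_frames, b.n_frames),
    )
    iu, ju = np.triu_indices(diff.shape[0], k=1)
    deltas = diff[iu, ju]
    nz = deltas != 0
    edges = pd.DataFrame({
        "res_i": [a.residue_labels[i] for i in iu[nz]],
        "res_j": [a.residue_labels[j] for j in ju[nz]],
        "delta": deltas[nz],
        "sign": np.sign(deltas[nz]).astype(int),
    })
    edges = edges.reindex(edges["delta"].abs().sort_values(ascending=False).index)
    return out, edges.reset_index(drop=True)
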