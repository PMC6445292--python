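"""Toy receptor trajectories with planted ground truth.

The generator emulates, at desk scale, the statistical structure of a
four-condition simulation study of a seven-helix receptor: a free receptor
that visits closed, intermediate and open pocket states; two partner-bound
conditions pinned to the closed state that share a planted rewiring of
intracellular contacts; and an agonist-bound condition whose pocket is
additionally occluded by a ligand.

The receptor is a bundle of seven ideal helices (eight residues each, real
residue names, 1-4 pseudo heavy atoms per side chain).  Two anchor
conformations share one topology:

* the *closed* anchor places three marker atoms (a Calpha and two side-chain
  tips) on a 15 A-perimeter triangle and two marker Calphas 7 A apart;
* the *open* anchor displaces one helix outward along its radial direction
  (default 7 A) and toggles the two side-chain rotamers outward (default
  3 A), which widens the triangle to ~25.7 A, the pair distance to 14 A, and
  strictly increases the pocket volume.

Frames are drawn from a two-state Markov chain with stationary open
probability ``p_open``; a configurable fraction of frames is replaced by
interpolated intermediates; isotropic Gaussian noise is added to every
coordinate.  All randomness is fixed by the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry_states import StateThresholds, classify_state
from .structure_io import ResidueSelection, Structure, Trajectory, write_trajectory, write_labels

__all__ = [
    "GeneratorSpec",
    "build_anchors",
    "simulate",
    "simulate_correlated_volume",
    "condition_specs",
    "generate_condition_suite",
    "emit_condition_suite",
    "TRIANGLE",
    "DIST_PAIR",
    "REWIRE_PAIRS",
    "MOBILE_HELIX_RESIDUES",
    "LIGAND_RESNAME",
]

# ----------------------------------------------------------------- layout
N_HELICES = 7
RES_PER_HELIX = 8
N_RESIDUES = N_HELICES * RES_PER_HELIX
RING_RADIUS = 11.0  # A, helix axes from the bundle centre
HELIX_RADIUS = 2.3  # A, Calpha helix radius
RISE = 1.5  # A per residue
TWIST = math.radians(100.0)

CHAIN = "A"
LIGAND_RESNAME = "NEC"
LIGAND_SEQ = 101

#: Mobile ("TM2-like") helix whose outward displacement opens the pocket.
MOBILE_HELIX = 1
MOBILE_HELIX_RESIDUES = tuple(
    MOBILE_HELIX * RES_PER_HELIX + k + 1 for k in range(RES_PER_HELIX)
)

#: Classification markers: triangle vertices and the Calpha distance pair.
TRIANGLE = (((CHAIN, 7), "CA"), ((CHAIN, 31), "CH2"), ((CHAIN, 39), "CD2"))
DIST_PAIR = ((CHAIN, 12), (CHAIN, 20))

#: Residue pairs whose side chains are forced into contact in "partner-bound"
#: conditions (the planted contact-rewiring pattern, intracellular side).
REWIRE_PAIRS = ((2, 49), (17, 25), (26, 34), (33, 41), (42, 50))

_U1 = np.array([math.cos(2 * math.pi / 7), math.sin(2 * math.pi / 7), 0.0])
_PAIR_CENTER = np.array([0.0, 0.0, 6.0])
_PAIR_HALF = 3.5
_T_VERTEX = np.array([5.0 / math.sqrt(3.0), 0.0, 9.0])
_W_VERTEX = np.array([-5.0 / (2.0 * math.sqrt(3.0)), 2.5, 9.0])
_H_VERTEX = np.array([-5.0 / (2.0 * math.sqrt(3.0)), -2.5, 9.0])

_SIDECHAIN_NAMES = {
    "ALA": ["CB"], "GLY": [], "SER": ["CB", "OG"], "CYS": ["CB", "SG"],
    "THR": ["CB", "OG1"], "VAL": ["CB", "CG1"], "LEU": ["CB", "CG", "CD1"],
    "ILE": ["CB", "CG1", "CD1"], "ASN": ["CB", "CG", "OD1"],
    "ASP": ["CB", "CG", "OD1"], "GLN": ["CB", "CG", "CD", "OE1"],
    "GLU": ["CB", "CG", "CD", "OE1"], "LYS": ["CB", "CG", "CD", "NZ"],
    "MET": ["CB", "CG", "SD"], "PHE": ["CB", "CG", "CZ"],
    "TYR": ["CB", "CG", "CZ", "OH"], "TRP": ["CB", "CG", "CH2"],
    "HIS": ["CB", "CG", "CD2"], "ARG": ["CB", "CG", "CD", "NH1"],
    "PRO": ["CB", "CG", "CD"],
}

_NAME_OVERRIDES = {
    7: "THR", 12: "ALA", 20: "VAL", 31: "TRP", 39: "HIS",
    8: "GLY", 56: "GLY",
    2: "LEU", 49: "LYS", 17: "PHE", 25: "MET", 26: "LEU",
    34: "GLN", 33: "ILE", 41: "LEU", 42: "LYS", 50: "GLU",
}
_PALETTE = ["LEU", "SER", "ILE", "PHE", "ASN", "VAL", "ALA", "TYR", "GLU", "LYS", "ASP", "MET"]

_SC_BOND = 1.6  # A between consecutive pseudo side-chain atoms


@dataclass(frozen=True)
class GeneratorSpec:
    """Statistical parameters of one simulated condition."""

    n_frames: int = 500
    p_open: float = 0.0  # stationary open-state probability
    persistence: float = 0.8  # Markov probability of keeping the current state
    noise_sigma: float = 0.1  # A, isotropic per-coordinate Gaussian noise
    intermediate_fraction: float = 0.0  # fraction of frames replaced by intermediates
    rewired: bool = False  # plant the partner contact-rewiring pattern
    with_ligand: bool = False  # place the pocket-occluding ligand
    helix_displacement: float = 7.0  # A, outward shift of the mobile helix (open)
    rotamer_shift: float = 3.0  # A, outward shift of the two marker rotamers (open)
    seed: int = 0
    condition: str = "condition"

    def __post_init__(self):
        if not (0.0 <= self.p_open <= 1.0):
            raise ValueError("p_open must lie in [0, 1]")
        if not (0.0 <= self.persistence < 1.0):
            raise ValueError("persistence must lie in [0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if not (0.0 <= self.intermediate_fraction <= 1.0):
            raise ValueError("intermediate_fraction must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("need at least one frame")


# ------------------------------------------------------------- construction

def _residue_name(seq: int) -> str:
    if seq in _NAME_OVERRIDES:
        return _NAME_OVERRIDES[seq]
    # A glycine-rich bottom (intracellular) layer keeps the planted
    # contact-rewiring zone free of accidental third-party contacts.
    if (seq - 1) % RES_PER_HELIX <= 2:
        return "GLY"
    return _PALETTE[(seq - 1) % len(_PALETTE)]


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def _helix_frame(seq: int) -> tuple[int, int]:
    h, k = divmod(seq - 1, RES_PER_HELIX)
    return h, k


def _generic_residue(seq: int) -> dict[str, np.ndarray]:
    """Idealised helix positions for one residue's atoms."""
    h, k = _helix_frame(seq)
    theta = 2.0 * math.pi * h / N_HELICES
    axis = RING_RADIUS * np.array([math.cos(theta), math.sin(theta), 0.0])
    # Phase anchored so residue index 5 of each helix faces the bundle centre.
    phi = (theta + math.pi - 5 * TWIST) + k * TWIST
    z = k * RISE

    def on_helix(angle: float, height: float, radius: float = HELIX_RADIUS) -> np.ndarray:
        return axis + radius * np.array([math.cos(angle), math.sin(angle), 0.0]) + np.array([0.0, 0.0, height])

    ca = on_helix(phi, z)
    atoms = {
        "N": on_helix(phi - math.radians(40.0), z - 0.5),
        "CA": ca,
        "C": on_helix(phi + math.radians(40.0), z + 0.5),
    }
    atoms["O"] = atoms["C"] + 0.6 * np.array([math.cos(phi), math.sin(phi), 0.0]) + np.array([0.0, 0.0, 0.4])
    direction = np.array([math.cos(phi), math.sin(phi), 0.0])
    for j, name in enumerate(_SIDECHAIN_NAMES[_residue_name(seq)], start=1):
        atoms[name] = ca + j * _SC_BOND * direction
    return atoms


def _chain_sidechain(ca: np.ndarray, names: list[str], anchor: np.ndarray,
                     tip: np.ndarray) -> dict[str, np.ndarray]:
    """Side chain running from the Calpha to ``anchor`` with ``tip`` branching off.

    The last two atoms are placed at ``anchor`` and ``tip``; any earlier atoms
    are spaced evenly between the Calpha and the anchor.
    """
    out: dict[str, np.ndarray] = {}
    n_bridge = len(names) - 2
    for j in range(n_bridge):
        frac = (j + 1) / (n_bridge + 1)
        out[names[j]] = ca + frac * (anchor - ca)
    out[names[-2]] = anchor
    out[names[-1]] = tip
    return out


def _tip_sidechain(ca: np.ndarray, names: list[str], tip: np.ndarray) -> dict[str, np.ndarray]:
    """Side chain whose atoms are spaced evenly from the Calpha to ``tip``."""
    out: dict[str, np.ndarray] = {}
    for j, name in enumerate(names, start=1):
        out[name] = ca + (j / len(names)) * (tip - ca)
    return out


# An elongated agonist analogue: a deep head in the pocket plus a tail that
# fills the otherwise-empty vestibule above the marker triangle.
_LIGAND_ATOMS = [
    ("C1", "C", np.array([0.0, 0.0, -0.4])),
    ("C2", "C", np.array([1.4, 0.0, 0.6])),
    ("C3", "C", np.array([-1.4, 0.0, 0.6])),
    ("C4", "C", np.array([0.0, 1.4, 0.6])),
    ("C5", "C", np.array([0.0, -1.4, 0.6])),
    ("C6", "C", np.array([0.0, 0.0, 1.6])),
    ("C7", "C", np.array([1.0, 1.0, 2.6])),
    ("C8", "C", np.array([-1.0, -1.0, 2.6])),
    ("N9", "N", np.array([0.0, 0.0, 3.0])),
    ("O10", "O", np.array([0.9, -0.9, 3.8])),
    ("O11", "O", np.array([-0.9, 0.9, 3.8])),
]
_LIGAND_CENTER = np.array([0.0, 0.0, 8.2])


def _build_structure(spec: GeneratorSpec, open_state: bool) -> Structure:
    chain_ids, seqs, res_names, atom_names, elements, coords, hetero = [], [], [], [], [], [], []

    marker_ca = {
        7: _T_VERTEX,
        12: _PAIR_CENTER + _PAIR_HALF * _U1,
        20: _PAIR_CENTER - _PAIR_HALF * _U1,
    }
    rotamer_tips = {31: _W_VERTEX.copy(), 39: _H_VERTEX.copy()}
    if open_state:
        for seq, tip in rotamer_tips.items():
            outward = np.array([tip[0], tip[1], 0.0])
            rotamer_tips[seq] = tip + spec.rotamer_shift * outward / np.linalg.norm(outward)

    rewire_geometry: dict[int, dict[str, np.ndarray]] = {}
    for seq_i, seq_j in REWIRE_PAIRS:
        ca_i = _generic_residue(seq_i)["CA"]
        ca_j = _generic_residue(seq_j)["CA"]
        if spec.rewired:
            mid = 0.5 * (ca_i + ca_j)
            direction = (ca_j - ca_i) / np.linalg.norm(ca_j - ca_i)
            perp = np.cross([0.0, 0.0, 1.0], direction)
            perp /= np.linalg.norm(perp)
            names_i = _SIDECHAIN_NAMES[_residue_name(seq_i)]
            names_j = _SIDECHAIN_NAMES[_residue_name(seq_j)]
            anchor_i = mid - 1.75 * direction
            anchor_j = mid + 1.75 * direction
            rewire_geometry[seq_i] = _chain_sidechain(ca_i, names_i, anchor_i, anchor_i + 1.5 * perp)
            rewire_geometry[seq_j] = _chain_sidechain(ca_j, names_j, anchor_j, anchor_j + 1.5 * perp)
        else:
            for seq, ca in ((seq_i, ca_i), (seq_j, ca_j)):
                outward = np.array([ca[0], ca[1], 0.0])
                outward /= np.linalg.norm(outward)
                names = _SIDECHAIN_NAMES[_residue_name(seq)]
                rewire_geometry[seq] = {
                    name: ca + j * _SC_BOND * outward for j, name in enumerate(names, start=1)
                }

    for seq in range(1, N_RESIDUES + 1):
        res_name = _residue_name(seq)
        atoms = _generic_residue(seq)
        if seq in marker_ca:
            shift = marker_ca[seq] - atoms["CA"]
            atoms = {name: pos + shift for name, pos in atoms.items()}
        if seq in rotamer_tips:
            atoms.update(_tip_sidechain(atoms["CA"], _SIDECHAIN_NAMES[res_name], rotamer_tips[seq]))
        if seq in rewire_geometry:
            atoms.update(rewire_geometry[seq])
        if open_state and seq in MOBILE_HELIX_RESIDUES:
            atoms = {name: pos + spec.helix_displacement * _U1 for name, pos in atoms.items()}
        order = ["N", "CA", "C", "O"] + _SIDECHAIN_NAMES[res_name]
        for name in order:
            chain_ids.append(CHAIN)
            seqs.append(seq)
            res_names.append(res_name)
            atom_names.append(name)
            elements.append(_element_of(name))
            coords.append(atoms[name])
            hetero.append(False)

    if spec.with_ligand:
        for name, element, offset in _LIGAND_ATOMS:
            chain_ids.append(CHAIN)
            seqs.append(LIGAND_SEQ)
            res_names.append(LIGAND_RESNAME)
            atom_names.append(name)
            elements.append(element)
            coords.append(_LIGAND_CENTER + offset)
            hetero.append(True)

    return Structure(chain_ids, seqs, res_names, atom_names, elements,
                     np.array(coords), hetero,
                     title="open anchor" if open_state else "closed anchor")


def _observables(structure: Structure) -> tuple[float, float]:
    idx = [structure.atom_index(res[0], res[1], atom) for res, atom in TRIANGLE]
    pa, pb, pc = (structure.coords[i] for i in idx)
    perimeter = (np.linalg.norm(pa - pb) + np.linalg.norm(pb - pc)
                 + np.linalg.norm(pc - pa))
    (ca_a, sa), (ca_b, sb) = DIST_PAIR
    d = np.linalg.norm(
        structure.coords[structure.atom_index(ca_a, sa, "CA")]
        - structure.coords[structure.atom_index(ca_b, sb, "CA")]
    )
    return float(perimeter), float(d)


def build_anchors(spec: GeneratorSpec) -> tuple[Structure, Structure]:
    """Closed and open anchor conformations sharing one topology.

    Raises if either anchor fails its planted state classification, which
    would indicate a construction bug or unusable displacement parameters.
    """
    closed = _build_structure(spec, open_state=False)
    opened = _build_structure(spec, open_state=True)
    thresholds = StateThresholds()
    if classify_state(*_observables(closed), thresholds) != "closed":
        raise RuntimeError("closed anchor does not classify as closed")
    if classify_state(*_observables(opened), thresholds) != "open":
        raise RuntimeError("open anchor does not classify as open")
    return closed, opened


# --------------------------------------------------------------- simulation

def _markov_states(rng: np.random.Generator, n: int, p_open: float,
                   persistence: float) -> np.ndarray:
    states = np.empty(n, dtype=bool)
    states[0] = rng.random() < p_open
    for t in range(1, n):
        if rng.random() < persistence:
            states[t] = states[t - 1]
        else:
            states[t] = rng.random() < p_open
    return states


def simulate(spec: GeneratorSpec) -> tuple[Trajectory, pd.DataFrame]:
    """Sample a trajectory from the spec's two-state model.

    Returns the trajectory and a per-frame ground-truth table with columns
    ``frame``, ``state`` (closed/open/intermediate) and ``lam`` (the
    interpolation coordinate between the anchors: 0 closed, 1 open).
    """
    rng = np.random.default_rng(spec.seed)
    closed, opened = build_anchors(spec)
    open_states = _markov_states(rng, spec.n_frames, spec.p_open, spec.persistence)
    lam = open_states.astype(float)
    labels = np.where(open_states, "open", "closed").astype(object)
    if spec.intermediate_fraction > 0:
        inter = rng.random(spec.n_frames) < spec.intermediate_fraction
        lam[inter] = rng.uniform(0.3, 0.7, size=int(inter.sum()))
        labels[inter] = "intermediate"
    delta = opened.coords - closed.coords
    coords = closed.coords[None, :, :] + lam[:, None, None] * delta[None, :, :]
    if spec.noise_sigma > 0:
        coords = coords + rng.normal(0.0, spec.noise_sigma, size=coords.shape)
    traj = Trajectory(closed, coords, spec.condition)
    truth = pd.DataFrame({"frame": np.arange(spec.n_frames), "state": labels, "lam": lam})
    return traj, truth


def simulate_correlated_volume(
    n_frames: int = 2000,
    target_r: float = 0.7,
    amplitude: float = 1.0,
    noise_sigma: float = 0.35,
    volume_scale: float = 150.0,
    base_volume: float = 2500.0,
    seed: int = 0,
):
    """A benchmark trajectory with a known distance-volume correlation.

    A latent standard-normal coordinate moves the two marker residues of
    :data:`DIST_PAIR` apart along their separation axis (total amplitude
    ``amplitude`` A per latent unit) on top of isotropic coordinate noise, and
    drives a synthetic pocket-volume series with independent Gaussian noise
    sized so that the population Pearson correlation between the planted
    pair's Calpha distance and the volume equals ``target_r`` exactly:

        r = b*c / (sqrt(b^2 + 2*sigma^2) * sqrt(c^2 + s^2))

    with b the amplitude, c the volume scale and s the volume noise solved
    for ``target_r``.  Distances of all other residue pairs couple to the
    latent coordinate at most partially, so the planted pair is also the
    top-ranked pair of a correlation scan.

    Returns ``(trajectory, volume_series, planted_pair, target_r)``.
    """
    from .pocket_volume import VolumeSeries

    if not (0.0 < target_r < 1.0):
        raise ValueError("target_r must lie in (0, 1)")
    b = amplitude
    sd_d = math.sqrt(b * b + 2.0 * noise_sigma ** 2)
    ratio = b / (target_r * sd_d)
    if ratio <= 1.0:
        raise ValueError("target_r unreachable: coordinate noise too large")
    volume_noise = volume_scale * math.sqrt(ratio * ratio - 1.0)

    rng = np.random.default_rng(seed)
    spec = GeneratorSpec(n_frames=n_frames, noise_sigma=noise_sigma, seed=seed,
                         condition="correlation_benchmark")
    closed, _ = build_anchors(spec)
    lam = rng.standard_normal(n_frames)
    coords = np.repeat(closed.coords[None, :, :], n_frames, axis=0)
    coords += rng.normal(0.0, noise_sigma, size=coords.shape)
    sel_a = ResidueSelection((DIST_PAIR[0],)).atom_indices(closed)
    sel_b = ResidueSelection((DIST_PAIR[1],)).atom_indices(closed)
    shift = 0.5 * b * lam[:, None] * _U1[None, :]
    coords[:, sel_a, :] += shift[:, None, :]
    coords[:, sel_b, :] -= shift[:, None, :]
    volumes = base_volume + volume_scale * lam + rng.normal(0.0, volume_noise, n_frames)
    traj = Trajectory(closed, coords, spec.condition)
    return traj, VolumeSeries(volumes, spec.condition, 0.0), DIST_PAIR, target_r


# ------------------------------------------------------------ condition suite

def condition_specs(n_frames: int = 300, seed: int = 20210) -> dict[str, GeneratorSpec]:
    """The four study conditions with their planted parameters.

    * ``free``: mobile pocket, p_open = 0.3, largest thermal noise.
    * ``miniG`` / ``alpha5``: pinned closed, shared contact-rewiring pattern.
    * ``miniG_agonist``: pinned closed, pocket occluded by the ligand,
      smallest thermal noise (the agonist rigidifies the site).
    """
    base = dict(n_frames=n_frames, helix_displacement=7.0, rotamer_shift=3.0)
    return {
        "free": GeneratorSpec(p_open=0.3, persistence=0.8, noise_sigma=0.15,
                              intermediate_fraction=0.10, rewired=False,
                              with_ligand=False, seed=seed + 1, condition="free", **base),
        "miniG": GeneratorSpec(p_open=0.0, persistence=0.8, noise_sigma=0.10,
                               intermediate_fraction=0.05, rewired=True,
                               with_ligand=False, seed=seed + 2, condition="miniG", **base),
        "alpha5": GeneratorSpec(p_open=0.0, persistence=0.8, noise_sigma=0.10,
                                intermediate_fraction=0.05, rewired=True,
                                with_ligand=False, seed=seed + 3, condition="alpha5", **base),
        "miniG_agonist": GeneratorSpec(p_open=0.0, persistence=0.8, noise_sigma=0.08,
                                       intermediate_fraction=0.0, rewired=False,
                                       with_ligand=True, seed=seed + 4,
                                       condition="miniG_agonist", **base),
    }


def generate_condition_suite(
    n_frames: int = 300, seed: int = 20210
) -> dict[str, tuple[Trajectory, pd.DataFrame]]:
    """Simulate all four conditions in memory."""
    return {label: simulate(spec) for label, spec in condition_specs(n_frames, seed).items()}


def emit_condition_suite(
    out_dir, n_frames: int = 300, seed: int = 20210
) -> dict[str, tuple[Path, Path]]:
    """Write the four-condition fixture suite as multi-model PDBs + truth TSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for label, (traj, truth) in generate_condition_suite(n_frames, seed).items():
        pdb_path = out_dir / f"{label}.pdb"
        truth_path = out_dir / f"{label}_truth.tsv"
        write_trajectory(traj, pdb_path)
        write_labels(truth, truth_path)
        paths[label] = (pdb_path, truth_path)
    return paths


def reference_complex(seed: int = 0) -> Structure:
    """Closed, ligand-bound conformation used to define the binding site."""
    spec = GeneratorSpec(with_ligand=True, seed=seed)
    closed, _ = build_anchors(spec)
    return closed
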