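"""Structures, trajectories and the tabular I/O conventions shared by all modules.

Coordinates are in Angstrom throughout.  Residues are identified by
``(chain_id, residue_seq)`` with the numbering taken verbatim from the source
file.  Multi-model PDB is the canonical interchange format for trajectories;
DCD/XTC with a PDB topology are accepted as optional conveniences when
``mdtraj`` is importable.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as _bts
import biotite.structure.io.pdb as _btpdb

__all__ = [
    "Atom",
    "Structure",
    "Trajectory",
    "ResidueSelection",
    "read_structure",
    "read_trajectory",
    "write_structure",
    "write_trajectory",
    "concatenate",
    "split_by_condition",
    "write_matrix",
    "read_matrix",
    "write_labels",
    "read_labels",
    "AMINO_ACIDS",
    "BACKBONE_ATOMS",
]

#: Three-letter codes treated as protein residues.
AMINO_ACIDS = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)

#: Backbone heavy-atom names; everything else heavy is "side chain".
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT"})


@dataclass(frozen=True)
class Atom:
    """A single atom record (PDB naming conventions, Angstrom coordinates)."""

    chain_id: str
    residue_seq: int
    residue_name: str
    atom_name: str
    element: str
    position: tuple[float, float, float]


class Structure:
    """One conformation: parallel per-atom annotation arrays plus coordinates.

    Atoms belonging to one residue must form a contiguous run, and
    ``(chain_id, residue_seq, atom_name)`` must be unique.
    """

    def __init__(
        self,
        chain_ids: Sequence[str],
        residue_seqs: Sequence[int],
        residue_names: Sequence[str],
        atom_names: Sequence[str],
        elements: Sequence[str],
        coords: np.ndarray,
        hetero: Sequence[bool] | None = None,
        title: str = "",
    ):
        self.chain_ids = np.asarray(chain_ids, dtype="U4")
        self.residue_seqs = np.asarray(residue_seqs, dtype=int)
        self.residue_names = np.asarray(residue_names, dtype="U4")
        self.atom_names = np.asarray(atom_names, dtype="U6")
        self.elements = np.char.upper(np.asarray(elements, dtype="U2"))
        self.coords = np.asarray(coords, dtype=float).reshape(-1, 3)
        n = self.coords.shape[0]
        if n == 0:
            raise ValueError("structure contains no atoms")
        if hetero is None:
            hetero = ~np.isin(self.residue_names, list(AMINO_ACIDS))
        self.hetero = np.asarray(hetero, dtype=bool)
        self.title = title
        for arr in (self.chain_ids, self.residue_seqs, self.residue_names,
                    self.atom_names, self.elements, self.hetero):
            if arr.shape[0] != n:
                raise ValueError("annotation array length does not match atom count")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        if np.any(self.atom_names == ""):
            raise ValueError("empty atom name")
        keys = list(zip(self.chain_ids, self.residue_seqs, self.atom_names))
        if len(set(keys)) != n:
            raise ValueError("duplicate (chain, residue, atom_name) key")

    # ------------------------------------------------------------------ basics
    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @cached_property
    def atoms(self) -> list[Atom]:
        return [
            Atom(c, int(s), rn, an, el, tuple(xyz))
            for c, s, rn, an, el, xyz in zip(
                self.chain_ids, self.residue_seqs, self.residue_names,
                self.atom_names, self.elements, self.coords
            )
        ]

    @cached_property
    def residue_ids(self) -> list[tuple[str, int]]:
        """Unique ``(chain, residue_seq)`` in order of first appearance."""
        out, seen = [], set()
        for c, s in zip(self.chain_ids, self.residue_seqs):
            key = (str(c), int(s))
            if key not in seen:
                seen.add(key)
                out.append(key)
        return out

    @cached_property
    def residue_index(self) -> np.ndarray:
        """Per-atom index into :attr:`residue_ids`."""
        lookup = {key: i for i, key in enumerate(self.residue_ids)}
        return np.array(
            [lookup[(str(c), int(s))] for c, s in zip(self.chain_ids, self.residue_seqs)],
            dtype=int,
        )

    def residue_name_of(self, chain_id: str, residue_seq: int) -> str:
        idx = self._residue_first_atom[(chain_id, residue_seq)]
        return str(self.residue_names[idx])

    @cached_property
    def _residue_first_atom(self) -> dict[tuple[str, int], int]:
        out: dict[tuple[str, int], int] = {}
        for i, (c, s) in enumerate(zip(self.chain_ids, self.residue_seqs)):
            out.setdefault((str(c), int(s)), i)
        return out

    # --------------------------------------------------------------- selection
    @cached_property
    def heavy_mask(self) -> np.ndarray:
        return ~np.isin(self.elements, ["H", "D"])

    @cached_property
    def backbone_mask(self) -> np.ndarray:
        return np.isin(self.atom_names, list(BACKBONE_ATOMS)) & ~self.hetero

    @cached_property
    def sidechain_mask(self) -> np.ndarray:
        return self.heavy_mask & ~self.backbone_mask & ~self.hetero

    @cached_property
    def protein_mask(self) -> np.ndarray:
        return np.isin(self.residue_names, list(AMINO_ACIDS)) & ~self.hetero

    def atom_index(self, chain_id: str, residue_seq: int, atom_name: str) -> int:
        hits = np.flatnonzero(
            (self.chain_ids == chain_id)
            & (self.residue_seqs == residue_seq)
            & (self.atom_names == atom_name)
        )
        if hits.size != 1:
            raise KeyError(f"atom {chain_id}:{residue_seq}:{atom_name} not found")
        return int(hits[0])

    def select(
        self,
        selection: "ResidueSelection | None" = None,
        heavy_only: bool = False,
        backbone_only: bool = False,
        sidechain_only: bool = False,
        atom_names: Iterable[str] | None = None,
    ) -> np.ndarray:
        """Atom indices matching the given filters, in structure order."""
        mask = np.ones(self.n_atoms, dtype=bool)
        if heavy_only:
            mask &= self.heavy_mask
        if backbone_only:
            mask &= self.backbone_mask
        if sidechain_only:
            mask &= self.sidechain_mask
        if atom_names is not None:
            mask &= np.isin(self.atom_names, list(atom_names))
        if selection is not None:
            selection.validate(self)
            keys = set(selection.members)
            in_sel = np.array(
                [(str(c), int(s)) in keys for c, s in zip(self.chain_ids, self.residue_seqs)]
            )
            mask &= in_sel
        return np.flatnonzero(mask)

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(
            self.chain_ids, self.residue_seqs, self.residue_names,
            self.atom_names, self.elements, coords, self.hetero, self.title,
        )

    def subset(self, indices: np.ndarray) -> "Structure":
        """A new structure containing only the given atoms (in structure order)."""
        idx = np.sort(np.asarray(indices, dtype=int))
        return Structure(
            self.chain_ids[idx], self.residue_seqs[idx], self.residue_names[idx],
            self.atom_names[idx], self.elements[idx], self.coords[idx],
            self.hetero[idx], self.title,
        )

    def same_topology(self, other: "Structure") -> bool:
        return (
            self.n_atoms == other.n_atoms
            and np.array_equal(self.chain_ids, other.chain_ids)
            and np.array_equal(self.residue_seqs, other.residue_seqs)
            and np.array_equal(self.atom_names, other.atom_names)
        )


@dataclass
class Trajectory:
    """An ordered frame stack sharing one topology.

    ``provenance`` keeps, for every frame, the condition label and frame index
    it originated from, so concatenated "super trajectories" can be split back
    into their sources exactly.
    """

    topology: Structure
    coords: np.ndarray  # (n_frames, n_atoms, 3) in Angstrom
    condition_label: str = ""
    provenance: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.coords.shape[1] != self.topology.n_atoms:
            raise ValueError(
                f"frame atom count {self.coords.shape[1]} does not match "
                f"topology atom count {self.topology.n_atoms}"
            )
        if not self.provenance:
            self.provenance = [(self.condition_label, i) for i in range(self.n_frames)]
        if len(self.provenance) != self.n_frames:
            raise ValueError("provenance length must equal frame count")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.coords[i]

    def frame_structure(self, i: int) -> Structure:
        return self.topology.with_coords(self.coords[i])

    def with_coords(self, coords: np.ndarray) -> "Trajectory":
        return Trajectory(self.topology, coords, self.condition_label,
                          list(self.provenance))

    def subset(self, indices: np.ndarray) -> "Trajectory":
        """Restrict every frame to the given atoms (e.g. the receptor only)."""
        idx = np.sort(np.asarray(indices, dtype=int))
        return Trajectory(self.topology.subset(idx), self.coords[:, idx, :],
                          self.condition_label, list(self.provenance))


@dataclass(frozen=True)
class ResidueSelection:
    """Ordered, duplicate-free set of ``(chain_id, residue_seq)`` identifiers."""

    members: tuple[tuple[str, int], ...]

    def __post_init__(self):
        object.__setattr__(
            self, "members", tuple((str(c), int(s)) for c, s in self.members)
        )
        if len(set(self.members)) != len(self.members):
            raise ValueError("duplicate residues in selection")

    @classmethod
    def from_seqs(cls, seqs: Iterable[int], chain_id: str = "A") -> "ResidueSelection":
        return cls(tuple((chain_id, int(s)) for s in seqs))

    @classmethod
    def all_protein(cls, structure: Structure) -> "ResidueSelection":
        mask = structure.protein_mask
        members, seen = [], set()
        for c, s in zip(structure.chain_ids[mask], structure.residue_seqs[mask]):
            key = (str(c), int(s))
            if key not in seen:
                seen.add(key)
                members.append(key)
        return cls(tuple(members))

    def __len__(self) -> int:
        return len(self.members)

    def __iter__(self):
        return iter(self.members)

    def __contains__(self, key) -> bool:
        return tuple(key) in set(self.members)

    def validate(self, structure: Structure) -> None:
        present = set(zip(map(str, structure.chain_ids), map(int, structure.residue_seqs)))
        missing = [m for m in self.members if m not in present]
        if missing:
            raise KeyError(f"selection residues not present in topology: {missing[:5]}")

    def atom_indices(self, structure: Structure, **kwargs) -> np.ndarray:
        return structure.select(selection=self, **kwargs)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# chain\tresidue_seq\n")
            for c, s in self.members:
                fh.write(f"{c}\t{s}\n")

    @classmethod
    def from_file(cls, path) -> "ResidueSelection":
        members = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            c, s = line.split()
            members.append((c, int(s)))
        return cls(tuple(members))


# ---------------------------------------------------------------------- PDB IO

def _structure_from_atom_array(arr: "_bts.AtomArray", title: str = "") -> Structure:
    elements = arr.element
    if np.all(elements == ""):
        # Fall back to the PDB convention of element-leading atom names
        elements = np.array([a.lstrip(string.digits)[:1] for a in arr.atom_name])
    return Structure(
        chain_ids=arr.chain_id,
        residue_seqs=arr.res_id,
        residue_names=arr.res_name,
        atom_names=arr.atom_name,
        elements=elements,
        coords=arr.coord,
        hetero=arr.hetero,
        title=title,
    )


def _atom_array_from_structure(structure: Structure) -> "_bts.AtomArray":
    arr = _bts.AtomArray(structure.n_atoms)
    arr.chain_id = structure.chain_ids
    arr.res_id = structure.residue_seqs
    arr.res_name = structure.residue_names
    arr.atom_name = structure.atom_names
    arr.element = structure.elements
    arr.hetero = structure.hetero
    arr.coord = np.asarray(structure.coords, dtype=np.float32)
    return arr


def read_structure(path) -> Structure:
    """Read a PDB file; with multiple MODELs, only the first is returned."""
    pdb_file = _btpdb.PDBFile.read(str(path))
    if pdb_file.get_model_count() < 1:
        raise ValueError(f"no coordinates in {path}")
    arr = pdb_file.get_structure(model=1)
    if arr.array_length() == 0:
        raise ValueError(f"no atoms in {path}")
    return _structure_from_atom_array(arr, title=Path(path).stem)


def read_trajectory(topology_path, traj_path=None, condition_label: str = "") -> Trajectory:
    """Read a trajectory.

    A multi-model PDB is treated as one frame per MODEL.  If ``traj_path``
    names a DCD/XTC file, it is read through :mod:`mdtraj` against the PDB
    topology.
    """
    topology = read_structure(topology_path)
    if traj_path is None:
        pdb_file = _btpdb.PDBFile.read(str(topology_path))
        stack = pdb_file.get_structure(model=None)
        coords = np.asarray(stack.coord, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        return Trajectory(topology, coords, condition_label)
    suffix = Path(traj_path).suffix.lower()
    if suffix == ".pdb":
        pdb_file = _btpdb.PDBFile.read(str(traj_path))
        stack = pdb_file.get_structure(model=None)
        coords = np.asarray(stack.coord, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
    elif suffix in (".dcd", ".xtc"):
        try:
            import mdtraj
        except ImportError as exc:  # pragma: no cover
            raise ImportError("reading DCD/XTC requires the optional mdtraj dependency") from exc
        t = mdtraj.load(str(traj_path), top=str(topology_path))
        coords = np.asarray(t.xyz, dtype=float) * 10.0  # nm -> Angstrom
    else:
        raise ValueError(f"unsupported trajectory format: {suffix}")
    if coords.shape[1] != topology.n_atoms:
        raise ValueError(
            f"trajectory atom count {coords.shape[1]} does not match topology "
            f"atom count {topology.n_atoms}"
        )
    return Trajectory(topology, coords, condition_label)


def write_structure(structure: Structure, path) -> None:
    pdb_file = _btpdb.PDBFile()
    pdb_file.set_structure(_atom_array_from_structure(structure))
    pdb_file.write(str(path))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write all frames as a multi-model PDB."""
    arr = _atom_array_from_structure(traj.topology)
    stack = _bts.stack([arr] * traj.n_frames)
    stack.coord = np.asarray(traj.coords, dtype=np.float32)
    pdb_file = _btpdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb_file.write(str(path))


# ------------------------------------------------------------- concatenation

def concatenate(trajectories: Sequence[Trajectory], condition_label: str = "concatenated") -> Trajectory:
    """Concatenate trajectories sharing one topology, keeping provenance."""
    if not trajectories:
        raise ValueError("nothing to concatenate")
    top = trajectories[0].topology
    for t in trajectories[1:]:
        if not top.same_topology(t.topology):
            raise ValueError("topology mismatch between trajectories")
    coords = np.concatenate([t.coords for t in trajectories], axis=0)
    provenance = [p for t in trajectories for p in t.provenance]
    return Trajectory(top, coords, condition_label, provenance)


def split_by_condition(traj: Trajectory) -> dict[str, Trajectory]:
    """Inverse of :func:`concatenate`: regroup frames by provenance label."""
    order: list[str] = []
    groups: dict[str, list[int]] = {}
    for i, (label, _) in enumerate(traj.provenance):
        if label not in groups:
            groups[label] = []
            order.append(label)
        groups[label].append(i)
    return {
        label: Trajectory(
            traj.topology,
            traj.coords[groups[label]],
            label,
            [traj.provenance[i] for i in groups[label]],
        )
        for label in order
    }


# ------------------------------------------------------------------ table IO

def write_matrix(matrix: pd.DataFrame, path) -> None:
    """Write a labelled square table as TSV (header row and index column)."""
    if not isinstance(matrix, pd.DataFrame):
        raise TypeError("write_matrix expects a labelled pandas DataFrame")
    matrix.to_csv(path, sep="\t")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_labels(series: pd.DataFrame, path) -> None:
    """Write a per-frame label/value table as TSV."""
    series.to_csv(path, sep="\t", index=False)


def read_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
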