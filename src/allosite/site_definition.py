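"""Definition of the agonist-binding-site residue set from a ligand-bound complex.

A protein residue belongs to the site when at least one of its heavy atoms
lies strictly within a cutoff (default 4.5 A) of any heavy atom of the bound
ligand.  Hydrogens are ignored on both sides, because crystallographic inputs
typically lack them.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import ResidueSelection, Structure

__all__ = ["define_binding_site"]


def define_binding_site(
    complex_structure: Structure,
    ligand_resname: str,
    cutoff: float = 4.5,
) -> ResidueSelection:
    """Protein residues with >=1 heavy atom strictly within ``cutoff`` of the ligand.

    The boundary is open: an atom pair at exactly ``cutoff`` does not qualify.
    Residues are returned ordered by (chain, residue number).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ligand_mask = (complex_structure.residue_names == ligand_resname) & complex_structure.heavy_mask
    if not ligand_mask.any():
        raise KeyError(f"ligand residue {ligand_resname!r} not present")
    protein_mask = complex_structure.protein_mask & complex_structure.heavy_mask
    protein_idx = np.flatnonzero(protein_mask)
    if protein_idx.size == 0:
        raise ValueError("no protein heavy atoms in structure")

    tree = cKDTree(complex_structure.coords[ligand_mask])
    dists, _ = tree.query(complex_structure.coords[protein_idx], k=1)
    close = protein_idx[dists < cutoff]
    if close.size == 0:
        raise ValueError(f"no protein residues within {cutoff} A of {ligand_resname}")

    members = sorted(
        {
            (str(complex_structure.chain_ids[i]), int(complex_structure.residue_seqs[i]))
            for i in close
        }
    )
    return ResidueSelection(tuple(members))
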