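"""Independent brute-force reference implementations used only by the tests.

These deliberately avoid the package's vectorised/tree-based code paths:
plain Python loops and direct formulas, so they can serve as oracles.
"""

import numpy as np

from allosite.structure_io import BACKBONE_ATOMS, AMINO_ACIDS, Structure


def brute_force_site(structure: Structure, ligand_resname: str, cutoff: float):
    """All-pairs scan for residues with a heavy atom within cutoff of the ligand."""
    atoms = structure.atoms
    ligand = [a for a in atoms if a.residue_name == ligand_resname and a.element not in ("H", "D")]
    found = set()
    for atom in atoms:
        if atom.residue_name not in AMINO_ACIDS or atom.element in ("H", "D"):
            continue
        for lig in ligand:
            d = np.linalg.norm(np.array(atom.position) - np.array(lig.position))
            if d < cutoff:
                found.add((atom.chain_id, atom.residue_seq))
                break
    return sorted(found)


def brute_force_psn(structure: Structure, coords, cutoff, norm_of, min_separation=3):
    """Quadruple-loop interaction strengths: residues x residues x atoms x atoms."""
    residues = structure.residue_ids
    res_atoms = {key: [] for key in residues}
    protein = set()
    for i, atom in enumerate(structure.atoms):
        key = (atom.chain_id, atom.residue_seq)
        if atom.residue_name in AMINO_ACIDS:
            protein.add(key)
            if atom.atom_name not in BACKBONE_ATOMS and atom.element not in ("H", "D"):
                res_atoms[key].append(i)
    protein_residues = [key for key in residues if key in protein]
    n = len(protein_residues)
    out = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            ra, rb = protein_residues[a], protein_residues[b]
            if ra[0] == rb[0] and abs(ra[1] - rb[1]) <= min_separation:
                continue
            count = 0
            for i in res_atoms[ra]:
                for j in res_atoms[rb]:
                    if np.linalg.norm(coords[i] - coords[j]) < cutoff:
                        count += 1
            name_a = structure.residue_name_of(*ra)
            name_b = structure.residue_name_of(*rb)
            strength = 100.0 * count / np.sqrt(norm_of(name_a) * norm_of(name_b))
            out[a, b] = out[b, a] = strength
    return protein_residues, out


def random_protein_frame(rng, n_residues=30, box=25.0):
    """A random compact 'protein' with 1-4 side-chain pseudo atoms per residue."""
    names_pool = ["ALA", "SER", "LEU", "LYS", "TRP", "HIS", "VAL", "GLY", "PHE", "GLU"]
    sidechains = {
        "ALA": ["CB"], "SER": ["CB", "OG"], "LEU": ["CB", "CG", "CD1"],
        "LYS": ["CB", "CG", "CD", "NZ"], "TRP": ["CB", "CG", "CH2"],
        "HIS": ["CB", "CG", "CD2"], "VAL": ["CB", "CG1"], "GLY": [],
        "PHE": ["CB", "CG", "CZ"], "GLU": ["CB", "CG", "CD"],
    }
    chain_ids, seqs, res_names, atom_names, elements, coords = [], [], [], [], [], []
    for seq in range(1, n_residues + 1):
        name = names_pool[rng.integers(len(names_pool))]
        center = rng.uniform(0, box, size=3)
        for atom in ["N", "CA", "C", "O"] + sidechains[name]:
            chain_ids.append("A")
            seqs.append(seq)
            res_names.append(name)
            atom_names.append(atom)
            elements.append(atom[0])
            coords.append(center + rng.normal(0, 1.5, size=3))
    return Structure(chain_ids, seqs, res_names, atom_names, elements, np.array(coords))
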