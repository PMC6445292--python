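import numpy as np
import pandas as pd
import pytest

from allosite import structure_io as sio
from allosite.synthetic_data import GeneratorSpec, simulate

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CH2 TRP A   2      12.760   7.059  -4.899  1.00  0.00           C
END
"""

TWO_MODEL_PDB = """\
MODEL        1
ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  CA  ALA A   1       9.000   9.000   9.000  1.00  0.00           C
ENDMDL
END
"""


def test_read_structure_preserves_atoms(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_ATOM_PDB)
    s = sio.read_structure(path)
    assert s.n_atoms == 3
    assert list(s.atom_names) == ["N", "CA", "CH2"]
    assert list(s.residue_names) == ["ALA", "ALA", "TRP"]
    np.testing.assert_allclose(s.coords[0], [11.104, 6.134, -6.504])


def test_read_structure_uses_first_model_only(tmp_path):
    path = tmp_path / "two_models.pdb"
    path.write_text(TWO_MODEL_PDB)
    s = sio.read_structure(path)
    assert s.n_atoms == 1
    np.testing.assert_allclose(s.coords[0], [0.0, 0.0, 0.0])


def test_structure_roundtrip_at_pdb_precision(tmp_path, anchors):
    closed, _ = anchors
    path = tmp_path / "closed.pdb"
    sio.write_structure(closed, path)
    back = sio.read_structure(path)
    assert back.n_atoms == closed.n_atoms
    assert list(back.atom_names) == list(closed.atom_names)
    np.testing.assert_allclose(back.coords, closed.coords, atol=1e-3)


def test_trajectory_roundtrip(tmp_path):
    traj, _ = simulate(GeneratorSpec(n_frames=10, noise_sigma=0.1, seed=4, condition="x"))
    path = tmp_path / "traj.pdb"
    sio.write_trajectory(traj, path)
    back = sio.read_trajectory(path, condition_label="x")
    assert back.n_frames == 10
    np.testing.assert_allclose(back.coords[0], traj.coords[0], atol=1e-3)
    np.testing.assert_allclose(back.coords[-1], traj.coords[-1], atol=1e-3)


def test_multi_model_read_counts_models(tmp_path):
    path = tmp_path / "five.pdb"
    traj, _ = simulate(GeneratorSpec(n_frames=5, seed=0))
    sio.write_trajectory(traj, path)
    assert sio.read_trajectory(path).n_frames == 5


def test_atom_count_mismatch_raises(tmp_path):
    top = tmp_path / "top.pdb"
    top.write_text(THREE_ATOM_PDB)
    frames = tmp_path / "frames.pdb"
    frames.write_text(TWO_MODEL_PDB)  # one atom per frame, topology has three
    with pytest.raises(ValueError, match="atom count"):
        sio.read_trajectory(top, frames)


def test_concatenate_and_split_are_inverse():
    trajs = [
        simulate(GeneratorSpec(n_frames=7, seed=s, condition=f"cond{s}"))[0]
        for s in range(4)
    ]
    merged = sio.concatenate(trajs)
    assert merged.n_frames == 28
    assert merged.provenance[0] == ("cond0", 0)
    assert merged.provenance[-1] == ("cond3", 6)
    split = sio.split_by_condition(merged)
    assert list(split) == [f"cond{s}" for s in range(4)]
    for original, recovered in zip(trajs, split.values()):
        np.testing.assert_array_equal(original.coords, recovered.coords)


def test_concatenate_single_input_is_identity():
    traj, _ = simulate(GeneratorSpec(n_frames=5, seed=1, condition="only"))
    merged = sio.concatenate([traj])
    np.testing.assert_array_equal(merged.coords, traj.coords)
    assert merged.provenance == traj.provenance


def test_concatenate_topology_mismatch_raises():
    a, _ = simulate(GeneratorSpec(n_frames=2, seed=0))
    b, _ = simulate(GeneratorSpec(n_frames=2, seed=0, with_ligand=True))
    with pytest.raises(ValueError, match="[Tt]opology"):
        sio.concatenate([a, b])


def test_matrix_tsv_roundtrip(tmp_path):
    m = pd.DataFrame([[0.0, 1.5], [1.5, 0.0]], index=["A:1", "A:2"], columns=["A:1", "A:2"])
    path = tmp_path / "m.tsv"
    sio.write_matrix(m, path)
    assert len(path.read_text().strip().splitlines()) == 3
    back = sio.read_matrix(path)
    pd.testing.assert_frame_equal(back, m)


def test_labels_tsv_roundtrip(tmp_path):
    table = pd.DataFrame({"frame": [0, 1], "state": ["open", "closed"]})
    path = tmp_path / "labels.tsv"
    sio.write_labels(table, path)
    pd.testing.assert_frame_equal(sio.read_labels(path), table)


def test_structure_invariants():
    with pytest.raises(ValueError, match="duplicate"):
        sio.Structure(["A", "A"], [1, 1], ["ALA"] * 2, ["CA", "CA"],
                      ["C", "C"], np.zeros((2, 3)))
    with pytest.raises(ValueError, match="no atoms"):
        sio.Structure([], [], [], [], [], np.zeros((0, 3)))


def test_residue_selection_contract(anchors):
    closed, _ = anchors
    with pytest.raises(ValueError, match="duplicate"):
        sio.ResidueSelection((("A", 1), ("A", 1)))
    sel = sio.ResidueSelection.from_seqs([12, 20])
    sel.validate(closed)
    missing = sio.ResidueSelection.from_seqs([999])
    with pytest.raises(KeyError):
        missing.validate(closed)


def test_residue_selection_file_roundtrip(tmp_path):
    sel = sio.ResidueSelection((("A", 7), ("B", 31)))
    path = tmp_path / "sel.txt"
    sel.to_file(path)
    assert sio.ResidueSelection.from_file(path) == sel


def test_subset_restricts_to_protein():
    traj, _ = simulate(GeneratorSpec(n_frames=3, seed=2, with_ligand=True))
    receptor = traj.subset(np.flatnonzero(~traj.topology.hetero))
    assert receptor.topology.n_atoms < traj.topology.n_atoms
    assert not receptor.topology.hetero.any()
    assert receptor.n_frames == 3
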