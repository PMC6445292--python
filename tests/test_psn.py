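import numpy as np
import pytest

from allosite import psn
from allosite.structure_io import Structure, Trajectory
from allosite.synthetic_data import GeneratorSpec, simulate
from oracles import brute_force_psn, random_protein_frame


def _two_residue_structure(seq_b=10, chain_b="A", n_contacts=4):
    """Two 2-atom side chains with a controllable number of close atom pairs."""
    data = [
        ("A", 1, "ALA", "N", [0, 0, -1]), ("A", 1, "ALA", "CA", [0, 0, 0]),
        ("A", 1, "ALA", "C", [0, 0, 1]), ("A", 1, "ALA", "O", [0, 0, 2]),
        ("A", 1, "ALA", "CB", [1.0, 0, 0]),
        (chain_b, seq_b, "ALA", "N", [3, 0, -1]), (chain_b, seq_b, "ALA", "CA", [3.0, 0, 0]),
        (chain_b, seq_b, "ALA", "C", [3, 0, 1]), (chain_b, seq_b, "ALA", "O", [3, 0, 2]),
        (chain_b, seq_b, "ALA", "CB", [2.0, 0, 0]),
    ]
    # For n_contacts=4 add an extra side-chain atom per residue nearby
    if n_contacts == 4:
        data.insert(5, ("A", 1, "ALA", "CB2", [1.0, 1.0, 0]))
        data.append((chain_b, seq_b, "ALA", "CB2", [2.0, 1.0, 0]))
    return Structure(
        [d[0] for d in data], [d[1] for d in data], [d[2] for d in data],
        [d[3] for d in data], ["C" if d[3][0] == "C" else d[3][0] for d in data],
        np.array([d[4] for d in data], dtype=float),
    )


def test_analytic_case_n4_norm4_gives_100():
    s = _two_residue_structure(n_contacts=4)
    norms = psn.NormalizationTable.uniform(4.0)
    matrix = psn.frame_interaction_strengths(s, norms=norms)
    assert matrix.values[0, 1] == pytest.approx(100.0)
    assert matrix.values[1, 0] == pytest.approx(100.0)


def test_no_contact_gives_zero():
    s = _two_residue_structure(n_contacts=1)
    shifted = s.with_coords(s.coords + np.where(
        (s.residue_seqs == 10)[:, None], np.array([50.0, 0, 0]), 0.0))
    matrix = psn.frame_interaction_strengths(shifted, norms=psn.NormalizationTable.uniform())
    assert matrix.values[0, 1] == 0.0


def test_sequence_adjacency_skip_rule():
    """Contacting residues 3 apart in sequence are skipped; 4 apart are not."""
    close = _two_residue_structure(seq_b=4, n_contacts=1)
    m3 = psn.frame_interaction_strengths(close, norms=psn.NormalizationTable.uniform())
    assert m3.values[0, 1] == 0.0
    far = _two_residue_structure(seq_b=5, n_contacts=1)
    m4 = psn.frame_interaction_strengths(far, norms=psn.NormalizationTable.uniform())
    assert m4.values[0, 1] > 0.0
    # inter-chain pairs are never sequence-adjacent
    other_chain = _two_residue_structure(seq_b=2, chain_b="B", n_contacts=1)
    mb = psn.frame_interaction_strengths(other_chain, norms=psn.NormalizationTable.uniform())
    assert mb.values[0, 1] > 0.0


def test_matches_brute_force_oracle_on_random_frames(rng):
    norms = psn.NormalizationTable.published(default=60.0)
    for _ in range(5):
        s = random_protein_frame(rng, n_residues=25)
        matrix = psn.frame_interaction_strengths(s, norms=norms)
        _, reference = brute_force_psn(s, s.coords, 4.5, lambda name: norms[name])
        np.testing.assert_allclose(matrix.values, reference, atol=1e-9)
        np.testing.assert_allclose(matrix.values, matrix.values.T, atol=0)
        np.testing.assert_allclose(np.diag(matrix.values), 0.0)


def test_normalization_scale_covariance(rng):
    s = random_protein_frame(rng, n_residues=15)
    base = psn.frame_interaction_strengths(s, norms=psn.NormalizationTable.uniform(1.0))
    doubled = psn.frame_interaction_strengths(s, norms=psn.NormalizationTable.uniform(2.0))
    np.testing.assert_allclose(doubled.values, base.values / 2.0, atol=1e-12)


def test_monotone_in_cutoff(rng):
    s = random_protein_frame(rng, n_residues=15)
    norms = psn.NormalizationTable.uniform()
    small = psn.frame_interaction_strengths(s, cutoff=3.5, norms=norms)
    large = psn.frame_interaction_strengths(s, cutoff=5.5, norms=norms)
    assert np.all(large.values >= small.values - 1e-12)


def test_unknown_residue_requires_default():
    s = _two_residue_structure(n_contacts=1)
    with pytest.raises(KeyError, match="no normalization"):
        psn.frame_interaction_strengths(s, norms=psn.NormalizationTable({"TRP": 106.7}))


def test_average_psn_contracts():
    traj, _ = simulate(GeneratorSpec(n_frames=6, noise_sigma=0.0, seed=0))
    single = psn.frame_interaction_strengths(traj.topology, traj.coords[0])
    averaged = psn.average_psn(traj)
    np.testing.assert_allclose(averaged.values, single.values, atol=1e-12)
    assert averaged.n_frames == 6

    half = psn.average_psn(traj, frame_mask=np.arange(6) < 3)
    assert half.n_frames == 3
    with pytest.raises(ValueError, match="no frames"):
        psn.average_psn(traj, frame_mask=np.zeros(6, dtype=bool))


def test_state_conditioned_averages_differ_as_planted():
    """Open-state frames lose the closed-state rotamer contacts."""
    spec = GeneratorSpec(n_frames=60, p_open=0.5, persistence=0.0,
                         noise_sigma=0.05, seed=3)
    traj, truth = simulate(spec)
    closed_avg = psn.average_psn(traj, frame_mask=(truth["state"] == "closed").to_numpy(),
                                 state_filter="closed")
    open_avg = psn.average_psn(traj, frame_mask=(truth["state"] == "open").to_numpy(),
                               state_filter="open")
    assert closed_avg.state_filter == "closed"
    diff, edges = psn.psn_difference(closed_avg, open_avg)
    assert np.abs(diff.values).max() > 0


def test_psn_difference_contracts(rng):
    s = random_protein_frame(rng, n_residues=12)
    m = psn.frame_interaction_strengths(s, norms=psn.NormalizationTable.uniform())
    zero, edges = psn.psn_difference(m, m)
    assert np.abs(zero.values).max() == 0.0
    assert edges.empty

    perturbed = s.with_coords(s.coords + rng.normal(0, 1.0, size=s.coords.shape))
    m2 = psn.frame_interaction_strengths(perturbed, norms=psn.NormalizationTable.uniform())
    ab, _ = psn.psn_difference(m, m2)
    ba, _ = psn.psn_difference(m2, m)
    np.testing.assert_allclose(ab.values, -ba.values, atol=1e-12)


def test_planted_rewired_edges_rank_top(small_suite):
    """The five strengthened contacts dominate the difference network."""
    from allosite.geometry_states import state_series
    from allosite.synthetic_data import DIST_PAIR, REWIRE_PAIRS, TRIANGLE

    free, _ = small_suite["free"]
    minig, _ = small_suite["miniG"]
    closed_mask = state_series(free, TRIANGLE, DIST_PAIR).mask("closed")
    free_closed = psn.average_psn(free, frame_mask=closed_mask, state_filter="closed")
    minig_avg = psn.average_psn(minig)
    _, edges = psn.psn_difference(minig_avg, free_closed)
    top5 = {
        tuple(sorted((int(r.res_i.split(":")[1]), int(r.res_j.split(":")[1]))))
        for r in edges.head(5).itertuples()
    }
    assert top5 == {tuple(sorted(p)) for p in REWIRE_PAIRS}
    assert (edges.head(5)["sign"] > 0).all()  # stronger in the partner-bound condition


def test_glycine_interacts_with_nothing():
    traj, _ = simulate(GeneratorSpec(n_frames=1, noise_sigma=0.0, seed=0))
    matrix = psn.frame_interaction_strengths(traj.topology, traj.coords[0])
    gly_rows = [i for i, label in enumerate(matrix.residue_labels)
                if label.endswith("GLY")]
    assert len(gly_rows) > 0
    assert np.abs(matrix.values[gly_rows]).max() == 0.0
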