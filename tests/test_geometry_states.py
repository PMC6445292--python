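import numpy as np
import pytest

from allosite import geometry_states as gs
from allosite.pocket_volume import VolumeSeries
from allosite.structure_io import Structure, Trajectory
from allosite.synthetic_data import (
    DIST_PAIR,
    TRIANGLE,
    GeneratorSpec,
    build_anchors,
    simulate,
    simulate_correlated_volume,
)


def _toy_pair_structure():
    """Two residues with three side-chain atoms each, plus one glycine."""
    data = [
        ("A", 1, "LEU", "N", [0, 0, -1]), ("A", 1, "LEU", "CA", [0, 0, 0]),
        ("A", 1, "LEU", "C", [0, 0, 1]), ("A", 1, "LEU", "O", [0, 0, 2]),
        ("A", 1, "LEU", "CB", [1.0, 0, 0]), ("A", 1, "LEU", "CG", [2.0, 0.5, 0]),
        ("A", 1, "LEU", "CD1", [3.0, 0, 0]),
        ("A", 2, "LEU", "N", [3, 4, -1]), ("A", 2, "LEU", "CA", [3.0, 4.0, 0.0]),
        ("A", 2, "LEU", "C", [3, 4, 1]), ("A", 2, "LEU", "O", [3, 4, 2]),
        ("A", 2, "LEU", "CB", [4.0, 4.0, 0]), ("A", 2, "LEU", "CG", [5.0, 3.5, 0]),
        ("A", 2, "LEU", "CD1", [6.0, 4.0, 0]),
        ("A", 3, "GLY", "N", [9, 9, -1]), ("A", 3, "GLY", "CA", [9, 9, 0]),
        ("A", 3, "GLY", "C", [9, 9, 1]), ("A", 3, "GLY", "O", [9, 9, 2]),
    ]
    return Structure(
        [d[0] for d in data], [d[1] for d in data], [d[2] for d in data],
        [d[3] for d in data], [d[3][0] for d in data],
        np.array([d[4] for d in data], dtype=float),
    )


@pytest.fixture()
def toy_traj():
    s = _toy_pair_structure()
    return Trajectory(s, s.coords[None], "toy")


def test_ca_distance_and_symmetry(toy_traj):
    d = gs.ca_distance(toy_traj, 1, 2)
    assert d.values[0] == pytest.approx(5.0)
    assert gs.ca_distance(toy_traj, 2, 1).values[0] == pytest.approx(d.values[0])


def test_sidechain_min_matches_brute_force(toy_traj):
    d = gs.sidechain_min_distance(toy_traj, 1, 2)
    s = toy_traj.topology
    a = [i for i in range(s.n_atoms) if s.residue_seqs[i] == 1 and s.sidechain_mask[i]]
    b = [i for i in range(s.n_atoms) if s.residue_seqs[i] == 2 and s.sidechain_mask[i]]
    brute = min(np.linalg.norm(s.coords[i] - s.coords[j]) for i in a for j in b)
    assert d.values[0] == pytest.approx(brute, abs=1e-12)


def test_glycine_has_no_sidechain(toy_traj):
    with pytest.raises(ValueError, match="GLY"):
        gs.sidechain_min_distance(toy_traj, 1, 3)


def test_triangle_perimeter_geometry():
    def perimeter_of(points):
        data = []
        names = ["CA", "CH2", "CD2"]
        resnames = ["THR", "TRP", "HIS"]
        for i, p in enumerate(points):
            data.append(("A", i + 1, resnames[i], names[i], p))
        s = Structure([d[0] for d in data], [d[1] for d in data],
                      [d[2] for d in data], [d[3] for d in data],
                      ["C"] * 3, np.array([d[4] for d in data], dtype=float))
        traj = Trajectory(s, s.coords[None], "t")
        return gs.triangle_perimeter(traj, ((("A", 1)), "CA"), (("A", 2), "CH2"),
                                     (("A", 3), "CD2"))[0]

    side = 5.0
    equilateral = [[0, 0, 0], [side, 0, 0], [side / 2, side * np.sqrt(3) / 2, 0]]
    assert perimeter_of(equilateral) == pytest.approx(15.0)
    collinear = [[0, 0, 0], [2, 0, 0], [7, 0, 0]]
    assert perimeter_of(collinear) == pytest.approx(2 * 7.0)


def test_triangle_matches_hand_sum(anchors):
    closed, _ = anchors
    traj = Trajectory(closed, closed.coords[None], "x")
    perim = gs.triangle_perimeter(traj, *TRIANGLE)[0]
    pts = [closed.coords[closed.atom_index(res[0], res[1], atom)] for res, atom in TRIANGLE]
    hand = sum(np.linalg.norm(pts[i] - pts[(i + 1) % 3]) for i in range(3))
    assert perim == pytest.approx(hand, abs=1e-9)


@pytest.mark.parametrize("perimeter,distance,expected", [
    (15.0, 7.0, "closed"),
    (22.0, 14.0, "open"),
    (16.0, 7.0, "intermediate"),  # boundary falls to intermediate
    (21.0, 13.0, "intermediate"),
    (15.0, 14.0, "intermediate"),
])
def test_classification_rules(perimeter, distance, expected):
    assert gs.classify_state(perimeter, distance) == expected


def test_classification_partitions_frames():
    rng = np.random.default_rng(0)
    p = rng.uniform(12, 26, 500)
    d = rng.uniform(5, 16, 500)
    labels = gs.classify_state(p, d)
    counts = {s: int((labels == s).sum()) for s in ("closed", "open", "intermediate")}
    assert sum(counts.values()) == 500


def test_state_recovery_on_planted_trajectory():
    spec = GeneratorSpec(n_frames=2000, p_open=0.3, persistence=0.8,
                         noise_sigma=0.1, intermediate_fraction=0.1, seed=21)
    traj, truth = simulate(spec)
    series = gs.state_series(traj, TRIANGLE, DIST_PAIR)
    agreement = np.mean(series.labels == truth["state"].to_numpy())
    assert agreement >= 0.99
    assert abs(series.fraction("open") - np.mean(truth["state"] == "open")) <= 0.03


def test_noiseless_anchors_classified_exactly():
    spec = GeneratorSpec(seed=0)
    closed, opened = build_anchors(spec)
    traj = Trajectory(closed, np.stack([closed.coords, opened.coords]), "x")
    series = gs.state_series(traj, TRIANGLE, DIST_PAIR)
    assert list(series.labels) == ["closed", "open"]


def test_correlation_trivial_and_affine_invariance(toy_traj, rng):
    n = 50
    s = _toy_pair_structure()
    coords = np.repeat(s.coords[None], n, axis=0)
    coords[:, 8, 0] += rng.normal(0, 0.5, n)  # CA of residue 2 moves along x
    traj = Trajectory(s, coords, "t")
    d = gs.ca_distance(traj, 1, 2).values
    from allosite.structure_io import ResidueSelection
    sel = ResidueSelection.from_seqs([1, 2])

    exact = VolumeSeries(2.0 * d + 1.0, "v", 0.5)
    table = gs.correlate_distance_volume(traj, sel, exact, modes=("ca",))
    assert table.iloc[0]["r"] == pytest.approx(1.0, abs=1e-12)

    negated = VolumeSeries(-d, "v", 0.5)
    table2 = gs.correlate_distance_volume(traj, sel, negated, modes=("ca",))
    assert table2.iloc[0]["r"] == pytest.approx(-1.0, abs=1e-12)

    rescaled = VolumeSeries(5.0 * (2.0 * d + 1.0) - 40.0, "v", 0.5)
    table3 = gs.correlate_distance_volume(traj, sel, rescaled, modes=("ca",))
    assert table3.iloc[0]["r"] == pytest.approx(table.iloc[0]["r"], abs=1e-12)


def test_planted_correlation_recovered(site_selection):
    traj, volume, pair, target = simulate_correlated_volume(n_frames=2000, seed=17)
    table = gs.correlate_distance_volume(traj, site_selection, volume)
    top = table.iloc[0]
    assert {top["res_i"], top["res_j"]} == {f"{c}:{s}" for c, s in pair}
    planted = table[(table["res_i"] == "A:12") & (table["res_j"] == "A:20")
                    & (table["mode"] == "ca")]["r"].iloc[0]
    assert abs(planted - target) <= 0.05


def test_difference_distance_matrix(anchors):
    closed, opened = anchors
    static = Trajectory(closed, closed.coords[None], "a")
    moved = Trajectory(closed, opened.coords[None], "b")
    m_closed = gs.mean_ca_distance_matrix(static)
    m_open = gs.mean_ca_distance_matrix(moved)
    # basic matrix structure
    np.testing.assert_allclose(m_closed.values, m_closed.values.T, atol=1e-12)
    np.testing.assert_allclose(np.diag(m_closed.values), 0.0, atol=1e-12)
    # identical inputs give the zero matrix
    zero = gs.difference_distance_matrix(m_closed, m_closed)
    assert np.abs(zero.values).max() == 0.0
    # the displaced helix block carries the largest changes
    diff = gs.difference_distance_matrix(m_open, m_closed)
    mobile = [f"A:{seq}" for seq in range(9, 17)]
    static = [label for label in diff.index if label not in mobile]
    i, j = np.unravel_index(np.abs(diff.values).argmax(), diff.shape)
    assert diff.index[i] in mobile or diff.columns[j] in mobile
    assert (
        diff.loc[mobile, static].abs().values.mean()
        > 10 * diff.loc[static, static].abs().values.mean()
    )


def test_contact_frequency_cases(rng):
    s = _toy_pair_structure()
    n = 1000
    coords = np.repeat(s.coords[None], n, axis=0)
    # plant a 40% contact: shift residue 2 away in 60% of frames
    apart = rng.random(n) > 0.4
    coords[apart, 7:14, :] += np.array([20.0, 0.0, 0.0])
    traj = Trajectory(s, coords, "t")
    freq = gs.contact_frequency(traj, [(1, 2)], cutoff=4.5)
    planted = 1.0 - apart.mean()
    assert abs(freq["frequency"].iloc[0] - planted) <= 0.04

    near = Trajectory(s, s.coords[None], "t")
    assert gs.contact_frequency(near, [(1, 2)])["frequency"].iloc[0] == 1.0
    far = Trajectory(s, (s.coords + 0)[None], "t")
    assert gs.contact_frequency(far, [(1, 3)])["frequency"].iloc[0] == 0.0


def test_density2d_mass_and_modes(rng):
    x = np.zeros(10)
    y = np.zeros(10)
    h, _, _ = gs.density2d(x, y, bins=5)
    assert h.max() == pytest.approx(1.0)
    x2 = np.concatenate([rng.normal(0, 0.2, 2000), rng.normal(5, 0.2, 2000)])
    y2 = np.concatenate([rng.normal(0, 0.2, 2000), rng.normal(5, 0.2, 2000)])
    h2, xe, ye = gs.density2d(x2, y2, bins=30)
    assert h2.sum() == pytest.approx(1.0, abs=1e-6)
    peaks = np.argwhere(h2 > 0.5 * h2.max())
    centers_x = (xe[:-1] + xe[1:]) / 2
    assert centers_x[peaks[:, 0]].min() < 1.0 and centers_x[peaks[:, 0]].max() > 4.0
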