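import numpy as np
import pytest

from tcrmsm import featurize as feat
from tcrmsm import synthetic
from tcrmsm.featurize import CollectiveVariable, collective_variable, dihedral
from tcrmsm.structure_io import RegionSelection, Trajectory

from conftest import random_rotation


def oracle_dihedral(p1, p2, p3, p4):
    """Independent vector-algebra oracle: atan2 of cross/dot products.

    Sign fixed so that the +90° quadrant matches a right-handed rotation of
    the p4 half-plane when sighting down p2→p3 (IUPAC).
    """
    p1, p2, p3, p4 = map(np.asarray, (p1, p2, p3, p4))
    u = p1 - p2
    axis = p3 - p2
    v = p4 - p3
    axis = axis / np.linalg.norm(axis)
    u_perp = u - np.dot(u, axis) * axis
    v_perp = v - np.dot(v, axis) * axis
    cosang = np.dot(u_perp, v_perp) / (np.linalg.norm(u_perp) * np.linalg.norm(v_perp))
    sign = np.sign(np.dot(np.cross(u_perp, v_perp), axis))
    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
    return sign * ang if sign != 0 else ang


@pytest.mark.parametrize("p4,expected", [
    ((1, 1, 0), 0.0),      # cis planar
    ((-1, 1, 0), 180.0),   # trans planar
    ((0, 1, 1), -90.0),    # perpendicular, sign fixed by the oracle
])
def test_dihedral_reference_geometries(p4, expected):
    got = dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), p4)
    assert got == pytest.approx(expected)
    assert oracle_dihedral((1, 0, 0), (0, 0, 0), (0, 1, 0), p4) == pytest.approx(expected)


def test_dihedral_matches_independent_oracle():
    rng = np.random.default_rng(3)
    for _ in range(50):
        pts = rng.uniform(-5, 5, (4, 3))
        try:
            got = dihedral(*pts)
        except ValueError:
            continue
        assert got == pytest.approx(oracle_dihedral(*pts), abs=1e-9)


def test_dihedral_rigid_motion_invariance_and_mirror_antisymmetry():
    rng = np.random.default_rng(7)
    for _ in range(25):
        pts = rng.uniform(-5, 5, (4, 3))
        base = dihedral(*pts)
        rot = random_rotation(rng)
        shift = rng.uniform(-10, 10, 3)
        moved = pts @ rot.T + shift
        assert dihedral(*moved) == pytest.approx(base, abs=1e-9)
        mirrored = pts * np.array([1.0, 1.0, -1.0])
        flipped = dihedral(*mirrored)
        if abs(base) < 179.999:  # ±180 is the same angle
            assert flipped == pytest.approx(-base, abs=1e-9)


def test_dihedral_degenerate_geometry_raises():
    with pytest.raises(ValueError, match="degenerate"):
        dihedral((0, 0, 0), (0, 0, 0), (1, 0, 0), (1, 1, 0))
    with pytest.raises(ValueError, match="degenerate"):
        dihedral((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


def _loop_trajectory(psi_rows, phi=-60.0):
    """Single-chain backbone trajectory with prescribed per-frame ψ."""
    psi = np.asarray(psi_rows, float)
    n_frames, n_psi = psi.shape
    n_res = n_psi + 1
    full_psi = np.concatenate([psi, np.zeros((n_frames, 1))], axis=1)
    coords = synthetic.build_backbone(np.full((n_frames, n_res), phi), full_psi)
    top = synthetic._backbone_topology({"A": n_res}, coords=coords[0])
    return Trajectory(top, coords, 1.0), RegionSelection("CDR3_alpha", "A", (1, n_res))


def test_constant_trajectory_gives_zero_variance_features():
    traj, sel = _loop_trajectory([[30.0, -100.0, 75.0]] * 6)
    fm = feat.psi_phi_features(traj, [sel], angles=("psi", "phi"))
    assert np.allclose(fm.values.std(axis=0), 0.0)


def test_psi_90_maps_to_sin_one_cos_zero():
    traj, sel = _loop_trajectory([[90.0, 10.0]])
    fm = feat.psi_phi_features(traj, [sel], angles=("psi",))
    i = fm.labels.index("A:1:psi:sin")
    assert fm.values[0, i] == pytest.approx(1.0, abs=1e-12)
    assert fm.values[0, i + 1] == pytest.approx(0.0, abs=1e-12)


def test_embedded_features_satisfy_unit_circle(two_state_hmm):
    spec, traj, _ = two_state_hmm
    fm = feat.psi_phi_features(traj, spec.selections(), angles=("psi", "phi"))
    norms = fm.values[:, 0::2] ** 2 + fm.values[:, 1::2] ** 2
    assert np.abs(norms - 1.0).max() < 1e-9


def test_hmm_decoded_angles_track_generating_state(two_state_hmm):
    spec, traj, hidden = two_state_hmm
    vals, labels = feat.backbone_dihedrals(traj, spec.selections()[:1], ("psi",))
    means = spec.psi_means["A"][hidden]          # (n_frames, 5)
    delta = np.abs((vals - means + 180.0) % 360.0 - 180.0)
    assert (delta < 3 * spec.emission_sigma).mean() > 0.99


def test_collective_variable_cases():
    traj, sel = _loop_trajectory([[90.0, 30.0, -45.0]] * 5)
    fm = feat.psi_phi_features(traj, [sel], angles=("psi",))
    zero = collective_variable(fm, CollectiveVariable(np.zeros(3), np.zeros(3)))
    assert np.allclose(zero, 0.0)
    single, sel1 = _loop_trajectory([[90.0]])
    fm1 = feat.psi_phi_features(single, [sel1], angles=("psi",))
    s = collective_variable(fm1, CollectiveVariable([1.0], [0.0]))
    assert s[0] == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError, match="weights"):
        collective_variable(fm, CollectiveVariable([1.0], [1.0]))


def test_collective_variable_matches_brute_force_sum():
    rng = np.random.default_rng(9)
    psi = rng.uniform(-179, 179, (5, 3))
    traj, sel = _loop_trajectory(psi)
    fm = feat.psi_phi_features(traj, [sel], angles=("psi",))
    a, b = rng.standard_normal(3), rng.standard_normal(3)
    got = collective_variable(fm, CollectiveVariable(a, b))
    rad = np.radians(psi)
    expected = (np.sin(rad) * a).sum(axis=1) + (np.cos(rad) * b).sum(axis=1)
    np.testing.assert_allclose(got, expected, atol=1e-9)


def test_center_of_mass_cases(two_state_hmm):
    _, traj, _ = two_state_hmm
    top = traj.topology
    # two equal masses at ±1
    coords = np.array([[1.0, 0, 0], [-1.0, 0, 0]])
    from tcrmsm.structure_io import Structure
    s2 = Structure(["CA", "CA"], np.array([1, 2]), ["A", "A"], ["C", "C"],
                   np.array([12.0, 12.0]), coords)
    com = feat.center_of_mass(coords, s2, np.array([0, 1]))
    np.testing.assert_allclose(com, 0.0, atol=1e-12)
    # masses 1 and 3 at x = 0 and 4
    s3 = Structure(["CA", "CA"], np.array([1, 2]), ["A", "A"], ["C", "C"],
                   np.array([1.0, 3.0]), np.array([[0.0, 0, 0], [4.0, 0, 0]]))
    com = feat.center_of_mass(s3.coordinates, s3, np.array([0, 1]))
    assert com[0] == pytest.approx(3.0)
    # unweighted mean differs
    com_u = feat.center_of_mass(s3.coordinates, s3, np.array([0, 1]),
                                mass_weighted=False)
    assert com_u[0] == pytest.approx(2.0)
    # loop-accumulation oracle on a random selection
    rng = np.random.default_rng(1)
    idx = rng.choice(top.n_atoms, 10, replace=False)
    got = feat.center_of_mass(traj.frames[0], top, idx)
    acc = np.zeros(3)
    total = 0.0
    for i in idx:
        acc += top.masses[i] * traj.frames[0, i]
        total += top.masses[i]
    np.testing.assert_allclose(got, acc / total, atol=1e-12)


@pytest.mark.parametrize("target", [-150.0, -90.0, -30.0, 30.0, 90.0, 150.0])
def test_interdomain_torsion_recovers_prescribed_target(target):
    spec = synthetic.TwoDomainSpec(targets_deg=[target], n_frames=3,
                                   loop_sigma_deg=0.0, seed=int(abs(target)))
    traj, _ = synthetic.generate_two_domain_trajectory(spec)
    r = spec.region_selections()
    series = feat.interdomain_torsion(traj, r["cdr_alpha"], r["v_alpha"],
                                      r["v_beta"], r["cdr_beta"])
    np.testing.assert_allclose(series.values, target, atol=1e-6)


def test_interdomain_torsion_rigid_motion_and_mirror():
    spec = synthetic.TwoDomainSpec(targets_deg=[60.0], n_frames=2,
                                   loop_sigma_deg=0.0, seed=4)
    traj, _ = synthetic.generate_two_domain_trajectory(spec)
    r = spec.region_selections()
    args = (r["cdr_alpha"], r["v_alpha"], r["v_beta"], r["cdr_beta"])
    rng = np.random.default_rng(0)
    rot = random_rotation(rng)
    moved = Trajectory(traj.topology, traj.frames @ rot.T + rng.uniform(-5, 5, 3),
                       traj.frame_interval)
    np.testing.assert_allclose(
        feat.interdomain_torsion(moved, *args).values, 60.0, atol=1e-9)
    mirrored = Trajectory(traj.topology, traj.frames * np.array([1.0, 1.0, -1.0]),
                          traj.frame_interval)
    np.testing.assert_allclose(
        feat.interdomain_torsion(mirrored, *args).values, -60.0, atol=1e-9)


def test_interdomain_torsion_rejects_overlapping_selections():
    spec = synthetic.TwoDomainSpec(targets_deg=[60.0], n_frames=1, seed=0)
    traj, _ = synthetic.generate_two_domain_trajectory(spec)
    r = spec.region_selections()
    with pytest.raises(ValueError, match="overlap"):
        feat.interdomain_torsion(traj, r["cdr_alpha"], r["cdr_alpha"],
                                 r["v_beta"], r["cdr_beta"])
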