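"""Superposition, RMSF, distances, H-bonds, dipoles, cosine correlation."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aquaflux import (
    Frame,
    Trajectory,
    atom_axis_series,
    dipole_moment,
    donor_pairs,
    hbond_series,
    make_three_site_waters,
    min_distance_series,
    rmsf,
    superpose,
    vector_correlation,
    vector_correlation_series,
)
from conftest import make_topology


# ---------------------------------------------------------------------------
# superposition

def _random_pair(n=20, seed=0, noise=0.4):
    rng = np.random.default_rng(seed)
    ref = rng.uniform(-8, 8, (n, 3))
    from scipy.spatial.transform import Rotation

    R = Rotation.random(random_state=rng).as_matrix()
    mob = ref @ R.T + rng.uniform(-5, 5, 3) + noise * rng.standard_normal((n, 3))
    return mob, ref


def quaternion_grid_rmsd(mob, ref, seed=1):
    """Brute-force minimum RMSD over rotations by quaternion grid refinement."""
    rng = np.random.default_rng(seed)
    a = ref - ref.mean(axis=0)
    b = mob - mob.mean(axis=0)

    def rmsd_of(quats):
        # quats (m, 4) -> rotation matrices -> rmsd per rotation
        q = quats / np.linalg.norm(quats, axis=1, keepdims=True)
        w, x, y, z = q.T
        R = np.empty((len(q), 3, 3))
        R[:, 0, 0] = 1 - 2 * (y * y + z * z)
        R[:, 0, 1] = 2 * (x * y - z * w)
        R[:, 0, 2] = 2 * (x * z + y * w)
        R[:, 1, 0] = 2 * (x * y + z * w)
        R[:, 1, 1] = 1 - 2 * (x * x + z * z)
        R[:, 1, 2] = 2 * (y * z - x * w)
        R[:, 2, 0] = 2 * (x * z - y * w)
        R[:, 2, 1] = 2 * (y * z + x * w)
        R[:, 2, 2] = 1 - 2 * (x * x + y * y)
        moved = np.einsum("mij,nj->mni", R, b)
        return np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=2), axis=1))

    quats = rng.standard_normal((4000, 4))
    vals = rmsd_of(quats)
    best = quats[np.argmin(vals)]
    best_val = vals.min()
    scale = 0.3
    for _ in range(60):
        cand = best + scale * rng.standard_normal((200, 4))
        vals = rmsd_of(cand)
        if vals.min() < best_val:
            best_val = vals.min()
            best = cand[np.argmin(vals)]
        scale *= 0.85
    return float(best_val)


def test_superpose_identity_and_translation():
    mob, ref = _random_pair(noise=0.0)
    t, r = superpose(ref, ref)
    assert r < 1e-12
    assert np.allclose(t.rotation, np.eye(3), atol=1e-9)
    t, r = superpose(ref + np.array([3.0, 4.0, 0.0]), ref)
    assert r < 1e-9


def test_superpose_matches_quaternion_grid_oracle():
    for seed in (0, 1, 2):
        mob, ref = _random_pair(seed=seed)
        _, kabsch = superpose(mob, ref)
        oracle = quaternion_grid_rmsd(mob, ref, seed=seed + 10)
        assert oracle >= kabsch - 1e-9  # least-squares optimality
        assert abs(oracle - kabsch) < 1e-4


def test_superposition_never_increases_rmsd():
    mob, ref = _random_pair(seed=5)
    raw = float(np.sqrt(np.mean(np.sum((mob - ref) ** 2, axis=1))))
    _, fitted = superpose(mob, ref)
    assert fitted <= raw + 1e-12


def test_collinear_selection_rejected():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError, match="collinear"):
        superpose(line, line)


# ---------------------------------------------------------------------------
# RMSF

def test_rigid_trajectory_has_zero_rmsf():
    top = make_topology(10)
    base = np.random.default_rng(0).uniform(-5, 5, (10, 3))
    traj = Trajectory(top, np.tile(base, (6, 1, 1)), np.arange(6.0))
    assert np.all(rmsf(traj) < 1e-9)


def test_two_point_oscillation_rmsf_is_amplitude():
    top = make_topology(5)
    base = np.array(
        [[0.0, 0, 0], [4, 0, 0], [0, 4, 0], [0, 0, 4], [4, 4, 0]]
    )
    n = 40
    pos = np.tile(base, (n, 1, 1))
    pos[::2, 0, 0] += 1.0
    pos[1::2, 0, 0] -= 1.0
    traj = Trajectory(top, pos, np.arange(float(n)))
    # fit on the four fixed atoms so the oscillator does not drag the frame
    out = rmsf(traj, selection=None, fit_selection=np.arange(1, 5))
    assert out[0] == pytest.approx(1.0, abs=1e-9)
    assert np.all(out[1:] < 1e-9)


def test_rmsf_single_frame_errors():
    top = make_topology(4)
    traj = Trajectory(top, np.zeros((1, 4, 3)), np.zeros(1))
    with pytest.raises(ValueError, match="2 frames"):
        rmsf(traj)


# ---------------------------------------------------------------------------
# minimal distances

def _two_group_traj(pos_by_frame):
    pts = np.asarray(pos_by_frame, dtype=np.float64)
    top = make_topology(pts.shape[1])
    return Trajectory(top, pts, np.arange(float(pts.shape[0])),
                      np.array([10.0, 10.0, 10.0]))


def test_min_distance_constant_pair():
    traj = _two_group_traj([[[0, 0, 0], [2, 0, 0]]] * 3)
    out = min_distance_series(traj, np.array([0]), np.array([1]))
    assert np.allclose(out, 2.0)


def test_min_distance_minimum_image():
    traj = _two_group_traj([[[1.0, 5, 5], [9.0, 5, 5]]])
    assert min_distance_series(traj, np.array([0]), np.array([1]),
                               periodic=True)[0] == pytest.approx(2.0)
    assert min_distance_series(traj, np.array([0]), np.array([1]),
                               periodic=False)[0] == pytest.approx(8.0)


def test_min_distance_matches_brute_force_and_is_symmetric():
    rng = np.random.default_rng(4)
    pts = rng.uniform(0, 30, (3, 100, 3))
    top = make_topology(100)
    traj = Trajectory(top, pts, np.arange(3.0))
    ga, gb = np.arange(50), np.arange(50, 100)
    out = min_distance_series(traj, ga, gb)
    for k in range(3):
        brute = min(
            math.dist(pts[k, i], pts[k, j]) for i in ga for j in gb
        )
        assert out[k] == pytest.approx(brute, abs=1e-12)
    assert np.allclose(out, min_distance_series(traj, gb, ga))


def test_min_distance_excludes_identical_pairs():
    traj = _two_group_traj([[[0, 0, 0], [1, 0, 0], [5, 0, 0]]])
    # overlapping groups allowed; self-distance (atom 1) never reported
    out = min_distance_series(traj, np.array([0, 1]), np.array([1, 2]))
    assert out[0] == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# hydrogen bonds

def _dha_fixture(d_a=2.8, angle_deg=0.0):
    """Donor at origin, H on the D->A axis rotated by angle_deg."""
    acceptor = np.array([d_a, 0.0, 0.0])
    a = np.deg2rad(angle_deg)
    h = 1.0 * np.array([np.cos(a), np.sin(a), 0.0])
    pts = np.stack([np.array([0.0, 0, 0]), h, acceptor])[None]
    top = make_topology(3)
    top.element[:] = np.array(["N", "H", "O"], dtype=object)
    return Trajectory(top, pts, np.zeros(1) + np.arange(1.0))


def test_ideal_linear_hbond_counts_one():
    traj = _dha_fixture(2.8, 0.0)
    assert hbond_series(traj, [(0, 1)], np.array([2]))[0] == 1


def test_long_distance_is_no_bond():
    traj = _dha_fixture(5.0, 0.0)
    assert hbond_series(traj, [(0, 1)], np.array([2]))[0] == 0


def test_wide_angle_is_no_bond():
    traj = _dha_fixture(2.8, 45.0)
    assert hbond_series(traj, [(0, 1)], np.array([2]))[0] == 0


def test_random_triplets_match_direct_geometry():
    rng = np.random.default_rng(8)
    n = 100
    donors = rng.uniform(0, 12, (n, 3))
    hydros = donors + rng.normal(0, 0.7, (n, 3))
    accept = rng.uniform(0, 12, (n, 3))
    pts = np.concatenate([donors, hydros, accept])[None]
    top = make_topology(3 * n)
    traj = Trajectory(top, pts, np.arange(1.0))
    pairs = [(i, n + i) for i in range(n)]
    counts = hbond_series(traj, pairs, np.arange(2 * n, 3 * n))
    brute = 0
    for i in range(n):
        for j in range(n):
            da = accept[j] - donors[i]
            dh = hydros[i] - donors[i]
            dist = np.linalg.norm(da)
            cosang = dh @ da / (np.linalg.norm(dh) * dist)
            if dist <= 3.5 and np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= 30:
                brute += 1
    assert counts[0] == brute


def test_three_site_waters_have_internal_geometry_and_donor_builder_works():
    top, frame = make_three_site_waters(np.array([[0, 0, 0], [5, 0, 0.0]]), seed=2)
    pairs = donor_pairs(top, frame, "name OW")
    assert len(pairs) == 4  # two hydrogens per water
    with pytest.raises(ValueError, match="no bonded hydrogen"):
        donor_pairs(top, frame, "name HW1")  # hydrogens have no bonded H


# ---------------------------------------------------------------------------
# dipoles

def test_unit_dipole():
    top = make_topology(2)
    top.charge[:] = [1.0, -1.0]
    frame = Frame(np.array([[1.0, 0, 0], [0.0, 0, 0]]))
    mu = dipole_moment(frame, top)
    assert mu == pytest.approx([1.0, 0.0, 0.0])


def test_mirrored_charge_pairs_cancel():
    top = make_topology(4)
    top.charge[:] = [0.5, 0.5, -0.5, -0.5]  # each charge mirrored through origin
    frame = Frame(np.array([[1.0, 2, 3], [-1, -2, -3], [4, 0, 0], [-4, 0, 0]]))
    assert np.allclose(dipole_moment(frame, top), 0.0, atol=1e-12)


def test_dipole_matches_brute_force_sum():
    rng = np.random.default_rng(9)
    top = make_topology(30)
    top.charge[:] = rng.uniform(-1, 1, 30)
    top.mass[:] = rng.uniform(1, 20, 30)
    pos = rng.uniform(-10, 10, (30, 3))
    frame = Frame(pos)
    com = (top.mass[:, None] * pos).sum(0) / top.mass.sum()
    brute = sum(top.charge[i] * (pos[i] - com) for i in range(30))
    assert dipole_moment(frame, top) == pytest.approx(brute, abs=1e-12)


def test_neutral_dipole_independent_of_reference():
    rng = np.random.default_rng(10)
    top = make_topology(10)
    q = rng.uniform(-1, 1, 10)
    top.charge[:] = q - q.mean()  # exactly neutral
    pos = rng.uniform(-10, 10, (10, 3))
    mu = dipole_moment(Frame(pos), top)
    origin_ref = (top.charge[:, None] * pos).sum(0)
    assert mu == pytest.approx(origin_ref, abs=1e-10)


def test_include_extra_adds_cation():
    top = make_topology(3)
    top.charge[:] = [0.0, 0.0, 2.0]  # third atom is the cation
    top.chain[:] = np.array(["A", "A", "Z"], dtype=object)
    frame = Frame(np.array([[0.0, 0, 0], [1.0, 0, 0], [0.0, 0, 3]]))
    with_zn = dipole_moment(frame, top, "chain A", include_extra="chain Z")
    without = dipole_moment(frame, top, "chain A")
    assert not np.allclose(with_zn, without)


# ---------------------------------------------------------------------------
# cosine vector correlation

def test_cosine_correlation_cardinal_cases():
    v = np.array([1.0, 2.0, -3.0])
    assert vector_correlation(v, v) == pytest.approx(1.0)
    assert vector_correlation(v, -v) == pytest.approx(-1.0)
    assert vector_correlation([1, 0, 0], [0, 1, 0]) == pytest.approx(0.0)
    with pytest.raises(ValueError, match="zero vector"):
        vector_correlation([0, 0, 0], v)


@settings(derandomize=True, max_examples=50)
@given(
    scale=st.floats(min_value=1e-3, max_value=1e3),
    seed=st.integers(min_value=0, max_value=10_000),
)
def test_cosine_scale_invariance_and_sign_flip(scale, seed):
    rng = np.random.default_rng(seed)
    v1, v2 = rng.standard_normal(3), rng.standard_normal(3)
    c = vector_correlation(v1, v2)
    assert vector_correlation(scale * v1, v2) == pytest.approx(c, abs=1e-9)
    assert vector_correlation(-v1, v2) == pytest.approx(-c, abs=1e-9)


def test_dipole_axis_correlation_series_reproducible():
    rng = np.random.default_rng(11)
    top = make_topology(6)
    top.charge[:] = rng.uniform(-1, 1, 6)
    pts = rng.uniform(-5, 5, (8, 6, 3))
    traj = Trajectory(top, pts, np.arange(8.0))
    from aquaflux import dipole_series

    d = dipole_series(traj)
    axis = atom_axis_series(traj, np.array([0]), np.array([1]))
    c1 = vector_correlation_series(d, axis)
    c2 = vector_correlation_series(d, axis)
    assert np.array_equal(c1, c2)
    assert np.all((c1 >= -1) & (c1 <= 1))
    mean_mode = vector_correlation_series(d, axis, mode="mean_vectors")
    assert -1 <= mean_mode <= 1
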