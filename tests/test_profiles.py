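"""Density, Boltzmann inversion, averaged structures, pore profiling."""

from __future__ import annotations

import numpy as np
import pytest

from aquaflux import (
    DensityProfile,
    Frame,
    PoreCylinder,
    Trajectory,
    average_structure,
    free_energy_profile,
    kT,
    make_toy_assembly,
    max_barrier,
    perturb_trajectory,
    pore_radius_profile,
    random_rigid_transforms,
    water_density_profile,
)
from aquaflux.synthetic import ToyAssemblySpec
from conftest import make_topology


@pytest.fixture
def cyl():
    return PoreCylinder(center=np.zeros(3), radius=15.0, half_length=15.0)


def test_single_fixed_water_occupies_one_bin(cyl):
    top = make_topology(1)
    pos = np.tile(np.array([[0.0, 0.0, 0.1]]), (10, 1, 1))
    traj = Trajectory(top, pos, np.arange(10.0))
    dens = water_density_profile(traj, cyl)
    assert dens.bin_width == 0.5  # protocol default slice width
    k = np.flatnonzero(dens.counts)
    assert len(k) == 1
    assert dens.counts[k[0]] == pytest.approx(1.0)
    assert dens.bin_centers[k[0]] == pytest.approx(0.25)


def test_density_total_matches_brute_force_count(flat_sim, cyl):
    traj = flat_sim.production()
    dens = water_density_profile(traj, cyl)
    # brute force: count every in-cylinder water observation
    rel = traj.positions - cyl.center
    s = rel[:, :, 2]
    radial = np.sqrt(np.maximum(np.sum(rel**2, axis=2) - s**2, 0))
    brute = int(np.sum((np.abs(s) <= 15.0) & (radial <= 15.0)))
    assert int(round(dens.counts.sum() * dens.n_frames_used)) == brute


def test_uniform_density_passes_chi_square(flat_sim, cyl):
    # single-frame counts are multinomial across independent particles
    traj = flat_sim.production()
    z = traj.positions[-1, :, 2]
    inside = np.abs(z) <= 15.0
    counts = np.histogram(z[inside], bins=np.linspace(-15, 15, 7))[0]
    from scipy import stats as sps

    assert sps.chisquare(counts).pvalue > 0.01


def test_padded_bin_flagged():
    top = make_topology(1)
    traj = Trajectory(top, np.zeros((2, 1, 3)), np.arange(2.0))
    odd = PoreCylinder(center=np.zeros(3), radius=15.0, half_length=15.1)
    assert water_density_profile(traj, odd).padded
    assert not water_density_profile(traj, PoreCylinder(center=np.zeros(3))).padded


def _profile(counts, width=0.5):
    counts = np.asarray(counts, dtype=float)
    centers = width / 2 + width * np.arange(len(counts))
    return DensityProfile(centers, counts, width, 1)


def test_flat_density_gives_zero_free_energy():
    fep = free_energy_profile(_profile(np.full(12, 3.0)), bulk=3.0)
    assert np.allclose(fep.G, 0.0)


def test_two_kt_depletion_at_body_temperature():
    counts = np.full(12, 5.0)
    counts[6] = 5.0 * np.exp(-2.0)
    fep = free_energy_profile(_profile(counts), bulk=5.0, temperature=310.15)
    assert fep.G[6] == pytest.approx(5.157, abs=2e-3)  # 2 kT at 310.15 K
    assert fep.G[6] == pytest.approx(2 * kT(310.15), rel=1e-12)


def test_boltzmann_inversion_exact_on_analytic_density():
    rng = np.random.default_rng(0)
    U = rng.uniform(0, 8, 60)
    rho_bulk = 4.2
    counts = rho_bulk * np.exp(-U / kT())
    fep = free_energy_profile(_profile(counts), bulk=rho_bulk)
    assert np.max(np.abs(fep.G - U)) < 1e-12


def test_zero_density_bins_censored_not_clamped():
    counts = np.array([4.0, 4.0, 0.0, 4.0, 4.0, 4.0, 4.0, 4.0, 4.0, 4.0])
    fep = free_energy_profile(_profile(counts), bulk=4.0)
    assert list(fep.censored_bins) == [2]
    assert np.isnan(fep.G[2])
    # censored bin is excluded from the barrier search
    pos, height = max_barrier(fep)
    assert height == 0.0


def test_auto_bulk_uses_outermost_bins():
    counts = np.concatenate([np.full(4, 2.0), np.full(8, 9.0), np.full(4, 4.0)])
    fep = free_energy_profile(_profile(counts), bulk="auto")
    assert fep.reference_bulk_density == pytest.approx(3.0)


def test_free_energy_errors():
    with pytest.raises(ValueError, match="zero density"):
        free_energy_profile(_profile(np.zeros(8)))
    with pytest.raises(ValueError, match="bulk"):
        free_energy_profile(_profile([0.0, 0.0, 1.0, 1.0, 0.0, 0.0]), bulk="auto",
                            n_bulk_bins=1)


def test_max_barrier_matches_exhaustive_scan():
    rng = np.random.default_rng(3)
    counts = rng.uniform(0.5, 9.0, 40)
    fep = free_energy_profile(_profile(counts), bulk=4.0)
    pos, height = max_barrier(fep)
    assert height == pytest.approx(np.max(fep.G) - np.min(fep.G))
    assert pos == fep.bin_centers[int(np.argmax(fep.G))]


def test_max_barrier_invariant_to_constant_shift():
    fep = free_energy_profile(_profile([4, 5, 9, 3, 4.0]), bulk=4.0)
    _, h0 = max_barrier(fep)
    fep.G = fep.G + 7.3
    _, h1 = max_barrier(fep)
    assert h1 == pytest.approx(h0)


def test_single_peak_barrier_position():
    centers = np.arange(-14.75, 15.0, 0.5)
    G = np.zeros_like(centers)
    G[np.argmin(np.abs(centers - 8.0))] = 3.0
    from aquaflux import FreeEnergyProfile

    prof = FreeEnergyProfile(centers, G, 1.0, 310.15, np.array([], dtype=int))
    pos, height = max_barrier(prof)
    assert (pos, height) == (pytest.approx(8.25, abs=0.5), pytest.approx(3.0))


# ---------------------------------------------------------------------------
# averaged structures

def test_static_trajectory_average_is_any_frame():
    top = make_topology(5)
    base = np.random.default_rng(1).uniform(-5, 5, (5, 3))
    traj = Trajectory(top, np.tile(base, (4, 1, 1)), np.arange(4.0))
    (avg,) = average_structure(traj)
    assert np.allclose(avg.positions, base)


def test_two_frame_average_without_superposition():
    top = make_topology(3)
    a = np.array([[0.0, 0, 0], [0, 1, 0], [1, 0, 0]])
    b = a + np.array([2.0, 0, 0])
    traj = Trajectory(top, np.stack([a, b]), np.arange(2.0))
    (avg,) = average_structure(traj, superpose_frames=False)
    assert avg.positions[0] == pytest.approx([1.0, 0.0, 0.0])


def test_rigid_rotation_removed_before_averaging():
    top = make_topology(30)
    base = Frame(np.random.default_rng(2).uniform(-8, 8, (30, 3)))
    res = perturb_trajectory(top, base,
                             random_rigid_transforms(20, 25.0, 4.0, seed=3),
                             n_frames=20)
    (avg,) = average_structure(res.trajectory)
    # average superposes onto the first frame; compare after aligning back
    from aquaflux import superpose

    transform, rms = superpose(avg.positions, base.positions)
    assert rms < 1e-6


# ---------------------------------------------------------------------------
# pore radius profiling

def test_single_ring_probe_radius_is_ring_minus_vdw():
    angles = 2 * np.pi * np.arange(24) / 24
    ring = np.column_stack([5.0 * np.cos(angles), 5.0 * np.sin(angles),
                            np.zeros(24)])
    top = make_topology(24, vdw=1.5)
    cyl = PoreCylinder(center=np.zeros(3), radius=8.0, half_length=1.0)
    prof = pore_radius_profile(Frame(ring), top, cyl, step=0.5, seed=1)
    at_plane = np.argmin(np.abs(prof.axial_positions))
    assert prof.radius[at_plane] == pytest.approx(3.5, abs=0.05)


def test_hourglass_profile_matches_analytic(hourglass):
    cyl = PoreCylinder(center=np.zeros(3), radius=6.0, half_length=5.0)
    prof = pore_radius_profile(hourglass.frame, hourglass.topology, cyl, seed=4)
    expected = hourglass.analytic_radius(prof.axial_positions)
    assert np.max(np.abs(prof.radius - expected)) < 0.05
    pos, radius = prof.constriction()
    assert pos == pytest.approx(0.0, abs=0.25)
    assert radius == pytest.approx(1.2, abs=0.05)


def test_vdw_inflation_shrinks_radius_boundedly(hourglass):
    cyl = PoreCylinder(center=np.zeros(3), radius=6.0, half_length=5.0)
    prof = pore_radius_profile(hourglass.frame, hourglass.topology, cyl,
                               step=1.0, seed=5)
    delta = 0.3
    inflated = make_topology(hourglass.topology.n_atoms,
                             vdw=hourglass.spec.atom_vdw + delta)
    prof2 = pore_radius_profile(hourglass.frame, inflated, cyl, step=1.0, seed=5)
    shrink = prof.radius - prof2.radius
    assert np.all(shrink >= -1e-6)
    assert np.all(shrink <= delta + 1e-6)


def test_pore_profile_requires_enough_atoms():
    top = make_topology(3)
    with pytest.raises(ValueError, match="at least 4"):
        pore_radius_profile(Frame(np.zeros((3, 3))), top,
                            PoreCylinder(center=np.zeros(3)))
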