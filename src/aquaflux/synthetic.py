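"""Synthetic trajectories and structures with known ground truth.

Three generators emulate the statistical structure the analyses assume:

* :func:`simulate_channel_waters` — overdamped (Brownian) Langevin dynamics
  of independent point waters in a cylinder, with a known 1D potential of
  mean force U(z) along the channel axis. The stationary axial density is
  exp(-U/kT) by construction, which makes the Boltzmann-inversion
  free-energy machinery testable against exact ground truth.
* :func:`make_toy_assembly` — a multi-chain scaffold of pseudo-atom rings
  whose largest-probe-sphere pore radius profile is known analytically,
  the oracle for HOLE-style pore profiling.
* :func:`perturb_trajectory` — rigid-body motion plus isotropic Gaussian
  noise on a base structure, with the closed-form expected RMSF retained.

Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kT
from .topology import Topology
from .trajectory import Frame, Trajectory

_CHAIN_LETTERS = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


# ---------------------------------------------------------------------------
# potentials

def flat_potential(z_max: float = 20.0, spacing: float = 0.25):
    """Zero potential tabulated over [-z_max, z_max]."""
    z = np.arange(-z_max, z_max + spacing / 2, spacing)
    return z, np.zeros_like(z)


def gaussian_barrier_potential(
    height_kj_mol: float,
    width: float = 2.0,
    center: float = 0.0,
    z_max: float = 20.0,
    spacing: float = 0.25,
):
    """Single Gaussian barrier U(z) = A·exp(-(z-c)²/2w²) in kJ/mol."""
    z = np.arange(-z_max, z_max + spacing / 2, spacing)
    return z, height_kj_mol * np.exp(-((z - center) ** 2) / (2 * width**2))


# ---------------------------------------------------------------------------
# single-file channel waters

@dataclass
class ChannelSimSpec:
    """Parameters of the Brownian channel-water simulation.

    Units: Å, ps, kJ/mol, K. The potential is tabulated as
    ``(z_grid, U)`` over [-z_max, z_max]; outside the grid it is held at
    its edge values (the reservoir is flat).
    """

    n_particles: int
    potential: tuple  # (z_grid, U) in Å / kJ/mol
    diffusion_coefficient: float = 0.3  # Å²/ps, bulk-water-like
    temperature: float = DEFAULT_TEMPERATURE
    cylinder_radius: float = 4.0
    z_extent: float = 20.0  # half-length of simulated column, > pore half-length
    timestep: float = 0.2
    n_frames: int = 2
    save_interval: float = 1.0
    seed: int = 0
    burn_in_fraction: float = 0.1

    def validate(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.diffusion_coefficient <= 0:
            raise ValueError("diffusion coefficient must be > 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if self.cylinder_radius <= 0 or self.z_extent <= 0:
            raise ValueError("cylinder_radius and z_extent must be > 0")
        z, U = map(np.asarray, self.potential)
        if z.ndim != 1 or z.shape != U.shape or len(z) < 2:
            raise ValueError("potential must be a 1D (z_grid, U) table")
        if np.any(np.diff(z) <= 0):
            raise ValueError("potential z grid must be strictly increasing")
        if np.max(np.diff(z)) > 0.5 + 1e-12:
            raise ValueError(
                "potential grid coarser than the 0.5 Å analysis bin width"
            )
        substeps = self.save_interval / self.timestep
        if abs(substeps - round(substeps)) > 1e-9 or round(substeps) < 1:
            raise ValueError("save_interval must be an integer multiple of timestep")
        if not 0 <= self.burn_in_fraction < 1:
            raise ValueError("burn_in_fraction must be in [0, 1)")


@dataclass
class ChannelSimResult:
    """Trajectory plus the ground truth needed by oracle checks."""

    trajectory: Trajectory
    spec: ChannelSimSpec
    z_grid: np.ndarray
    potential: np.ndarray  # U(z) kJ/mol
    burn_in_frames: int

    @property
    def paths(self) -> np.ndarray:
        """Per-particle saved paths, shape (n_frames, n_particles, 3)."""
        return self.trajectory.positions

    def production(self) -> Trajectory:
        """Trajectory with the burn-in frames discarded."""
        if self.burn_in_frames == 0:
            return self.trajectory
        return self.trajectory.slice_frames(
            self.burn_in_frames, self.trajectory.n_frames
        )

    def stationary_probability(self, bin_edges: np.ndarray) -> np.ndarray:
        """Exact stationary probability of z falling in each bin.

        The stationary law is p(z) ∝ exp(-U(z)/kT) over the simulated
        column [-z_extent, z_extent].
        """
        kt = kT(self.spec.temperature)
        fine = np.linspace(-self.spec.z_extent, self.spec.z_extent, 20001)
        w = np.exp(-np.interp(fine, self.z_grid, self.potential) / kt)
        cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(fine))])
        cdf /= cdf[-1]
        edge_cdf = np.interp(bin_edges, fine, cdf)
        return np.diff(edge_cdf)


def _water_topology(n: int) -> Topology:
    return Topology(
        serial=np.arange(1, n + 1),
        name=np.array(["OW"] * n, dtype=object),
        element=np.array(["O"] * n, dtype=object),
        resname=np.array(["SOL"] * n, dtype=object),
        resid=np.arange(1, n + 1),
        chain=np.array(["W"] * n, dtype=object),
        mass=np.full(n, 18.0153),
        charge=np.zeros(n),
        vdw_radius=np.full(n, 1.52),
        selections={"waters": np.arange(n)},
    )


def _reflect(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Fold values back into [lo, hi] by specular reflection."""
    span = hi - lo
    v = np.mod(values - lo, 2 * span)
    v = np.where(v > span, 2 * span - v, v)
    return v + lo


def simulate_channel_waters(spec: ChannelSimSpec) -> ChannelSimResult:
    """Brownian dynamics of independent waters in a capped cylinder.

    Euler–Maruyama integration of overdamped Langevin motion: along z the
    drift is -D/kT·U'(z) with reflecting caps at ±z_extent; x,y diffuse
    freely with a reflecting wall at the cylinder radius. Initial states
    are drawn from the stationary law, and the first ``burn_in_fraction``
    of frames is flagged for discarding by the ground-truth bookkeeping.
    """
    spec.validate()
    z_grid = np.asarray(spec.potential[0], dtype=np.float64)
    U = np.asarray(spec.potential[1], dtype=np.float64)
    kt = kT(spec.temperature)
    D = spec.diffusion_coefficient
    dt = spec.timestep

    force_grid = -np.gradient(U, z_grid)  # kJ/mol/Å
    max_drift = D / kt * np.max(np.abs(force_grid)) * dt
    if max_drift > 0.5:
        raise ValueError(
            f"timestep too large: drift per step {max_drift:.3f} Å exceeds "
            "0.5 Å at the steepest potential gradient; reduce the timestep"
        )

    rng = np.random.default_rng(spec.seed)
    n = spec.n_particles

    # stationary initialisation by inverse-CDF sampling of exp(-U/kT)
    fine = np.linspace(-spec.z_extent, spec.z_extent, 20001)
    w = np.exp(-np.interp(fine, z_grid, U) / kt)
    cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(fine))])
    cdf /= cdf[-1]
    z = np.interp(rng.random(n), cdf, fine)
    r = spec.cylinder_radius * np.sqrt(rng.random(n))
    phi = 2 * np.pi * rng.random(n)
    x, y = r * np.cos(phi), r * np.sin(phi)

    substeps = round(spec.save_interval / dt)
    sigma = math.sqrt(2 * D * dt)
    mobility = D / kt

    positions = np.empty((spec.n_frames, n, 3))
    positions[0] = np.column_stack([x, y, z])
    for k in range(1, spec.n_frames):
        for _ in range(substeps):
            drift = mobility * np.interp(z, z_grid, force_grid) * dt
            z = _reflect(z + drift + sigma * rng.standard_normal(n),
                         -spec.z_extent, spec.z_extent)
            x = x + sigma * rng.standard_normal(n)
            y = y + sigma * rng.standard_normal(n)
            rad = np.hypot(x, y)
            over = rad > spec.cylinder_radius
            if np.any(over):
                folded = _reflect(rad[over], 0.0, spec.cylinder_radius)
                scale = folded / rad[over]
                x[over] *= scale
                y[over] *= scale
        positions[k] = np.column_stack([x, y, z])

    times = spec.save_interval * np.arange(spec.n_frames)
    pad = 2.0
    box = np.array(
        [2 * spec.cylinder_radius + pad, 2 * spec.cylinder_radius + pad,
         2 * spec.z_extent]
    )
    traj = Trajectory(_water_topology(n), positions, times, box)
    return ChannelSimResult(
        trajectory=traj,
        spec=spec,
        z_grid=z_grid,
        potential=U,
        burn_in_frames=int(spec.burn_in_fraction * spec.n_frames),
    )


# ---------------------------------------------------------------------------
# toy assembly with analytic pore profile

@dataclass
class ToyAssemblySpec:
    """Multi-chain ring scaffold with a known hourglass cavity.

    ``cavity_profile`` is a tabulated target pore radius r(z) in Å; rings
    of pseudo-atoms (vdW radius ``atom_vdw``) are placed at radius
    r(z) + atom_vdw so the largest on-axis probe sphere at each slice has
    exactly radius r(z). ``charge_plan`` assigns per-atom charges within
    each chain (cycled over the chain's atoms); default is neutral.
    """

    cavity_profile: tuple  # (z_grid, r_grid) in Å
    n_chains: int = 4
    atom_spacing: float = 1.0
    atom_vdw: float = 1.0
    charge_plan: tuple | None = None
    seed: int = 0

    def validate(self) -> None:
        z, r = map(np.asarray, self.cavity_profile)
        if z.ndim != 1 or z.shape != r.shape or len(z) < 2:
            raise ValueError("cavity_profile must be a 1D (z, r) table")
        if np.any(np.diff(z) <= 0):
            raise ValueError("cavity z grid must be strictly increasing")
        if np.any(r <= 0):
            raise ValueError("cavity_profile must be strictly positive")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")
        if self.atom_spacing <= 0 or self.atom_vdw <= 0:
            raise ValueError("atom_spacing and atom_vdw must be > 0")
        if np.min(r) < self.atom_vdw:
            raise ValueError(
                f"cavity radius {np.min(r):.3f} Å is narrower than the "
                f"ring-atom vdW radius {self.atom_vdw:.3f} Å"
            )


@dataclass
class ToyAssembly:
    """Constructed scaffold plus its exact analytic pore-radius profile."""

    topology: Topology
    frame: Frame
    spec: ToyAssemblySpec
    ring_z: np.ndarray
    ring_radius: np.ndarray  # atom-centre ring radii

    def analytic_radius(self, z) -> np.ndarray:
        """Exact largest-probe radius at axial position(s) z.

        Every atom of a ring is equidistant from any on-axis point, so the
        on-axis probe radius is min over rings of
        sqrt(R_k² + (z_k - z)²) - vdw, and the on-axis point is optimal
        (moving off-axis brings the probe closer to some ring atom).
        """
        z = np.atleast_1d(np.asarray(z, dtype=np.float64))
        d = np.sqrt(
            self.ring_radius[None, :] ** 2 + (self.ring_z[None, :] - z[:, None]) ** 2
        )
        out = d.min(axis=1) - self.spec.atom_vdw
        return out if out.size > 1 else float(out[0])


def make_toy_assembly(spec: ToyAssemblySpec) -> ToyAssembly:
    spec.validate()
    z_grid = np.asarray(spec.cavity_profile[0], dtype=np.float64)
    r_grid = np.asarray(spec.cavity_profile[1], dtype=np.float64)
    ring_radius = r_grid + spec.atom_vdw

    serial, name, element, resname, resid, chain, charge, xyz = (
        [], [], [], [], [], [], [], []
    )
    plan = None if spec.charge_plan is None else list(spec.charge_plan)
    sector = 2 * np.pi / spec.n_chains
    next_serial = 1
    per_chain_counter = [0] * spec.n_chains
    for k, (zk, Rk) in enumerate(zip(z_grid, ring_radius)):
        n_ring = max(spec.n_chains, math.ceil(2 * np.pi * Rk / spec.atom_spacing))
        n_ring = spec.n_chains * math.ceil(n_ring / spec.n_chains)
        angles = 2 * np.pi * (np.arange(n_ring) + 0.5) / n_ring
        for a in angles:
            c = min(int(a // sector), spec.n_chains - 1)
            serial.append(next_serial)
            next_serial += 1
            name.append("CR")
            element.append("C")
            resname.append("RNG")
            resid.append(k + 1)
            chain.append(_CHAIN_LETTERS[c])
            if plan:
                charge.append(plan[per_chain_counter[c] % len(plan)])
            else:
                charge.append(0.0)
            per_chain_counter[c] += 1
            xyz.append((Rk * np.cos(a), Rk * np.sin(a), zk))

    n = len(serial)
    top = Topology(
        serial=np.array(serial),
        name=np.array(name, dtype=object),
        element=np.array(element, dtype=object),
        resname=np.array(resname, dtype=object),
        resid=np.array(resid),
        chain=np.array(chain, dtype=object),
        mass=np.full(n, 12.011),
        charge=np.array(charge),
        vdw_radius=np.full(n, spec.atom_vdw),
    )
    span = 2 * (ring_radius.max() + spec.atom_vdw) + 4.0
    box = np.array([span, span, (z_grid[-1] - z_grid[0]) + 4.0])
    frame = Frame(np.array(xyz), box=box, time=0.0)
    return ToyAssembly(top, frame, spec, z_grid, ring_radius)


# ---------------------------------------------------------------------------
# rigid motion + noise perturbations

@dataclass
class PerturbResult:
    trajectory: Trajectory
    expected_rmsf: float  # noise_sd·sqrt(3·(1 - 1/n_frames)), per atom
    transforms: list = field(repr=False, default_factory=list)


def random_rigid_transforms(
    n_frames: int,
    max_angle_deg: float = 10.0,
    max_translation: float = 2.0,
    seed: int = 0,
) -> list:
    """Random small rotations (about random axes) and translations."""
    from scipy.spatial.transform import Rotation

    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_frames):
        axis = rng.standard_normal(3)
        axis /= np.linalg.norm(axis)
        angle = np.deg2rad(rng.uniform(-max_angle_deg, max_angle_deg))
        R = Rotation.from_rotvec(angle * axis).as_matrix()
        t = rng.uniform(-max_translation, max_translation, 3)
        out.append((R, t))
    return out


def perturb_trajectory(
    topology: Topology,
    base: Frame,
    rigid_transforms=None,
    noise_sd: float = 0.0,
    n_frames: int = 10,
    seed: int = 0,
    dt: float = 1.0,
) -> PerturbResult:
    """frame k = R_k · base + t_k + isotropic Gaussian noise.

    The expected per-atom RMSF after superposition removes the rigid part
    is noise_sd·sqrt(3·(1 - 1/n_frames)) (the mean structure absorbs 1/n
    of the noise variance per coordinate).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if rigid_transforms is None:
        eye = np.eye(3)
        zero = np.zeros(3)
        rigid_transforms = [(eye, zero)] * n_frames
    if len(rigid_transforms) != n_frames:
        raise ValueError("need one rigid transform per frame")
    rng = np.random.default_rng(seed)
    positions = np.empty((n_frames, base.n_atoms, 3))
    for k, (R, t) in enumerate(rigid_transforms):
        positions[k] = base.positions @ np.asarray(R).T + np.asarray(t)
        if noise_sd > 0:
            positions[k] += noise_sd * rng.standard_normal((base.n_atoms, 3))
    traj = Trajectory(topology, positions, dt * np.arange(n_frames), base.box)
    expected = noise_sd * math.sqrt(3.0 * (1.0 - 1.0 / n_frames))
    return PerturbResult(traj, expected, list(rigid_transforms))


# ---------------------------------------------------------------------------
# explicit 3-site water fixtures (for hydrogen-bond tests)

def make_three_site_waters(oxygen_positions: np.ndarray, seed: int = 0):
    """Explicit O-H1-H2 waters at given oxygen positions, random orientations.

    TIP3P-like geometry (O-H 0.9572 Å, H-O-H 104.52°) and charges
    (O -0.834 e, H +0.417 e). Returns (Topology, Frame).
    """
    from scipy.spatial.transform import Rotation

    oxy = np.asarray(oxygen_positions, dtype=np.float64).reshape(-1, 3)
    rng = np.random.default_rng(seed)
    r_oh = 0.9572
    half = np.deg2rad(104.52 / 2)
    h1_local = r_oh * np.array([np.sin(half), 0.0, np.cos(half)])
    h2_local = r_oh * np.array([-np.sin(half), 0.0, np.cos(half)])

    serial, name, element, resname, resid, chain, mass, charge, vdw, xyz = (
        [], [], [], [], [], [], [], [], [], []
    )
    for i, o in enumerate(oxy):
        R = Rotation.random(random_state=rng).as_matrix()
        for nm, el, q, m, rad, pos in (
            ("OW", "O", -0.834, 15.999, 1.52, o),
            ("HW1", "H", 0.417, 1.008, 1.20, o + R @ h1_local),
            ("HW2", "H", 0.417, 1.008, 1.20, o + R @ h2_local),
        ):
            serial.append(len(serial) + 1)
            name.append(nm)
            element.append(el)
            resname.append("SOL")
            resid.append(i + 1)
            chain.append("W")
            mass.append(m)
            charge.append(q)
            vdw.append(rad)
            xyz.append(pos)
    top = Topology(
        serial=np.array(serial),
        name=np.array(name, dtype=object),
        element=np.array(element, dtype=object),
        resname=np.array(resname, dtype=object),
        resid=np.array(resid),
        chain=np.array(chain, dtype=object),
        mass=np.array(mass),
        charge=np.array(charge),
        vdw_radius=np.array(vdw),
    )
    return top, Frame(np.array(xyz))
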