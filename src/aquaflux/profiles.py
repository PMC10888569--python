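"""Axial water density, free-energy and pore-radius profiles.

The free-energy profile is obtained by Boltzmann inversion of the axial
water density inside the analysis cylinder,

    G(z) = -kT · ln( rho(z) / rho_bulk ),

computed on 0.5 Å slices by default and reported in kJ/mol at 310.15 K.
Zero-density bins are censored (no finite G), never clamped to a cap.

The pore-radius profile re-implements the largest-probe-sphere algorithm:
at each axial position the probe centre is moved in the slice plane to
maximise min over atoms of (|probe - atom| - vdW_atom), by simulated
annealing seeded from the previous slice's optimum and finished with a
deterministic simplex polish.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kT
from .metrics import superpose
from .permeation import PoreCylinder
from .topology import Topology
from .trajectory import Frame, Trajectory

DEFAULT_BIN_WIDTH = 0.5
DEFAULT_BULK_BINS = 4


@dataclass
class DensityProfile:
    """Mean water count per axial bin per frame inside the cylinder."""

    bin_centers: np.ndarray
    counts: np.ndarray
    bin_width: float
    n_frames_used: int
    padded: bool = False  # last bin widened when length % bin_width != 0

    @property
    def bin_edges(self) -> np.ndarray:
        first = self.bin_centers[0] - self.bin_width / 2
        return np.concatenate(
            [[first], first + self.bin_width * np.arange(1, len(self.bin_centers) + 1)]
        )


@dataclass
class FreeEnergyProfile:
    bin_centers: np.ndarray
    G: np.ndarray  # censored bins hold NaN
    reference_bulk_density: float
    temperature: float
    censored_bins: np.ndarray
    units: str = "kJ/mol"


@dataclass
class PoreRadiusProfile:
    axial_positions: np.ndarray
    radius: np.ndarray
    probe_centers: np.ndarray  # (n_slices, 3)
    open_mask: np.ndarray = field(default=None)  # probe escaped: excluded from constriction

    def constriction(self):
        """(position, radius) of the narrowest non-open slice."""
        mask = (
            np.ones(len(self.radius), dtype=bool)
            if self.open_mask is None
            else ~self.open_mask
        )
        if not mask.any():
            raise ValueError("every slice is flagged open")
        k = int(np.flatnonzero(mask)[np.argmin(self.radius[mask])])
        return float(self.axial_positions[k]), float(self.radius[k])


# ---------------------------------------------------------------------------
# density and free energy

def water_density_profile(
    trajectory: Trajectory,
    cylinder: PoreCylinder,
    bin_width: float = DEFAULT_BIN_WIDTH,
    selection=None,
) -> DensityProfile:
    """Per-frame axial histogram of in-cylinder waters, averaged over frames."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if trajectory.n_frames == 0:
        raise ValueError("no frames")
    top = trajectory.topology
    idx = top.resolve(selection) if top is not None else np.arange(trajectory.n_atoms)
    if idx.size == 0:
        raise ValueError("empty selection")

    length = cylinder.length
    n_bins = math.ceil(length / bin_width - 1e-9)
    padded = abs(n_bins * bin_width - length) > 1e-9 * max(1.0, length)
    edges = -cylinder.half_length + bin_width * np.arange(n_bins + 1)

    s, radial = cylinder.axial_radial(trajectory.positions[:, idx, :])
    inside = (
        (np.abs(s) <= cylinder.half_length + 1e-12) & (radial <= cylinder.radius)
    )
    hist = np.histogram(s[inside], bins=edges)[0].astype(np.float64)
    counts = hist / trajectory.n_frames
    centers = (edges[:-1] + edges[1:]) / 2
    return DensityProfile(centers, counts, bin_width, trajectory.n_frames, padded)


def free_energy_profile(
    density: DensityProfile,
    bulk="auto",
    temperature: float = DEFAULT_TEMPERATURE,
    n_bulk_bins: int = DEFAULT_BULK_BINS,
    units: str = "kJ/mol",
) -> FreeEnergyProfile:
    """Boltzmann inversion G(z) = -kT·ln(rho(z)/rho_bulk).

    ``bulk="auto"`` estimates rho_bulk as the mean count over the
    outermost ``n_bulk_bins`` bins at each end of the cylinder (those
    slices sit in the vestibules). Zero-density bins are censored, not
    clamped.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    counts = np.asarray(density.counts, dtype=np.float64)
    if np.all(counts == 0):
        raise ValueError("all bins have zero density")
    if bulk == "auto":
        m = min(n_bulk_bins, len(counts) // 2)
        bulk_value = float(np.mean(np.concatenate([counts[:m], counts[-m:]])))
        if bulk_value == 0:
            raise ValueError(
                "auto bulk estimate is zero (empty end bins); supply an "
                "explicit bulk density"
            )
    else:
        bulk_value = float(bulk)
        if bulk_value <= 0:
            raise ValueError("bulk density must be > 0")
    censored = np.flatnonzero(counts == 0)
    kt = kT(temperature)
    with np.errstate(divide="ignore"):
        G = -kt * np.log(counts / bulk_value)
    G[censored] = np.nan
    if units == "kT":
        G = G / kt
    elif units != "kJ/mol":
        raise ValueError(f"unknown units {units!r}")
    return FreeEnergyProfile(
        density.bin_centers.copy(), G, bulk_value, temperature, censored, units
    )


def max_barrier(profile: FreeEnergyProfile):
    """Highest barrier: (argmax position, max G - min G) over finite bins."""
    finite = np.isfinite(profile.G)
    if not finite.any():
        raise ValueError("all bins are censored")
    g = profile.G[finite]
    centers = profile.bin_centers[finite]
    height = float(g.max() - g.min())
    position = float(centers[np.argmax(g)])
    return position, height


# ---------------------------------------------------------------------------
# time-averaged structures

def average_structure(
    trajectory: Trajectory,
    window: float | None = None,
    selection=None,
    superpose_frames: bool = True,
    fit_selection=None,
) -> list[Frame]:
    """Per-window unweighted mean coordinates of the selection.

    Every frame of a window is superposed onto the window's first frame
    (least-squares, over ``fit_selection`` or the selection itself) before
    averaging, unless ``superpose_frames`` is False. ``window`` in ps;
    None averages the whole trajectory as one window.
    """
    top = trajectory.topology
    idx = top.resolve(selection) if top is not None else np.arange(trajectory.n_atoms)
    fit_idx = (
        top.resolve(fit_selection)
        if (fit_selection is not None and top is not None)
        else idx
    )
    dt = trajectory.frame_interval
    if window is None or dt is None:
        frames_per_window = trajectory.n_frames
    else:
        frames_per_window = int(round(window / dt))
        if frames_per_window < 1 or frames_per_window > trajectory.n_frames:
            raise ValueError("empty window")
    n_windows = trajectory.n_frames // frames_per_window
    out = []
    for w in range(n_windows):
        lo = w * frames_per_window
        hi = lo + frames_per_window
        ref = trajectory.positions[lo]
        acc = np.zeros((idx.size, 3))
        for k in range(lo, hi):
            pos = trajectory.positions[k]
            if superpose_frames and k > lo:
                transform, _ = superpose(pos[fit_idx], ref[fit_idx])
                acc += transform.apply(pos[idx])
            else:
                acc += pos[idx]
        out.append(
            Frame(acc / frames_per_window, trajectory.box_at(lo),
                  float(trajectory.times[lo]))
        )
    return out


# ---------------------------------------------------------------------------
# pore radius profiling

def _plane_basis(axis: np.ndarray):
    helper = np.array([1.0, 0.0, 0.0])
    if abs(axis @ helper) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, helper)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    return u, v


def pore_radius_profile(
    structure: Frame,
    topology: Topology,
    cylinder: PoreCylinder,
    step: float = 0.25,
    seed: int = 0,
    selection=None,
    n_moves: int = 1000,
    initial_move_scale: float = 0.5,
) -> PoreRadiusProfile:
    """Largest-probe-sphere radius at each axial slice.

    At each position (spacing ``step``) the probe centre is optimised in
    the slice plane by simulated annealing (``n_moves`` trial moves, move
    scale and temperature halved every n_moves/5 moves, start at the
    previous slice's optimum) followed by a Nelder–Mead polish. Slices
    where the probe escapes the cylinder radius are flagged open and
    excluded from the constriction search.
    """
    from scipy.optimize import minimize

    if step <= 0:
        raise ValueError("step must be > 0")
    idx = topology.resolve(selection)
    if idx.size < 4:
        raise ValueError("pore profiling needs at least 4 atoms with vdW radii")
    topology.require_positive_vdw(idx)
    atoms = structure.positions[idx]
    radii = topology.vdw_radius[idx]
    max_vdw = float(radii.max())

    axis = cylinder.axis
    u, v = _plane_basis(axis)
    s_atoms = (atoms - cylinder.center) @ axis

    rng = np.random.default_rng(seed)
    n_slices = int(round(cylinder.length / step)) + 1
    s_values = -cylinder.half_length + step * np.arange(n_slices)

    positions = np.empty(n_slices)
    radius_out = np.empty(n_slices)
    centers_out = np.empty((n_slices, 3))
    open_mask = np.zeros(n_slices, dtype=bool)

    prev_ab = np.zeros(2)
    cooling = max(1, n_moves // 5)
    for si, s0 in enumerate(s_values):
        plane_point = cylinder.center + s0 * axis
        reach = cylinder.radius + max_vdw
        near = np.abs(s_atoms - s0) <= reach
        sub = atoms[near]
        sub_r = radii[near]

        if sub.shape[0] == 0:
            positions[si] = s0
            radius_out[si] = cylinder.radius
            centers_out[si] = plane_point
            open_mask[si] = True
            prev_ab = np.zeros(2)
            continue

        def objective(ab):
            p = plane_point + ab[0] * u + ab[1] * v
            d = np.linalg.norm(sub - p, axis=1) - sub_r
            return float(d.min())

        def penalised(ab):
            # keeps the (unbounded) local polish inside the cylinder
            overshoot = math.hypot(ab[0], ab[1]) - cylinder.radius
            return objective(ab) - (1e6 * overshoot if overshoot > 0 else 0.0)

        ab = prev_ab.copy()
        best_ab = ab.copy()
        f = objective(ab)
        best_f = f
        scale = initial_move_scale
        temp = 0.05
        for m in range(n_moves):
            if m and m % cooling == 0:
                scale /= 2
                temp /= 2
            trial = ab + scale * rng.standard_normal(2)
            if trial @ trial > cylinder.radius**2:
                continue
            ft = objective(trial)
            if ft > f or rng.random() < math.exp(min((ft - f) / temp, 0.0)):
                ab, f = trial, ft
                if f > best_f:
                    best_ab, best_f = ab.copy(), f
        res = minimize(
            lambda p: -penalised(p),
            best_ab,
            method="Nelder-Mead",
            options={"xatol": 1e-5, "fatol": 1e-10, "maxiter": 400},
        )
        if -res.fun > best_f:
            best_ab, best_f = res.x, -res.fun

        positions[si] = s0
        radius_out[si] = best_f
        centers_out[si] = plane_point + best_ab[0] * u + best_ab[1] * v
        if best_f > cylinder.radius:
            open_mask[si] = True
        prev_ab = best_ab
    return PoreRadiusProfile(positions, radius_out, centers_out, open_mask)
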