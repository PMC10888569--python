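"""Superposition-based structural observables and vector statistics.

RMSD/RMSF use optimal least-squares rigid superposition (Kabsch, via
scipy's rotation machinery). Hydrogen bonds use the geometric criterion
donor–acceptor distance <= 3.5 Å and hydrogen–donor–acceptor angle
<= 30°. Dipole moments are computed relative to the selection's centre
of mass so that charged selections (e.g. a chain plus its bound Zn²⁺)
have a defined, reported convention. The correlation statistic between
two observable vectors is the cosine of the angle between them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .topology import Topology
from .trajectory import Frame, Trajectory

DEFAULT_HBOND_DISTANCE = 3.5  # Å, donor-acceptor
DEFAULT_HBOND_ANGLE = 30.0  # degrees, H-D-A


@dataclass
class RigidTransform:
    """x -> R·x + t."""

    rotation: np.ndarray
    translation: np.ndarray

    def apply(self, positions: np.ndarray) -> np.ndarray:
        return positions @ self.rotation.T + self.translation


def _coords(obj) -> np.ndarray:
    return obj.positions if isinstance(obj, Frame) else np.asarray(obj, dtype=np.float64)


def superpose(mobile, reference, selection=None, topology: Topology | None = None):
    """Optimal least-squares rigid superposition of mobile onto reference.

    Returns ``(RigidTransform, rmsd)`` where the RMSD is over the
    selection after applying the transform. Requires at least 3
    non-collinear atoms.
    """
    mob = _coords(mobile)
    ref = _coords(reference)
    if topology is not None and selection is not None:
        idx = topology.resolve(selection)
        mob_sel, ref_sel = mob[idx], ref[idx]
    elif selection is not None:
        idx = np.asarray(selection, dtype=np.int64)
        mob_sel, ref_sel = mob[idx], ref[idx]
    else:
        mob_sel, ref_sel = mob, ref
    if mob_sel.shape != ref_sel.shape:
        raise ValueError("mobile and reference selections differ in size")
    if mob_sel.shape[0] < 3:
        raise ValueError("superposition needs at least 3 atoms")
    mob_cen = mob_sel.mean(axis=0)
    ref_cen = ref_sel.mean(axis=0)
    a = ref_sel - ref_cen
    b = mob_sel - mob_cen
    sv = np.linalg.svd(a, compute_uv=False)
    if sv[1] <= 1e-8 * max(sv[0], 1e-300):
        raise ValueError("degenerate (collinear) selection: rotation underdetermined")
    rot, _ = Rotation.align_vectors(a, b)
    R = rot.as_matrix()
    t = ref_cen - R @ mob_cen
    moved = b @ R.T
    rmsd = float(np.sqrt(np.mean(np.sum((moved - a) ** 2, axis=1))))
    return RigidTransform(R, t), rmsd


def rmsd_series(
    trajectory: Trajectory,
    reference: Frame,
    selection=None,
    fit: bool = True,
) -> np.ndarray:
    """Per-frame RMSD to a reference structure (superposed by default)."""
    top = trajectory.topology
    idx = top.resolve(selection) if top is not None else np.arange(trajectory.n_atoms)
    ref = reference.positions
    out = np.empty(trajectory.n_frames)
    for k in range(trajectory.n_frames):
        pos = trajectory.positions[k]
        if fit:
            _, out[k] = superpose(pos[idx], ref[idx])
        else:
            out[k] = float(
                np.sqrt(np.mean(np.sum((pos[idx] - ref[idx]) ** 2, axis=1)))
            )
    return out


def rmsf(trajectory: Trajectory, selection=None, fit_selection=None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation about the mean structure.

    Each frame is first superposed onto the first frame using
    ``fit_selection`` (default: the analysis selection itself).
    """
    if trajectory.n_frames < 2:
        raise ValueError("RMSF needs at least 2 frames")
    top = trajectory.topology
    idx = top.resolve(selection) if top is not None else np.arange(trajectory.n_atoms)
    fit_idx = (
        top.resolve(fit_selection)
        if (fit_selection is not None and top is not None)
        else idx
    )
    ref = trajectory.positions[0]
    fitted = np.empty((trajectory.n_frames, idx.size, 3))
    for k in range(trajectory.n_frames):
        pos = trajectory.positions[k]
        if k == 0:
            fitted[k] = pos[idx]
        else:
            transform, _ = superpose(pos[fit_idx], ref[fit_idx])
            fitted[k] = transform.apply(pos[idx])
    mean = fitted.mean(axis=0)
    return np.sqrt(np.mean(np.sum((fitted - mean) ** 2, axis=2), axis=0))


def _min_image(diff: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return diff
    return diff - box * np.round(diff / box)


def min_distance_series(
    trajectory: Trajectory,
    group_a,
    group_b,
    periodic: bool = False,
) -> np.ndarray:
    """Per-frame minimum pairwise distance between two atom groups.

    Identical atom pairs (same index in both groups) are excluded; with
    ``periodic`` the minimum-image convention is applied using the
    orthorhombic box.
    """
    top = trajectory.topology
    ia = top.resolve(group_a)
    ib = top.resolve(group_b)
    if ia.size == 0 or ib.size == 0:
        raise ValueError("both groups must be nonempty")
    same = ia[:, None] == ib[None, :]
    if same.all():
        raise ValueError("groups share every atom; no distinct pairs to measure")
    out = np.empty(trajectory.n_frames)
    for k in range(trajectory.n_frames):
        pos = trajectory.positions[k]
        diff = pos[ia][:, None, :] - pos[ib][None, :, :]
        if periodic:
            box = trajectory.box_at(k)
            if box is None:
                raise ValueError("periodic distances requested but no box present")
            diff = _min_image(diff, box)
        d = np.sqrt(np.sum(diff**2, axis=2))
        d[same] = np.inf
        out[k] = d.min()
    return out


# ---------------------------------------------------------------------------
# hydrogen bonds

def donor_pairs(
    topology: Topology,
    frame: Frame,
    donor_selection,
    h_cutoff: float = 1.25,
) -> list[tuple[int, int]]:
    """Build (donor, hydrogen) pairs from a donor heavy-atom selection.

    Hydrogens are found by covalent distance (< ``h_cutoff`` Å) in the
    given frame; a donor without any bonded hydrogen is an error.
    """
    donors = topology.resolve(donor_selection)
    hydro = np.flatnonzero(np.char.upper(topology.element.astype(str)) == "H")
    pairs: list[tuple[int, int]] = []
    for d in donors:
        dist = np.linalg.norm(frame.positions[hydro] - frame.positions[d], axis=1)
        bonded = hydro[(dist < h_cutoff) & (hydro != d)]
        if bonded.size == 0:
            raise ValueError(
                f"donor atom {int(topology.serial[d])} ({topology.name[d]}) has "
                f"no bonded hydrogen within {h_cutoff} Å"
            )
        pairs.extend((int(d), int(h)) for h in bonded)
    return pairs


def hbond_series(
    trajectory: Trajectory,
    donors: list[tuple[int, int]],
    acceptors,
    d_cut: float = DEFAULT_HBOND_DISTANCE,
    angle_cut: float = DEFAULT_HBOND_ANGLE,
) -> np.ndarray:
    """Per-frame geometric hydrogen-bond count.

    A bond exists when the donor–acceptor distance is <= ``d_cut`` and
    the hydrogen–donor–acceptor angle is <= ``angle_cut`` degrees.
    """
    if not donors:
        raise ValueError("no donor-hydrogen pairs supplied")
    top = trajectory.topology
    acc = top.resolve(acceptors)
    if acc.size == 0:
        raise ValueError("no acceptor atoms")
    d_idx = np.array([d for d, _ in donors])
    h_idx = np.array([h for _, h in donors])
    cos_cut = np.cos(np.deg2rad(angle_cut))
    counts = np.zeros(trajectory.n_frames, dtype=np.int64)
    for k in range(trajectory.n_frames):
        pos = trajectory.positions[k]
        da = pos[acc][None, :, :] - pos[d_idx][:, None, :]  # (nd, na, 3)
        dist = np.linalg.norm(da, axis=2)
        dh = pos[h_idx] - pos[d_idx]  # (nd, 3)
        dh_norm = np.linalg.norm(dh, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cosang = np.einsum("ij,iaj->ia", dh, da) / (
                dh_norm[:, None] * dist
            )
        ok = (dist <= d_cut) & (cosang >= cos_cut)
        ok &= d_idx[:, None] != acc[None, :]  # donor is not its own acceptor
        counts[k] = int(ok.sum())
    return counts


# ---------------------------------------------------------------------------
# dipoles and vector correlation

def dipole_moment(
    frame: Frame,
    topology: Topology,
    selection=None,
    include_extra=None,
) -> np.ndarray:
    """Dipole moment of a selection in e·Å, relative to its centre of mass.

    ``include_extra`` adds further atoms (e.g. a bound zinc cation) to
    the selection before computing both the reference point and the sum
    mu = sum q_i (r_i - r_com).
    """
    idx = topology.resolve(selection)
    if include_extra is not None:
        idx = np.unique(np.concatenate([idx, topology.resolve(include_extra)]))
    if idx.size == 0:
        raise ValueError("empty selection")
    q = topology.charge[idx]
    if np.any(~np.isfinite(q)):
        raise ValueError("missing (non-finite) partial charge on selected atom")
    masses = topology.mass[idx]
    pos = frame.positions[idx]
    total_mass = masses.sum()
    r_ref = (
        pos.mean(axis=0) if total_mass == 0 else (masses[:, None] * pos).sum(0) / total_mass
    )
    return (q[:, None] * (pos - r_ref)).sum(axis=0)


def dipole_series(
    trajectory: Trajectory, selection=None, include_extra=None
) -> np.ndarray:
    """Per-frame dipole moments, shape (n_frames, 3)."""
    return np.stack(
        [
            dipole_moment(frame, trajectory.topology, selection, include_extra)
            for frame in trajectory
        ]
    )


def atom_axis_series(trajectory: Trajectory, start_atom, end_atom) -> np.ndarray:
    """Per-frame vector from one atom to another (e.g. arginine CA -> CZ)."""
    top = trajectory.topology
    i = top.resolve(start_atom)
    j = top.resolve(end_atom)
    if i.size != 1 or j.size != 1:
        raise ValueError("start and end selections must each resolve to one atom")
    return trajectory.positions[:, j[0], :] - trajectory.positions[:, i[0], :]


def vector_correlation(v1, v2) -> float:
    """Cosine of the angle between two vectors, in [-1, 1].

    The two vectors are translated to the origin and normalised; the
    cosine of the angle between them is the correlation coefficient.
    """
    a = np.asarray(v1, dtype=np.float64)
    b = np.asarray(v2, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector has no direction")
    return float(np.clip(a @ b / (na * nb), -1.0, 1.0))


def vector_correlation_series(
    series_a: np.ndarray, series_b: np.ndarray, mode: str = "per_frame"
):
    """Correlation between two per-frame vector observables.

    ``per_frame`` returns the cosine for every frame pair-wise;
    ``mean_vectors`` time-averages each series first and returns one
    cosine.
    """
    a = np.asarray(series_a, dtype=np.float64)
    b = np.asarray(series_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("series must both be (n_frames, 3)")
    if mode == "mean_vectors":
        return vector_correlation(a.mean(axis=0), b.mean(axis=0))
    if mode != "per_frame":
        raise ValueError(f"unknown mode {mode!r}")
    return np.array([vector_correlation(x, y) for x, y in zip(a, b)])
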