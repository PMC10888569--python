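"""Water permeation counting in a channel-aligned analysis cylinder.

One permeation event is one water molecule crossing the whole
transmembrane section of the conducting pore — a cylinder of radius 15 Å
and length 30 Å centred on the centre of geometry of the alpha carbons of
the two NPA-motif asparagines, its axis along +z by default.

The counter is a per-particle three-state machine over the axial
coordinate s = (r - center)·axis:

* LOW   : s < -half_length
* IN    : |s| <= half_length and radial distance <= radius
* HIGH  : s > +half_length

An event is scored when a particle last seen in LOW reaches HIGH
(direction "up") or vice versa ("down") having occupied only IN states in
between. Leaving the cylinder radially while |s| <= half_length resets
the particle's pending origin, as does an apparent axial jump larger than
half the box length (a periodic wrap, not a permeation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .topology import Topology
from .trajectory import Frame, Trajectory

DEFAULT_RADIUS = 15.0
DEFAULT_HALF_LENGTH = 15.0
DEFAULT_WINDOW_PS = 10_000.0  # 10 ns


@dataclass
class PoreCylinder:
    """Channel-aligned analysis region."""

    center: np.ndarray
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    radius: float = DEFAULT_RADIUS
    half_length: float = DEFAULT_HALF_LENGTH

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=np.float64)
        self.axis = np.asarray(self.axis, dtype=np.float64)
        if self.center.shape != (3,) or self.axis.shape != (3,):
            raise ValueError("center and axis must be 3-vectors")
        if abs(np.linalg.norm(self.axis) - 1.0) > 1e-9:
            raise ValueError("axis must have unit norm (within 1e-9)")
        if self.radius <= 0 or self.half_length <= 0:
            raise ValueError("radius and half_length must be > 0")

    @property
    def length(self) -> float:
        return 2.0 * self.half_length

    def axial_radial(self, positions: np.ndarray):
        """Axial coordinate s and radial distance for (..., 3) positions."""
        rel = positions - self.center
        s = rel @ self.axis
        radial_sq = np.maximum(np.einsum("...i,...i->...", rel, rel) - s**2, 0.0)
        return s, np.sqrt(radial_sq)


@dataclass
class PermeationEvent:
    particle_id: int
    entry_frame: int
    exit_frame: int
    direction: str  # "up" | "down"


@dataclass
class PermeationRecord:
    """Events plus per-window and cumulative bookkeeping for one cylinder."""

    events: list
    window_ps: float
    n_windows: int
    per_window_counts: np.ndarray  # (n_windows,)
    cumulative: np.ndarray  # per-frame running totals
    times: np.ndarray
    label: str = ""

    @property
    def n_events(self) -> int:
        return len(self.events)

    def counts(self, direction: str | None = None) -> int:
        if direction is None:
            return self.n_events
        return sum(1 for e in self.events if e.direction == direction)

    def events_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "particle_id": e.particle_id,
                    "entry_frame": e.entry_frame,
                    "exit_frame": e.exit_frame,
                    "direction": e.direction,
                }
                for e in self.events
            ],
            columns=["particle_id", "entry_frame", "exit_frame", "direction"],
        )


def define_pore_cylinder(
    topology: Topology,
    frame: Frame,
    npa_selection,
    radius: float = DEFAULT_RADIUS,
    half_length: float = DEFAULT_HALF_LENGTH,
    axis=(0.0, 0.0, 1.0),
) -> PoreCylinder:
    """Cylinder centred on the centre of geometry of the NPA CA atoms.

    ``npa_selection`` normally resolves to the two asparagine alpha
    carbons of the NPA motifs; the centre is their unweighted mean
    position and the axis defaults to +z.
    """
    idx = topology.resolve(npa_selection)
    if idx.size == 0:
        raise ValueError("NPA selection resolves to no atoms")
    center = frame.positions[idx].mean(axis=0)
    return PoreCylinder(center=center, axis=np.asarray(axis, dtype=np.float64),
                        radius=radius, half_length=half_length)


_LOW, _IN, _HIGH, _OUT = 0, 1, 2, 3


def count_permeations(
    trajectory: Trajectory,
    cylinder: PoreCylinder,
    particle_selection=None,
    window: float = DEFAULT_WINDOW_PS,
    label: str = "",
) -> PermeationRecord:
    """Count complete traversals of the cylinder per particle.

    ``window`` (ps) must fit into the trajectory at least once; events in
    a trailing partial window contribute to the cumulative series but not
    to ``per_window_counts``.
    """
    top = trajectory.topology
    idx = top.resolve(particle_selection) if top is not None else np.arange(
        trajectory.n_atoms
    )
    if idx.size == 0:
        raise ValueError("empty particle selection")
    n_frames = trajectory.n_frames
    dt = trajectory.frame_interval
    if window <= 0:
        raise ValueError("window must be > 0")
    if dt is not None:
        frames_per_window = int(round(window / dt))
        if frames_per_window < 1 or frames_per_window > n_frames:
            raise ValueError(
                f"window of {window} ps does not fit into the trajectory "
                f"({n_frames} frames at {dt} ps)"
            )
        n_windows = n_frames // frames_per_window
    else:
        frames_per_window, n_windows = n_frames, 1

    pos = trajectory.positions[:, idx, :]
    s, radial = cylinder.axial_radial(pos)  # each (n_frames, n_sel)

    region = np.full(s.shape, _IN, dtype=np.int8)
    region[s < -cylinder.half_length] = _LOW
    region[s > cylinder.half_length] = _HIGH
    mid = region == _IN
    region[mid & (radial > cylinder.radius)] = _OUT

    box = trajectory.box
    if box is not None:
        axis_box = abs(float((box if box.ndim == 1 else box[0]) @ np.abs(cylinder.axis)))
    else:
        axis_box = None

    n_sel = idx.size
    pending = np.zeros(n_sel, dtype=np.int8)  # 0 none, 1 low, 2 high
    origin_frame = np.full(n_sel, -1, dtype=np.int64)
    events: list[PermeationEvent] = []
    cumulative = np.zeros(n_frames, dtype=np.int64)
    total = 0
    for k in range(n_frames):
        reg = region[k]
        if k > 0 and axis_box is not None:
            wrapped = np.abs(s[k] - s[k - 1]) > axis_box / 2
            pending[wrapped] = 0
        up = (pending == 1) & (reg == _HIGH)
        down = (pending == 2) & (reg == _LOW)
        for j in np.flatnonzero(up):
            events.append(
                PermeationEvent(int(idx[j]), int(origin_frame[j]), k, "up")
            )
        for j in np.flatnonzero(down):
            events.append(
                PermeationEvent(int(idx[j]), int(origin_frame[j]), k, "down")
            )
        total += int(up.sum() + down.sum())
        cumulative[k] = total
        low_mask = reg == _LOW
        high_mask = reg == _HIGH
        pending[low_mask] = 1
        pending[high_mask] = 2
        pending[reg == _OUT] = 0
        origin_frame[low_mask | high_mask] = k

    per_window = np.zeros(n_windows, dtype=np.int64)
    for e in events:
        w = e.exit_frame // frames_per_window
        if w < n_windows:
            per_window[w] += 1
    return PermeationRecord(
        events=events,
        window_ps=window,
        n_windows=n_windows,
        per_window_counts=per_window,
        cumulative=cumulative,
        times=trajectory.times.copy(),
        label=label,
    )


def count_permeations_per_chain(
    trajectory: Trajectory,
    cylinders: dict[str, PoreCylinder],
    particle_selection=None,
    window: float = DEFAULT_WINDOW_PS,
) -> dict[str, PermeationRecord]:
    """One PermeationRecord per chain, each in its own cylinder."""
    return {
        chain: count_permeations(trajectory, cyl, particle_selection, window, chain)
        for chain, cyl in cylinders.items()
    }


def per_window_table(records: dict[str, PermeationRecord],
                     condition: str = "") -> pd.DataFrame:
    """Stack per-chain window counts into a replicate table."""
    rows = []
    for chain, rec in records.items():
        for w, c in enumerate(rec.per_window_counts):
            rows.append(
                {"condition": condition, "chain": chain, "window": w,
                 "value": int(c)}
            )
    return pd.DataFrame(rows, columns=["condition", "chain", "window", "value"])
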