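"""Frame and Trajectory containers.

Positions are stored as a dense ``(n_frames, n_atoms, 3)`` float64 array in
Å with per-frame times in ps. Boxes are orthorhombic (three edge lengths);
triclinic cells are rejected at the I/O layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class TrajectoryError(ValueError):
    """Raised for malformed frames or inconsistent time bases."""


@dataclass
class Frame:
    """One coordinate set: positions (N, 3) in Å, box lengths in Å, time in ps."""

    positions: np.ndarray
    box: np.ndarray | None = None
    time: float = 0.0

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.float64)
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise TrajectoryError(
                f"positions must be (N, 3), got {self.positions.shape}"
            )
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=np.float64)
            if self.box.shape != (3,):
                raise TrajectoryError("box must be three orthorhombic edge lengths")
            if np.any(self.box <= 0):
                raise TrajectoryError("box lengths must be > 0")

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[0]

    def copy(self) -> "Frame":
        return Frame(
            self.positions.copy(),
            None if self.box is None else self.box.copy(),
            self.time,
        )


class Trajectory:
    """Time-ordered coordinate frames bound to one Topology.

    Frame times must be strictly increasing with a constant interval
    (within ``interval_rtol`` relative tolerance). A single-frame
    trajectory is allowed; its ``frame_interval`` is None.
    """

    def __init__(
        self,
        topology,
        positions: np.ndarray,
        times: np.ndarray,
        box: np.ndarray | None = None,
        interval_rtol: float = 1e-6,
    ) -> None:
        positions = np.asarray(positions, dtype=np.float64)
        times = np.asarray(times, dtype=np.float64)
        if positions.ndim != 3 or positions.shape[2] != 3:
            raise TrajectoryError(
                f"positions must be (n_frames, n_atoms, 3), got {positions.shape}"
            )
        if times.shape != (positions.shape[0],):
            raise TrajectoryError("one time stamp per frame required")
        if positions.shape[0] == 0:
            raise TrajectoryError("trajectory must contain at least one frame")
        if topology is not None and positions.shape[1] != topology.n_atoms:
            raise TrajectoryError(
                f"frame atom count {positions.shape[1]} does not match "
                f"topology atom count {topology.n_atoms}"
            )
        dt_all = np.diff(times)
        if np.any(dt_all <= 0):
            k = int(np.flatnonzero(dt_all <= 0)[0]) + 1
            raise TrajectoryError(f"frame times not strictly increasing at frame {k}")
        if len(dt_all):
            dt = dt_all[0]
            if np.any(np.abs(dt_all - dt) > interval_rtol * abs(dt)):
                raise TrajectoryError(
                    "frame interval is not constant within tolerance"
                )
            self.frame_interval: float | None = float(dt)
        else:
            self.frame_interval = None
        if box is not None:
            box = np.asarray(box, dtype=np.float64)
            if box.shape == (3,):
                pass
            elif box.shape == (positions.shape[0], 3):
                pass
            else:
                raise TrajectoryError("box must be (3,) or (n_frames, 3)")
            if np.any(box <= 0):
                raise TrajectoryError("box lengths must be > 0")
        self.topology = topology
        self.positions = positions
        self.times = times
        self.box = box

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]

    def box_at(self, k: int) -> np.ndarray | None:
        if self.box is None:
            return None
        return self.box if self.box.ndim == 1 else self.box[k]

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, k: int) -> Frame:
        if not -self.n_frames <= k < self.n_frames:
            raise IndexError(k)
        k = k % self.n_frames
        return Frame(self.positions[k], self.box_at(k), float(self.times[k]))

    def __iter__(self):
        for k in range(self.n_frames):
            yield self[k]

    def slice_frames(self, start: int, stop: int) -> "Trajectory":
        """Sub-trajectory over frame indices [start, stop)."""
        if stop - start < 1:
            raise TrajectoryError("empty frame slice")
        box = self.box
        if box is not None and box.ndim == 2:
            box = box[start:stop]
        return Trajectory(
            self.topology, self.positions[start:stop], self.times[start:stop], box
        )

    def time_reversed(self) -> "Trajectory":
        """Frames in reverse order on the same (forward) time grid.

        Useful for symmetry checks: reversing time swaps the direction of
        every permeation event.
        """
        box = self.box
        if box is not None and box.ndim == 2:
            box = box[::-1].copy()
        return Trajectory(
            self.topology, self.positions[::-1].copy(), self.times.copy(), box
        )
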