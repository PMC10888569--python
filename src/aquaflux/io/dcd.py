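"""Binary DCD trajectory support, delegated to MDAnalysis.

DCD stores float32 coordinates; round trips are exact only to float32
precision. Unit cells are validated as orthorhombic on read.
"""

from __future__ import annotations

import warnings

import numpy as np

from ..trajectory import Trajectory
from .errors import ParseError, UnsupportedBoxError


def read_dcd_trajectory(path, topology, dt: float = 1.0) -> Trajectory:
    from MDAnalysis.coordinates.DCD import DCDReader

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        reader = DCDReader(str(path))
        coords, times, boxes = [], [], []
        try:
            for k, ts in enumerate(reader):
                if ts.positions.shape[0] != topology.n_atoms:
                    raise ParseError(
                        path, None,
                        f"frame {k} atom count {ts.positions.shape[0]} != "
                        f"topology {topology.n_atoms}",
                    )
                coords.append(ts.positions.astype(np.float64))
                times.append(float(ts.time))
                if ts.dimensions is not None and np.all(ts.dimensions[:3] > 0):
                    if not np.allclose(ts.dimensions[3:], 90.0, atol=1e-3):
                        raise UnsupportedBoxError(
                            f"{path}: triclinic cell in DCD frame {k}"
                        )
                    boxes.append(np.array(ts.dimensions[:3], dtype=np.float64))
        finally:
            reader.close()
    if not coords:
        raise ParseError(path, None, "empty DCD file")
    times = np.asarray(times)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        times = dt * np.arange(len(coords))
    box = np.stack(boxes) if len(boxes) == len(coords) else None
    return Trajectory(topology, np.stack(coords), times, box)


def write_dcd(path, trajectory: Trajectory) -> None:
    import MDAnalysis as mda
    from MDAnalysis.coordinates.memory import MemoryReader

    n_atoms = trajectory.n_atoms
    dt = trajectory.frame_interval or 1.0
    dims = None
    if trajectory.box is not None:
        box = trajectory.box
        if box.ndim == 1:
            box = np.tile(box, (trajectory.n_frames, 1))
        dims = np.concatenate(
            [box, np.full((trajectory.n_frames, 3), 90.0)], axis=1
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe.empty(n_atoms, trajectory=True)
        u.load_new(
            trajectory.positions.astype(np.float32),
            format=MemoryReader,
            dt=dt,
            dimensions=dims,
        )
        with mda.Writer(str(path), n_atoms=n_atoms, dt=dt) as writer:
            for ts in u.trajectory:
                writer.write(u.atoms)
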