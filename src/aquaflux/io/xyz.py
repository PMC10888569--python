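"""Plain XYZ trajectory reading/writing (Å).

The comment line of each block carries the frame time as ``t= <ps>``;
blocks without a parsable time fall back to a uniform grid at ``dt``.
"""

from __future__ import annotations

import re

import numpy as np

from ..trajectory import Trajectory
from .errors import ParseError

_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)")


def read_xyz_trajectory(path, topology, dt: float = 1.0) -> Trajectory:
    coords, times = [], []
    with open(path) as fh:
        lineno = 0
        k = 0
        while True:
            count_line = fh.readline()
            lineno += 1
            if count_line == "":
                break
            if not count_line.strip():
                continue
            try:
                n_atoms = int(count_line)
            except ValueError:
                raise ParseError(path, lineno, f"bad atom count {count_line.strip()!r}") from None
            if n_atoms != topology.n_atoms:
                raise ParseError(
                    path, lineno,
                    f"frame {k} atom count {n_atoms} != topology {topology.n_atoms}",
                )
            comment = fh.readline()
            lineno += 1
            m = _TIME_RE.search(comment)
            times.append(float(m.group(1)) if m else None)
            frame = np.empty((n_atoms, 3))
            for i in range(n_atoms):
                line = fh.readline()
                lineno += 1
                if line == "":
                    raise ParseError(path, lineno, "truncated XYZ block")
                tokens = line.split()
                if len(tokens) < 4:
                    raise ParseError(path, lineno, "XYZ atom line needs symbol + 3 coordinates")
                try:
                    frame[i] = [float(t) for t in tokens[1:4]]
                except ValueError:
                    raise ParseError(path, lineno, "bad coordinate field") from None
            coords.append(frame)
            k += 1
    if not coords:
        raise ParseError(path, 1, "empty XYZ file")
    if any(t is None for t in times):
        times = dt * np.arange(len(coords))
    else:
        times = np.array(times, dtype=np.float64)
        if np.any(np.diff(times) <= 0):
            raise ParseError(path, None, "non-monotone frame times")
    return Trajectory(topology, np.stack(coords), np.asarray(times), box=None)


def write_xyz(path, topology, trajectory_or_frames) -> None:
    frames = (
        trajectory_or_frames
        if hasattr(trajectory_or_frames, "__iter__")
        else [trajectory_or_frames]
    )
    with open(path, "w") as fh:
        for frame in frames:
            fh.write(f"{topology.n_atoms}\n")
            fh.write(f"t= {frame.time:.6f} ps\n")
            for i in range(topology.n_atoms):
                p = frame.positions[i]
                fh.write(f"{str(topology.element[i]):<3s} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")
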