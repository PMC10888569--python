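"""GROMACS GRO reading/writing. GRO stores nm; everything internal is Å.

GRO has no chain column, so chain identity comes from residue-number
blocks via an explicit ``chain_map``: a sequence of
``(first_resid, last_resid, chain_id)`` tuples. Without a map every atom
lands in chain "A".
"""

from __future__ import annotations

import re

import numpy as np

from .. import elements
from ..topology import Topology
from ..trajectory import Frame, Trajectory
from .errors import ParseError, UnsupportedBoxError

NM_TO_A = 10.0

_TIME_RE = re.compile(r"t\s*=\s*([-+0-9.eE]+)")


def _chain_for_resid(resid: int, chain_map) -> str:
    if chain_map is None:
        return "A"
    for lo, hi, chain in chain_map:
        if lo <= resid <= hi:
            return str(chain)
    raise ParseError(None, None, f"residue {resid} not covered by chain_map")


def _parse_box_line(line: str, path, lineno: int) -> np.ndarray:
    try:
        vals = [float(tok) for tok in line.split()]
    except ValueError:
        raise ParseError(path, lineno, "bad box line") from None
    if len(vals) == 3:
        box = np.array(vals)
    elif len(vals) == 9:
        if any(abs(v) > 1e-12 for v in vals[3:]):
            raise UnsupportedBoxError(
                f"{path}:{lineno}: triclinic box is not supported"
            )
        box = np.array(vals[:3])
    else:
        raise ParseError(path, lineno, f"box line has {len(vals)} values, expected 3 or 9")
    return box * NM_TO_A


def _read_gro_block(fh, path, lineno0: int):
    """Read one GRO frame block; returns None at clean EOF."""
    title = fh.readline()
    if title == "":
        return None
    count_line = fh.readline()
    if count_line == "":
        raise ParseError(path, lineno0 + 2, "truncated GRO block: missing atom count")
    try:
        n_atoms = int(count_line)
    except ValueError:
        raise ParseError(path, lineno0 + 2, f"bad atom count {count_line.strip()!r}") from None
    records = []
    for i in range(n_atoms):
        line = fh.readline()
        lineno = lineno0 + 3 + i
        if line == "":
            raise ParseError(path, lineno, "truncated GRO block: missing atom line")
        if len(line.rstrip("\n")) < 44:
            raise ParseError(path, lineno, "GRO atom line shorter than 44 columns")
        try:
            resid = int(line[0:5])
        except ValueError:
            raise ParseError(path, lineno, f"bad residue number field {line[0:5]!r}") from None
        resname = line[5:10].strip()
        name = line[10:15].strip()
        try:
            serial = int(line[15:20])
        except ValueError:
            raise ParseError(path, lineno, f"bad atom serial field {line[15:20]!r}") from None
        try:
            x = float(line[20:28])
            y = float(line[28:36])
            z = float(line[36:44])
        except ValueError:
            raise ParseError(path, lineno, "bad coordinate field") from None
        records.append((resid, resname, name, serial, (x, y, z)))
    box_line = fh.readline()
    if box_line == "":
        raise ParseError(path, lineno0 + 3 + n_atoms, "truncated GRO block: missing box line")
    box = _parse_box_line(box_line, path, lineno0 + 3 + n_atoms)
    m = _TIME_RE.search(title)
    time = float(m.group(1)) if m else None
    return title, records, box, time, lineno0 + 3 + n_atoms


def _topology_from_records(records, chain_map, vdw_overrides):
    resid, resname, name, serial, _ = map(list, zip(*records))
    element = [elements.element_from_atom_name(n) for n in name]
    return Topology(
        serial=np.array(serial),
        name=np.array(name, dtype=object),
        element=np.array(element, dtype=object),
        resname=np.array(resname, dtype=object),
        resid=np.array(resid),
        chain=np.array([_chain_for_resid(r, chain_map) for r in resid], dtype=object),
        mass=np.array([elements.mass_of(e) for e in element]),
        charge=np.zeros(len(serial)),
        vdw_radius=np.array([elements.vdw_radius_of(e, vdw_overrides) for e in element]),
    )


def read_gro_structure(path, chain_map=None, vdw_overrides=None):
    with open(path) as fh:
        block = _read_gro_block(fh, path, 0)
    if block is None:
        raise ParseError(path, 1, "empty GRO file")
    _, records, box, time, _ = block
    top = _topology_from_records(records, chain_map, vdw_overrides)
    coords = np.array([r[4] for r in records]) * NM_TO_A
    return top, Frame(coords, box=box, time=time or 0.0)


def read_gro_trajectory(path, topology, dt: float = 1.0):
    """Read a concatenated series of GRO blocks as a trajectory."""
    coords, times, boxes = [], [], []
    lineno = 0
    with open(path) as fh:
        k = 0
        while True:
            block = _read_gro_block(fh, path, lineno)
            if block is None:
                break
            _, records, box, time, lineno = block
            if len(records) != topology.n_atoms:
                raise ParseError(
                    path, None,
                    f"frame {k} atom count {len(records)} != topology {topology.n_atoms}",
                )
            coords.append(np.array([r[4] for r in records]) * NM_TO_A)
            times.append(time)
            boxes.append(box)
            k += 1
    if not coords:
        raise ParseError(path, 1, "empty GRO file")
    if any(t is None for t in times):
        times = dt * np.arange(len(coords))
    else:
        times = np.array(times, dtype=np.float64)
        if np.any(np.diff(times) <= 0):
            raise ParseError(path, None, "non-monotone frame times")
    return Trajectory(topology, np.stack(coords), np.asarray(times), np.stack(boxes))


def write_gro(path, topology: Topology, frames, times=None) -> None:
    """Write one Frame or a sequence of Frames as (a series of) GRO blocks."""
    if isinstance(frames, Frame):
        frames = [frames]
    with open(path, "w") as fh:
        for frame in frames:
            if frame.n_atoms != topology.n_atoms:
                raise ValueError("frame atom count does not match topology")
            fh.write(f"aquaflux, t= {frame.time:.4f}\n")
            fh.write(f"{topology.n_atoms:5d}\n")
            pos_nm = frame.positions / NM_TO_A
            for i in range(topology.n_atoms):
                fh.write(
                    f"{int(topology.resid[i]) % 100000:5d}"
                    f"{str(topology.resname[i]):<5.5s}"
                    f"{str(topology.name[i]):>5.5s}"
                    f"{int(topology.serial[i]) % 100000:5d}"
                    f"{pos_nm[i, 0]:8.3f}{pos_nm[i, 1]:8.3f}{pos_nm[i, 2]:8.3f}\n"
                )
            box = frame.box if frame.box is not None else np.zeros(3) + 1.0
            fh.write(
                f"{box[0] / NM_TO_A:10.5f}{box[1] / NM_TO_A:10.5f}{box[2] / NM_TO_A:10.5f}\n"
            )
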