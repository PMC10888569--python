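"""Reading and writing of molecular structures, trajectories and tables.

Formats: PDB (single and multi-model), GRO (single and series), XYZ, DCD.
Coordinates are Å internally; GRO's nm are converted on read/write.
"""

from __future__ import annotations

from pathlib import Path

from ..topology import Topology
from ..trajectory import Frame, Trajectory
from .errors import ParseError, UnsupportedBoxError
from .gro import read_gro_structure, read_gro_trajectory, write_gro
from .pdb import read_pdb_structure, read_pdb_trajectory, write_pdb
from .tables import read_table, write_dataframe, write_table
from .xyz import read_xyz_trajectory, write_xyz
from .dcd import read_dcd_trajectory, write_dcd

_STRUCTURE_FORMATS = ("pdb", "gro")
_TRAJECTORY_FORMATS = ("pdb", "gro", "xyz", "dcd")


def _infer_format(path, fmt, allowed) -> str:
    if fmt is None:
        fmt = Path(path).suffix.lstrip(".").lower()
    fmt = fmt.lower()
    if fmt not in allowed:
        raise ValueError(f"unsupported format {fmt!r}; expected one of {allowed}")
    return fmt


def read_structure(path, fmt=None, chain_map=None, vdw_overrides=None):
    """Read a structure file into (Topology, Frame).

    Masses and vdW radii are filled from the element attribute table
    (overridable via ``vdw_overrides``); partial charges default to 0 e.
    For GRO, ``chain_map`` assigns chains from residue-number blocks.
    """
    fmt = _infer_format(path, fmt, _STRUCTURE_FORMATS)
    if fmt == "pdb":
        return read_pdb_structure(path, vdw_overrides)
    return read_gro_structure(path, chain_map, vdw_overrides)


def write_structure(path, topology: Topology, frame: Frame, fmt=None) -> None:
    fmt = _infer_format(path, fmt, _STRUCTURE_FORMATS)
    if fmt == "pdb":
        write_pdb(path, topology, frame)
    else:
        write_gro(path, topology, frame)


def read_trajectory(path, topology: Topology, fmt=None, dt: float = 1.0) -> Trajectory:
    """Read a coordinate trajectory against an existing Topology.

    ``dt`` (ps) supplies the frame interval for formats that carry no
    time stamps. Frame times must be strictly increasing; atom-count
    mismatches are reported with the offending frame index.
    """
    fmt = _infer_format(path, fmt, _TRAJECTORY_FORMATS)
    if fmt == "pdb":
        return read_pdb_trajectory(path, topology, dt)
    if fmt == "gro":
        return read_gro_trajectory(path, topology, dt)
    if fmt == "xyz":
        return read_xyz_trajectory(path, topology, dt)
    return read_dcd_trajectory(path, topology, dt)


def write_trajectory(path, trajectory: Trajectory, fmt=None) -> None:
    fmt = _infer_format(path, fmt, _TRAJECTORY_FORMATS)
    top = trajectory.topology
    if fmt == "pdb":
        write_pdb(path, top, list(trajectory))
    elif fmt == "gro":
        write_gro(path, top, list(trajectory))
    elif fmt == "xyz":
        write_xyz(path, top, list(trajectory))
    else:
        write_dcd(path, trajectory)


__all__ = [
    "ParseError",
    "UnsupportedBoxError",
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_table",
    "write_table",
    "write_dataframe",
]
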