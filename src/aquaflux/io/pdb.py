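"""Strict fixed-column PDB reading and writing (ATOM/HETATM, MODEL/ENDMDL).

Only orthorhombic CRYST1 cells are accepted. Charges default to 0 e and
masses / vdW radii are filled from the element attribute table; an unknown
element with no table entry is an error, never a silent default.
"""

from __future__ import annotations

import numpy as np

from .. import elements
from ..topology import Topology
from ..trajectory import Frame, Trajectory
from .errors import ParseError, UnsupportedBoxError


def _parse_atom_line(line: str, path, lineno: int):
    if len(line.rstrip("\n")) < 54:
        raise ParseError(path, lineno, "ATOM/HETATM record shorter than 54 columns")
    try:
        serial = int(line[6:11])
    except ValueError:
        raise ParseError(path, lineno, f"bad atom serial field {line[6:11]!r}") from None
    name = line[12:16].strip()
    resname = line[17:21].strip()
    chain = line[21].strip() or "A"
    try:
        resid = int(line[22:26])
    except ValueError:
        raise ParseError(path, lineno, f"bad residue number field {line[22:26]!r}") from None
    try:
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
    except ValueError:
        raise ParseError(path, lineno, "bad coordinate field") from None
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        element = elements.element_from_atom_name(name)
    return serial, name, resname, chain, resid, (x, y, z), element


def _parse_cryst1(line: str, path, lineno: int) -> np.ndarray:
    try:
        a, b, c = float(line[6:15]), float(line[15:24]), float(line[24:33])
        alpha, beta, gamma = (
            float(line[33:40]),
            float(line[40:47]),
            float(line[47:54]),
        )
    except ValueError:
        raise ParseError(path, lineno, "bad CRYST1 record") from None
    if not np.allclose([alpha, beta, gamma], 90.0, atol=1e-3):
        raise UnsupportedBoxError(
            f"{path}:{lineno}: triclinic cell (angles {alpha}, {beta}, {gamma}) "
            "is not supported; orthorhombic boxes only"
        )
    return np.array([a, b, c])


def read_pdb_models(path, vdw_overrides=None, max_models=None):
    """Parse a (possibly multi-model) PDB file.

    Returns (Topology, list of coordinate arrays, box or None). The
    topology is built from the first model; later models must repeat the
    same atom count.
    """
    box = None
    models: list[list[tuple]] = []
    current: list[tuple] = []
    in_model = False
    saw_model_records = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                current.append(_parse_atom_line(line, path, lineno))
            elif rec == "CRYST1":
                box = _parse_cryst1(line, path, lineno)
            elif rec == "MODEL":
                saw_model_records = True
                if in_model:
                    raise ParseError(path, lineno, "nested MODEL record")
                in_model = True
                current = []
            elif rec == "ENDMDL":
                if not in_model:
                    raise ParseError(path, lineno, "ENDMDL without MODEL")
                in_model = False
                models.append(current)
                if max_models is not None and len(models) >= max_models:
                    break
                current = []
    if in_model:
        raise ParseError(path, None, "MODEL record without closing ENDMDL")
    if not saw_model_records:
        models = [current]
    models = [m for m in models if m]
    if not models:
        raise ParseError(path, None, "no ATOM/HETATM records found")

    first = models[0]
    serial, name, resname, chain, resid, xyz, element = map(list, zip(*first))
    mass = [elements.mass_of(e) for e in element]
    vdw = [elements.vdw_radius_of(e, vdw_overrides) for e in element]
    top = Topology(
        serial=np.array(serial),
        name=np.array(name, dtype=object),
        element=np.array([elements.normalize_element(e) for e in element], dtype=object),
        resname=np.array(resname, dtype=object),
        resid=np.array(resid),
        chain=np.array(chain, dtype=object),
        mass=np.array(mass),
        charge=np.zeros(len(serial)),
        vdw_radius=np.array(vdw),
    )
    coords = []
    for k, model in enumerate(models):
        if len(model) != top.n_atoms:
            raise ParseError(
                path,
                None,
                f"model {k} has {len(model)} atoms, expected {top.n_atoms}",
            )
        coords.append(np.array([rec[5] for rec in model]))
    return top, coords, box


def read_pdb_structure(path, vdw_overrides=None):
    top, coords, box = read_pdb_models(path, vdw_overrides, max_models=1)
    return top, Frame(coords[0], box=box, time=0.0)


def read_pdb_trajectory(path, topology, dt: float = 1.0, vdw_overrides=None):
    file_top, coords, box = read_pdb_models(path, vdw_overrides)
    for k, c in enumerate(coords):
        if c.shape[0] != topology.n_atoms:
            raise ParseError(
                path, None, f"frame {k} atom count {c.shape[0]} != topology {topology.n_atoms}"
            )
    times = dt * np.arange(len(coords))
    return Trajectory(topology, np.stack(coords), times, box)


def _atom_line(serial, name, resname, chain, resid, pos, element) -> str:
    # Short names start in column 14 per convention; 4-char names fill 13-16.
    nm = name if len(name) >= 4 else f" {name:<3s}"
    return (
        f"ATOM  {serial:5d} {nm:<4.4s} {resname:<4.4s}{chain:1.1s}{resid:4d}    "
        f"{pos[0]:8.3f}{pos[1]:8.3f}{pos[2]:8.3f}  1.00  0.00          "
        f"{element:>2.2s}\n"
    )


def write_pdb(path, topology: Topology, frames, box=None) -> None:
    """Write one Frame or a sequence of Frames (multi-model) as PDB."""
    if isinstance(frames, Frame):
        frames = [frames]
    frames = list(frames)
    with open(path, "w") as fh:
        b = frames[0].box if frames[0].box is not None else box
        if b is not None:
            fh.write(
                f"CRYST1{b[0]:9.3f}{b[1]:9.3f}{b[2]:9.3f}"
                f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1\n"
            )
        multi = len(frames) > 1
        for k, frame in enumerate(frames):
            if frame.n_atoms != topology.n_atoms:
                raise ValueError("frame atom count does not match topology")
            if multi:
                fh.write(f"MODEL     {k + 1:4d}\n")
            for i in range(topology.n_atoms):
                fh.write(
                    _atom_line(
                        int(topology.serial[i]) % 100000,
                        str(topology.name[i]),
                        str(topology.resname[i]),
                        str(topology.chain[i]),
                        int(topology.resid[i]) % 10000,
                        frame.positions[i],
                        str(topology.element[i]),
                    )
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")
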