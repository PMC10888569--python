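"""Static atom table (Topology) and a small text selection language.

A :class:`Topology` is the per-atom metadata shared by every frame of a
trajectory: serials, names, elements, residue identity, chain identity,
masses, partial charges and van der Waals radii. Selections are expressed
either as named index sets stored on the topology or in a mini-language of
``and``-joined clauses, e.g. ``"chain A and resid 216 and name CA"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class TopologyError(ValueError):
    """Raised for invariant violations in the atom table."""


class SelectionError(ValueError):
    """Raised for unparsable or unresolvable selections."""


_CLAUSE_KEYS = ("chain", "resid", "resname", "name", "element")


@dataclass
class Topology:
    """Per-atom attribute table.

    Parameters
    ----------
    serial : int array — unique atom serial numbers.
    name : str array — atom names (e.g. CA, OW).
    element : str array — element symbols.
    resname : str array — residue names.
    resid : int array — residue numbers.
    chain : str array — chain identifiers.
    mass : float array — masses in Da (>= 0).
    charge : float array — partial charges in e.
    vdw_radius : float array — van der Waals radii in Å.
    selections : dict of named index arrays.
    """

    serial: np.ndarray
    name: np.ndarray
    element: np.ndarray
    resname: np.ndarray
    resid: np.ndarray
    chain: np.ndarray
    mass: np.ndarray
    charge: np.ndarray
    vdw_radius: np.ndarray
    selections: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.serial)
        arrays = {
            "serial": np.asarray(self.serial, dtype=np.int64),
            "name": np.asarray(self.name, dtype=object),
            "element": np.asarray(self.element, dtype=object),
            "resname": np.asarray(self.resname, dtype=object),
            "resid": np.asarray(self.resid, dtype=np.int64),
            "chain": np.asarray(self.chain, dtype=object),
            "mass": np.asarray(self.mass, dtype=np.float64),
            "charge": np.asarray(self.charge, dtype=np.float64),
            "vdw_radius": np.asarray(self.vdw_radius, dtype=np.float64),
        }
        for key, arr in arrays.items():
            if arr.shape != (n,):
                raise TopologyError(
                    f"field {key!r} has shape {arr.shape}, expected ({n},)"
                )
            setattr(self, key, arr)
        if n and len(np.unique(self.serial)) != n:
            counts = np.unique(self.serial, return_counts=True)
            dup = counts[0][counts[1] > 1]
            raise TopologyError(f"duplicated atom serial number(s): {dup.tolist()}")
        if np.any(self.mass < 0):
            raise TopologyError("negative atomic mass")
        for sel_name, idx in list(self.selections.items()):
            idx = np.asarray(idx, dtype=np.int64)
            if idx.size and (idx.min() < 0 or idx.max() >= n):
                raise TopologyError(
                    f"selection {sel_name!r} references atom indices outside [0, {n})"
                )
            self.selections[sel_name] = idx

    @property
    def n_atoms(self) -> int:
        return len(self.serial)

    @property
    def chain_ids(self) -> list[str]:
        """Distinct chain identifiers in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chain:
            seen.setdefault(c)
        return list(seen)

    def require_positive_vdw(self, indices: np.ndarray | None = None) -> None:
        """Pore profiling needs strictly positive vdW radii for the atoms used."""
        radii = self.vdw_radius if indices is None else self.vdw_radius[indices]
        if np.any(radii <= 0):
            raise TopologyError("vdW radius must be > 0 for every atom used")

    # -- selection language ------------------------------------------------

    def select(self, expression: str) -> np.ndarray:
        """Resolve a selection expression to sorted atom indices.

        The language is ``and``-joined clauses; each clause is a key
        followed by one or more values (OR within the clause):

        - ``chain A`` / ``chain A B``
        - ``resid 216`` / ``resid 10:20`` / ``resid 5 7 9``
        - ``resname HOH`` — residue name
        - ``name CA OW`` — atom name
        - ``element O`` — element symbol

        A leading ``@`` refers to a named selection stored on the topology.
        """
        expression = expression.strip()
        if not expression:
            raise SelectionError("empty selection expression")
        if expression.startswith("@"):
            key = expression[1:]
            if key not in self.selections:
                raise SelectionError(f"no named selection {key!r}")
            return np.sort(self.selections[key])
        mask = np.ones(self.n_atoms, dtype=bool)
        for clause in expression.split(" and "):
            tokens = clause.split()
            if len(tokens) < 2 or tokens[0] not in _CLAUSE_KEYS:
                raise SelectionError(
                    f"cannot parse clause {clause.strip()!r}; expected one of "
                    f"{_CLAUSE_KEYS} followed by value(s)"
                )
            key, values = tokens[0], tokens[1:]
            mask &= self._clause_mask(key, values)
        return np.flatnonzero(mask)

    def _clause_mask(self, key: str, values: list[str]) -> np.ndarray:
        if key == "resid":
            mask = np.zeros(self.n_atoms, dtype=bool)
            for v in values:
                if ":" in v:
                    lo_s, hi_s = v.split(":", 1)
                    try:
                        lo, hi = int(lo_s), int(hi_s)
                    except ValueError:
                        raise SelectionError(f"bad resid range {v!r}") from None
                    mask |= (self.resid >= lo) & (self.resid <= hi)
                else:
                    try:
                        mask |= self.resid == int(v)
                    except ValueError:
                        raise SelectionError(f"bad resid {v!r}") from None
            return mask
        column = {
            "chain": self.chain,
            "resname": self.resname,
            "name": self.name,
            "element": self.element,
        }[key]
        mask = np.zeros(self.n_atoms, dtype=bool)
        for v in values:
            if key == "element":
                mask |= np.char.upper(column.astype(str)) == v.upper()
            else:
                mask |= column.astype(str) == v
        return mask

    def resolve(self, selection) -> np.ndarray:
        """Accept an expression string, an index array, or None (all atoms)."""
        if selection is None:
            return np.arange(self.n_atoms)
        if isinstance(selection, str):
            idx = self.select(selection)
        else:
            idx = np.asarray(selection, dtype=np.int64)
            if idx.size and (idx.min() < 0 or idx.max() >= self.n_atoms):
                raise SelectionError("selection indices out of range")
        return idx
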