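"""Element attribute table: masses and van der Waals radii.

Structure files rarely carry masses or vdW radii, so readers fill them from
this element-keyed table. The vdW radii are the Bondi set for the elements
that matter here; pore profiling depends on them, so they are declared (and
overridable) rather than inherited silently from an external tool.
"""

from __future__ import annotations

#: Atomic masses in Da.
MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
    "K": 39.098,
    "CL": 35.45,
    "NA": 22.990,
    "ZN": 65.38,
    "MG": 24.305,
    "CA": 40.078,
    "FE": 55.845,
}

#: van der Waals radii in Å.
VDW_RADII: dict[str, float] = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "ZN": 1.39,
    "P": 1.80,
    "K": 2.75,
    "CL": 1.75,
    "NA": 2.27,
    "MG": 1.73,
    "CA": 2.31,
    "FE": 1.63,
}


class UnknownElementError(KeyError):
    """Raised when an element has no entry in the attribute table."""


def normalize_element(symbol: str) -> str:
    """Canonical (upper-case, stripped) element symbol."""
    return symbol.strip().upper()


def element_from_atom_name(name: str) -> str:
    """Best-effort element guess from a PDB-style atom name.

    Two-letter element symbols (e.g. ZN, CL) are recognised when the full
    name matches; otherwise the first alphabetic character is taken, which
    is the PDB convention for protein/water atom names like CA, OW, 1HB.
    """
    stripped = name.strip().upper()
    if stripped in VDW_RADII:
        return stripped
    for ch in stripped:
        if ch.isalpha():
            return ch
    raise UnknownElementError(f"cannot infer element from atom name {name!r}")


def lookup(
    element: str,
    table: dict[str, float],
    what: str,
    overrides: dict[str, float] | None = None,
) -> float:
    key = normalize_element(element)
    if overrides and key in overrides:
        return overrides[key]
    try:
        return table[key]
    except KeyError:
        raise UnknownElementError(
            f"element {element!r} has no {what} in the attribute table; "
            f"supply an override instead of relying on a silent default"
        ) from None


def mass_of(element: str, overrides: dict[str, float] | None = None) -> float:
    return lookup(element, MASSES, "mass", overrides)


def vdw_radius_of(element: str, overrides: dict[str, float] | None = None) -> float:
    return lookup(element, VDW_RADII, "vdW radius", overrides)
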