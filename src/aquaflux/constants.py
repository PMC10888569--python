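"""Physical constants and unit conventions.

All coordinates are angstroms (Å), times are picoseconds (ps), energies are
kJ/mol, charges are elementary charges (e), masses are daltons (Da).
"""

#: Boltzmann constant in kJ/(mol·K) (i.e. the molar gas constant R).
KB_KJ_PER_MOL_K = 0.00831446261815324

#: Default absolute temperature (K) for free-energy profiles.
DEFAULT_TEMPERATURE = 310.15


def kT(temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Thermal energy kT in kJ/mol at the given temperature in kelvin."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0 K, got {temperature}")
    return KB_KJ_PER_MOL_K * temperature
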