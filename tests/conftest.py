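"""Shared fixtures: small structures, seeded synthetic runs, toy assemblies."""

from __future__ import annotations

import numpy as np
import pytest

from aquaflux import (
    ChannelSimSpec,
    PoreCylinder,
    ToyAssemblySpec,
    Topology,
    flat_potential,
    make_toy_assembly,
    simulate_channel_waters,
)


def make_topology(n: int, chain: str = "A", element: str = "C",
                  charge: float = 0.0, vdw: float = 1.7) -> Topology:
    """Minimal n-atom topology for geometric tests."""
    return Topology(
        serial=np.arange(1, n + 1),
        name=np.array([f"X{i}" for i in range(n)], dtype=object),
        element=np.array([element] * n, dtype=object),
        resname=np.array(["RES"] * n, dtype=object),
        resid=np.arange(1, n + 1),
        chain=np.array([chain] * n, dtype=object),
        mass=np.full(n, 12.0),
        charge=np.full(n, charge),
        vdw_radius=np.full(n, vdw),
    )


@pytest.fixture(scope="session")
def flat_sim():
    """Flat-potential Brownian channel run reused across permeation tests."""
    spec = ChannelSimSpec(
        n_particles=100,
        potential=flat_potential(20.0),
        diffusion_coefficient=0.3,
        n_frames=2000,
        timestep=0.5,
        save_interval=5.0,
        seed=7,
    )
    return simulate_channel_waters(spec)


@pytest.fixture(scope="session")
def analysis_cylinder():
    return PoreCylinder(center=np.zeros(3), radius=15.0, half_length=15.0)


@pytest.fixture(scope="session")
def hourglass():
    """Four-chain hourglass scaffold with a 1.2 Å waist at z=0."""
    z = np.arange(-5.0, 5.01, 0.5)
    r = 4.0 - 2.8 * np.exp(-(z**2) / (2 * 2.0**2))
    return make_toy_assembly(
        ToyAssemblySpec(cavity_profile=(z, r), n_chains=4, atom_spacing=1.0,
                        atom_vdw=1.0, seed=0)
    )
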