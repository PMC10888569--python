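# aquaflux

Trajectory analysis of water permeation through channel proteins such as
aquaporins, for structural biologists and molecular-modelling groups who
want the full analysis protocol — event counting, free-energy profiles,
pore geometry, structural observables and the replicate statistics — as
one tested, scriptable package instead of a collection of one-off tools.

Aquaporins conduct water in single file through an hourglass-shaped pore;
tiny (~0.5 Å) changes at the aromatic/arginine constriction are enough to
modulate the channel's water permeability, e.g. when divalent cations
bind at sub-unit interfaces. Detecting such effects from molecular
dynamics trajectories requires a precise, reproducible chain of analyses,
which this package implements:

- **Permeation counting.** One permeation event is one water crossing the
  whole transmembrane pore section: a cylinder of radius 15 Å and length
  30 Å centred on the centre of geometry of the alpha carbons of the two
  NPA-motif asparagines. A per-particle three-state machine (below /
  inside / above the cylinder, with radial and periodic-wrap resets)
  scores complete traversals and their direction.
- **Free-energy profiles by Boltzmann inversion.** The axial water
  density ρ(z) on 0.5 Å slices gives the Gibbs free energy
  `G(z) = −kT · ln(ρ(z)/ρ_bulk)` (kJ/mol, 310.15 K by default);
  zero-density slices are censored, never clamped.
- **Pore-radius profiles.** The largest probe sphere that fits at each
  axial position without overlapping atomic van der Waals spheres, found
  by simulated annealing of the probe centre in each slice plane.
- **Structural observables.** Least-squares superposition (RMSD/RMSF),
  minimal inter-group distances (with minimum-image convention),
  geometric hydrogen bonds (D–A ≤ 3.5 Å, H–D–A ≤ 30°), dipole moments of
  (possibly charged) selections, and the cosine of the angle between two
  observable vectors as their correlation coefficient.
- **Windowed-replicate statistics.** Trajectories are split into 10-ns
  sub-trajectories over all four sub-units (80 replicates per 200-ns
  condition, 20 per chain); Shapiro–Wilk and Levene gates select Student's
  t / ANOVA+Tukey or Mann–Whitney / pairwise rank-sum with Bonferroni.
- **Synthetic ground truth.** Seeded generators produce Brownian
  single-file water motion in a known 1D potential of mean force (its
  stationary density is exp(−U/kT) by construction), multi-chain ring
  scaffolds with an analytically known pore profile, and rigid-motion +
  noise trajectories with closed-form expected RMSF — so every analysis
  is validated against exact oracles.

I/O covers PDB, GRO (nm converted to Å), XYZ and DCD, with strict
reject-don't-repair parsing; results are tab-separated tables. A CLI
(`aquaflux simulate|permeation|fep|pore|metrics|stats|all`) orchestrates
the stages from a YAML config with a single root seed and writes a
provenance manifest.

## Worked example

```python
import numpy as np
from aquaflux import *

# Brownian waters in a channel with a 2 kT Gaussian barrier at the centre
z, U = gaussian_barrier_potential(2 * kT(), width=2.0, z_max=20.0)
spec = ChannelSimSpec(n_particles=100, potential=(z, U),
                      diffusion_coefficient=0.3, n_frames=4000,
                      timestep=0.5, save_interval=5.0, seed=1)
sim = simulate_channel_waters(spec)
traj = sim.production()                       # burn-in discarded

cylinder = PoreCylinder(center=np.zeros(3))   # radius 15 A, length 30 A
record = count_permeations(traj, cylinder, window=1000.0)
print(f"permeation events: {record.n_events} "
      f"(up {record.counts('up')}, down {record.counts('down')})")

density = water_density_profile(traj, cylinder)            # 0.5 A slices
fep = free_energy_profile(density, temperature=310.15)     # kJ/mol
position, height = max_barrier(fep)
print(f"highest free-energy barrier: {height:.2f} kJ/mol at z = {position:+.2f} A "
      f"(ground truth {2 * kT():.2f} kJ/mol at z = 0)")

flat = simulate_channel_waters(ChannelSimSpec(
    n_particles=100, potential=flat_potential(20.0), diffusion_coefficient=0.3,
    n_frames=4000, timestep=0.5, save_interval=5.0, seed=1))
open_counts = count_permeations(flat.production(), cylinder,
                                window=1000.0).per_window_counts
report = two_group_test(open_counts.astype(float),
                        record.per_window_counts.astype(float),
                        labels=("flat", "barrier"))
c = report.comparisons[0]
print(f"{report.test_used}: flat {open_counts.mean():.0f} vs barrier "
      f"{record.per_window_counts.mean():.0f} events/window, p = {c['p_raw']:.2e}")
```

Output:

```
permeation events: 526 (up 257, down 269)
highest free-energy barrier: 5.05 kJ/mol at z = +0.25 A (ground truth 5.16 kJ/mol at z = 0)
Mann-Whitney: flat 44 vs barrier 29 events/window, p = 6.21e-06
```

The simulated barrier of 2 kT (5.16 kJ/mol at 310.15 K) is recovered by
Boltzmann inversion at the right position; the same barrier measurably
and significantly suppresses the per-window permeation counts relative to
the flat (open) channel — the same direction-of-effect logic used to read
permeability changes off window-count comparisons between conditions.

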