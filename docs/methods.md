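# Methods

This note documents the models, conventions and numerical choices behind
aquaflux, and what the synthetic validation does and does not establish
about real molecular-dynamics data.

## Units and containers

Coordinates are Å, times ps, energies kJ/mol, charges elementary charges,
masses Da. GRO files (nm) are converted on read/write. Boxes are
orthorhombic only; triclinic cells are rejected explicitly, which keeps
minimum-image arithmetic trivially correct. A `Topology` (atom serials,
names, elements, residue and chain identity, masses, partial charges,
van der Waals radii) is shared by all frames of a `Trajectory`, a dense
`(n_frames, n_atoms, 3)` float64 array with strictly increasing,
uniformly spaced times. Masses and vdW radii missing from structure files
are filled from a declared element table (C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20, Zn 1.39 Å, Bondi set), overridable per call; an element absent
from the table is an error rather than a silent default, because pore
profiles depend on these radii. PDB/GRO/XYZ parsers are strict: malformed
mandatory fields raise an error naming the file line; nothing is
repaired. DCD I/O delegates to MDAnalysis and round-trips at float32
precision.

## Permeation counting

The analysis region is a cylinder of radius 15 Å and half-length 15 Å,
centred on the centre of geometry of the alpha carbons of the two
NPA-motif asparagines, axis +z unless overridden. For each candidate
particle the axial coordinate s = (r − center)·axis classifies frames
into LOW (s < −L/2), IN (|s| ≤ L/2 and radial distance ≤ R) and HIGH
(s > L/2). An event is scored when a particle last seen at one boundary
reaches the other having occupied only IN states in between. Two reset
rules make the classification deterministic frame by frame:

- leaving the cylinder radially while |s| ≤ L/2 clears the pending
  origin (a water that detours out of the pore mid-crossing may not
  complete an event; this is the strictest reading of "crossing the
  whole transmembrane section", and is a deliberate design choice);
- an apparent axial jump larger than half the box length is a periodic
  wrap, not a permeation, and clears the pending origin (standard
  minimum-image criterion).

A particle that starts inside the cylinder has no pending origin and
cannot score until it first reaches a boundary, which avoids counting
half-crossings at trajectory start. Per-chain attribution builds one
cylinder per chain from per-chain landmark selections. Events are
aggregated per 10-ns window (the default window, matching the save
interval bookkeeping of 1000 frames per window at 10 ps) and as per-frame
cumulative totals. Time reversal of a trajectory exactly swaps
up/down counts; rigid motions applied jointly to the system and the
cylinder leave counts unchanged. Both properties are asserted in tests.

## Free-energy profiles

The axial density ρ(z) is the per-frame mean count of in-cylinder waters
in 0.5 Å slices (the last slice is widened and flagged if the cylinder
length is not a multiple of the bin width). Boltzmann inversion gives

    G(z) = −kT · ln(ρ(z) / ρ_bulk),

reported in kJ/mol at T = 310.15 K by default (kT = 2.5786 kJ/mol), with
a kT-units toggle. ρ_bulk defaults to the mean count over the outermost
4 bins at each cylinder end — in these systems the cylinder ends sit in
the vestibules — and can be supplied explicitly. Zero-density bins are
censored (NaN, reported as NA) rather than clamped to an arbitrary cap,
and are excluded from the barrier search. The highest barrier is defined
as max G − min G over non-censored bins; with bulk-referenced profiles
whose minimum is the bulk level the two conventions coincide, and
max − min is robust to censored ends. On an analytic density
ρ = ρ_bulk·exp(−U/kT) the inversion recovers U to machine precision; on
sampled Brownian trajectories with ≥ 2×10⁶ retained samples the maximum
recovery error of a 2 kT Gaussian barrier is below 0.3 kJ/mol (measured
≈ 0.1 kJ/mol at 3.6×10⁶ samples).

## Pore-radius profiles

At each axial position (0.25 Å spacing by default) the profiler
maximises, over probe-centre positions in the slice plane, the quantity
min over atoms of (|probe − atom| − vdW). The optimiser is simulated
annealing: 1000 trial Gaussian moves starting from the previous slice's
optimum, move scale 0.5 Å and acceptance temperature 0.05 both halved
every 200 moves, proposals outside the cylinder rejected, followed by a
deterministic Nelder–Mead polish of the best point (with a wall penalty
so the polish cannot escape through gaps between atoms). Slices where
the best radius exceeds the cylinder radius are flagged open and excluded
from the constriction search. On the analytic ring scaffold the profile
is recovered to < 0.05 Å at every slice with zero spread across 10
annealing seeds. Inflating every vdW radius by δ shrinks each reported
radius by between 0 and δ (tested).

## Structural observables

Superposition is optimal least-squares rigid alignment (Kabsch, via
scipy's rotation machinery); selections of fewer than 3 atoms or with
collinear geometry are rejected. RMSF superposes every frame onto the
first via a fit selection, then reports per-atom fluctuation about the
mean structure; RMSD/RMSF default to alpha-carbon scope in the selection
language, with backbone or arbitrary scopes available. Minimal distances
are per-frame minima over all inter-group pairs, excluding identical
atoms, with optional minimum-image treatment. Hydrogen bonds use the
geometric criterion D–A ≤ 3.5 Å and H–D–A ≤ 30° (the referenced
GROMACS-style defaults, overridable); donor–hydrogen pairs are built by
covalent distance and a donor without a bonded hydrogen is an error at
selection build. The dipole moment of a selection is Σ qᵢ(rᵢ − r_com)
with r_com the selection's centre of mass (including any extra atoms such
as a bound Zn²⁺); for charged selections the dipole is origin-dependent,
so the reference convention is fixed and logged. The correlation between
two observable vectors (e.g. a chain's dipole moment and its arginine
CA→CZ axis) is the cosine of the angle between them after translation to
the origin and normalisation — exactly the stated convention, despite the
"Pearson" label such numbers often carry. Correlations can be computed
per frame (default) or on time-averaged vectors; both modes are exposed
because either reading is defensible.

## Statistical protocol

Per-frame observables are aggregated over non-overlapping 10-ns windows
(sum for event counts, mean for distances and H-bond counts); each
(chain, window) pair is one replicate, so a 200-ns tetramer trajectory
yields 80 replicates per condition and 20 per chain. Successive windows
are treated as independent replicates; this is the protocol's own
assumption, documented rather than defended — windows shorter than the
observable's autocorrelation time would overstate the effective sample
size. Before testing, Shapiro–Wilk normality per group and Levene
homoscedasticity across groups are gated at α = 0.05 (configurable). All
gates passing selects Student's t (2 groups) or one-way ANOVA with
Tukey's HSD (> 2); any failure selects Mann–Whitney (2 groups) or
all-pairs two-sample rank-sum with Bonferroni correction (> 2). The
"Wilcoxon" branch is interpreted as the two-sample rank-sum test because
the compared conditions are independent; a signed-rank test would require
a pairing the data structure does not establish. Mann–Whitney p-values
are exact (distribution enumeration) for combined n ≤ 20 without ties,
otherwise the normal approximation with tie and continuity corrections;
a fully degenerate comparison (all values equal) returns p = 1. The exact
branch agrees with exhaustive permutation enumeration to 1e-12 for all
group sizes ≤ 7, and the whole gated procedure holds its nominal 5% level
within ±1.5 points in a 2000-run null calibration at n = 80 per group.

## Synthetic generators and what they establish

`simulate_channel_waters` integrates overdamped (inertialess) Langevin
dynamics per particle by Euler–Maruyama: axial drift −D/kT·U′(z)·dt plus
noise of variance 2D·dt, with reflecting caps at ±z_extent and a
reflecting radial wall; x,y diffuse freely. Overdamped dynamics is chosen
because only the stationary law and crossing statistics matter to the
analyses, and its stationary density exp(−U/kT) is closed-form. Initial
states are drawn from that stationary law by inverse-CDF sampling, and
the first 10% of frames are additionally flagged as burn-in
(configurable); reflecting caps rather than periodic z give well-defined
bulk slices and cannot produce fake wrap-around permeations. A timestep
whose worst-case drift exceeds 0.5 Å is rejected with advice to reduce
it; defaults (D = 0.3 Å²/ps, bulk-water-like; dt = 0.2–0.5 ps) keep the
integrator's stationary bias well below the free-energy tolerance.
Waters are single-point particles except for the explicit 3-site
(TIP3P-geometry) fixtures emitted for hydrogen-bond tests.

`make_toy_assembly` stacks rings of single-element pseudo-atoms whose
centres sit at cavity_radius + vdW, divided azimuthally into chains. All
atoms of a ring are equidistant from any on-axis point, so the exact
largest-probe radius is min over rings of sqrt(R_k² + Δz²) − vdW, and the
on-axis point is optimal; this closed form is the pore-profiling oracle.
A cavity narrower than the ring-atom vdW radius is rejected.
`perturb_trajectory` applies per-frame rigid transforms plus isotropic
Gaussian noise; superposition removes the rigid part, leaving expected
per-atom RMSF of σ·sqrt(3(1 − 1/n)).

These generators reproduce the statistical structure the analyses assume
— equilibrium single-file occupancy set by a 1D potential, a known cavity
geometry, known rigid/thermal motion — but not force-field physics,
water–water interactions, membranes or electrostatics. Passing tests
therefore establish the correctness of the analysis chain (counting,
inversion, profiling, statistics), not the realism of any particular MD
system; applied to real trajectories the package measures, it does not
simulate.

## Problem sizes used in validation

Free-energy recovery uses 500 particles × 8000 frames (3.6×10⁶ retained
samples, ≈ 4 s); the direction-of-effect comparison uses 30 particles ×
30 ns × 5 seeds per condition (15 window replicates each); pore profiling
uses a 21-ring, 4-chain hourglass over 10 Å at 0.25 Å slices and 10
annealing seeds; the null calibration uses 2000 simulated studies. These
sizes were chosen so each check is decisively stronger than its tolerance
while the whole suite remains a desk-scale computation.

## Known limitations

- Orthorhombic boxes only; no XTC/TRR or bonded-topology formats.
- Permeation semantics forbid completing an event after a radial detour;
  trajectories saved at intervals long relative to the crossing time will
  undercount regardless of semantics.
- The pore profiler reports in-plane probe optima (no spherical end
  detection or conductance estimates).
- No autocorrelation-aware alternatives (block bootstrap) to the
  window-independence assumption; no effect sizes or equivalence tests.
- Osmotic/diffusive permeability coefficients (p_f, p_d) are out of
  scope; the package reports raw counts.
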